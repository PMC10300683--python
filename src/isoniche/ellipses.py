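"""Bivariate standard ellipses in (δ¹³C, δ¹⁵N) space.

The *standard ellipse* of a bivariate sample is the c = 1 Mahalanobis
contour of its covariance; it encloses ≈ 40% of bivariate-normal data and
its area

.. math:: \\mathrm{SEA} = \\pi \\sqrt{\\det \\hat\\Sigma}

is the conventional bivariate isotopic-niche width.  The small-sample
corrected area is SEAc = SEA·(n−1)/(n−2).  The Bayesian analogue (SEAb)
summarises the posterior of Σ under a vague conjugate
Normal–Inverse-Wishart prior, sampled directly (no MCMC required).

Ellipse–ellipse overlap area is computed by clipping fine polygonal
boundaries (Sutherland–Hodgman on convex polygons) and applying the
shoelace formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import polygon_area

__all__ = [
    "GroupEllipse",
    "PosteriorEllipse",
    "NIWPrior",
    "ml_ellipse",
    "bayesian_ellipse",
    "ellipse_boundary",
    "ellipse_overlap",
]


@dataclass
class GroupEllipse:
    """Maximum-likelihood standard ellipse of one group.

    ``mu`` is the (δ¹³C, δ¹⁵N) centroid (‰); ``Sigma`` the 2×2 sample
    covariance (‰², n−1 denominator).
    """

    label: str
    n: int
    mu: np.ndarray
    Sigma: np.ndarray

    @property
    def SEA(self) -> float:
        return float(np.pi * np.sqrt(np.linalg.det(self.Sigma)))

    @property
    def SEAc(self) -> float:
        if self.n <= 2:
            raise ValueError("SEAc requires n > 2")
        return self.SEA * (self.n - 1) / (self.n - 2)


@dataclass
class PosteriorEllipse:
    """Posterior draws of (μ, Σ) and the derived SEA distribution.

    ``SEAb_mode`` is the kernel-density mode of the SEA draws (the
    conventional Bayesian point summary); the median and a 95% credible
    interval are carried alongside.
    """

    label: str
    n: int
    mu_draws: np.ndarray       # (m, 2)
    Sigma_draws: np.ndarray    # (m, 2, 2)
    SEA_draws: np.ndarray      # (m,)
    seed: int | None

    @property
    def n_draws(self) -> int:
        return len(self.SEA_draws)

    @property
    def SEAb_mode(self) -> float:
        kde = stats.gaussian_kde(self.SEA_draws)
        lo, hi = self.SEA_draws.min(), self.SEA_draws.max()
        grid = np.linspace(lo, hi, 1024)
        return float(grid[np.argmax(kde(grid))])

    @property
    def SEAb_median(self) -> float:
        return float(np.median(self.SEA_draws))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.SEA_draws, [a, 1.0 - a])
        return float(lo), float(hi)

    @property
    def posterior_mean_mu(self) -> np.ndarray:
        return self.mu_draws.mean(axis=0)

    @property
    def posterior_mean_Sigma(self) -> np.ndarray:
        return self.Sigma_draws.mean(axis=0)


@dataclass(frozen=True)
class NIWPrior:
    """Normal–Inverse-Wishart prior: μ | Σ ~ N(mu0, Σ/kappa0), Σ ~ IW(nu0, Psi).

    Defaults are vague: a near-flat location prior (kappa0 = 10⁻³, giving
    prior variance 10³·Σ for μ) and the minimal proper Inverse-Wishart
    (nu0 = 2 = dim, identity scale).
    """

    mu0: tuple[float, float] = (0.0, 0.0)
    kappa0: float = 1e-3
    nu0: float = 2.0
    psi: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))


def _points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N)")
    return pts


def ml_ellipse(points, label: str = "") -> GroupEllipse:
    """Standard ellipse from the sample mean and covariance.

    Requires n ≥ 3 non-collinear points (positive-definite covariance).
    """
    pts = _points(points)
    n = len(pts)
    if n < 3:
        raise ValueError(f"group {label!r}: need >= 3 points, got {n}")
    mu = pts.mean(axis=0)
    Sigma = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(Sigma) <= 0:
        raise ValueError(f"group {label!r}: degenerate (collinear) point cloud")
    return GroupEllipse(label=label, n=n, mu=mu, Sigma=Sigma)


def bayesian_ellipse(
    points,
    prior: NIWPrior | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
    label: str = "",
) -> PosteriorEllipse:
    """Direct conjugate sampling of the (μ, Σ) posterior.

    The Normal–Inverse-Wishart prior is conjugate for i.i.d. bivariate
    normal data, so the posterior is again NIW with

    .. math::

        \\kappa_n = \\kappa_0 + n, \\quad \\nu_n = \\nu_0 + n, \\quad
        \\mu_n = (\\kappa_0 \\mu_0 + n \\bar y)/\\kappa_n,

        \\Psi_n = \\Psi_0 + S +
        \\frac{\\kappa_0 n}{\\kappa_n}(\\bar y-\\mu_0)(\\bar y-\\mu_0)^T

    with ``S`` the centred scatter matrix; draws are taken exactly
    (Σ ~ IW(ν_n, Ψ_n), then μ | Σ ~ N(μ_n, Σ/κ_n)).
    """
    pts = _points(points)
    n = len(pts)
    if n < 3:
        raise ValueError(f"group {label!r}: need >= 3 points, got {n}")
    if np.linalg.det(np.cov(pts, rowvar=False, ddof=1)) <= 0:
        raise ValueError(f"group {label!r}: singular sample covariance")
    if n_draws < 1000:
        warnings.warn(f"n_draws={n_draws} < 1000; SEAb summaries will be noisy", stacklevel=2)
    prior = prior or NIWPrior()

    ybar = pts.mean(axis=0)
    S = (pts - ybar).T @ (pts - ybar)
    mu0 = np.asarray(prior.mu0, dtype=float)
    psi0 = np.asarray(prior.psi, dtype=float)
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    mu_n = (prior.kappa0 * mu0 + n * ybar) / kappa_n
    dev = (ybar - mu0)[:, None]
    psi_n = psi0 + S + (prior.kappa0 * n / kappa_n) * (dev @ dev.T)

    rng = np.random.default_rng(seed)
    Sigma_draws = stats.invwishart.rvs(df=nu_n, scale=psi_n, size=n_draws, random_state=rng)
    Sigma_draws = np.asarray(Sigma_draws).reshape(n_draws, 2, 2)
    z = rng.standard_normal((n_draws, 2))
    chol = np.linalg.cholesky(Sigma_draws / kappa_n)
    mu_draws = mu_n + np.einsum("nij,nj->ni", chol, z)
    sea = np.pi * np.sqrt(np.linalg.det(Sigma_draws))
    return PosteriorEllipse(
        label=label, n=n, mu_draws=mu_draws, Sigma_draws=Sigma_draws,
        SEA_draws=sea, seed=seed,
    )


def ellipse_boundary(e: GroupEllipse, n_vertices: int = 4096, scale: float = 1.0) -> np.ndarray:
    """Counter-clockwise polygon approximating the ellipse boundary.

    Vertices are μ + √c · L(cos θ, sin θ) on a uniform θ grid, with L the
    Cholesky factor of Σ and c = ``scale``² ... strictly, ``scale`` is the
    Mahalanobis radius c of the contour (1 = standard ellipse).  The
    polygon area converges to c²·SEA as ``n_vertices`` grows.
    """
    if n_vertices < 16:
        raise ValueError("n_vertices must be >= 16")
    L = np.linalg.cholesky(e.Sigma)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    return (e.mu[:, None] + scale * (L @ circle)).T


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Keep the part of convex polygon ``poly`` left of the directed line a→b."""
    ab = b - a
    d = ab[0] * (poly[:, 1] - a[1]) - ab[1] * (poly[:, 0] - a[0])
    inside = d >= 0.0
    if inside.all():
        return poly
    if not inside.any():
        return poly[:0]
    d_next = np.roll(d, -1)
    p_next = np.roll(poly, -1, axis=0)
    inside_next = d_next >= 0.0
    crossing = inside != inside_next
    denom = d - d_next
    t = np.where(crossing, d / np.where(denom == 0.0, 1.0, denom), 0.0)
    inter = poly + t[:, None] * (p_next - poly)

    counts = crossing.astype(int) + inside_next.astype(int)
    start = np.concatenate([[0], np.cumsum(counts)[:-1]])
    out = np.empty((counts.sum(), 2))
    out[start[crossing]] = inter[crossing]
    out[(start + crossing)[inside_next]] = p_next[inside_next]
    return out


def convex_polygon_intersection(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Intersection of two convex CCW polygons (Sutherland–Hodgman)."""
    out = p1
    n = len(p2)
    for i in range(n):
        out = _clip_halfplane(out, p2[i], p2[(i + 1) % n])
        if len(out) == 0:
            break
    return out


def ellipse_overlap(
    e1: GroupEllipse,
    e2: GroupEllipse,
    n_vertices: int = 4096,
    scale: float = 1.0,
    corrected: bool = False,
) -> float:
    """Area (‰²) of the intersection of two standard-ellipse interiors.

    ``corrected=True`` inflates each boundary to enclose SEAc instead of
    SEA (an alternative convention).  Symmetric in its arguments; bounded
    above by min(area₁, area₂); 0 for disjoint ellipses.
    """
    s1 = s2 = scale
    if corrected:
        s1 = scale * np.sqrt((e1.n - 1) / (e1.n - 2))
        s2 = scale * np.sqrt((e2.n - 1) / (e2.n - 2))
    b1 = ellipse_boundary(e1, n_vertices, s1)
    b2 = ellipse_boundary(e2, n_vertices, s2)
    inter = convex_polygon_intersection(b1, b2)
    if len(inter) < 3:
        return 0.0
    return polygon_area(inter, check_simple=False)
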