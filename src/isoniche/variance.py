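"""Univariate trophic-niche variance components: WIC, BIC, TNW, WIC/TNW.

Two estimation routes for the same decomposition of isotopic variation in
repeated-measures (multi-layer) data:

* **ANOVA** — sequential (Type I) sums of squares for ``δ ~ layer + turtle``;
  the within-individual component (WIC) is the residual mean square and the
  between-individual component (BIC) is the individual (turtle) mean square.
* **LMM** — a Gaussian random-intercept model ``δ ~ layer + (1 | turtle)``
  estimated by profiled REML (or ML); WIC is the residual variance σ²_w and
  BIC the random-intercept variance σ²_b.

Total niche width is TNW = WIC + BIC and WIC/TNW ∈ [0, 1] indexes
individual specialization (→ 0 specialists, → 1 generalists).

The mixed-model engine is written from first principles: the marginal
covariance of group *i* is σ²_w (I + λ J) with λ = σ²_b/σ²_w, inverted in
closed form via the Sherman–Morrison identity, and the (restricted)
likelihood is profiled down to a one-dimensional search over log λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import Isotope

__all__ = [
    "AnovaTable",
    "TrophicMetrics",
    "RandomInterceptModel",
    "RandomInterceptResults",
    "two_way_anova_ss",
    "anova_trophic_metrics",
    "fit_random_intercept",
    "lmm_trophic_metrics",
]

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# ANOVA route
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sequential (Type I) ANOVA decomposition.

    ``terms`` maps term name → (sum of squares ‰², degrees of freedom,
    mean square ‰²), in fitting order, with ``"residual"`` last.
    """

    terms: dict[str, tuple[float, int, float]]
    ss_total: float
    nobs: int

    def __getitem__(self, term: str) -> tuple[float, int, float]:
        return self.terms[term]

    def mean_square(self, term: str) -> float:
        return self.terms[term][2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, ss, df, ms) for t, (ss, df, ms) in self.terms.items()],
            columns=["term", "sum_sq", "df", "mean_sq"],
        )


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def two_way_anova_ss(
    values,
    layer=None,
    turtle=None,
    layer_as_factor: bool = False,
) -> AnovaTable:
    """Sequential SS for ``δ ~ layer + turtle`` (layer first, then turtle).

    ``layer`` enters as a numeric covariate (1 df) by default; set
    ``layer_as_factor=True`` for factor coding.  Pass ``layer=None`` for a
    one-way layout ``δ ~ turtle``.  Sequential SS are order-dependent in
    unbalanced layouts; the fitting order is fixed to match the model
    formula.
    """
    y = np.asarray(values, dtype=float)
    if turtle is None:
        raise ValueError("turtle group labels are required")
    codes, levels = pd.factorize(np.asarray(turtle))
    if len(levels) < 2:
        raise ValueError(f"need >= 2 individuals, got {len(levels)}")
    n = y.size
    ss_total = float(np.sum((y - y.mean()) ** 2))

    terms: dict[str, tuple[float, int, float]] = {}
    X = np.ones((n, 1))
    rss_prev = ss_total
    df_used = 1

    if layer is not None:
        lay = np.asarray(layer, dtype=float)
        if layer_as_factor:
            lcodes, llev = pd.factorize(lay)
            Xl = _dummies(lcodes, len(llev))
        else:
            Xl = (lay - lay.mean())[:, None]
        X = np.hstack([X, Xl])
        rss1 = _rss(X, y)
        df_l = Xl.shape[1]
        terms["layer"] = (rss_prev - rss1, df_l, (rss_prev - rss1) / df_l)
        rss_prev, df_used = rss1, df_used + df_l

    Xt = _dummies(codes, len(levels))
    X = np.hstack([X, Xt])
    rss2 = _rss(X, y)
    df_t = len(levels) - 1
    terms["turtle"] = (rss_prev - rss2, df_t, (rss_prev - rss2) / df_t)

    df_res = n - df_used - df_t
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need >= 2 rows per individual)")
    terms["residual"] = (rss2, df_res, rss2 / df_res)
    return AnovaTable(terms=terms, ss_total=ss_total, nobs=n)


# ---------------------------------------------------------------------------
# Trophic metrics container
# ---------------------------------------------------------------------------

@dataclass
class TrophicMetrics:
    """WIC/BIC/TNW/(WIC/TNW) for one isotope, one animal set, one estimator.

    All components are variances (‰²); the ratio is dimensionless.  When the
    total width is zero the ratio is undefined and reported as NaN.
    """

    isotope: Isotope
    estimator: str  # "anova" | "lmm"
    WIC: float
    BIC: float
    n_turtles: int
    n_rows: int
    boundary: bool = False  # LMM variance estimate pinned at zero

    @property
    def TNW(self) -> float:
        return self.WIC + self.BIC

    @property
    def ratio(self) -> float:
        return self.WIC / self.TNW if self.TNW > 0 else float("nan")

    def as_dict(self) -> dict:
        return {
            "isotope": self.isotope.name,
            "estimator": self.estimator,
            "WIC": self.WIC,
            "BIC": self.BIC,
            "TNW": self.TNW,
            "ratio": self.ratio,
            "n_turtles": self.n_turtles,
            "n_rows": self.n_rows,
        }


def _analysis_arrays(scute: pd.DataFrame, isotope: Isotope):
    col = Isotope(isotope).column
    df = scute.dropna(subset=[col, "layer", "turtle_id"])
    return (
        df[col].to_numpy(dtype=float),
        df["layer"].to_numpy(dtype=float),
        df["turtle_id"].to_numpy(),
    )


def anova_trophic_metrics(
    scute: pd.DataFrame,
    isotope: Isotope,
    include_layer: bool = True,
    layer_as_factor: bool = False,
) -> TrophicMetrics:
    """ANOVA-route metrics from a filtered scute table.

    WIC = residual mean square, BIC = turtle mean square of the sequential
    decomposition of ``δ ~ layer + turtle``.
    """
    y, lay, tid = _analysis_arrays(scute, isotope)
    tab = two_way_anova_ss(
        y, lay if include_layer else None, tid, layer_as_factor=layer_as_factor
    )
    return TrophicMetrics(
        isotope=Isotope(isotope),
        estimator="anova",
        WIC=tab.mean_square("residual"),
        BIC=tab.mean_square("turtle"),
        n_turtles=int(pd.unique(tid).size),
        n_rows=y.size,
    )


# ---------------------------------------------------------------------------
# Random-intercept mixed model (profiled REML/ML)
# ---------------------------------------------------------------------------

@dataclass
class RandomInterceptResults:
    """Fit of ``y = X β + u_group + e`` with u ~ N(0, σ²_b), e ~ N(0, σ²_w)."""

    model: "RandomInterceptModel"
    params: np.ndarray          # fixed effects, order = model.exog_names
    sigma2_between: float       # σ²_b, random-intercept variance
    sigma2_within: float        # σ²_w, residual variance
    llf: float                  # maximized (restricted) log-likelihood
    method: str                 # "reml" | "ml"
    converged: bool
    boundary: bool              # σ²_b estimated at the zero boundary
    opt_trace: dict = field(default_factory=dict)

    @property
    def variance_ratio(self) -> float:
        return self.sigma2_between / self.sigma2_within if self.sigma2_within > 0 else np.inf

    def predict_group_means(self) -> pd.Series:
        """BLUP-shrunken group intercept deviations."""
        m = self.model
        lam = self.variance_ratio
        resid = m.endog - m.exog @ self.params
        sums = np.bincount(m.group_codes, weights=resid, minlength=m.n_groups)
        shrink = lam * m.group_sizes / (1.0 + lam * m.group_sizes)
        return pd.Series(shrink * sums / np.maximum(m.group_sizes, 1), index=m.group_levels)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Random-intercept mixed model",
            f"  method: {self.method.upper()}   groups: {m.n_groups}   obs: {m.nobs}",
            f"  converged: {self.converged}" + ("   (sigma2_between at boundary 0)" if self.boundary else ""),
            f"  log-likelihood: {self.llf:.4f}",
            "  fixed effects:",
        ]
        for name, b in zip(m.exog_names, self.params):
            lines.append(f"    {name:>10s}  {b: .6f}")
        lines += [
            "  variance components:",
            f"    between (sigma2_b)  {self.sigma2_between:.6f}",
            f"    within  (sigma2_w)  {self.sigma2_within:.6f}",
        ]
        return "\n".join(lines)


class RandomInterceptModel:
    """Gaussian linear mixed model with a single random intercept per group.

    Parameters
    ----------
    endog : array-like
        Response (δ values, ‰).
    groups : array-like
        Group (individual) labels, one per observation.
    exog : array-like or None
        Fixed-effect design matrix *without* intercept column; an intercept
        is always prepended.  ``None`` fits intercept only.
    exog_names : sequence of str, optional
        Names for the non-intercept columns.

    The profile of the (restricted) likelihood over the variance ratio
    λ = σ²_b/σ²_w is exploited: for fixed λ the GLS fixed effects and the
    scale σ²_w have closed forms, leaving a one-dimensional maximization
    over log λ.  For balanced one-way designs the REML maximizer matches
    the method-of-moments closed form max(0, (MS_between − MS_within)/k).
    """

    def __init__(self, endog, groups, exog=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        n = self.endog.size
        codes, levels = pd.factorize(np.asarray(groups))
        if len(levels) < 2:
            raise ValueError(f"need >= 2 groups, got {len(levels)}")
        self.group_codes = codes
        self.group_levels = levels
        self.n_groups = len(levels)
        self.group_sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        if exog is None:
            X = np.ones((n, 1))
            names = ["intercept"]
        else:
            Xr = np.atleast_2d(np.asarray(exog, dtype=float))
            if Xr.shape[0] != n:
                Xr = Xr.T
            X = np.hstack([np.ones((n, 1)), Xr])
            names = ["intercept"] + list(
                exog_names or [f"x{j}" for j in range(1, X.shape[1])]
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.exog = X
        self.exog_names = names
        self.nobs = n

    # -- profiled objective -------------------------------------------------

    def _gls_pieces(self, lam: float):
        """XᵀV⁻¹X, XᵀV⁻¹y, yᵀV⁻¹y and log|V| for V = I + λ Z Zᵀ."""
        X, y, codes, sizes = self.exog, self.endog, self.group_codes, self.group_sizes
        w = lam / (1.0 + lam * sizes)  # Sherman–Morrison weight per group
        Sx = np.vstack([
            np.bincount(codes, weights=X[:, j], minlength=self.n_groups)
            for j in range(X.shape[1])
        ])
        Sy = np.bincount(codes, weights=y, minlength=self.n_groups)
        XtVX = X.T @ X - (Sx * w) @ Sx.T
        XtVy = X.T @ y - (Sx * w) @ Sy
        ytVy = y @ y - np.sum(w * Sy * Sy)
        logdet_v = float(np.sum(np.log1p(lam * sizes)))
        return XtVX, XtVy, ytVy, logdet_v

    def _profile_neg2ll(self, lam: float, reml: bool):
        XtVX, XtVy, ytVy, logdet_v = self._gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        q = max(ytVy - beta @ XtVy, 1e-300)  # rᵀV⁻¹r
        n, p = self.nobs, self.exog.shape[1]
        if reml:
            dof = n - p
            s2 = q / dof
            sign, logdet_a = np.linalg.slogdet(XtVX)
            neg2 = dof * (_LOG_2PI + np.log(s2)) + logdet_v + logdet_a + dof
        else:
            s2 = q / n
            neg2 = n * (_LOG_2PI + np.log(s2)) + logdet_v + n
        return neg2, beta, s2

    def fit(self, method: str = "reml") -> RandomInterceptResults:
        """Maximize the (restricted) likelihood.

        Raises
        ------
        RuntimeError
            on optimizer failure; the exception message carries the last
            iterate and objective value.
        """
        method = method.lower()
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = method == "reml"

        def obj(log_lam: float) -> float:
            return self._profile_neg2ll(np.exp(log_lam), reml)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(-18.0, 18.0), method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        if not res.success:
            raise RuntimeError(
                f"variance-ratio optimization failed at log_lambda={res.x:.4g}, "
                f"objective={res.fun:.6g}: {res.message}"
            )
        lam = float(np.exp(res.x))
        neg2, beta, s2 = self._profile_neg2ll(lam, reml)
        # compare with the sigma2_between = 0 boundary
        neg2_0, beta_0, s2_0 = self._profile_neg2ll(0.0, reml)
        boundary = neg2_0 <= neg2 + 1e-10
        if boundary:
            lam, neg2, beta, s2 = 0.0, neg2_0, beta_0, s2_0
        return RandomInterceptResults(
            model=self,
            params=beta,
            sigma2_between=lam * s2,
            sigma2_within=s2,
            llf=-0.5 * neg2,
            method=method,
            converged=True,
            boundary=boundary,
            opt_trace={"log_lambda": float(res.x), "iterations": int(res.nfev)},
        )


def fit_random_intercept(
    values, layer=None, turtle=None, method: str = "reml"
) -> RandomInterceptResults:
    """Fit ``δ ~ layer + (1 | turtle)`` (or intercept-only if ``layer=None``)."""
    if turtle is None:
        raise ValueError("turtle group labels are required")
    exog = None if layer is None else np.asarray(layer, dtype=float)[:, None]
    model = RandomInterceptModel(
        values, turtle, exog=exog, exog_names=None if layer is None else ["layer"]
    )
    return model.fit(method=method)


def lmm_trophic_metrics(
    scute: pd.DataFrame,
    isotope: Isotope,
    include_layer: bool = True,
    method: str = "reml",
) -> TrophicMetrics:
    """LMM-route metrics: WIC = σ̂²_within, BIC = σ̂²_between."""
    y, lay, tid = _analysis_arrays(scute, isotope)
    fit = fit_random_intercept(y, lay if include_layer else None, tid, method=method)
    return TrophicMetrics(
        isotope=Isotope(isotope),
        estimator="lmm",
        WIC=fit.sigma2_within,
        BIC=fit.sigma2_between,
        n_turtles=int(pd.unique(tid).size),
        n_rows=y.size,
        boundary=fit.boundary,
    )


def trophic_metrics_table(
    scute: pd.DataFrame,
    estimators=("anova", "lmm"),
    group_by_lifestage: bool = True,
) -> pd.DataFrame:
    """Study-style summary: rows (all/adults/subadults × estimator), columns
    WIC/BIC/TNW/ratio per isotope."""
    subsets = {"all": scute}
    if group_by_lifestage and "lifestage" in scute.columns:
        for g in ("adult", "subadult"):
            sub = scute[scute["lifestage"] == g]
            if len(sub):
                subsets[g + "s"] = sub
    rows = []
    for est in estimators:
        fn = anova_trophic_metrics if est == "anova" else lmm_trophic_metrics
        for name, sub in subsets.items():
            row = {"estimator": est, "group": name}
            for iso, tag in ((Isotope.C13, "C"), (Isotope.N15, "N")):
                m = fn(sub, iso)
                row.update({
                    f"WIC_{tag}": m.WIC, f"BIC_{tag}": m.BIC,
                    f"TNW_{tag}": m.TNW, f"ratio_{tag}": m.ratio,
                })
            rows.append(row)
    return pd.DataFrame(rows)
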