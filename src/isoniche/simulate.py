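"""Synthetic repeated-measures isotope data with known ground truth.

The generator emulates a two-tissue stable-isotope study of a sea-turtle
foraging aggregation: a short-turnover tissue (epidermis, one measurement
per animal) and an inert archival tissue (scute keratin, one measurement
per milled layer, 4–18 layers per animal).  The data-generating model is a
random-intercept hierarchy:

.. math::

    b_i \\sim N_2(0, \\Sigma_B), \\qquad
    y_{ij} = \\mu_{g(i),t} + \\beta_{\\mathrm{size},t}(x_i - \\bar x_{g(i)})
             + b_i + \\beta_{\\mathrm{layer}} (j-1) + e_{ij}

with one latent bivariate (δ¹³C, δ¹⁵N) centroid deviation ``b_i`` per
animal shared across tissues, lifestage-specific tissue means
``μ_{g,t}``, a size (CCLmin) covariate centred within lifestage, a linear
layer drift for scute, and i.i.d. within-individual noise ``e`` (an AR(1)
option across layers exists but defaults to off).

Default parameter values reproduce the structure of the emulated study:
98 epidermis animals (53 adults of which 10 males, 45 subadults), 55 scute
animals (34 adults of which 6 males, 21 subadults), layer counts from a
rounded normal(10, 4) truncated to [4, 18], CCLmin from truncated normals
split at the 80 cm adult threshold, and tissue-level marginal moments
close to the emulated study's printed means and standard deviations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ADULT_CCLMIN_CM, classify_lifestage, classify_sex

__all__ = ["SimConfig", "SimTruth", "ConfigError", "default_config", "simulate_population"]

ISOTOPES = ("d13C", "d15N")
LIFESTAGES = ("adult", "subadult")
TISSUES = ("epidermis", "scute")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _iso_dict(d13C: float, d15N: float) -> dict[str, float]:
    return {"d13C": float(d13C), "d15N": float(d15N)}


@dataclass
class SimConfig:
    """All knobs of the synthetic population.

    Counts are animals; δ parameters are ‰; CCLmin parameters are cm.
    """

    # roster sizes (epidermis = full roster; scute animals are a subset)
    n_adults: int = 53
    n_subadults: int = 45
    n_adult_males: int = 10
    scute_adults: int = 34
    scute_subadults: int = 21
    scute_adult_males: int = 6

    # scute layer-count law: rounded normal truncated to [layer_min, layer_max]
    layer_mean: float = 10.0
    layer_sd: float = 4.0
    layer_min: int = 4
    layer_max: int = 18

    # lifestage-specific (δ13C, δ15N) means per tissue, ‰
    group_means: dict = field(default_factory=lambda: {
        "epidermis": {"adult": (-14.04, 6.91), "subadult": (-15.14, 8.50)},
        "scute": {"adult": (-15.89, 5.88), "subadult": (-16.71, 6.68)},
    })

    # between-individual (centroid) s.d. per isotope, ‰, and cross-isotope
    # correlation of the centroid deviations; within-lifestage values — the
    # lifestage mean contrast adds to the pooled between-animal variance
    sigma_between: dict = field(default_factory=lambda: _iso_dict(1.08, 1.33))
    rho_between: float = -0.30

    # within-individual s.d. per tissue and isotope, ‰ (scute: layer-to-layer
    # variation; epidermis: residual/measurement-scale variation)
    sigma_within: dict = field(default_factory=lambda: {
        "epidermis": _iso_dict(0.25, 0.31),
        "scute": _iso_dict(0.91, 1.01),
    })

    # linear drift across scute layers, ‰ per layer
    layer_slope: dict = field(default_factory=lambda: _iso_dict(0.02, -0.02))

    # size effect on the centroid, ‰ per cm CCLmin (centred within lifestage)
    size_slope: dict = field(default_factory=lambda: {
        "epidermis": _iso_dict(0.042, 0.0),
        "scute": _iso_dict(0.031, -0.041),
    })

    # CCLmin laws: truncated normals per lifestage, split at 80 cm
    ccl_mean: dict = field(default_factory=lambda: {"adult": 88.0, "subadult": 70.0})
    ccl_sd: dict = field(default_factory=lambda: {"adult": 7.0, "subadult": 7.0})
    ccl_bounds: dict = field(default_factory=lambda: {
        "adult": (ADULT_CCLMIN_CM, 105.8), "subadult": (53.6, ADULT_CCLMIN_CM),
    })

    # AR(1) correlation of within-individual noise across adjacent scute
    # layers; 0 = exchangeable residuals (the analysis models' assumption)
    ar1_rho: float = 0.0

    seed: int = 20160121

    def validate(self) -> "SimConfig":
        for name in ("n_adults", "n_subadults", "scute_adults", "scute_subadults"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0 <= self.n_adult_males <= self.n_adults):
            raise ConfigError("n_adult_males must be in [0, n_adults]")
        if not (0 <= self.scute_adult_males <= self.scute_adults):
            raise ConfigError("scute_adult_males must be in [0, scute_adults]")
        if self.scute_adults > self.n_adults or self.scute_subadults > self.n_subadults:
            raise ConfigError("scute counts cannot exceed roster counts")
        if not (1 <= self.layer_min <= self.layer_max):
            raise ConfigError("layer_min/layer_max must satisfy 1 <= min <= max")
        for iso in ISOTOPES:
            if self.sigma_between[iso] < 0:
                raise ConfigError(f"sigma_between[{iso}] must be >= 0")
            for t in TISSUES:
                if self.sigma_within[t][iso] < 0:
                    raise ConfigError(f"sigma_within[{t}][{iso}] must be >= 0")
        if not -1.0 <= self.rho_between <= 1.0:
            raise ConfigError("rho_between must be in [-1, 1]")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must be in (-1, 1)")
        for g in LIFESTAGES:
            lo, hi = self.ccl_bounds[g]
            if not (0 < lo < hi):
                raise ConfigError(f"ccl_bounds[{g}] must satisfy 0 < lo < hi")
            if self.ccl_sd[g] <= 0:
                raise ConfigError(f"ccl_sd[{g}] must be > 0")
        return self

    def scaled(self, factor: float) -> "SimConfig":
        """Copy with all roster counts multiplied by ``factor`` (for
        large-sample Monte Carlo checks)."""
        return replace(
            self,
            n_adults=int(round(self.n_adults * factor)),
            n_subadults=int(round(self.n_subadults * factor)),
            n_adult_males=int(round(self.n_adult_males * factor)),
            scute_adults=int(round(self.scute_adults * factor)),
            scute_subadults=int(round(self.scute_subadults * factor)),
            scute_adult_males=int(round(self.scute_adult_males * factor)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``centroids`` has one row per animal with its lifestage, CCLmin and the
    latent bivariate centroid deviation (``b_d13C``, ``b_d15N``).
    ``sigma2_between``/``sigma2_within`` are the realized (empirical, over
    the scute animals) variance components per isotope, against which
    estimator recovery is judged.
    """

    config: SimConfig
    centroids: pd.DataFrame
    sigma2_between: dict[str, float]
    sigma2_within: dict[str, float]
    size_slope: dict
    layer_slope: dict[str, float]
    seed: int


def default_config() -> SimConfig:
    """The study-structure configuration (see module docstring)."""
    return SimConfig().validate()


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _layer_counts(rng, cfg: SimConfig, size: int) -> np.ndarray:
    draws = np.rint(rng.normal(cfg.layer_mean, cfg.layer_sd, size=size))
    return np.clip(draws, cfg.layer_min, cfg.layer_max).astype(int)


def simulate_population(config: SimConfig | None = None, seed: int | None = None):
    """Generate one synthetic dataset.

    Parameters
    ----------
    config
        Simulation configuration; defaults to :func:`default_config`.
    seed
        Overrides ``config.seed`` when given.

    Returns
    -------
    (epidermis, scute, truth)
        Two tidy :class:`~pandas.DataFrame` tables (canonical columns) and
        a :class:`SimTruth`.  Identical config + seed give identical output.
    """
    cfg = (config or default_config()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    n = cfg.n_adults + cfg.n_subadults
    lifestage = np.array(["adult"] * cfg.n_adults + ["subadult"] * cfg.n_subadults)
    turtle_id = np.array([f"T{i + 1:03d}" for i in range(n)])

    ccl = np.empty(n)
    for g in LIFESTAGES:
        m = lifestage == g
        lo, hi = cfg.ccl_bounds[g]
        ccl[m] = _truncated_normal(rng, cfg.ccl_mean[g], cfg.ccl_sd[g], lo, hi, m.sum())
    assert all(classify_lifestage(c) == g for c, g in zip(ccl, lifestage))

    # first n_adult_males adults are males (adults are exchangeable here)
    tail_long = np.zeros(n, dtype=bool)
    tail_long[: cfg.n_adult_males] = True
    sex = np.array([classify_sex(g, t) for g, t in zip(lifestage, tail_long)])

    # latent centroid deviations, shared across tissues
    sb = np.array([cfg.sigma_between[i] for i in ISOTOPES])
    cov_b = np.array([
        [sb[0] ** 2, cfg.rho_between * sb[0] * sb[1]],
        [cfg.rho_between * sb[0] * sb[1], sb[1] ** 2],
    ])
    # eigh-based sampling tolerates semi-definite Σ (zero variances, |rho|=1)
    b = rng.multivariate_normal(np.zeros(2), cov_b, size=n, method="eigh")

    ccl_bar = {
        g: ccl[lifestage == g].mean() if (lifestage == g).any() else 0.0
        for g in LIFESTAGES
    }

    def centroid(tissue: str) -> np.ndarray:
        mu = np.array([cfg.group_means[tissue][g] for g in lifestage])
        slope = np.array([[cfg.size_slope[tissue][i] for i in ISOTOPES]])
        dx = (ccl - np.array([ccl_bar[g] for g in lifestage]))[:, None]
        return mu + slope * dx + b

    # --- epidermis: one row per animal -----------------------------------
    sw_epi = np.array([cfg.sigma_within["epidermis"][i] for i in ISOTOPES])
    epi_vals = centroid("epidermis") + rng.normal(0.0, 1.0, size=(n, 2)) * sw_epi
    epidermis = pd.DataFrame({
        "turtle_id": turtle_id,
        "tissue": "epidermis",
        "layer": np.nan,
        "d13C": epi_vals[:, 0],
        "d15N": epi_vals[:, 1],
        "cclmin": ccl,
        "lifestage": lifestage,
        "sex": sex,
    })

    # --- scute: subset of the roster, one row per layer -------------------
    adult_idx = np.flatnonzero(lifestage == "adult")
    sub_idx = np.flatnonzero(lifestage == "subadult")
    # keep the male fraction: males were placed first among adults
    scute_idx = np.concatenate([
        adult_idx[: cfg.scute_adult_males],
        adult_idx[cfg.n_adult_males: cfg.n_adult_males + cfg.scute_adults - cfg.scute_adult_males],
        sub_idx[: cfg.scute_subadults],
    ])
    n_layers = _layer_counts(rng, cfg, scute_idx.size)
    sc_centroid = centroid("scute")
    sw_sc = np.array([cfg.sigma_within["scute"][i] for i in ISOTOPES])
    lsl = np.array([cfg.layer_slope[i] for i in ISOTOPES])

    rows = []
    for k, i in enumerate(scute_idx):
        L = n_layers[k]
        layers = np.arange(1, L + 1)
        eps = rng.normal(0.0, 1.0, size=(L, 2))
        if cfg.ar1_rho != 0.0:
            r = cfg.ar1_rho
            for j in range(1, L):
                eps[j] = r * eps[j - 1] + np.sqrt(1 - r * r) * eps[j]
        vals = sc_centroid[i] + np.outer(layers - 1, lsl) + eps * sw_sc
        rows.append(pd.DataFrame({
            "turtle_id": turtle_id[i],
            "tissue": "scute",
            "layer": layers,
            "d13C": vals[:, 0],
            "d15N": vals[:, 1],
            "cclmin": ccl[i],
            "lifestage": lifestage[i],
            "sex": sex[i],
        }))
    scute = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=epidermis.columns)

    centroids = pd.DataFrame({
        "turtle_id": turtle_id,
        "lifestage": lifestage,
        "cclmin": ccl,
        "b_d13C": b[:, 0],
        "b_d15N": b[:, 1],
        "in_scute": np.isin(np.arange(n), scute_idx),
    })
    in_sc = centroids["in_scute"].to_numpy()
    truth = SimTruth(
        config=cfg,
        centroids=centroids,
        sigma2_between={
            iso: float(np.var(b[in_sc, j], ddof=1)) if in_sc.sum() > 1 else 0.0
            for j, iso in enumerate(ISOTOPES)
        },
        sigma2_within={iso: float(cfg.sigma_within["scute"][iso] ** 2) for iso in ISOTOPES},
        size_slope=cfg.size_slope,
        layer_slope=dict(cfg.layer_slope),
        seed=int(cfg.seed if seed is None else seed),
    )
    return epidermis, scute, truth
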