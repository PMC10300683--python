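"""Isotope–body-size trend models and their likelihood-ratio tests.

Epidermis (one measurement per animal): ordinary least squares
``δ ~ size`` tested against the intercept-only null via the Gaussian
deviance identity LRT = n·log(RSS₀/RSS₁), df = 1.

Scute (repeated measures): random-intercept mixed model
``δ ~ size + (1 | turtle)`` tested against ``δ ~ 1 + (1 | turtle)``.  The
reported slope comes from the REML fit; the likelihood-ratio test compares
ML fits, because restricted likelihoods are not comparable across fixed-
effect structures.  ``size`` is CCLmin in cm, so slopes are ‰ per cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Isotope
from .variance import RandomInterceptModel, RandomInterceptResults

__all__ = ["TrendFit", "ols_trend", "lmm_trend", "likelihood_ratio_test"]


@dataclass
class TrendFit:
    """A fitted size trend for one tissue × isotope."""

    tissue: str
    isotope: Isotope
    kind: str              # "ols" | "lmm"
    slope: float           # ‰ per cm CCLmin
    intercept: float       # ‰
    lrt_stat: float
    lrt_df: int
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "tissue": self.tissue, "isotope": self.isotope.name, "kind": self.kind,
            "slope": self.slope, "intercept": self.intercept,
            "lrt_stat": self.lrt_stat, "df": self.lrt_df, "p": self.p_value,
            "n": self.n,
        }


def likelihood_ratio_test(full, null, df: int = 1) -> tuple[float, int, float]:
    """LRT of nested Gaussian models: stat = 2(llf_full − llf_null), χ²_df p.

    ``full``/``null`` may be log-likelihood floats or fitted results
    carrying ``.llf``.  Both must be ML fits of the same data; REML fits
    with different fixed effects are rejected.
    """
    def _llf(obj):
        if isinstance(obj, RandomInterceptResults):
            if obj.method != "ml":
                raise ValueError("likelihood_ratio_test requires ML fits, got REML")
            return obj.llf
        return float(obj)

    if (
        isinstance(full, RandomInterceptResults)
        and isinstance(null, RandomInterceptResults)
        and full.model.nobs != null.model.nobs
    ):
        raise ValueError("full and null models were fit to different data")
    stat = 2.0 * (_llf(full) - _llf(null))
    p = float(stats.chi2.sf(max(stat, 0.0), df)) if stat > 0 else 1.0
    return float(stat), df, p


def ols_trend(values, size, tissue: str = "epidermis", isotope: Isotope = Isotope.C13) -> TrendFit:
    """Closed-form least-squares δ-on-size fit with Gaussian-deviance LRT."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(size, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("size is constant; slope is unidentifiable")
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    rss1 = float(np.sum((y - intercept - slope * x) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss1 == 0.0:
        stat, p = np.inf, 0.0
    else:
        stat = n * np.log(rss0 / rss1)
        p = float(stats.chi2.sf(stat, 1))
    return TrendFit(
        tissue=tissue, isotope=Isotope(isotope), kind="ols",
        slope=slope, intercept=intercept,
        lrt_stat=float(stat), lrt_df=1, p_value=p, n=n,
    )


def lmm_trend(scute: pd.DataFrame, isotope: Isotope, tissue: str = "scute") -> TrendFit:
    """Random-intercept size trend for repeated-measures (scute) data.

    The per-animal size covariate is constant across layers, so the slope
    is identified from between-animal contrasts while the random intercept
    absorbs residual individual differences.
    """
    col = Isotope(isotope).column
    df = scute.dropna(subset=[col, "cclmin", "turtle_id"])
    y = df[col].to_numpy(dtype=float)
    x = df["cclmin"].to_numpy(dtype=float)
    tid = df["turtle_id"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("size is constant; slope is unidentifiable")

    reml = RandomInterceptModel(y, tid, exog=x[:, None], exog_names=["size"]).fit("reml")
    full = RandomInterceptModel(y, tid, exog=x[:, None], exog_names=["size"]).fit("ml")
    null = RandomInterceptModel(y, tid, exog=None).fit("ml")
    stat, dof, p = likelihood_ratio_test(full, null, df=1)
    return TrendFit(
        tissue=tissue, isotope=Isotope(isotope), kind="lmm",
        slope=float(reml.params[1]), intercept=float(reml.params[0]),
        lrt_stat=stat, lrt_df=dof, p_value=p, n=y.size,
    )
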