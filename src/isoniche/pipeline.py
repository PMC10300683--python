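"""End-to-end analysis pipeline.

One :class:`RunConfig` drives the whole analysis: ingest (or simulate) the
epidermis and scute tables, apply the scute filters, and produce

* a trophic-niche metrics table (ANOVA and LMM routes, per isotope, for
  all animals and per lifestage),
* per-lifestage epidermis standard ellipses (ML + Bayesian) and their
  maximum-likelihood overlap,
* Layman community metrics over per-animal scute centroids within each
  lifestage community,
* size-trend fits (OLS for epidermis, random-intercept LMM for scute),
* biplot figures and a JSON manifest recording seed, filters and row
  counts at every stage.

Grouping conventions: for epidermis, lifestages are the groups of a single
community; for scute, individual animals are the groups and lifestages the
communities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import convex_hull, layman_metrics
from .ellipses import GroupEllipse, bayesian_ellipse, ellipse_overlap, ml_ellipse
from .io import Isotope, filter_scute_samples, read_samples, validate_samples
from .simulate import SimConfig, default_config, simulate_population
from .trends import lmm_trend, ols_trend
from .variance import trophic_metrics_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisRun", "run_analysis", "make_biplots"]

_ISO_TAGS = ((Isotope.C13, "C"), (Isotope.N15, "N"))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    simulate: bool = True
    sim: SimConfig | None = None          # used when simulate=True
    epidermis_path: str | None = None     # used when simulate=False
    scute_path: str | None = None
    outdir: str = "isoniche_out"
    seed: int = 0
    draws: int = 10_000                   # posterior draws per group
    estimators: tuple[str, ...] = ("anova", "lmm")
    bayesian_centroids: bool = False      # posterior-mean scute centroids
    rounding: int = 2                     # decimals in serialized tables
    make_figures: bool = True

    def __post_init__(self):
        if self.simulate and (self.epidermis_path or self.scute_path):
            raise ValueError("set either simulate=True or input paths, not both")
        if not self.simulate and not (self.epidermis_path and self.scute_path):
            raise ValueError("input paths required when simulate=False")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            base = dataclasses.asdict(default_config())
            base.update(sim)
            cfg.sim = SimConfig(**base).validate()
        return cfg


@dataclass
class AnalysisRun:
    """In-memory results of one pipeline run."""

    config: RunConfig
    epidermis: pd.DataFrame
    scute: pd.DataFrame
    exclusions: pd.DataFrame
    trophic: pd.DataFrame
    ellipse_stats: pd.DataFrame
    overlap: pd.DataFrame
    layman: pd.DataFrame
    size_trends: pd.DataFrame
    ml_ellipses: dict[str, GroupEllipse]
    scute_centroids: pd.DataFrame
    manifest: dict
    figures: list[str] = field(default_factory=list)


def _round_floats(df: pd.DataFrame, nd: int) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(nd)
    return out


def scute_group_centroids(
    scute: pd.DataFrame, bayesian: bool = False, draws: int = 2000, seed: int | None = None
) -> pd.DataFrame:
    """Per-animal (δ¹³C, δ¹⁵N) centroids of scute layers.

    With ``bayesian=True`` the centroid is the posterior mean of μ under
    the conjugate ellipse model (asymptotically identical to the sample
    mean; requires ≥ 3 layers per animal).
    """
    rows = []
    for i, (tid, grp) in enumerate(scute.groupby("turtle_id", sort=True)):
        pts = grp[["d13C", "d15N"]].to_numpy(dtype=float)
        if bayesian and len(pts) >= 3:
            post = bayesian_ellipse(
                pts, n_draws=draws, label=str(tid),
                seed=None if seed is None else seed + i,
            )
            c = post.posterior_mean_mu
        else:
            c = pts.mean(axis=0)
        rows.append({
            "turtle_id": tid, "lifestage": grp["lifestage"].iloc[0],
            "d13C": c[0], "d15N": c[1], "n_layers": len(pts),
        })
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig, outdir: str | Path | None = None) -> AnalysisRun:
    """Execute the full pipeline; deterministic under a fixed seed.

    Writes tables, figures and ``manifest.json`` under ``outdir`` (defaults
    to ``config.outdir``) and returns the in-memory bundle.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest ----------------------------------------------------------
    if config.simulate:
        sim_cfg = config.sim or default_config()
        epidermis, scute_raw, _truth = simulate_population(sim_cfg, seed=config.seed)
    else:
        epidermis = read_samples(config.epidermis_path, tissue="epidermis")
        scute_raw = read_samples(config.scute_path, tissue="scute")
    validate_samples(epidermis)
    n_scute_raw = scute_raw["turtle_id"].nunique()

    scute, exclusions = filter_scute_samples(scute_raw)
    validate_samples(scute)

    # --- univariate trophic metrics --------------------------------------
    trophic = trophic_metrics_table(scute, estimators=config.estimators)

    # --- epidermis ellipses (groups = lifestages, one community) ----------
    ml: dict[str, GroupEllipse] = {}
    ell_rows = []
    for k, (g, grp) in enumerate(sorted(epidermis.groupby("lifestage"))):
        pts = grp[["d13C", "d15N"]].to_numpy(dtype=float)
        e = ml_ellipse(pts, label=g)
        post = bayesian_ellipse(
            pts, n_draws=config.draws, seed=config.seed + 1000 + k, label=g
        )
        lo, hi = post.credible_interval(0.95)
        ml[g] = e
        ell_rows.append({
            "group": g, "n": e.n, "mu_C": e.mu[0], "mu_N": e.mu[1],
            "SEA": e.SEA, "SEAc": e.SEAc,
            "SEAb_mode": post.SEAb_mode, "SEAb_median": post.SEAb_median,
            "ci_lo": lo, "ci_hi": hi, "n_draws": post.n_draws,
        })
    ellipse_stats = pd.DataFrame(ell_rows)

    ov_rows = []
    groups = sorted(ml)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            ov_rows.append({
                "group1": g1, "group2": g2,
                "overlap_ml": ellipse_overlap(ml[g1], ml[g2]),
                "overlap_seac": ellipse_overlap(ml[g1], ml[g2], corrected=True),
            })
    overlap = pd.DataFrame(ov_rows, columns=["group1", "group2", "overlap_ml", "overlap_seac"])

    # --- scute Layman metrics (groups = animals, communities = lifestages) -
    centroids = scute_group_centroids(
        scute, bayesian=config.bayesian_centroids,
        draws=min(config.draws, 2000), seed=config.seed + 2000,
    )
    lay_rows = []
    for g, grp in sorted(centroids.groupby("lifestage")):
        m = layman_metrics(grp[["d13C", "d15N"]].to_numpy(dtype=float))
        lay_rows.append({"community": g + "s", **m.as_dict()})
    layman = pd.DataFrame(lay_rows)

    # --- size trends -------------------------------------------------------
    trend_rows = []
    for iso, _tag in _ISO_TAGS:
        epi = epidermis.dropna(subset=[iso.column, "cclmin"])
        trend_rows.append(
            ols_trend(epi[iso.column], epi["cclmin"], tissue="epidermis", isotope=iso).as_dict()
        )
        trend_rows.append(lmm_trend(scute, iso).as_dict())
    size_trends = pd.DataFrame(trend_rows)

    # --- serialize ---------------------------------------------------------
    nd = config.rounding
    _round_floats(trophic, nd).to_csv(out / "trophic_metrics.csv", index=False)
    _round_floats(ellipse_stats, nd).to_csv(out / "ellipses.csv", index=False)
    _round_floats(overlap, nd).to_csv(out / "ellipse_overlap.csv", index=False)
    _round_floats(layman, nd).to_csv(out / "layman_metrics.csv", index=False)
    size_trends.round({"slope": 3, "intercept": 3, "lrt_stat": 2, "p": 4}).to_csv(
        out / "size_trends.csv", index=False)
    exclusions.to_csv(out / "scute_exclusions.csv", index=False)

    manifest = {
        "isoniche_version": __version__,
        "seed": int(config.seed),
        "mode": "simulate" if config.simulate else "files",
        "draws": int(config.draws),
        "counts": {
            "epidermis_analyzed": int(epidermis["turtle_id"].nunique()),
            "scute_before_filters": int(n_scute_raw),
            "scute_retained": int(scute["turtle_id"].nunique()),
            "scute_rows": int(len(scute)),
            "exclusions": exclusions.to_dict("records"),
        },
        "filters": ["min_layers>=4", "recapture_duplicate"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    run = AnalysisRun(
        config=config, epidermis=epidermis, scute=scute, exclusions=exclusions,
        trophic=trophic, ellipse_stats=ellipse_stats, overlap=overlap,
        layman=layman, size_trends=size_trends, ml_ellipses=ml,
        scute_centroids=centroids, manifest=manifest,
    )
    if config.make_figures:
        run.figures = make_biplots(run, out)
    return run


_GROUP_COLORS = {"adult": "#1f6f8b", "subadult": "#e07b39"}


def make_biplots(run: AnalysisRun, outdir: str | Path) -> list[str]:
    """δ¹³C–δ¹⁵N biplots: epidermis with group ellipses, scute centroids
    with community convex hulls.  Writes PNG (raster) and PDF (vector)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(outdir)
    paths: list[str] = []
    from .ellipses import ellipse_boundary

    fig, ax = plt.subplots(figsize=(6, 5))
    for g, grp in sorted(run.epidermis.groupby("lifestage")):
        if len(grp) == 0:
            logger.warning("empty epidermis group %s omitted from biplot", g)
            continue
        c = _GROUP_COLORS.get(g, "grey")
        ax.scatter(grp["d13C"], grp["d15N"], s=14, alpha=0.6, color=c, label=g)
        if g in run.ml_ellipses:
            b = ellipse_boundary(run.ml_ellipses[g], n_vertices=256)
            ax.plot(np.append(b[:, 0], b[0, 0]), np.append(b[:, 1], b[0, 1]), color=c)
    ax.set_xlabel("δ13C (‰)")
    ax.set_ylabel("δ15N (‰)")
    ax.legend(title="lifestage")
    ax.set_title("Epidermis with standard ellipses")
    for ext in ("png", "pdf"):
        p = out / f"biplot_epidermis.{ext}"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(str(p))
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    for g, grp in sorted(run.scute_centroids.groupby("lifestage")):
        if len(grp) == 0:
            logger.warning("empty scute community %s omitted from biplot", g)
            continue
        c = _GROUP_COLORS.get(g, "grey")
        pts = grp[["d13C", "d15N"]].to_numpy(dtype=float)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=c, label=g + "s")
        if len(pts) >= 3:
            h = convex_hull(pts)
            ax.plot(np.append(h[:, 0], h[0, 0]), np.append(h[:, 1], h[0, 1]),
                    color=c, linestyle="--")
    ax.set_xlabel("δ13C (‰)")
    ax.set_ylabel("δ15N (‰)")
    ax.legend(title="community")
    ax.set_title("Scute animal centroids with community hulls")
    for ext in ("png", "pdf"):
        p = out / f"biplot_scute.{ext}"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(str(p))
    plt.close(fig)
    return paths
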