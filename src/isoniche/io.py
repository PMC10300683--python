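"""Reading, validation and filtering of tidy stable-isotope sample tables.

The central container is a plain :class:`pandas.DataFrame` in long format
("one row per measurement"): epidermis tables carry one row per turtle,
scute tables one row per turtle per keratin layer.  Column names are
configurable through :class:`SampleSchema`; the canonical names are

``turtle_id, tissue, layer, d13C, d15N, cclmin, lifestage, sex, capture_date``

δ values are per-mil (‰) relative to VPDB (carbon) and AT-Air (nitrogen).
``cclmin`` is the minimum curved carapace length in centimetres, the
standard in-water proxy for lifestage in hard-shelled sea turtles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Isotope",
    "SampleSchema",
    "DeltaValue",
    "delta_from_ratios",
    "classify_lifestage",
    "classify_sex",
    "validate_samples",
    "filter_scute_samples",
    "read_samples",
    "write_samples",
    "ADULT_CCLMIN_CM",
    "MIN_SCUTE_LAYERS",
]

#: CCLmin threshold (cm) separating subadults (<) from adults (>=).
ADULT_CCLMIN_CM = 80.0

#: Minimum number of scute layers for a sample to enter the analysis.
MIN_SCUTE_LAYERS = 4

# plausibility windows for marine-consumer keratin/epidermis; values outside
# trigger a warning, never a silent drop
_D13C_RANGE = (-30.0, -5.0)
_D15N_RANGE = (0.0, 20.0)


class Isotope(str, Enum):
    """The two isotope systems measured: δ¹³C and δ¹⁵N."""

    C13 = "d13C"
    N15 = "d15N"

    @property
    def column(self) -> str:
        return self.value


@dataclass(frozen=True)
class DeltaValue:
    """A δ value in per-mil (‰) for one isotope system."""

    value: float
    isotope: Isotope


@dataclass
class SampleSchema:
    """Column mapping for CSV input/output.

    Defaults follow the canonical tidy layout; override individual names to
    adapt to external files without rewriting them.
    """

    turtle_id: str = "turtle_id"
    tissue: str = "tissue"
    layer: str = "layer"
    d13C: str = "d13C"
    d15N: str = "d15N"
    cclmin: str = "cclmin"
    lifestage: str = "lifestage"
    sex: str = "sex"
    capture_date: str = "capture_date"
    #: columns that must be present in every input file
    required: Sequence[str] = field(
        default_factory=lambda: ("turtle_id", "tissue", "d13C", "d15N")
    )

    def rename_map(self) -> dict[str, str]:
        """Mapping from file column names to canonical names."""
        canonical = (
            "turtle_id", "tissue", "layer", "d13C", "d15N",
            "cclmin", "lifestage", "sex", "capture_date",
        )
        return {getattr(self, c): c for c in canonical}


def delta_from_ratios(r_sample: float, r_standard: float, isotope: Isotope) -> DeltaValue:
    """δX = (R_sample / R_standard − 1) × 1000, in per-mil.

    ``R`` is the heavy:light isotope ratio (¹⁵N:¹⁴N or ¹³C:¹²C) of the
    sample and of the international standard (AT-Air or VPDB).

    Raises
    ------
    ValueError
        if ``r_standard`` is not strictly positive or ``r_sample`` is
        negative.
    """
    if not np.isfinite(r_standard) or r_standard <= 0:
        raise ValueError(f"invalid standard ratio: {r_standard!r} (must be > 0)")
    if not np.isfinite(r_sample) or r_sample < 0:
        raise ValueError(f"invalid sample ratio: {r_sample!r} (must be >= 0)")
    return DeltaValue(value=(r_sample / r_standard - 1.0) * 1000.0, isotope=Isotope(isotope))


def classify_lifestage(cclmin: float) -> str:
    """Classify a turtle as ``"subadult"`` (CCLmin < 80 cm) or ``"adult"`` (≥ 80 cm)."""
    if not np.isfinite(cclmin) or cclmin <= 0:
        raise ValueError(f"cclmin must be positive and finite, got {cclmin!r}")
    return "subadult" if cclmin < ADULT_CCLMIN_CM else "adult"


def classify_sex(lifestage: str, tail_past_carapace: bool) -> str:
    """Sex from external morphology.

    Adults with tails extending past the carapace are males; all other
    adults are classified as females.  Subadults cannot be sexed externally
    and are recorded as ``"unknown"``.
    """
    if lifestage not in ("adult", "subadult"):
        raise ValueError(f"unknown lifestage {lifestage!r}")
    if lifestage == "subadult":
        return "unknown"
    return "male" if tail_past_carapace else "female"


def validate_samples(table: pd.DataFrame, tissue: str | None = None) -> pd.DataFrame:
    """Check invariants of a sample table; returns the table unchanged.

    Warns (never drops) on δ values outside typical marine-consumer windows
    and raises on duplicate ``(turtle_id, tissue, layer)`` keys or on
    lifestage labels inconsistent with the CCLmin rule.
    """
    for iso, (lo, hi) in ((Isotope.C13, _D13C_RANGE), (Isotope.N15, _D15N_RANGE)):
        vals = pd.to_numeric(table[iso.column], errors="coerce")
        bad = table.loc[vals.notna() & ((vals < lo) | (vals > hi))]
        if len(bad):
            warnings.warn(
                f"{len(bad)} {iso.column} values outside typical range [{lo}, {hi}] ‰",
                stacklevel=2,
            )
    key_cols = [c for c in ("turtle_id", "tissue", "layer") if c in table.columns]
    dup = table.duplicated(subset=key_cols)
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate sample keys on {key_cols}: "
            f"{table.loc[dup, key_cols].head().to_dict('records')}"
        )
    if "lifestage" in table.columns and "cclmin" in table.columns:
        both = table.dropna(subset=["lifestage", "cclmin"])
        expected = np.where(both["cclmin"] < ADULT_CCLMIN_CM, "subadult", "adult")
        mismatch = both.loc[both["lifestage"].to_numpy() != expected]
        if len(mismatch):
            raise ValueError(
                f"lifestage inconsistent with CCLmin {ADULT_CCLMIN_CM} cm rule for "
                f"turtles {sorted(mismatch['turtle_id'].unique())[:5]}"
            )
    if tissue is not None and "tissue" in table.columns:
        other = set(table["tissue"].unique()) - {tissue}
        if other:
            raise ValueError(f"expected tissue {tissue!r}, found also {sorted(other)}")
    return table


def filter_scute_samples(
    table: pd.DataFrame, min_layers: int = MIN_SCUTE_LAYERS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the scute analysis filters.

    Two rules:

    * turtles whose scute sample has fewer than ``min_layers`` milled layers
      are excluded (too short a time series);
    * for turtles sampled on more than one capture date, only the earliest
      capture's sample is retained (recapture duplicates excluded).

    Returns
    -------
    (filtered, exclusion_log)
        ``filtered`` is the retained table; ``exclusion_log`` has columns
        ``turtle_id, reason`` with one row per excluded sample
        (reasons ``"min_layers"`` and ``"recapture_duplicate"``).
    """
    log_rows: list[dict] = []
    if table.empty:
        warnings.warn("empty scute table passed to filter_scute_samples", stacklevel=2)
        return table.copy(), pd.DataFrame(columns=["turtle_id", "reason"])

    out = table.copy()
    # recapture de-duplication first: each (turtle, capture) is one sample
    if "capture_date" in out.columns and out["capture_date"].notna().any():
        dates = pd.to_datetime(out["capture_date"])
        first = dates.groupby(out["turtle_id"]).transform("min")
        dup_mask = dates > first
        for tid in out.loc[dup_mask, "turtle_id"].unique():
            log_rows.append({"turtle_id": tid, "reason": "recapture_duplicate"})
        out = out.loc[~dup_mask]

    layer_counts = out.groupby("turtle_id")["layer"].nunique()
    short = layer_counts.index[layer_counts < min_layers]
    for tid in short:
        log_rows.append({"turtle_id": tid, "reason": "min_layers"})
    out = out.loc[~out["turtle_id"].isin(short)].reset_index(drop=True)

    log = pd.DataFrame(log_rows, columns=["turtle_id", "reason"])
    if len(log):
        logger.info("filter_scute_samples excluded %d samples", len(log))
    return out, log


def read_samples(path, schema: SampleSchema | None = None, tissue: str | None = None) -> pd.DataFrame:
    """Read a tidy sample CSV into a canonical-column DataFrame.

    Malformed numeric cells (δ values, cclmin, layer) are coerced to NaN and
    reported with their row numbers; rows with missing δ values are kept in
    the table but flagged, so the caller decides whether to drop them from
    an analysis set.
    """
    schema = schema or SampleSchema()
    df = pd.read_csv(path)
    missing = [getattr(schema, c) for c in schema.required if getattr(schema, c) not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns in {path}: {missing}")
    df = df.rename(columns=schema.rename_map())
    for col in ("d13C", "d15N", "cclmin", "layer"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                logger.warning(
                    "%s: non-numeric %s at CSV rows %s", path, col, [int(i) + 2 for i in bad]
                )
            df[col] = coerced
    return validate_samples(df, tissue=tissue)


def write_samples(table: pd.DataFrame, path) -> None:
    """Write a sample table as UTF-8 CSV with header; full precision."""
    table.to_csv(path, index=False)
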