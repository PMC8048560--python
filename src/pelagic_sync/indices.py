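"""Standardized anomalies, encounter rates, and summary utilities.

Survey indices from disparate platforms (seabird strip transects, whale
counts, plankton nets) are made comparable by standardizing each series
to mean 0 and SD 1 within a grouping (by default season × region,
across years), with values beyond 2 SD flagged as unusual.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "flag_extremes",
    "encounter_rate",
    "percent_change",
    "seasonal_biomass_summary",
]


def standardize(
    df: pd.DataFrame,
    value_col: str = "value",
    group_cols: list[str] = ("season", "region"),
    out_col: str = "z",
) -> pd.DataFrame:
    """z = (x − mean) / SD within each group (sample SD, n−1).

    Groups with fewer than 2 values or zero SD are flagged: their z is
    NaN and ``z_flagged`` is True.
    """
    out = df.copy()
    grouped = out.groupby(list(group_cols))[value_col]
    mean = grouped.transform("mean").astype(float)
    sd = grouped.transform("std").astype(float)  # ddof=1
    count = grouped.transform("count")
    flagged = (count < 2) | ~np.isfinite(sd) | (sd == 0)
    if flagged.any():
        logger.warning(
            "%d rows in groups with zero/undefined SD flagged", int(flagged.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (out[value_col].astype(float) - mean) / sd
    out[out_col] = z.where(~flagged)
    out["z_flagged"] = flagged
    return out


def flag_extremes(z: np.ndarray | pd.Series, threshold: float = 2.0) -> np.ndarray:
    """Boolean flag where z exceeds the threshold (strict >)."""
    return np.asarray(z, dtype=float) > threshold


def encounter_rate(count: float, effort_km: float) -> float:
    """Individuals per km surveyed; the calf index (calves per adult)
    uses the same form.  Pool counts and effort before dividing — the
    rate over pooled segments is the pooled count over pooled effort,
    not the mean of per-segment rates."""
    if effort_km <= 0:
        raise ValueError("effort must be positive")
    return count / effort_km


def percent_change(first: float, second: float) -> float:
    """Percent decline from ``first`` to ``second``: 100 (first − second)/first.

    Positive for a decrease; e.g. 100 → 27 is a 73% decline."""
    if first <= 0:
        raise ValueError("first value must be positive")
    return 100.0 * (first - second) / first


def seasonal_biomass_summary(
    samples: pd.DataFrame,
    value_col: str = "biomass",
    group_cols: list[str] = ("region", "season", "year", "species"),
    known_regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean and sample SD of station-level biomass per group.

    Region labels are input metadata (e.g. Inner shelf < 50 km from
    shore, Middle shelf to the 1000 m isobath, Oceanic beyond); they are
    validated against ``known_regions`` when given, never recomputed
    from bathymetry.  Single-station groups report SD 0 with a flag.
    """
    if known_regions is not None:
        bad = set(samples["region"].unique()) - set(known_regions)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
    rows = []
    for keys, grp in samples.groupby(list(group_cols)):
        vals = grp[value_col].astype(float)
        single = len(vals) < 2
        rows.append(
            dict(
                zip(group_cols, keys if isinstance(keys, tuple) else (keys,)),
                mean_biomass=float(vals.mean()),
                sd_biomass=0.0 if single else float(vals.std(ddof=1)),
                n=len(vals),
                sd_flagged=single,
            )
        )
    return pd.DataFrame(rows)
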