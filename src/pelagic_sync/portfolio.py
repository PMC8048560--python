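"""Diet-based forage-fish availability indices and portfolio effects.

Frequency of occurrence ``F`` is the proportion of predator diet samples
in a year × feeding-guild cell that contain a given prey species.  The
variance ratio over a window of years,

    VR = var(sum_species F) / sum_species var(F),

equals 1 for uncorrelated species series, exceeds 1 under synchrony and
falls below 1 under compensation; the portfolio effect PE = 1 − VR, so
low PE flags a synchronized (unbuffered) forage community.  Sample
variance (n − 1) is used throughout; the ratio is invariant to that
convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GUILDS = ("diver", "surface")
DEFAULT_SPECIES = ("capelin", "sand_lance", "herring")

__all__ = [
    "frequency_of_occurrence",
    "variance_ratio",
    "rolling_portfolio_effect",
    "guild_correlation",
    "read_diet_csv",
    "DEFAULT_SPECIES",
    "GUILDS",
]


def read_diet_csv(path: str) -> pd.DataFrame:
    """Read a long-form diet table (``sample_id,year,guild,species,present``)."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "year", "guild", "species", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"diet table missing columns: {sorted(missing)}")
    return df


def frequency_of_occurrence(
    samples: pd.DataFrame, species: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per year × guild × species frequency of occurrence.

    ``samples`` is a long table with columns ``sample_id, year, guild,
    species, present`` (one row per sample × species; ``present`` is
    0/1).  Returns columns ``year, guild, species, F, n_samples``.
    """
    df = samples.copy()
    bad = set(df["guild"].unique()) - set(GUILDS)
    if bad:
        raise ValueError(f"unknown guild labels: {sorted(bad)}")
    if species is not None:
        df = df[df["species"].isin(species)]
    rows = []
    for (year, guild), grp in df.groupby(["year", "guild"], sort=True):
        n = grp["sample_id"].nunique()
        if n == 0:
            logger.warning("empty (year=%s, guild=%s) cell omitted", year, guild)
            continue
        present = grp[grp["present"].astype(bool)]
        counts = present.groupby("species")["sample_id"].nunique()
        sp_list = species if species is not None else sorted(grp["species"].unique())
        for sp in sp_list:
            rows.append(
                {
                    "year": int(year),
                    "guild": guild,
                    "species": sp,
                    "F": counts.get(sp, 0) / n,
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows)


def variance_ratio(series_by_species: dict[str, np.ndarray] | pd.DataFrame) -> float:
    """Variance of the summed series over the sum of per-species variances.

    Returns NaN when all per-species variances are zero (the statistic
    is undefined there; a constant community carries no synchrony
    information).
    """
    if isinstance(series_by_species, pd.DataFrame):
        mat = series_by_species.to_numpy(dtype=float)
    else:
        mat = np.column_stack([np.asarray(v, dtype=float) for v in series_by_species.values()])
    if mat.shape[1] < 2:
        raise ValueError("variance ratio needs >= 2 species")
    if mat.shape[0] < 2:
        raise ValueError("variance ratio needs a window of >= 2 years")
    if not np.all(np.isfinite(mat)):
        raise ValueError("variance ratio requires complete data in the window")
    var_sum = float(np.var(mat.sum(axis=1), ddof=1))
    sum_var = float(np.var(mat, axis=0, ddof=1).sum())
    # constant series produce rounding noise ~ (eps*x)^2, not exact zeros
    scale = float(np.max(np.abs(mat))) ** 2
    if sum_var <= 1e-25 * scale or scale == 0.0:
        return float("nan")
    return var_sum / sum_var


def rolling_portfolio_effect(
    freq: pd.DataFrame,
    window_len: int = 3,
    centered: bool = True,
    species: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Rolling variance-ratio portfolio effect per (center year, guild).

    A window contributes a row only when every window year has a
    frequency for every species (no zero imputation for absent
    species); windows with all per-species variances zero yield NaN.
    Returns ``center_year, guild, VR, PE, n_window_years``.
    """
    if centered and window_len % 2 == 0:
        raise ValueError("window_len must be odd for centered windows")
    if species is None:
        species = tuple(sorted(freq["species"].unique()))
    half = window_len // 2
    rows = []
    for guild, grp in freq.groupby("guild", sort=True):
        wide = grp.pivot_table(index="year", columns="species", values="F")
        wide = wide.reindex(columns=list(species))
        years = wide.index.to_numpy()
        if len(years) == 0:
            continue
        for cy in range(int(years.min()), int(years.max()) + 1):
            window = (
                list(range(cy - half, cy + half + 1))
                if centered
                else list(range(cy - window_len + 1, cy + 1))
            )
            sub = wide.reindex(window)
            if sub.isna().any().any():
                logger.info(
                    "window centered on %s (%s) skipped: incomplete years", cy, guild
                )
                continue
            vr = variance_ratio(sub)
            rows.append(
                {
                    "center_year": cy,
                    "guild": guild,
                    "VR": vr,
                    "PE": 1.0 - vr if np.isfinite(vr) else float("nan"),
                    "n_window_years": window_len,
                }
            )
    return pd.DataFrame(
        rows, columns=["center_year", "guild", "VR", "PE", "n_window_years"]
    )


def guild_correlation(
    series_a: pd.Series, series_b: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between two year-indexed series over shared
    years, with the two-sided p-value from the t transform."""
    shared = series_a.index.intersection(series_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared years for a correlation")
    a = series_a.loc[shared].to_numpy(dtype=float)
    b = series_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
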