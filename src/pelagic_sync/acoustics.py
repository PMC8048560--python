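"""Multifrequency acoustic classification and echo integration.

Fluid-like macrozooplankton (euphausiids) scatter relatively more sound
at 120 kHz than at 38 kHz, while swim-bladdered fish do not: the dB
difference dSv = Sv(120) − Sv(38) between cell means separates the two.
Samples of 5 pings × 5 m with dSv in [8, 30] dB are classified as
macrozooplankton; a −80 dB floor suppresses noise-driven differences,
and cells floored at both frequencies are excluded.  The
macrozooplankton index is the nautical area scattering coefficient

    NASC = 4 pi 1852^2 * integral(s_v dz)   [m^2 nmi^-2]

from the 120 kHz data restricted to macrozooplankton-classified
samples, exported on 0.5 km × 5 m cells and averaged per region-year.

Cell means are computed in the linear domain (s_v = 10^(Sv/10)) and
converted back to dB before differencing, the standard echo-integration
convention; a pure log-domain mean is available via ``mean_domain``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# class codes for sample cells
MASKED = -1
BELOW_THRESHOLD = 0
MACROZOOPLANKTON = 1
OTHER = 2

CLASS_NAMES = {
    MASKED: "masked",
    BELOW_THRESHOLD: "below_threshold",
    MACROZOOPLANKTON: "macrozooplankton",
    OTHER: "other",
}

NASC_CONST = 4.0 * np.pi * 1852.0**2  # m^2 nmi^-2 per (m^-1 * m)

__all__ = [
    "Echogram",
    "SampleGrid",
    "bin_samples",
    "classify",
    "compute_nasc",
    "regional_index",
    "read_echogram_csv",
    "NASC_CONST",
    "MACROZOOPLANKTON",
    "OTHER",
    "BELOW_THRESHOLD",
    "MASKED",
]


@dataclass
class Echogram:
    """Two-frequency volume backscatter on a ping × depth-bin grid.

    ``sv38``/``sv120`` are Sv in dB re 1 m^-1, shape (n_pings, n_bins);
    NaN marks no-data.  ``depth_top`` gives the top edge (m below
    surface) of each bin; bins are half-open [top, top + bin_height).
    """

    distance_km: np.ndarray
    depth_top: np.ndarray
    bin_height: float
    sv38: np.ndarray
    sv120: np.ndarray
    bottom_depth: np.ndarray
    region: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.distance_km = np.asarray(self.distance_km, dtype=float)
        self.depth_top = np.asarray(self.depth_top, dtype=float)
        self.sv38 = np.asarray(self.sv38, dtype=float)
        self.sv120 = np.asarray(self.sv120, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        if self.sv38.shape != self.sv120.shape:
            raise ValueError("38 and 120 kHz grids must have identical shape")
        n_pings, n_bins = self.sv120.shape
        if len(self.distance_km) != n_pings or len(self.bottom_depth) != n_pings:
            raise ValueError("per-ping arrays must match the number of pings")
        if len(self.depth_top) != n_bins:
            raise ValueError("depth_top must match the number of depth bins")
        if np.any(np.diff(self.distance_km) < 0):
            raise ValueError("along-track distance must be non-decreasing")
        dz = np.diff(self.depth_top)
        if len(dz) and not np.allclose(dz, self.bin_height, rtol=1e-9):
            raise ValueError("depth bins must be uniform with height bin_height")

    @property
    def n_pings(self) -> int:
        return self.sv120.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv120.shape[1]

    def valid_domain(self, surface_exclusion: float = 4.0, bottom_offset: float = 1.0) -> np.ndarray:
        """Boolean (n_pings, n_bins): bin lies fully within
        [surface_exclusion, bottom_depth − bottom_offset]."""
        top = self.depth_top[None, :]
        bot = top + self.bin_height
        limit = (self.bottom_depth - bottom_offset)[:, None]
        return (top >= surface_exclusion) & (bot <= limit)


@dataclass
class SampleGrid:
    """Cell means on the 5-ping × 5-m sample grid."""

    sv38_db: np.ndarray  # (n_ping_cells, n_depth_cells), floored
    sv120_db: np.ndarray
    dsv: np.ndarray
    valid: np.ndarray  # cells with >= 1 in-domain bin
    at_floor: np.ndarray  # both frequencies at the floor
    ping_cell_index: np.ndarray  # (n_pings,) cell id or -1 for dropped trailing pings
    depth_cell_index: np.ndarray  # (n_bins,) cell id or -1
    floor_db: float


def _cell_index(n: int, per_cell: int) -> np.ndarray:
    """Assign items to consecutive cells; a trailing partial cell is kept
    only when at least half full, otherwise its items get -1."""
    idx = np.arange(n) // per_cell
    n_full, rem = divmod(n, per_cell)
    if rem and rem < per_cell / 2.0:
        idx[n_full * per_cell :] = -1
        logger.info("dropped trailing partial cell of %d/%d items", rem, per_cell)
    return idx


def bin_samples(
    eg: Echogram,
    pings_per_cell: int = 5,
    meters_per_cell: float = 5.0,
    floor_db: float = -80.0,
    mean_domain: str = "linear",
) -> SampleGrid:
    """Average the echogram onto the classification sample grid.

    Per cell and frequency the mean is taken over in-domain, non-missing
    bins — in the linear domain by default — and converted to dB; cell
    means below ``floor_db`` are floored there before the dB difference
    is formed.
    """
    ratio = meters_per_cell / eg.bin_height
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("bin height must divide the sample-cell height")
    bins_per_cell = int(round(ratio))

    ping_idx = _cell_index(eg.n_pings, pings_per_cell)
    depth_idx = _cell_index(eg.n_bins, bins_per_cell)
    n_pc = ping_idx.max() + 1
    n_dc = depth_idx.max() + 1

    domain = eg.valid_domain()
    means = {}
    for name, sv in (("38", eg.sv38), ("120", eg.sv120)):
        ok = domain & np.isfinite(sv) & (ping_idx[:, None] >= 0) & (depth_idx[None, :] >= 0)
        if mean_domain == "linear":
            vals = np.where(ok, 10.0 ** (sv / 10.0), 0.0)
        elif mean_domain == "log":
            vals = np.where(ok, sv, 0.0)
        else:
            raise ValueError("mean_domain must be 'linear' or 'log'")
        sums = np.zeros((n_pc, n_dc))
        counts = np.zeros((n_pc, n_dc))
        pi = np.clip(ping_idx, 0, None)
        di = np.clip(depth_idx, 0, None)
        np.add.at(sums, (pi[:, None], di[None, :]) , vals)
        np.add.at(counts, (pi[:, None], di[None, :]), ok.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = sums / counts
            db = 10.0 * np.log10(mean) if mean_domain == "linear" else mean
        means[name] = db

    valid = ~np.isnan(means["38"]) & ~np.isnan(means["120"])
    sv38 = np.maximum(means["38"], floor_db)
    sv120 = np.maximum(means["120"], floor_db)
    at_floor = valid & (sv38 <= floor_db) & (sv120 <= floor_db)
    dsv = np.where(valid, sv120 - sv38, np.nan)
    return SampleGrid(
        sv38_db=sv38,
        sv120_db=sv120,
        dsv=dsv,
        valid=valid,
        at_floor=at_floor,
        ping_cell_index=ping_idx,
        depth_cell_index=depth_idx,
        floor_db=floor_db,
    )


def classify(grid: SampleGrid, lo: float = 8.0, hi: float = 30.0) -> np.ndarray:
    """Class code per sample cell from the dB-difference window [lo, hi]."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    cls = np.full(grid.dsv.shape, MASKED, dtype=int)
    cls[grid.valid] = OTHER
    cls[grid.valid & grid.at_floor] = BELOW_THRESHOLD
    macro = grid.valid & ~grid.at_floor & (grid.dsv >= lo) & (grid.dsv <= hi)
    cls[macro] = MACROZOOPLANKTON
    return cls


def compute_nasc(
    eg: Echogram,
    grid: SampleGrid,
    cls: np.ndarray,
    horiz_km: float = 0.5,
    vert_m: float = 5.0,
) -> pd.DataFrame:
    """Echo-integrate 120 kHz backscatter over macrozooplankton cells.

    Export cells are ``horiz_km`` of along-track distance × ``vert_m``
    of depth.  Per export cell, NASC = 4π·1852² × the ping-averaged
    integral of linear s_v over macrozooplankton-classified bins
    inside the cell; non-macrozooplankton backscatter contributes 0.
    Fully-masked export cells carry NaN.

    Returns a frame with ``dist_cell, depth_cell, region, year, NASC``.
    """
    ratio = vert_m / eg.bin_height
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("bin height must divide the export-cell height")

    # per-bin macrozooplankton membership, mapped back from sample cells
    bin_class = np.full((eg.n_pings, eg.n_bins), MASKED, dtype=int)
    live = (grid.ping_cell_index[:, None] >= 0) & (grid.depth_cell_index[None, :] >= 0)
    pi = np.clip(grid.ping_cell_index, 0, None)
    di = np.clip(grid.depth_cell_index, 0, None)
    bin_class[live] = cls[pi[:, None], di[None, :]][live]
    in_domain = eg.valid_domain() & np.isfinite(eg.sv120)

    sv_lin = np.where(
        in_domain & (bin_class == MACROZOOPLANKTON), 10.0 ** (eg.sv120 / 10.0), 0.0
    )

    dist_cell = np.floor(eg.distance_km / horiz_km).astype(int)
    depth_cell = np.floor(eg.depth_top / vert_m + 1e-9).astype(int)

    rows = []
    for dc in np.unique(dist_cell):
        pings = dist_cell == dc
        for zc in np.unique(depth_cell):
            bins = depth_cell == zc
            block_domain = in_domain[np.ix_(pings, bins)]
            if not block_domain.any():
                rows.append(
                    {"dist_cell": int(dc), "depth_cell": int(zc), "NASC": np.nan}
                )
                continue
            integ = sv_lin[np.ix_(pings, bins)].sum(axis=1) * eg.bin_height
            rows.append(
                {
                    "dist_cell": int(dc),
                    "depth_cell": int(zc),
                    "NASC": NASC_CONST * float(integ.mean()),
                }
            )
    out = pd.DataFrame(rows)
    out["region"] = eg.region
    out["year"] = eg.year
    return out


def regional_index(cells: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean NASC per region × year over export cells."""
    valid = cells.dropna(subset=["NASC"])
    rows = []
    for (region, year), grp in cells.groupby(["region", "year"], dropna=False):
        vals = grp["NASC"].dropna()
        if len(vals) == 0:
            logger.warning("region=%s year=%s has no unmasked cells; omitted", region, year)
            continue
        rows.append(
            {
                "region": region,
                "year": year,
                "mean_NASC": float(vals.mean()),
                "n_cells": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def read_echogram_csv(path: str, region: str | None = None, year: int | None = None) -> Echogram:
    """Read a long-form echogram export
    (``ping,distance_km,depth_m,sv38_db,sv120_db,bottom_m``)."""
    df = pd.read_csv(path, comment="#")
    pings = np.sort(df["ping"].unique())
    depths = np.sort(df["depth_m"].unique())
    dz = float(np.diff(depths)[0]) if len(depths) > 1 else 5.0
    shape = (len(pings), len(depths))
    sv38 = np.full(shape, np.nan)
    sv120 = np.full(shape, np.nan)
    pmap = {p: i for i, p in enumerate(pings)}
    zmap = {z: j for j, z in enumerate(depths)}
    rows = df["ping"].map(pmap).to_numpy()
    cols = df["depth_m"].map(zmap).to_numpy()
    sv38[rows, cols] = df["sv38_db"].to_numpy()
    sv120[rows, cols] = df["sv120_db"].to_numpy()
    per_ping = df.drop_duplicates("ping").sort_values("ping")
    return Echogram(
        distance_km=per_ping["distance_km"].to_numpy(),
        depth_top=depths,
        bin_height=dz,
        sv38=sv38,
        sv120=sv120,
        bottom_depth=per_ping["bottom_m"].to_numpy(),
        region=region,
        year=year,
    )
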