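"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of a scenario configuration and a
seed, returning both the simulated input and a ground-truth record
sufficient to score recovery without re-simulation.  Generators draw
from independent RNG streams (seed + a per-generator offset), so adding
one never perturbs another.  The default scenario mimics the structure
of a multi-year warm anomaly: a sustained SST boxcar, a synchronized
diet crash across forage species, a zooplankton scattering layer over a
fish layer, multimodal lengths, and hierarchical energetics with year
effects and site random intercepts.  Magnitudes are structural only —
no attempt is made to match real Gulf of Alaska levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .acoustics import Echogram, NASC_CONST
from .energetics import ED_CN_COEF, ED_DRYWET_COEF, ED_INTERCEPT
from .mhw import SSTSeries

# per-generator RNG stream offsets (D1: independent streams)
_STREAM = {"sst": 11, "diet": 23, "echo": 37, "lengths": 53, "energetics": 71}

__all__ = [
    "ScenarioConfig",
    "gen_sst",
    "gen_diet",
    "gen_echogram",
    "gen_lengths",
    "gen_energetics",
]


@dataclass
class ScenarioConfig:
    """Parameters for all generators; defaults give the 'heatwave
    collapse' scenario used in the examples and the pipeline driver."""

    seed: int = 0
    # SST: seasonal cycle + AR(1) noise + injected warm boxcars
    sst_years: tuple[int, int] = (1982, 2018)
    sst_mean: float = 8.0
    sst_amplitude: float = 4.0
    sst_ar1_phi: float = 0.8
    sst_noise_sd: float = 0.35
    sst_events: tuple = (("2014-06-01", 200, 2.5), ("2015-03-01", 300, 2.2))
    # diet: Bernoulli presence with controllable cross-species synchrony
    diet_years: tuple[int, int] = (1994, 2019)
    diet_species: tuple = ("capelin", "sand_lance", "herring")
    diet_base_freq: tuple = (0.45, 0.55, 0.25)
    diet_rho: float = 0.2
    diet_shock_sd: float = 1.0
    diet_samples_per_year: int = 200
    diet_crash: tuple | None = ((2014, 2015), -2.5)  # shared logit shock in these years
    # echogram: horizontal layers on a two-frequency grid
    echo_pings: int = 250
    echo_ping_spacing_km: float = 0.01
    echo_bin_height_m: float = 1.0
    echo_max_depth_m: float = 60.0
    echo_bottom_m: float = 55.0
    echo_background_sv: float = -95.0
    echo_noise_sd: float = 0.5
    # layers: (top m, bottom m, Sv120 dB, dSv dB, label)
    echo_layers: tuple = (
        (10.0, 25.0, -70.0, 16.0, "zooplankton"),
        (35.0, 45.0, -55.0, -2.0, "fish"),
    )
    # lengths: lognormal mixture (mm)
    lengths_k: int = 3
    lengths_weights: tuple = (0.5, 0.3, 0.2)
    lengths_meanlog: tuple = (4.094, 4.605, 5.011)  # ~60, 100, 150 mm
    lengths_sdlog: tuple = (0.10, 0.08, 0.07)
    lengths_n: int = 2000
    # energetics: hierarchical log total energy
    energetics_years: tuple = (2010, 2011, 2012, 2013, 2014, 2015)
    energetics_year_effects: tuple = (0.0, 0.1, 0.05, -0.05, -0.35, -0.5)
    energetics_sites_per_year: int = 4
    energetics_fish_per_site: int = 15
    energetics_site_sd: float = 0.15
    energetics_resid_sd: float = 0.25
    energetics_base_ed: float = 5.0  # kJ g^-1 wet at zero effects
    energetics_wet_mass_g: float = 8.0
    energetics_month: str = "Mar"

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, _STREAM[stream]])


def gen_sst(cfg: ScenarioConfig) -> tuple[SSTSeries, dict]:
    """Daily SST = mean + seasonal sinusoid + AR(1) noise + event boxcars."""
    y0, y1 = cfg.sst_years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    n = len(dates)
    rng = _rng(cfg.seed, "sst")
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.sst_mean + cfg.sst_amplitude * np.sin(2 * np.pi * doy / 365.25 - np.pi / 2)
    noise = np.zeros(n)
    eps = rng.normal(0.0, cfg.sst_noise_sd, size=n)
    for t in range(1, n):
        noise[t] = cfg.sst_ar1_phi * noise[t - 1] + eps[t]
    sst = seasonal + noise

    intervals = []
    for start, duration, amp in cfg.sst_events:
        s = pd.Timestamp(start)
        e = s + pd.Timedelta(days=int(duration) - 1)
        for ps, pe, _ in intervals:
            if s <= pe and e >= ps:
                raise ValueError(f"injected events overlap: {start}")
        intervals.append((s, e, float(amp)))
        mask = (dates >= s) & (dates <= e)
        sst[mask] += amp

    truth = {
        "events": [
            {"start": str(s.date()), "end": str(e.date()), "amplitude": a}
            for s, e, a in intervals
        ]
    }
    return SSTSeries(dates=dates, sst=sst, cell_id="synthetic"), truth


def gen_diet(cfg: ScenarioConfig, rho: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Bernoulli diet-presence samples with latent logit-scale synchrony.

    Per year and species the presence probability is
    logit^-1(logit(base) + rho * common + (1 - rho) * idiosyncratic),
    shocks N(0, shock_sd); the same latent series drives both guilds so
    guild indices are correlated, as for predators feeding on a shared
    forage field.
    """
    rho = cfg.diet_rho if rho is None else rho
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = _rng(cfg.seed, "diet")
    y0, y1 = cfg.diet_years
    years = np.arange(y0, y1 + 1)
    k = len(cfg.diet_species)
    base_logit = np.log(np.asarray(cfg.diet_base_freq) / (1 - np.asarray(cfg.diet_base_freq)))
    common = rng.normal(0.0, cfg.diet_shock_sd, size=len(years))
    idio = rng.normal(0.0, cfg.diet_shock_sd, size=(len(years), k))
    logit = base_logit[None, :] + rho * common[:, None] + (1.0 - rho) * idio
    if cfg.diet_crash is not None:
        crash_years, shock = cfg.diet_crash
        logit[np.isin(years, list(crash_years)), :] += shock
    p = 1.0 / (1.0 + np.exp(-logit))

    m = cfg.diet_samples_per_year
    n_y = len(years)
    frames = []
    offset = 0
    for guild in ("diver", "surface"):
        present = rng.random((n_y, m, k)) < p[:, None, :]  # year x sample x species
        sample_ids = np.arange(offset, offset + n_y * m)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.char.add(
                        "s", np.repeat(sample_ids, k).astype(str)
                    ),
                    "year": np.repeat(np.repeat(years, m), k),
                    "guild": guild,
                    "species": np.tile(np.asarray(cfg.diet_species), n_y * m),
                    "present": present.reshape(-1).astype(int),
                }
            )
        )
        offset += n_y * m
    truth = {
        "rho": rho,
        "years": years.tolist(),
        "latent_p": p.tolist(),
        "species": list(cfg.diet_species),
    }
    return pd.concat(frames, ignore_index=True), truth


def gen_echogram(cfg: ScenarioConfig, density_scale: float = 1.0) -> tuple[Echogram, dict]:
    """Layered two-frequency echogram with Gaussian dB noise.

    Sv120 is the layer value (+noise); Sv38 = Sv120 − true dSv
    (+independent noise).  ``density_scale`` multiplies linear
    backscatter in every layer (10 log10 shift), for two-region
    contrast experiments.  Truth stores each layer's noise-free NASC
    column integral.
    """
    rng = _rng(cfg.seed, "echo")
    n_bins = int(round(cfg.echo_max_depth_m / cfg.echo_bin_height_m))
    depth_top = np.arange(n_bins) * cfg.echo_bin_height_m
    shape = (cfg.echo_pings, n_bins)
    db_shift = 10.0 * np.log10(density_scale)
    sv120_true = np.full(shape, cfg.echo_background_sv)
    dsv_true = np.zeros(shape)
    for top, bot, sv, dsv, label in cfg.echo_layers:
        if bot > cfg.echo_bottom_m:
            raise ValueError(f"layer '{label}' extends below the bottom")
        sel = (depth_top >= top) & (depth_top + cfg.echo_bin_height_m <= bot)
        sv120_true[:, sel] = sv + db_shift
        dsv_true[:, sel] = dsv
    sv120 = sv120_true + rng.normal(0.0, cfg.echo_noise_sd, size=shape)
    sv38 = sv120_true - dsv_true + rng.normal(0.0, cfg.echo_noise_sd, size=shape)

    layer_truth = []
    for top, bot, sv, dsv, label in cfg.echo_layers:
        sel = (depth_top >= top) & (depth_top + cfg.echo_bin_height_m <= bot)
        thickness = float(sel.sum()) * cfg.echo_bin_height_m
        sv_lin = 10.0 ** ((sv + db_shift) / 10.0)
        layer_truth.append(
            {
                "label": label,
                "dsv": dsv,
                "nasc_column": NASC_CONST * sv_lin * thickness,
                "thickness_m": thickness,
            }
        )
    eg = Echogram(
        distance_km=np.arange(cfg.echo_pings) * cfg.echo_ping_spacing_km,
        depth_top=depth_top,
        bin_height=cfg.echo_bin_height_m,
        sv38=sv38,
        sv120=sv120,
        bottom_depth=np.full(cfg.echo_pings, cfg.echo_bottom_m),
    )
    return eg, {"layers": layer_truth, "density_scale": density_scale}


def gen_lengths(cfg: ScenarioConfig) -> tuple[np.ndarray, dict]:
    """Draw lengths (mm) from the configured lognormal mixture."""
    rng = _rng(cfg.seed, "lengths")
    w = np.asarray(cfg.lengths_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    comp = rng.choice(cfg.lengths_k, size=cfg.lengths_n, p=w)
    mu = np.asarray(cfg.lengths_meanlog)[comp]
    sd = np.asarray(cfg.lengths_sdlog)[comp]
    lengths = np.exp(rng.normal(mu, sd))
    truth = {
        "weights": list(cfg.lengths_weights),
        "meanlog": list(cfg.lengths_meanlog),
        "sdlog": list(cfg.lengths_sdlog),
        "component": comp.tolist(),
    }
    return lengths, truth


def gen_energetics(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Hierarchical fish-energy records consistent with the C:N formula.

    log TE = log(base ED × wet mass) + year effect + site intercept +
    residual; C:N is drawn and the dry/wet ratio back-solved from the
    energy-density formula, so recomputing ED from the stored C:N and
    masses reproduces TE / wet mass exactly.
    """
    rng = _rng(cfg.seed, "energetics")
    rows = []
    site_effects = {}
    for yi, year in enumerate(cfg.energetics_years):
        for s in range(cfg.energetics_sites_per_year):
            site = f"site{s + 1}"
            u = rng.normal(0.0, cfg.energetics_site_sd)
            site_effects[f"{year}:{site}"] = float(u)
            for _ in range(cfg.energetics_fish_per_site):
                wet = cfg.energetics_wet_mass_g * np.exp(rng.normal(0.0, 0.15))
                log_te = (
                    np.log(cfg.energetics_base_ed * wet)
                    + cfg.energetics_year_effects[yi]
                    + u
                    + rng.normal(0.0, cfg.energetics_resid_sd)
                )
                te = float(np.exp(log_te))
                ed = te / wet
                cn = rng.uniform(3.0, 7.0)
                dry_wet = (ed - ED_CN_COEF * cn - ED_INTERCEPT) / ED_DRYWET_COEF
                if not 0.0 < dry_wet <= 1.0:
                    cn = 3.0
                    dry_wet = (ed - ED_CN_COEF * cn - ED_INTERCEPT) / ED_DRYWET_COEF
                length = float(np.clip(rng.normal(85.0, 12.0), 56.0, 114.0))
                rows.append(
                    {
                        "species": "herring",
                        "year": int(year),
                        "month": cfg.energetics_month,
                        "site": site,
                        "fork_length_mm": length,
                        "wet_g": float(wet),
                        "dry_g": float(dry_wet * wet),
                        "cn_ratio": float(cn),
                        "total_energy_kj": te,
                    }
                )
    truth = {
        "years": list(cfg.energetics_years),
        "year_effects": list(cfg.energetics_year_effects),
        "site_effects": site_effects,
        "base_log_te": float(np.log(cfg.energetics_base_ed * cfg.energetics_wet_mass_g)),
    }
    return pd.DataFrame(rows), truth
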