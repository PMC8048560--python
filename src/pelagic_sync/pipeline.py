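"""End-to-end driver: configuration, provenance, and stage chaining.

``run_pipeline`` executes the analysis stages in dependency order on
either synthetic inputs (generated from the scenario configuration) or
user-supplied files, writing one tidy CSV per stage, a ``manifest.json``
with input parameters and output checksums, and an echo of the resolved
configuration for provenance.  Outputs are byte-identical for a fixed
configuration and seed (floats printed at fixed 1e-6 precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import acoustics as ac
from . import energetics as en
from . import indices as ix
from . import mhw
from . import portfolio as pf
from . import sizestruct as sz
from .synth import ScenarioConfig, gen_diet, gen_echogram, gen_energetics, gen_lengths, gen_sst

logger = logging.getLogger(__name__)

STAGES = ("mhw", "portfolio", "acoustics", "sizestruct", "energetics", "indices")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults follow the per-stage
    design choices documented in each module."""

    seed: int = 0
    out_dir: str = "pelagic_sync_out"
    stages: tuple = STAGES
    scenario: dict = field(default_factory=dict)
    # mhw
    mhw_window_halfwidth: int = 5
    mhw_smooth_width: int = 31
    mhw_min_duration: int = 5
    mhw_max_gap: int = 2
    mhw_period: tuple = ("2014-01-01", "2016-12-31")
    # portfolio
    portfolio_window: int = 3
    portfolio_species: tuple = ("capelin", "sand_lance", "herring")
    # acoustics
    acoustics_floor_db: float = -80.0
    acoustics_dsv_lo: float = 8.0
    acoustics_dsv_hi: float = 30.0
    acoustics_horiz_km: float = 0.5
    acoustics_vert_m: float = 5.0
    # sizestruct
    sizestruct_k: int = 3
    sizestruct_boundaries: tuple = (100.0, 130.0)
    sizestruct_n_starts: int = 10
    # indices
    indices_flag_sd: float = 2.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d = json.loads(json.dumps(d))  # tuples -> lists for clean YAML
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig) -> None:
    params = dataclasses.asdict(cfg)
    params.pop("out_dir", None)  # paths must not perturb provenance hashes
    params_hash = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# pelagic-sync v{__version__}, stage={stage}, params-hash={params_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages on the synthetic scenario and write a
    results bundle.  Returns the manifest dict.  A stage failure leaves
    a ``<stage>.failed`` marker and re-raises."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen = ScenarioConfig(seed=cfg.seed, **cfg.scenario)
    outputs: dict[str, str] = {}
    truths: dict[str, dict] = {}

    def run_stage(name, fn):
        try:
            fn()
        except Exception:
            (out / f"{name}.failed").touch()
            logger.exception("stage %s failed", name)
            raise

    if "mhw" in cfg.stages:
        def _mhw():
            series, truth = gen_sst(scen)
            truths["sst"] = truth
            clim = mhw.compute_climatology(
                series,
                window_halfwidth=cfg.mhw_window_halfwidth,
                smooth_width=cfg.mhw_smooth_width,
            )
            events = mhw.detect_events(
                series, clim, min_duration=cfg.mhw_min_duration, max_gap=cfg.mhw_max_gap
            )
            _write_csv(mhw.events_to_frame(events), out / "events.csv", "mhw", cfg)
            summ = mhw.summarize_grid(
                {series.cell_id: events},
                (pd.Timestamp(cfg.mhw_period[0]), pd.Timestamp(cfg.mhw_period[1])),
            )
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "cell_id": s.cell_id,
                            "total_hw_days": s.total_hw_days,
                            "mean_event_intensity": s.mean_event_intensity,
                        }
                        for s in summ
                    ]
                ),
                out / "grid_summary.csv",
                "mhw",
                cfg,
            )
            outputs["events.csv"] = _checksum(out / "events.csv")
            outputs["grid_summary.csv"] = _checksum(out / "grid_summary.csv")
        run_stage("mhw", _mhw)

    if "portfolio" in cfg.stages:
        def _portfolio():
            diet, truth = gen_diet(scen)
            truths["diet"] = {"rho": truth["rho"]}
            freq = pf.frequency_of_occurrence(diet, species=cfg.portfolio_species)
            _write_csv(freq, out / "frequencies.csv", "portfolio", cfg)
            pe = pf.rolling_portfolio_effect(
                freq, window_len=cfg.portfolio_window, species=cfg.portfolio_species
            )
            _write_csv(pe, out / "portfolio.csv", "portfolio", cfg)
            outputs["frequencies.csv"] = _checksum(out / "frequencies.csv")
            outputs["portfolio.csv"] = _checksum(out / "portfolio.csv")
        run_stage("portfolio", _portfolio)

    if "acoustics" in cfg.stages:
        def _acoustics():
            eg, truth = gen_echogram(scen)
            eg.region, eg.year = "PWS", 2017
            truths["echogram"] = truth
            grid = ac.bin_samples(eg, floor_db=cfg.acoustics_floor_db)
            cls = ac.classify(grid, lo=cfg.acoustics_dsv_lo, hi=cfg.acoustics_dsv_hi)
            cells = ac.compute_nasc(
                eg, grid, cls, horiz_km=cfg.acoustics_horiz_km, vert_m=cfg.acoustics_vert_m
            )
            _write_csv(cells, out / "nasc_cells.csv", "acoustics", cfg)
            _write_csv(ac.regional_index(cells), out / "nasc_regional.csv", "acoustics", cfg)
            outputs["nasc_cells.csv"] = _checksum(out / "nasc_cells.csv")
            outputs["nasc_regional.csv"] = _checksum(out / "nasc_regional.csv")
        run_stage("acoustics", _acoustics)

    if "sizestruct" in cfg.stages:
        def _sizestruct():
            lengths, truth = gen_lengths(scen)
            truths["lengths"] = {k: truth[k] for k in ("weights", "meanlog", "sdlog")}
            fit = sz.fit_lognormal_mixture(
                lengths, k=cfg.sizestruct_k, n_starts=cfg.sizestruct_n_starts, seed=cfg.seed
            )
            props = sz.component_proportions(fit, list(cfg.sizestruct_boundaries))
            fits = pd.DataFrame(
                {
                    "component": np.arange(1, fit.k + 1),
                    "weight": fit.weights,
                    "meanlog": fit.meanlog,
                    "sdlog": fit.sdlog,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                }
            )
            _write_csv(fits, out / "mixture_fits.csv", "sizestruct", cfg)
            _write_csv(
                pd.DataFrame(
                    {"size_class": np.arange(1, len(props) + 1), "proportion": props}
                ),
                out / "size_class_proportions.csv",
                "sizestruct",
                cfg,
            )
            outputs["mixture_fits.csv"] = _checksum(out / "mixture_fits.csv")
            outputs["size_class_proportions.csv"] = _checksum(
                out / "size_class_proportions.csv"
            )
        run_stage("sizestruct", _sizestruct)

    if "energetics" in cfg.stages:
        def _energetics():
            records, truth = gen_energetics(scen)
            truths["energetics"] = {k: truth[k] for k in ("years", "year_effects")}
            estimates = en.annual_energy_model(records)
            _write_csv(
                pd.DataFrame([dataclasses.asdict(e) for e in estimates]),
                out / "annual_energy.csv",
                "energetics",
                cfg,
            )
            anova = en.annual_group_comparison(records)
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "F": anova["F"],
                            "p": anova["p"],
                            "r2": anova["r2"],
                            "df_between": anova["df_between"],
                            "df_within": anova["df_within"],
                        }
                    ]
                ),
                out / "anova.csv",
                "energetics",
                cfg,
            )
            outputs["annual_energy.csv"] = _checksum(out / "annual_energy.csv")
            outputs["anova.csv"] = _checksum(out / "anova.csv")
        run_stage("energetics", _energetics)

    if "indices" in cfg.stages:
        def _indices():
            records, _ = gen_energetics(scen)
            dens = (
                records.groupby(["year", "site"])["total_energy_kj"].mean().reset_index()
            )
            dens = dens.rename(columns={"site": "region", "total_energy_kj": "value"})
            dens["season"] = "spring"
            z = ix.standardize(dens, group_cols=("season", "region"))
            z["extreme"] = ix.flag_extremes(z["z"], cfg.indices_flag_sd)
            _write_csv(z, out / "anomalies.csv", "indices", cfg)
            outputs["anomalies.csv"] = _checksum(out / "anomalies.csv")
        run_stage("indices", _indices)

    cfg.to_yaml(str(out / "run_config.yaml"))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "outputs": outputs,
        "truth": json.loads(json.dumps(truths, default=float)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate(scen: ScenarioConfig, out_dir: str) -> dict:
    """Write all synthetic inputs plus ``truth.json`` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = {}
    series, truths["sst"] = gen_sst(scen)
    pd.DataFrame(
        {
            "date": series.dates.strftime("%Y-%m-%d"),
            "cell_id": series.cell_id,
            "lat": 59.0,
            "lon": -148.0,
            "sst": series.sst,
        }
    ).to_csv(out / "sst.csv", index=False, float_format="%.6f")
    diet, truths["diet"] = gen_diet(scen)
    diet.to_csv(out / "diet.csv", index=False)
    eg, truths["echogram"] = gen_echogram(scen)
    n_pings, n_bins = eg.sv120.shape
    long = pd.DataFrame(
        {
            "ping": np.repeat(np.arange(n_pings), n_bins),
            "distance_km": np.repeat(eg.distance_km, n_bins),
            "depth_m": np.tile(eg.depth_top, n_pings),
            "sv38_db": eg.sv38.ravel(),
            "sv120_db": eg.sv120.ravel(),
            "bottom_m": np.repeat(eg.bottom_depth, n_bins),
        }
    )
    long.to_csv(out / "echogram.csv", index=False, float_format="%.4f")
    lengths, truths["lengths"] = gen_lengths(scen)
    pd.DataFrame({"year": 2017, "length_mm": lengths}).to_csv(
        out / "lengths.csv", index=False, float_format="%.3f"
    )
    records, truths["energetics"] = gen_energetics(scen)
    records.to_csv(out / "energy.csv", index=False, float_format="%.6f")
    truths_clean = json.loads(json.dumps(truths, default=float))
    (out / "truth.json").write_text(json.dumps(truths_clean, indent=2, sort_keys=True))
    return truths_clean
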