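"""End-to-end orchestration: geometry -> classify -> profiles -> windows
-> abundance -> trend, with a provenance manifest and deterministic reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import classify as cl
from . import profiles as pr
from . import simulate as sim
from . import trend as tr
from . import windows as win
from .geometry import RadarSite, assign_gates_to_columns, build_cvp_lattice, terrain_mask
from .raster import Raster

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Everything a rerun needs; echoed verbatim into the manifest."""

    out_dir: str
    seed: int = 0
    site_id: str = "synthetic-wsr"
    sigma_cm2: float = 1.0e-3  # no hidden default in the abundance stage
    beta_db: float | None = 26.58
    wavelength_cm: float | None = None  # alternative to beta_db
    band_m: int = 500
    dr_threshold: float = -12.5
    z_cap: float = 45.0
    zdr_min: float = 3.0
    min_gates: int = 3
    windows: str = "preset"  # "preset" | "fit"
    simulate: bool = True
    #: a 2-element (start, end) pair simulated daily, or an explicit list
    #: of 1 or 3+ dates
    dates: tuple[str, str] | list[str] = ("2014-06-10", "2014-06-12")
    hours: tuple[int, int] = (8, 22)
    interval_minutes: float = 60.0
    annual_change: float = 0.0
    scene_overrides: dict = field(default_factory=dict)
    terrain_path: str | None = None
    fit_trend: bool = True

    def constants(self) -> ab.RadarConstants:
        if self.beta_db is not None:
            return ab.RadarConstants(sigma=self.sigma_cm2, beta=self.beta_db)
        if self.wavelength_cm is None:
            raise ValueError("supply beta_db or wavelength_cm")
        return ab.RadarConstants.from_wavelength(self.sigma_cm2, self.wavelength_cm)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Each stage's artifact is written before the next begins, so failures
    preserve partial output.  With an all-zero scene the estimate table is
    empty and the trend stage is skipped with a notice.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, path: Path, **extra) -> None:
        manifest["stages"][stage] = {"path": str(path), "sha256": _sha(path), **extra}

    # -- geometry ----------------------------------------------------------
    site = RadarSite(site_id=config.site_id)
    lattice = build_cvp_lattice(site)
    if config.terrain_path:
        lattice = terrain_mask(lattice, Raster.read_ascii(config.terrain_path), site)
    lattice.export_csv(out / "lattice.csv", site)
    record("geometry", out / "lattice.csv", counts=lattice.counts())
    mapping = assign_gates_to_columns(lattice, site)

    # -- scene -------------------------------------------------------------
    if not config.simulate:
        raise NotImplementedError("only simulated inputs are wired into run_end_to_end")
    scene = sim.SceneConfig(
        seed=config.seed, annual_change=config.annual_change, **config.scene_overrides
    )
    if len(config.dates) == 2:
        dates = pd.date_range(config.dates[0], config.dates[1], freq="D")
    else:
        dates = pd.DatetimeIndex([pd.Timestamp(d) for d in config.dates])
    volumes, truth, rain_days = sim.simulate_study(
        scene, site, lattice, dates, hours=config.hours,
        interval_minutes=config.interval_minutes, mapping=mapping,
    )
    truth_path = _write(truth, out / "truth.csv")
    record("simulate", truth_path, n_volumes=len(volumes),
           rain_days=sorted(str(d) for d in rain_days))

    # -- classification ----------------------------------------------------
    fcfg = cl.FilterConfig(config.dr_threshold, config.z_cap, config.zdr_min)
    filtered, summaries = [], []
    for vol in volumes:
        fv, counts = cl.filter_volume(vol, fcfg)
        filtered.append(fv)
        summaries.append({"timestamp": vol.timestamp, **counts})
    summary_path = _write(pd.DataFrame(summaries), out / "classification_summary.csv")
    record("classify", summary_path, thresholds=asdict(fcfg))

    # -- profiles ----------------------------------------------------------
    pcfg = pr.ProfileConfig(min_gates=config.min_gates)
    raw_profiles = pr.profile_series(volumes, lattice, mapping, pcfg)
    profiles = pr.profile_series(filtered, lattice, mapping, pcfg)
    prof_path = _write(profiles, out / "profiles.csv")
    record("profiles", prof_path, n_rows=len(profiles))

    # -- windows -----------------------------------------------------------
    if config.windows == "fit" and len(raw_profiles):
        series = pr.band_zdr_series(raw_profiles, config.band_m)
        ts = pd.to_datetime(series.index)
        hours_f = ts.hour + ts.minute / 60.0
        curve = win.fit_activity_smooth(hours_f, series.to_numpy(), win.WindowKind.DIEL)
        diel = win.extract_peak_window(curve) or win.preset_diel_windows()
    else:
        diel = win.preset_diel_windows()
    wdf = pd.DataFrame(
        [{"kind": w.kind.value, "start": w.start, "end": w.end, "peak": w.peak} for w in diel]
    )
    win_path = _write(wdf, out / "windows.csv")
    record("windows", win_path, mode=config.windows)
    # scan selection uses the unfiltered ZDR profile: the share of elongated
    # bioscatter, not just its mean shape, is what peaks with activity
    selected = win.select_scan_per_window(raw_profiles, diel, config.band_m)

    # -- abundance ---------------------------------------------------------
    constants = config.constants()
    if selected.empty:
        est = pd.DataFrame()
    else:
        sel_keys = selected[["grid_row", "grid_col", "timestamp", "window", "date"]]
        merged = profiles.merge(sel_keys, on=["grid_row", "grid_col", "timestamp"])
        est = ab.abundance_table(merged, constants)
    est_path = _write(est, out / "abundance.csv")
    record("abundance", est_path, sigma_cm2=constants.sigma, beta_db=constants.beta,
           n_estimates=len(est))

    # -- trend -------------------------------------------------------------
    if est.empty or not config.fit_trend:
        manifest["stages"]["trend"] = {
            "skipped": True,
            "reason": "no abundance estimates" if est.empty else "disabled by config",
        }
    else:
        covs = sim.generate_covariate_rasters(config.seed + 1)
        band_est = est[est["band_lower_m"] == config.band_m]
        table = tr.assemble_model_table(band_est, covs, lattice)
        table_path = _write(table, out / "model_table.csv")
        if table["year"].nunique() < 2 or len(table) < 50:
            manifest["stages"]["trend"] = {
                "skipped": True,
                "reason": "too few years or rows for trend fitting",
                "table": str(table_path),
            }
        else:
            ladder = tr.default_candidate_ladder(table, with_year_by_radar=False, k_xy=16)
            rho = tr.estimate_rho_refined(ladder[-1], table, n_iter=1)
            for spec in ladder:
                spec.ar_rho = rho
            ranking = tr.select_best_model(ladder, table)
            best = ranking.iloc[0]["fit"]
            annual, change = tr.annual_trend(best, table)
            _write(annual, out / "annual_trend.csv")
            _write(change, out / "change_map.csv")
            manifest["stages"]["trend"] = {
                "table": str(table_path),
                "best_model": ranking.iloc[0]["name"],
                "rho": rho,
                "deviance_explained": float(ranking.iloc[0]["deviance_explained"]),
                "annual_trend": str(out / "annual_trend.csv"),
                "change_map": str(out / "change_map.csv"),
            }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
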