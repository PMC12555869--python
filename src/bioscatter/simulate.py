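"""Synthetic polarimetric scenes, covariate fields and trap counts.

The generator emulates the statistical structure the analysis assumes:
an insect layer whose number density declines linearly with height and is
modulated by a bimodal diel activity curve (peaks near 11:00 and 20:00 GMT)
and a flat-topped seasonal envelope (near-zero outside April-October);
precipitation cells with near-spherical polarimetry (ZDR ~ 0.8 dB,
rho_hv ~ 0.99, hence strongly negative depolarization ratio); bird-like
point targets with intermediate ZDR (~2 dB); and a weak clear-air
background.  Painted insect gates carry Z = 10 log10(density * sigma) - beta,
the exact forward model inverted by the abundance stage, so with noise off
the pipeline recovers the truth table identically.

Everything is reproducible: each scan derives its RNG stream from the
scene seed and the scan timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    LATTICE_N,
    CvpLattice,
    GateColumnMap,
    HeightBands,
    RadarSite,
    assign_gates_to_columns,
)
from .raster import Raster
from .volume import PolarVolume, Sweep

__all__ = [
    "InsectLayer",
    "DielCurve",
    "SeasonEnvelope",
    "PrecipCells",
    "BirdTargets",
    "NoiseLevels",
    "SceneConfig",
    "simulate_scan_volume",
    "simulate_study",
    "simulate_activity_zdr_series",
    "sample_labelled_gates",
    "generate_covariate_rasters",
    "simulate_model_table",
    "simulate_trap_counts",
    "GATE_CLASSES",
]

GATE_CLASSES = {"empty": 0, "insect": 1, "precipitation": 2, "bird": 3, "background": 4}


@dataclass(frozen=True)
class InsectLayer:
    base_density: float = 1.0e7  # per km^3 in the lowest band at full activity
    vertical_slope: float = -1.0e6  # per km^3 per 200 m band step (negative)
    zdr_mean: float = 6.0  # dB, truncated above 3 dB
    zdr_sd: float = 1.5
    zdr_min: float = 3.0
    rhohv_range: tuple[float, float] = (0.3, 0.7)
    #: density at which a gate is certainly occupied; None = always occupied
    occupancy_ref: float | None = 1.5e7
    #: sd of the per-(day, band) lognormal decoupling between height layers
    band_jitter: float = 0.1

    def band_density(self, activity: float = 1.0, jitter: np.ndarray | None = None) -> np.ndarray:
        b = np.arange(HeightBands.n_bands)
        d = np.maximum(self.base_density + self.vertical_slope * b, 0.0) * activity
        if jitter is not None:
            d = d * jitter
        return d


@dataclass(frozen=True)
class DielCurve:
    centres: tuple[float, float] = (11.0, 20.0)  # GMT hours
    widths: tuple[float, float] = (1.5, 1.2)
    amplitudes: tuple[float, float] = (1.0, 0.8)

    def __call__(self, hour) -> np.ndarray:
        h = np.asarray(hour, dtype=float)
        out = np.zeros_like(h)
        for c, w, a in zip(self.centres, self.widths, self.amplitudes):
            out = out + a * np.exp(-0.5 * ((h - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class SeasonEnvelope:
    """Flat-topped annual multiplier, near-zero outside the flight season."""

    centre_doy: float = 197.0
    half_width_days: float = 87.0
    order: int = 6

    def __call__(self, day_of_year) -> np.ndarray:
        d = np.asarray(day_of_year, dtype=float)
        return np.exp(-(((d - self.centre_doy) / self.half_width_days) ** self.order))


@dataclass(frozen=True)
class PrecipCells:
    count: int = 3
    radius_km: float = 6.0
    z_range: tuple[float, float] = (20.0, 55.0)
    zdr_mean: float = 0.8
    zdr_sd: float = 0.2
    rhohv_mean: float = 0.99
    rhohv_sd: float = 0.005


@dataclass(frozen=True)
class BirdTargets:
    count: int = 200  # gates per scan
    zdr_mean: float = 2.0
    zdr_sd: float = 0.5
    rhohv_mean: float = 0.9
    rhohv_sd: float = 0.03
    z_mean: float = 10.0
    z_sd: float = 3.0


@dataclass(frozen=True)
class NoiseLevels:
    z_dbz: float = 0.5
    zdr_db: float = 0.2
    rhohv: float = 0.01


@dataclass(frozen=True)
class SceneConfig:
    seed: int = 0
    sigma_true: float = 1.0e-3  # cm^2, mean single-arthropod cross-section
    beta: float = 26.58  # dB
    insect: InsectLayer = field(default_factory=InsectLayer)
    diel: DielCurve = field(default_factory=DielCurve)
    season: SeasonEnvelope = field(default_factory=SeasonEnvelope)
    precip: PrecipCells = field(default_factory=PrecipCells)
    birds: BirdTargets = field(default_factory=BirdTargets)
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    precip_day_fraction: float = 0.15
    #: multiplicative abundance change per year relative to reference_year
    annual_change: float = 0.0
    reference_year: int = 2014

    def noiseless(self) -> "SceneConfig":
        """Insect-only copy with measurement noise, layer decoupling,
        partial occupancy and contaminant targets all switched off — the
        configuration under which the pipeline must invert the forward
        model exactly."""
        return replace(
            self,
            noise=NoiseLevels(0.0, 0.0, 0.0),
            insect=replace(self.insect, occupancy_ref=None, band_jitter=0.0),
            precip=replace(self.precip, count=0),
            birds=replace(self.birds, count=0),
            precip_day_fraction=0.0,
        )


def _scan_rng(config: SceneConfig, timestamp: pd.Timestamp) -> np.random.Generator:
    t = int(pd.Timestamp(timestamp).value)
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), t % 2**31, (t >> 31) % 2**31])
    )


def _day_rng(config: SceneConfig, date) -> np.random.Generator:
    d = pd.Timestamp(date)
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 7919, int(d.dayofyear), int(d.year)])
    )


def _truncnorm_above(rng, mean, sd, lower, size) -> np.ndarray:
    """Rejection-sampled normal truncated to (lower, inf); sd may be 0."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def day_band_jitter(config: SceneConfig, date) -> np.ndarray:
    """Per-day lognormal decoupling factor per height band (mean ~1)."""
    sd = config.insect.band_jitter
    if sd == 0:
        return np.ones(HeightBands.n_bands)
    rng = _day_rng(config, date)
    return np.exp(rng.normal(0.0, sd, HeightBands.n_bands))


def true_band_densities(config: SceneConfig, timestamp: pd.Timestamp) -> np.ndarray:
    """Truth number density per km^3 for each height band at one scan time."""
    ts = pd.Timestamp(timestamp)
    activity = float(config.diel(ts.hour + ts.minute / 60.0)) * float(
        config.season(ts.dayofyear)
    )
    activity *= (1.0 + config.annual_change) ** (ts.year - config.reference_year)
    return config.insect.band_density(activity, day_band_jitter(config, ts.date()))


def simulate_scan_volume(
    config: SceneConfig,
    site: RadarSite,
    lattice: CvpLattice,
    timestamp,
    mapping: GateColumnMap | None = None,
    rain: bool = False,
):
    """One polar volume plus its truth slice.

    Returns ``(volume, truth_bands, gate_labels)`` where ``truth_bands`` is a
    frame keyed by (grid_row, grid_col, band_lower_m, timestamp) holding the
    painted density, and ``gate_labels`` maps elevation to an int8 class
    array (see ``GATE_CLASSES``).
    """
    ts = pd.Timestamp(timestamp)
    if mapping is None:
        mapping = assign_gates_to_columns(lattice, site)
    rng = _scan_rng(config, ts)
    dens = true_band_densities(config, ts)
    az = site.azimuths()
    rng_km = site.gate_ranges(45.0)[: mapping.n_ranges]
    nz = config.noise
    vol = PolarVolume(
        site_id=site.site_id,
        timestamp=ts,
        gate_length=site.gate_length,
        azimuth_step=site.azimuth_step,
    )
    labels: dict[float, np.ndarray] = {}
    precip_centres = None
    if rain and config.precip.count > 0:
        r = np.sqrt(rng.uniform(0.0, 1.0, config.precip.count)) * 30.0
        th = rng.uniform(0.0, 2 * np.pi, config.precip.count)
        precip_centres = np.column_stack([r * np.sin(th), r * np.cos(th)])
    for el in site.elevation_angles:
        ci = mapping.cell_index[el]
        bi = mapping.band_index[el]
        shape = ci.shape
        z = np.full(shape, np.nan)
        zdr = np.full(shape, np.nan)
        rho = np.full(shape, np.nan)
        lab = np.zeros(shape, dtype=np.int8)
        assigned = ci >= 0
        d_gate = np.where(assigned, dens[np.clip(bi, 0, HeightBands.n_bands - 1)], 0.0)
        ref = config.insect.occupancy_ref
        if ref is None:
            occ = assigned & (d_gate > 0)
        else:
            occ = assigned & (rng.random(shape) < np.minimum(1.0, d_gate / ref)) & (d_gate > 0)
        n_ins = int(occ.sum())
        if n_ins:
            z[occ] = 10.0 * np.log10(d_gate[occ] * config.sigma_true) - config.beta
            zdr[occ] = _truncnorm_above(
                rng, config.insect.zdr_mean, config.insect.zdr_sd, config.insect.zdr_min, n_ins
            )
            rho[occ] = rng.uniform(*config.insect.rhohv_range, n_ins)
            lab[occ] = GATE_CLASSES["insect"]
        bg = assigned & ~occ
        n_bg = int(bg.sum())
        if n_bg:
            z[bg] = rng.normal(-5.0, 2.0, n_bg)
            zdr[bg] = rng.normal(0.0, 0.3, n_bg)
            rho[bg] = np.clip(rng.normal(0.85, 0.03, n_bg), 0.0, 1.0)
            lab[bg] = GATE_CLASSES["background"]
        if precip_centres is not None:
            g = rng_km[None, :] * np.cos(np.deg2rad(el))
            east = g * np.sin(np.deg2rad(az))[:, None]
            north = g * np.cos(np.deg2rad(az))[:, None]
            wet = np.zeros(shape, dtype=bool)
            for cx, cy in precip_centres:
                wet |= (east - cx) ** 2 + (north - cy) ** 2 <= config.precip.radius_km**2
            n_wet = int(wet.sum())
            if n_wet:
                z[wet] = rng.uniform(*config.precip.z_range, n_wet)
                zdr[wet] = rng.normal(config.precip.zdr_mean, config.precip.zdr_sd, n_wet)
                rho[wet] = np.clip(
                    rng.normal(config.precip.rhohv_mean, config.precip.rhohv_sd, n_wet), 0.0, 1.0
                )
                lab[wet] = GATE_CLASSES["precipitation"]
        if config.birds.count > 0:
            flat = rng.integers(0, lab.size, config.birds.count)
            bmask = np.zeros(lab.size, dtype=bool)
            bmask[flat] = True
            bmask = bmask.reshape(shape) & (lab != GATE_CLASSES["precipitation"])
            n_b = int(bmask.sum())
            if n_b:
                z[bmask] = rng.normal(config.birds.z_mean, config.birds.z_sd, n_b)
                zdr[bmask] = rng.normal(config.birds.zdr_mean, config.birds.zdr_sd, n_b)
                rho[bmask] = np.clip(
                    rng.normal(config.birds.rhohv_mean, config.birds.rhohv_sd, n_b), 0.0, 1.0
                )
                lab[bmask] = GATE_CLASSES["bird"]
        painted = lab > 0
        if nz.z_dbz > 0:
            z[painted] += rng.normal(0.0, nz.z_dbz, int(painted.sum()))
        if nz.zdr_db > 0:
            zdr[painted] += rng.normal(0.0, nz.zdr_db, int(painted.sum()))
        if nz.rhohv > 0:
            rho[painted] = np.clip(
                rho[painted] + rng.normal(0.0, nz.rhohv, int(painted.sum())), 0.0, 1.0
            )
        vol.sweeps[el] = Sweep(el, z, zdr, rho)
        labels[el] = lab
    truth_rows = []
    for cell in lattice.retained():
        flat = cell.grid_row * LATTICE_N + cell.grid_col
        for b, lower in enumerate(HeightBands.lower_edges):
            if mapping.counts[flat, b] == 0:
                continue
            truth_rows.append(
                {
                    "grid_row": cell.grid_row,
                    "grid_col": cell.grid_col,
                    "band_lower_m": lower,
                    "timestamp": ts,
                    "true_density_per_km3": float(dens[b]),
                }
            )
    return vol, pd.DataFrame(truth_rows), labels


def simulate_study(
    config: SceneConfig,
    site: RadarSite,
    lattice: CvpLattice,
    dates,
    hours=(8, 23),
    interval_minutes: float | None = 60.0,
    mapping: GateColumnMap | None = None,
):
    """Volumes at regular scan times across a date range, plus truth.

    Returns ``(volumes, truth, rain_days)``; rain days are drawn per day
    with probability ``config.precip_day_fraction`` and carry precipitation
    cells in every scan of that day.
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("empty date range")
    if mapping is None:
        mapping = assign_gates_to_columns(lattice, site)
    step = interval_minutes if interval_minutes is not None else site.scan_interval
    volumes, truths, rain_days = [], [], set()
    for day in dates:
        rain = bool(_day_rng(config, day).random() < config.precip_day_fraction)
        if rain:
            rain_days.add(day.date())
        t = day + pd.Timedelta(hours=hours[0])
        end = day + pd.Timedelta(hours=hours[1])
        while t <= end:
            vol, truth, _ = simulate_scan_volume(config, site, lattice, t, mapping, rain=rain)
            volumes.append(vol)
            truths.append(truth)
            t = t + pd.Timedelta(minutes=step)
    return volumes, pd.concat(truths, ignore_index=True), rain_days


def simulate_activity_zdr_series(
    config: SceneConfig, kind: str, seed: int, noise_sd: float = 0.3
):
    """A lightweight mean-ZDR activity series for window fitting.

    For ``kind='diel'``: hourly-resolution series over one day; for
    ``'seasonal'``: daily series over one year.  The expectation follows the
    gate-occupancy model: mean ZDR ~ occupancy fraction x insect ZDR mean,
    with background ZDR centred on zero.
    """
    rng = np.random.default_rng(seed)
    ref = config.insect.occupancy_ref or config.insect.base_density
    if kind == "diel":
        t = np.arange(0.0, 24.0, 0.25)
        frac = np.minimum(1.0, config.insect.base_density * config.diel(t) / ref)
    elif kind == "seasonal":
        t = np.arange(1.0, 366.0)
        peak_diel = float(config.diel(config.diel.centres[0]))
        frac = np.minimum(
            1.0, config.insect.base_density * peak_diel * config.season(t) / ref
        )
    else:
        raise ValueError("kind must be 'diel' or 'seasonal'")
    zdr = frac * config.insect.zdr_mean + rng.normal(0.0, noise_sd, t.size)
    return t, zdr


def sample_labelled_gates(config: SceneConfig, n: int, seed: int):
    """Draw n gates from the class mixture with known labels.

    Mixture: 40% insect, 30% precipitation, 15% bird, 15% background.
    Used to calibrate the echo filter against construction truth.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(
        [GATE_CLASSES["insect"], GATE_CLASSES["precipitation"], GATE_CLASSES["bird"],
         GATE_CLASSES["background"]],
        size=n,
        p=[0.40, 0.30, 0.15, 0.15],
    )
    z = np.empty(n)
    zdr = np.empty(n)
    rho = np.empty(n)
    ins = labels == GATE_CLASSES["insect"]
    d = rng.uniform(0.2, 1.0, int(ins.sum())) * config.insect.base_density
    z[ins] = 10.0 * np.log10(d * config.sigma_true) - config.beta
    zdr[ins] = _truncnorm_above(
        rng, config.insect.zdr_mean, config.insect.zdr_sd, config.insect.zdr_min, int(ins.sum())
    )
    rho[ins] = rng.uniform(*config.insect.rhohv_range, int(ins.sum()))
    wet = labels == GATE_CLASSES["precipitation"]
    z[wet] = rng.uniform(*config.precip.z_range, int(wet.sum()))
    zdr[wet] = rng.normal(config.precip.zdr_mean, config.precip.zdr_sd, int(wet.sum()))
    rho[wet] = np.clip(
        rng.normal(config.precip.rhohv_mean, config.precip.rhohv_sd, int(wet.sum())), 0, 1
    )
    brd = labels == GATE_CLASSES["bird"]
    z[brd] = rng.normal(config.birds.z_mean, config.birds.z_sd, int(brd.sum()))
    zdr[brd] = rng.normal(config.birds.zdr_mean, config.birds.zdr_sd, int(brd.sum()))
    rho[brd] = np.clip(rng.normal(config.birds.rhohv_mean, config.birds.rhohv_sd, int(brd.sum())), 0, 1)
    bg = labels == GATE_CLASSES["background"]
    z[bg] = rng.normal(-5.0, 2.0, int(bg.sum()))
    zdr[bg] = rng.normal(0.0, 0.3, int(bg.sum()))
    rho[bg] = np.clip(rng.normal(0.85, 0.03, int(bg.sum())), 0, 1)
    return z, zdr, rho, labels


# ---------------------------------------------------------------------------
# covariate fields and model-table simulation
# ---------------------------------------------------------------------------

COVARIATE_RANGES = {
    "tmax": (8.0, 28.0),  # degC
    "rain": (0.0, 20.0),  # mm/day
    "wind": (0.0, 15.0),  # m/s
    "alan": (0.0, 63.0),  # DN brightness
    "elevation": (0.0, 400.0),  # m
}
LAND_COVERS = ("arable", "woodland", "grassland", "urban")


def _smooth_field(rng, shape, scale_px: float = 6.0) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), scale_px)
    f -= f.min()
    rng_ = f.max() - f.min()
    return f / rng_ if rng_ > 0 else f


def generate_covariate_rasters(
    seed: int,
    extent_km: float = 60.0,
    cell_size_km: float = 1.0,
    origin: tuple[float, float] = (-30.0, -30.0),
) -> dict[str, Raster]:
    """Smooth random covariate fields over a square extent.

    Continuous covariates span their realistic ranges; the four land-cover
    percentages are non-negative and sum to at most 100 per pixel.
    """
    rng = np.random.default_rng(seed)
    n = int(round(extent_km / cell_size_km))
    out: dict[str, Raster] = {}
    for name, (lo, hi) in COVARIATE_RANGES.items():
        f = _smooth_field(rng, (n, n))
        out[name] = Raster(lo + (hi - lo) * f, origin[0], origin[1], cell_size_km)
    raw = np.stack([_smooth_field(rng, (n, n)) for _ in LAND_COVERS])
    total = raw.sum(axis=0)
    scale = np.where(total > 0, 0.9 / np.maximum(total, 1e-9), 0.0)
    for i, name in enumerate(LAND_COVERS):
        vals = np.clip(100.0 * raw[i] * scale, 0.0, 100.0)
        out[name] = Raster(vals, origin[0], origin[1], cell_size_km)
    return out


#: known smooth effects used by the trend-recovery simulations
TRUE_EFFECTS = {
    "tmax": lambda t: 0.4 * np.tanh((np.asarray(t, float) - 18.0) / 4.0),
    "alan": lambda a: -0.006 * np.asarray(a, float),
    "urban": lambda u: 0.004 * np.asarray(u, float),
}


def true_spatial_field(x, y) -> np.ndarray:
    return 0.3 * np.sin(np.asarray(x, float) / 15.0) * np.cos(np.asarray(y, float) / 18.0)


def true_trend_slope(y_km, y_extent: float = 30.0) -> np.ndarray:
    """Per-year trend: negative in the north, positive in the south."""
    return -0.04 * np.asarray(y_km, float) / y_extent


def simulate_model_table(
    seed: int,
    n_cells: int = 127,
    years=range(2014, 2022),
    scans_per_year: int = 2,
    ar_rho: float = 0.6,
    noise_sd: float = 0.15,
    cell_re_sd: float = 0.1,
    include_effects: bool = True,
    include_spatial: bool = True,
    include_trend: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """A modelling table with known effect functions and AR(1) noise.

    One row per (cell, year, scan); the response (log10 abundance scale) is
    the sum of the configured covariate effects, a spatial smooth, a
    latitude-dependent year trend, a cell random intercept, and AR(1)
    noise within each cell's time series.  Radars are latitude terciles of
    the cell grid (three spatially contiguous blocks).  Returns
    (table, truth).
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    x = (gx.ravel()[:n_cells] - side / 2) * 5.0 + 2.5
    y = (gy.ravel()[:n_cells] - side / 2) * 5.0 + 2.5
    y_edges = np.quantile(y, [1 / 3, 2 / 3])
    covs = {}
    for name, (lo, hi) in COVARIATE_RANGES.items():
        base = lo + (hi - lo) * rng.beta(2, 2, n_cells)
        covs[name] = base
    for name in LAND_COVERS:
        covs[name] = 100.0 * rng.beta(2, 5, n_cells)
    years = list(years)
    n_t = len(years) * scans_per_year
    cell_re = rng.normal(0.0, cell_re_sd, n_cells) if cell_re_sd > 0 else np.zeros(n_cells)
    rows = []
    truth_effects = {k: v for k, v in TRUE_EFFECTS.items()} if include_effects else {}
    for i in range(n_cells):
        eta_cov = sum(f(covs[k][i]) for k, f in truth_effects.items())
        eta_sp = true_spatial_field(x[i], y[i]) if include_spatial else 0.0
        if ar_rho > 0:
            eps = np.empty(n_t)
            eps[0] = rng.normal(0.0, noise_sd / np.sqrt(1 - ar_rho**2))
            for t in range(1, n_t):
                eps[t] = ar_rho * eps[t - 1] + rng.normal(0.0, noise_sd)
        else:
            eps = rng.normal(0.0, noise_sd, n_t)
        radar = "r" + str(int(np.searchsorted(y_edges, y[i], side="right")))
        t_idx = 0
        for yr in years:
            for s in range(scans_per_year):
                year_c = yr - np.mean(years)
                eta_tr = float(true_trend_slope(y[i]) * year_c) if include_trend else 0.0
                resp = 2.0 + eta_cov + eta_sp + eta_tr + cell_re[i] + eps[t_idx]
                rows.append(
                    {
                        "cell": f"c{i:03d}",
                        "x": float(x[i]),
                        "y": float(y[i]),
                        "year": float(yr),
                        "year_c": float(year_c),
                        "scan": s,
                        "month": 5 + s,
                        "radar": radar,
                        **{k: float(covs[k][i]) for k in covs},
                        "response": float(resp),
                    }
                )
                t_idx += 1
    table = pd.DataFrame(rows)
    truth = {
        "effects": truth_effects,
        "spatial": true_spatial_field if include_spatial else None,
        "trend_slope": true_trend_slope if include_trend else None,
        "ar_rho": ar_rho,
        "noise_sd": noise_sd,
        "intercept": 2.0,
    }
    return table, truth


def simulate_trap_counts(
    truth: pd.DataFrame,
    trap_cell: tuple[int, int],
    scaling: float = 1.0,
    noise_sd: float = 0.0,
    rain_days=frozenset(),
    seed: int = 0,
) -> pd.DataFrame:
    """Daily ground-trap counts coupled to the lowest-band truth density.

    count = scaling x daily mean near-ground density x lognormal noise;
    days in ``rain_days`` are flagged (heavy rain idles both the trap and
    the radar estimate).
    """
    rng = np.random.default_rng(seed)
    at_cell = truth[
        (truth["grid_row"] == trap_cell[0]) & (truth["grid_col"] == trap_cell[1])
    ]
    if at_cell.empty:
        raise ValueError("truth table has no rows for the trap cell")
    low = at_cell["band_lower_m"].min()  # lowest band the beam reaches there
    sub = at_cell[at_cell["band_lower_m"] == low].copy()
    sub["date"] = pd.to_datetime(sub["timestamp"]).dt.date
    daily = sub.groupby("date")["true_density_per_km3"].mean().reset_index()
    factor = np.exp(rng.normal(0.0, noise_sd, len(daily))) if noise_sd > 0 else 1.0
    daily["count"] = scaling * daily["true_density_per_km3"] * factor
    rain = {pd.Timestamp(d).date() for d in rain_days}
    daily["rain_day"] = daily["date"].isin(rain)
    return daily[["date", "count", "rain_day"]]
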