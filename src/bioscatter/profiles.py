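"""Columnar vertical profiles: azimuthal averaging of gates into height bands.

Reflectivity factor is averaged in linear units (mm^6 m^-3) and converted
back to dBZ — reflectivity is power-additive, so the linear-domain mean is
the physically meaningful band value and is never below the dB-domain mean
(Jensen).  ZDR is averaged arithmetically in dB and rho_hv in natural units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LATTICE_N, CvpLattice, GateColumnMap, HeightBands
from .volume import PolarVolume

__all__ = ["ProfileConfig", "build_profile", "profile_series", "band_zdr_series"]


@dataclass(frozen=True)
class ProfileConfig:
    #: minimum surviving gates for a band value; single-gate bands are noise-prone
    min_gates: int = 3

    def __post_init__(self) -> None:
        if self.min_gates < 1:
            raise ValueError("min_gates must be >= 1")


def _accumulate(volume: PolarVolume, mapping: GateColumnMap):
    """Sum moments per (cell, band) over all sweeps; returns sums and counts."""
    n = LATTICE_N * LATTICE_N * HeightBands.n_bands
    z_lin = np.zeros(n)
    zdr = np.zeros(n)
    rho = np.zeros(n)
    n_valid = np.zeros(n, dtype=int)
    n_gates = np.zeros(n, dtype=int)
    for el, sw in volume.sweeps.items():
        ci = mapping.cell_index.get(el)
        if ci is None:
            continue
        bi = mapping.band_index[el]
        nr = min(sw.z.shape[1], ci.shape[1])
        flat = ci[:, :nr] * HeightBands.n_bands + bi[:, :nr]
        assigned = ci[:, :nr] >= 0
        np.add.at(n_gates, flat[assigned], 1)
        z = sw.z[:, :nr]
        ok = assigned & np.isfinite(z) & np.isfinite(sw.zdr[:, :nr]) & np.isfinite(sw.rhohv[:, :nr])
        idx = flat[ok]
        np.add.at(z_lin, idx, 10.0 ** (z[ok] / 10.0))
        np.add.at(zdr, idx, sw.zdr[:, :nr][ok])
        np.add.at(rho, idx, sw.rhohv[:, :nr][ok])
        np.add.at(n_valid, idx, 1)
    return z_lin, zdr, rho, n_valid, n_gates


def build_profile(
    volume: PolarVolume,
    lattice: CvpLattice,
    mapping: GateColumnMap,
    cfg: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Band-wise means for every retained column at one scan time.

    Returns a long-format frame keyed by (grid_row, grid_col, band_lower_m);
    bands with fewer surviving gates than ``cfg.min_gates`` are marked
    invalid and carry no values.
    """
    z_lin, zdr, rho, n_valid, n_gates = _accumulate(volume, mapping)
    rows = []
    for cell in lattice.retained():
        base = (cell.grid_row * LATTICE_N + cell.grid_col) * HeightBands.n_bands
        for b, lower in enumerate(HeightBands.lower_edges):
            i = base + b
            if n_gates[i] == 0:
                continue  # geometrically unreachable band
            valid = n_valid[i] >= cfg.min_gates
            rows.append(
                {
                    "site_id": lattice.site_id,
                    "grid_row": cell.grid_row,
                    "grid_col": cell.grid_col,
                    "timestamp": volume.timestamp,
                    "band_lower_m": lower,
                    "mean_z_dbz": 10.0 * np.log10(z_lin[i] / n_valid[i]) if valid else np.nan,
                    "mean_zdr_db": zdr[i] / n_valid[i] if valid else np.nan,
                    "mean_rhohv": rho[i] / n_valid[i] if valid else np.nan,
                    "gate_count": int(n_gates[i]),
                    "arthropod_gate_count": int(n_valid[i]),
                    "band_valid": bool(valid),
                }
            )
    return pd.DataFrame(rows)


def profile_series(
    volumes,
    lattice: CvpLattice,
    mapping: GateColumnMap,
    cfg: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Concatenate per-volume profiles into a time-indexed table.

    Volumes must be chronologically ordered with unique timestamps; rows are
    unique on (cell, band, timestamp) and only valid bands are kept.
    """
    frames = []
    seen: set = set()
    last = None
    for vol in volumes:
        if vol.timestamp in seen:
            raise ValueError(f"duplicate timestamp {vol.timestamp}")
        if last is not None and vol.timestamp < last:
            raise ValueError("volumes must be chronologically ordered")
        seen.add(vol.timestamp)
        last = vol.timestamp
        prof = build_profile(vol, lattice, mapping, cfg)
        if len(prof):
            frames.append(prof[prof["band_valid"]])
    if not frames:
        return pd.DataFrame(
            columns=[
                "site_id", "grid_row", "grid_col", "timestamp", "band_lower_m",
                "mean_z_dbz", "mean_zdr_db", "mean_rhohv", "gate_count",
                "arthropod_gate_count", "band_valid",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def band_zdr_series(profiles: pd.DataFrame, band_lower_m: int = 500) -> pd.Series:
    """Network-mean ZDR per scan time at one band (input to window fitting)."""
    sub = profiles[profiles["band_lower_m"] == band_lower_m]
    return sub.groupby("timestamp")["mean_zdr_db"].mean()
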