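"""Radar scan geometry: beam propagation, the CVP lattice, and gate assignment.

A columnar vertical profile (CVP) is a cylindrical column of atmosphere,
2.5 km in radius, over a fixed ground location near the radar.  Each radar
carries a 12 x 12 lattice of such columns inside a 60 x 60 km box centred on
the antenna; polar gates (range/azimuth/elevation resolution cells) are
assigned to the column whose centre they fall within and to a 200 m height
band between 100 and 2100 m above the radar ground reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "EARTH_RADIUS_KM",
    "EFFECTIVE_RADIUS_KM",
    "RadarSite",
    "CellStatus",
    "CvpCell",
    "CvpLattice",
    "GateLocus",
    "HeightBands",
    "GateColumnMap",
    "beam_height",
    "gate_ground_position",
    "build_cvp_lattice",
    "assign_gates_to_columns",
    "terrain_mask",
]

EARTH_RADIUS_KM = 6371.0
#: 4/3 effective-earth-radius model for standard microwave refraction.
EFFECTIVE_RADIUS_KM = 4.0 / 3.0 * EARTH_RADIUS_KM

CVP_RADIUS_KM = 2.5
CVP_SPACING_KM = 5.0
LATTICE_N = 12


@dataclass
class RadarSite:
    """Geometry and scan-strategy constants for one C-band radar.

    Defaults mirror an operational UK network radar: 5.3 cm wavelength,
    1.1 degree beam, 600 m gates averaged to 1 degree azimuth sectors,
    elevation sweeps between 0.5 and 4.0 degrees every 5 minutes.
    """

    site_id: str
    latitude: float = 51.0
    longitude: float = -0.5
    antenna_altitude: float = 50.0  # m ASL
    wavelength: float = 5.3  # cm
    beam_width: float = 1.1  # degrees
    elevation_angles: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    gate_length: float = 600.0  # m
    azimuth_step: float = 1.0  # degrees
    max_range: float = 250.0  # km
    scan_interval: float = 5.0  # minutes

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        angles = tuple(float(a) for a in self.elevation_angles)
        if not all(0.0 < a < 90.0 for a in angles):
            raise ValueError("elevation angles must lie in (0, 90) degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("elevation angles must be strictly increasing")
        self.elevation_angles = angles

    @property
    def n_azimuths(self) -> int:
        return int(round(360.0 / self.azimuth_step))

    def azimuths(self) -> np.ndarray:
        """Sector-centre azimuths, clockwise from north."""
        return (np.arange(self.n_azimuths) + 0.5) * self.azimuth_step

    def gate_ranges(self, max_range_km: float | None = None) -> np.ndarray:
        """Gate-centre slant ranges in km."""
        rmax = self.max_range if max_range_km is None else max_range_km
        n = int(np.floor(rmax * 1000.0 / self.gate_length))
        return (np.arange(n) + 0.5) * self.gate_length / 1000.0


class CellStatus(str, enum.Enum):
    RETAINED = "retained"
    CORNER_UNPROCESSED = "corner_unprocessed"
    CENTRAL_CLUTTER = "central_clutter"
    TERRAIN_BLOCKED = "terrain_blocked"


@dataclass
class CvpCell:
    grid_row: int
    grid_col: int
    easting: float  # km east of the radar
    northing: float  # km north of the radar
    radius: float = CVP_RADIUS_KM
    status: CellStatus = CellStatus.RETAINED


@dataclass
class CvpLattice:
    site_id: str
    cells: list[CvpCell] = field(default_factory=list)

    def cell(self, row: int, col: int) -> CvpCell:
        return self.cells[row * LATTICE_N + col]

    def retained(self) -> list[CvpCell]:
        return [c for c in self.cells if c.status is CellStatus.RETAINED]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {s.value: 0 for s in CellStatus}
        for c in self.cells:
            out[c.status.value] += 1
        return out

    def to_frame(self, site: RadarSite | None = None) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rec = {
                "site_id": self.site_id,
                "grid_row": c.grid_row,
                "grid_col": c.grid_col,
                "easting_km": c.easting,
                "northing_km": c.northing,
                "status": c.status.value,
            }
            if site is not None:
                # local equirectangular approximation, adequate within 30 km
                rec["lat"] = site.latitude + c.northing / 111.195
                rec["lon"] = site.longitude + c.easting / (
                    111.195 * np.cos(np.deg2rad(site.latitude))
                )
            rows.append(rec)
        return pd.DataFrame(rows)

    def export_csv(self, path: str | Path, site: RadarSite | None = None) -> None:
        self.to_frame(site).to_csv(path, index=False)


@dataclass
class GateLocus:
    elevation: float
    azimuth: float
    range: float  # km, slant
    easting: float  # km
    northing: float  # km
    height: float  # m above the radar ground reference


class HeightBands:
    """Ten half-open 200 m bands between 100 and 2100 m, named by lower edge."""

    lower_edges = tuple(range(100, 2100, 200))
    depth = 200.0
    bottom = 100.0
    top = 2100.0
    n_bands = 10

    @classmethod
    def band_index(cls, height_m) -> np.ndarray:
        """Band index for each height; -1 outside [100, 2100)."""
        h = np.asarray(height_m, dtype=float)
        idx = np.floor((h - cls.bottom) / cls.depth).astype(int)
        idx[(h < cls.bottom) | (h >= cls.top)] = -1
        return idx

    @classmethod
    def lower_edge(cls, index: int) -> int:
        return cls.lower_edges[index]


def beam_height(range_km, elevation_deg, antenna_altitude_m: float = 0.0):
    """Beam-axis height (m) under 4/3 effective-earth-radius propagation.

    h = sqrt(r^2 + R'^2 + 2 r R' sin(theta)) - R' + antenna altitude,
    with R' the effective earth radius.  Monotone increasing in both range
    and elevation.
    """
    r = np.asarray(range_km, dtype=float)
    if np.any(r < 0):
        raise ValueError("range must be non-negative")
    theta = np.deg2rad(elevation_deg)
    if np.any(theta < 0) or np.any(theta >= np.pi / 2):
        raise ValueError("elevation must lie in [0, 90) degrees")
    rp = EFFECTIVE_RADIUS_KM
    h_km = np.sqrt(r**2 + rp**2 + 2.0 * r * rp * np.sin(theta)) - rp
    out = h_km * 1000.0 + antenna_altitude_m
    return float(out) if np.isscalar(range_km) and np.isscalar(elevation_deg) else out


def gate_ground_position(
    site: RadarSite, elevation: float, azimuth, range_km
) -> GateLocus | list[GateLocus]:
    """Ground-projected locus of a gate; azimuth clockwise from north.

    Ground distance uses the flat projection g = r cos(theta); the error
    against the full spherical inversion is below 0.1% at the 30 km working
    ranges.
    """
    az = np.asarray(azimuth, dtype=float)
    if np.any(az < 0) or np.any(az >= 360.0):
        raise ValueError("azimuth must lie in [0, 360) degrees")
    r = np.asarray(range_km, dtype=float)
    if np.any(r > site.max_range):
        raise ValueError("range exceeds site max_range")
    g = r * np.cos(np.deg2rad(elevation))
    east = g * np.sin(np.deg2rad(az))
    north = g * np.cos(np.deg2rad(az))
    h = beam_height(r, elevation, 0.0)
    if np.isscalar(azimuth) and np.isscalar(range_km):
        return GateLocus(elevation, float(az), float(r), float(east), float(north), float(h))
    return [
        GateLocus(elevation, float(a), float(rr), float(e), float(n), float(hh))
        for a, rr, e, n, hh in zip(
            np.broadcast_to(az, r.shape).ravel(), r.ravel(), east.ravel(), north.ravel(), np.ravel(h)
        )
    ]


def build_cvp_lattice(site: RadarSite) -> CvpLattice:
    """12 x 12 lattice of CVP columns in the 60 x 60 km box around the radar.

    Row 0 is the northernmost row, column 0 the westernmost column.  The
    4 x 4 central block (|easting| and |northing| <= 7.5 km) is marked as
    clutter-removed, and the single upper-right corner cell (maximal easting
    and northing) as unprocessed, leaving 127 retained columns.
    """
    offsets = -27.5 + CVP_SPACING_KM * np.arange(LATTICE_N)  # west -> east
    cells: list[CvpCell] = []
    for row in range(LATTICE_N):
        northing = -offsets[row]  # row 0 = northernmost
        for col in range(LATTICE_N):
            easting = offsets[col]
            status = CellStatus.RETAINED
            if abs(easting) <= 7.5 and abs(northing) <= 7.5:
                status = CellStatus.CENTRAL_CLUTTER
            if easting == offsets[-1] and northing == -offsets[0]:
                status = CellStatus.CORNER_UNPROCESSED
            cells.append(CvpCell(row, col, float(easting), float(northing), status=status))
    return CvpLattice(site_id=site.site_id, cells=cells)


@dataclass
class GateColumnMap:
    """Vectorised gate -> (cell, band) assignment for one site/lattice.

    For each elevation sweep, ``cell_index`` and ``band_index`` are
    (n_azimuth, n_range) integer arrays; -1 marks gates assigned to no
    retained column or no height band.  ``counts`` holds the number of
    gates contributing to each (cell, band).
    """

    site: RadarSite
    lattice: CvpLattice
    cell_index: dict[float, np.ndarray]
    band_index: dict[float, np.ndarray]
    counts: np.ndarray  # (144, n_bands)
    n_ranges: int

    def gate_count(self, row: int, col: int, band: int) -> int:
        return int(self.counts[row * LATTICE_N + col, band])


def assign_gates_to_columns(
    lattice: CvpLattice, site: RadarSite, max_range_km: float = 45.0
) -> GateColumnMap:
    """Assign every gate within ``max_range_km`` to a retained column and band.

    A gate belongs to the column whose centre lies within 2.5 km of its
    ground projection; adjacent column circles are tangent, so the nearest
    centre is unique up to a measure-zero boundary (ties resolve to the
    lowest (row, col)).  The band is the 200 m interval containing the gate's
    beam-axis height above the radar ground reference.
    """
    az = site.azimuths()
    rng = site.gate_ranges(max_range_km)
    cell_status = np.array([c.status is CellStatus.RETAINED for c in lattice.cells])
    offsets = -27.5 + CVP_SPACING_KM * np.arange(LATTICE_N)
    cell_idx: dict[float, np.ndarray] = {}
    band_idx: dict[float, np.ndarray] = {}
    counts = np.zeros((LATTICE_N * LATTICE_N, HeightBands.n_bands), dtype=int)
    for el in site.elevation_angles:
        g = rng[None, :] * np.cos(np.deg2rad(el))
        east = g * np.sin(np.deg2rad(az))[:, None]
        north = g * np.cos(np.deg2rad(az))[:, None]
        h = beam_height(rng, el, 0.0)[None, :] * np.ones((az.size, 1))
        # nearest lattice centre via rounding to the 5 km grid
        col = np.rint((east - offsets[0]) / CVP_SPACING_KM).astype(int)
        row = np.rint((-north - offsets[0]) / CVP_SPACING_KM).astype(int)
        inside = (col >= 0) & (col < LATTICE_N) & (row >= 0) & (row < LATTICE_N)
        colc = np.clip(col, 0, LATTICE_N - 1)
        rowc = np.clip(row, 0, LATTICE_N - 1)
        ce = offsets[colc]
        cn = -offsets[rowc]
        within = (east - ce) ** 2 + (north - cn) ** 2 <= CVP_RADIUS_KM**2
        flat = rowc * LATTICE_N + colc
        ok = inside & within & cell_status[flat]
        ci = np.where(ok, flat, -1)
        bi = HeightBands.band_index(h)
        bi = np.where(ci >= 0, bi, -1)
        ci = np.where(bi >= 0, ci, -1)
        cell_idx[el] = ci
        band_idx[el] = bi
        sel = ci >= 0
        np.add.at(counts, (ci[sel], bi[sel]), 1)
    return GateColumnMap(
        site=site,
        lattice=lattice,
        cell_index=cell_idx,
        band_index=band_idx,
        counts=counts,
        n_ranges=rng.size,
    )


def terrain_mask(lattice: CvpLattice, terrain: Raster, site: RadarSite) -> CvpLattice:
    """Mark retained columns whose lowest beam is intercepted by terrain.

    The lowest-elevation ray toward each retained cell centre is sampled
    every gate length; if the terrain surface (m ASL) reaches the beam-axis
    height anywhere along the ray, the column is flagged as blocked.
    Blockage is monotone in terrain height by construction.
    """
    half = LATTICE_N / 2 * CVP_SPACING_KM
    if not terrain.covers(-half, -half, half, half):
        raise ValueError("terrain raster does not cover the 60 x 60 km lattice box")
    el0 = site.elevation_angles[0]
    step_km = site.gate_length / 1000.0
    out = CvpLattice(site_id=lattice.site_id, cells=[CvpCell(**vars(c)) for c in lattice.cells])
    for cell in out.cells:
        if cell.status is not CellStatus.RETAINED:
            continue
        dist = float(np.hypot(cell.easting, cell.northing))
        n_samples = max(2, int(np.ceil(dist / step_km)) + 1)
        frac = np.linspace(0.0, 1.0, n_samples)[1:]
        xs = cell.easting * frac
        ys = cell.northing * frac
        ground = dist * frac
        slant = ground / np.cos(np.deg2rad(el0))
        beam = beam_height(slant, el0, site.antenna_altitude)
        surf = np.asarray(terrain.sample(xs, ys), dtype=float)
        if np.any(surf >= beam):
            cell.status = CellStatus.TERRAIN_BLOCKED
    return out
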