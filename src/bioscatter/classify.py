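"""Per-gate echo classification: precipitation, extreme reflectivity, birds.

The separation of bioscatter from precipitation relies on the depolarization
ratio, a composite of differential reflectivity and co-polar correlation:
near-spherical raindrops (high rho_hv, near-zero ZDR) give strongly negative
DR, while irregular, horizontally elongated arthropods give DR well above
-12.5 dB.  Birds sit between arthropods and rain in ZDR, so gates retained
by the DR test are further required to exceed a conservative ZDR threshold
(3 dB) before being counted as arthropod echoes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .volume import PolarVolume

__all__ = [
    "GateLabel",
    "FilterConfig",
    "depolarization_ratio",
    "classify_gates",
    "classify_gate",
    "filter_volume",
]


class GateLabel(enum.IntEnum):
    MISSING = 0
    PRECIPITATION = 1
    HIGH_REFLECTIVITY = 2
    BIRD_LIKE = 3
    ARTHROPOD = 4


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the echo filter; all configurable per run.

    dr_threshold : gates with DR strictly below this are precipitation.
    z_cap : gates with Z strictly above this are extreme-reflectivity.
    zdr_min : gates with ZDR strictly above this (having survived the first
        two tests) are arthropods; the remainder are bird-like.
    dr_floor : numerical floor for DR when the ratio underflows (rho -> 1).
    """

    dr_threshold: float = -12.5
    z_cap: float = 45.0
    zdr_min: float = 3.0
    dr_floor: float = -60.0

    def __post_init__(self) -> None:
        if self.dr_threshold >= 0:
            raise ValueError("dr_threshold must be negative")
        if self.zdr_min <= 0:
            raise ValueError("zdr_min must be positive")


def depolarization_ratio(zdr, rho_hv, floor: float = -60.0):
    """Depolarization ratio (dB) from ZDR (dB) and rho_hv.

    DR = 10 log10[(z + 1 - 2 sqrt(z) rho) / (z + 1 + 2 sqrt(z) rho)] with
    z = 10^(ZDR/10).  Always <= 0; strictly decreasing in rho_hv at fixed
    ZDR; floored at ``floor`` dB when the numerator underflows.
    """
    rho = np.asarray(rho_hv, dtype=float)
    if np.any((rho < 0) | (rho > 1) & np.isfinite(rho)):
        raise ValueError("rho_hv must lie in [0, 1]")
    zeta = 10.0 ** (np.asarray(zdr, dtype=float) / 10.0)
    s = 2.0 * np.sqrt(zeta) * rho
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = 10.0 * np.log10((zeta + 1.0 - s) / (zeta + 1.0 + s))
    dr = np.maximum(dr, floor)
    if np.isscalar(zdr) and np.isscalar(rho_hv):
        return float(dr)
    return dr


def classify_gates(z, zdr, rho_hv, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Vectorised gate classification under the precedence rule.

    missing -> precipitation (DR < threshold) -> high_reflectivity
    (Z > cap) -> arthropod (ZDR > minimum) -> bird_like.  Each gate gets
    exactly one label; a gate failing an earlier test never reaches later
    ones.
    """
    z = np.asarray(z, dtype=float)
    zdr = np.asarray(zdr, dtype=float)
    rho = np.asarray(rho_hv, dtype=float)
    dr = depolarization_ratio(zdr, np.clip(rho, 0.0, 1.0), cfg.dr_floor)
    labels = np.full(z.shape, GateLabel.BIRD_LIKE, dtype=np.int8)
    labels[np.asarray(zdr > cfg.zdr_min)] = GateLabel.ARTHROPOD
    labels[np.asarray(z > cfg.z_cap)] = GateLabel.HIGH_REFLECTIVITY
    labels[np.asarray(dr < cfg.dr_threshold)] = GateLabel.PRECIPITATION
    missing = ~(np.isfinite(z) & np.isfinite(zdr) & np.isfinite(rho))
    labels[missing] = GateLabel.MISSING
    return labels


def classify_gate(z: float, zdr: float, rho_hv: float, cfg: FilterConfig = FilterConfig()) -> GateLabel:
    """Classify a single gate; see :func:`classify_gates`."""
    return GateLabel(int(classify_gates(np.array([z]), np.array([zdr]), np.array([rho_hv]), cfg)[0]))


def filter_volume(
    volume: PolarVolume, cfg: FilterConfig = FilterConfig()
) -> tuple[PolarVolume, dict[str, int]]:
    """Blank every non-arthropod gate in a volume; return per-label counts.

    Counts are conserved: the label counts sum to the total number of gates.
    Filtering is idempotent (already-blanked gates are 'missing').
    """
    out = volume.copy()
    counts = {lab.name.lower(): 0 for lab in GateLabel}
    for el, sw in out.sweeps.items():
        labels = classify_gates(sw.z, sw.zdr, sw.rhohv, cfg)
        for lab in GateLabel:
            counts[lab.name.lower()] += int(np.sum(labels == lab))
        keep = labels == GateLabel.ARTHROPOD
        sw.z[~keep] = np.nan
        sw.zdr[~keep] = np.nan
        sw.rhohv[~keep] = np.nan
    return out, counts
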