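"""Reflectivity-to-abundance conversion and derived summaries.

The reflectivity factor Z (dBZ) of a band is converted to radar
reflectivity eta (cm^2 km^-3) via eta_dB = Z + beta, where beta is the
Rayleigh-scattering constant 10 log10(10^3 pi^5 |K_m|^2 / lambda^4) for
wavelength lambda in cm.  Dividing the linear reflectivity by the mean
radar cross-section sigma of a single arthropod (cm^2) gives a number
density per km^3; multiplying by the band volume V_h = pi r^2 h
(r = 2.5 km, h = 0.2 km) gives a head count for the column band.

sigma carries the taxon mix of the airspace and has no defensible default;
it must be supplied explicitly (the synthetic scene's sigma_true in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RadarConstants",
    "compute_beta",
    "band_abundance",
    "abundance_table",
    "vertical_gradient",
    "extrapolate_region",
    "trap_validation_ols",
]

CVP_RADIUS_KM = 2.5
BAND_DEPTH_KM = 0.2


def compute_beta(wavelength_cm: float, dielectric_factor: float = 0.93) -> float:
    """Rayleigh dBZ -> dB(eta) offset: 10 log10(10^3 pi^5 |K|^2 / lambda^4).

    Decreasing in wavelength; 26.58 dB at lambda = 5.0 cm with |K|^2 = 0.93.
    """
    if wavelength_cm <= 0:
        raise ValueError("wavelength must be positive")
    if dielectric_factor <= 0:
        raise ValueError("dielectric factor must be positive")
    return 10.0 * np.log10(1.0e3 * np.pi**5 * dielectric_factor / wavelength_cm**4)


@dataclass(frozen=True)
class RadarConstants:
    """Conversion constants; sigma is deliberately without a default."""

    sigma: float  # cm^2, mean single-arthropod radar cross-section
    beta: float = 26.58  # dB
    dielectric_factor: float = 0.93

    def __post_init__(self) -> None:
        if self.sigma is None or self.sigma <= 0:
            raise ValueError("sigma (cm^2) must be supplied and positive")

    @classmethod
    def from_wavelength(cls, sigma: float, wavelength_cm: float,
                        dielectric_factor: float = 0.93) -> "RadarConstants":
        return cls(sigma=sigma, beta=compute_beta(wavelength_cm, dielectric_factor),
                   dielectric_factor=dielectric_factor)

    @property
    def band_volume_km3(self) -> float:
        return float(np.pi * CVP_RADIUS_KM**2 * BAND_DEPTH_KM)


def band_abundance(mean_z_dbz, constants: RadarConstants):
    """(eta_db, density per km^3, total count in the band volume).

    density = 10^((Z + beta)/10) / sigma is independent of the band volume;
    total = density * V_h.  Vectorised over ``mean_z_dbz``.
    """
    z = np.asarray(mean_z_dbz, dtype=float)
    eta_db = z + constants.beta
    eta_lin = 10.0 ** (eta_db / 10.0)  # cm^2 per km^3
    density = eta_lin / constants.sigma
    total = density * constants.band_volume_km3
    if np.isscalar(mean_z_dbz):
        return float(eta_db), float(density), float(total)
    return eta_db, density, total


def abundance_table(selected_profiles: pd.DataFrame, constants: RadarConstants) -> pd.DataFrame:
    """Abundance estimates for a table of selected band profiles.

    Expects columns mean_z_dbz and the profile keys; bands without a value
    produce no estimate (absence is instrumental, not a zero count).
    """
    out = selected_profiles.copy()
    out = out[np.isfinite(out["mean_z_dbz"].to_numpy(dtype=float))]
    eta_db, density, total = band_abundance(out["mean_z_dbz"].to_numpy(dtype=float), constants)
    out["eta_db"] = eta_db
    out["density_per_km3"] = density
    out["total_count"] = total
    out["sigma_cm2"] = constants.sigma
    out["beta_db"] = constants.beta
    return out


def vertical_gradient(estimates: pd.DataFrame, value: str = "total_count",
                      band: str = "band_lower_m") -> dict:
    """OLS slope of abundance on band index (individuals per 200 m step).

    Returns slope, its SE, adjusted R^2 and p-value; needs >= 3 distinct
    bands.
    """
    bands = np.sort(estimates[band].unique())
    if bands.size < 3:
        raise ValueError("need at least 3 height bands for a vertical gradient")
    step = np.diff(bands).min()
    x = (estimates[band].to_numpy(dtype=float) - bands[0]) / step
    y = estimates[value].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "slope_se": float(fit.bse[1]),
        "adj_r2": float(fit.rsquared_adj),
        "p_value": float(fit.pvalues[1]),
        "n": int(fit.nobs),
    }


def extrapolate_region(mean_density_per_km3: float, region_area_km2: float,
                       band_depth_km: float = BAND_DEPTH_KM) -> float:
    """Total individuals over a region: density x area x band depth."""
    if mean_density_per_km3 < 0 or region_area_km2 <= 0 or band_depth_km <= 0:
        raise ValueError("inputs must be positive (density may be zero)")
    return float(mean_density_per_km3 * region_area_km2 * band_depth_km)


def trap_validation_ols(trap_counts: pd.DataFrame, estimates: pd.DataFrame,
                        rain_days=frozenset(), min_days: int = 10) -> pd.DataFrame:
    """Per-band OLS of z-scored trap counts on z-scored radar estimates.

    Both series are standardized before fitting, so the slope equals the
    Pearson correlation; days with heavy rainfall are excluded outright.
    ``trap_counts`` needs columns (date, count); ``estimates`` needs
    (date, band_lower_m, density_per_km3).
    """
    rain_days = {pd.Timestamp(d).date() if not hasattr(d, "toordinal") else d for d in rain_days}
    traps = trap_counts.copy()
    traps["date"] = pd.to_datetime(traps["date"]).dt.date
    traps = traps[~traps["date"].isin(rain_days)]
    est = estimates.copy()
    est["date"] = pd.to_datetime(est["date"]).dt.date
    est = est[~est["date"].isin(rain_days)]
    rows = []
    for band, grp in est.groupby("band_lower_m"):
        daily = grp.groupby("date")["density_per_km3"].mean()
        merged = traps.merge(daily.rename("radar"), on="date")
        merged = merged.dropna(subset=["count", "radar"])
        if len(merged) < min_days:
            raise ValueError(
                f"band {band}: only {len(merged)} overlapping non-rain days (< {min_days})"
            )
        zc = _zscore(merged["count"].to_numpy(dtype=float))
        zr = _zscore(merged["radar"].to_numpy(dtype=float))
        fit = sm.OLS(zc, sm.add_constant(zr)).fit()
        rows.append(
            {
                "band_lower_m": band,
                "slope": float(fit.params[1]),
                "adj_r2": float(fit.rsquared_adj),
                "p_value": float(fit.pvalues[1]),
                "n_days": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows).sort_values("band_lower_m", ignore_index=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance series cannot be standardized")
    return (x - x.mean()) / sd
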