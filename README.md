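# bioscatter

Estimating aerial arthropod abundance from dual-polarization weather
surveillance radar, as a tested, reusable pipeline.  The intended users are
radar aeroecologists and biodiversity researchers who want to turn
operational C-band polar volumes into column-resolved insect number
densities and national-scale spatio-temporal trends — and to validate every
stage of that conversion against synthetic scenes with known ground truth.

## What it computes

A weather radar's polar volumes (reflectivity factor Z in dBZ, differential
reflectivity Z_DR in dB, co-polar correlation ρ_HV) are processed in six
stages:

1. **Scan geometry** — beams propagate under the 4/3-effective-earth-radius
   model; a 12 × 12 lattice of *columnar vertical profiles* (CVPs: cylinders
   of 2.5 km radius, ten 200 m height bands between 100 and 2100 m) covers
   the 60 × 60 km box around the radar.  The 4 × 4 central block (ground
   clutter) and one corner cell are removed, leaving 127 columns; terrain
   blockage masks columns whose lowest beam intersects the surface.
2. **Echo classification** — the depolarization ratio
   `DR = 10 log10[(ζ + 1 − 2√ζ ρ_HV)/(ζ + 1 + 2√ζ ρ_HV)]`, ζ = 10^(Z_DR/10),
   separates near-spherical precipitation (DR < −12.5 dB) from bioscatter;
   gates above 45 dBZ are removed as extreme reflectivity; of the remainder,
   only strongly elongated targets (Z_DR > 3 dB) count as arthropods.
3. **Profiles** — surviving gates are azimuthally averaged per column and
   band (Z in linear units, Z_DR in dB, ρ_HV in natural units).
4. **Activity windows** — penalized cyclic splines fitted to diel and annual
   Z_DR series locate the two daily activity peaks (≈ 11:00 and 20:00 GMT)
   and the April–October flight season; one scan (maximum Z_DR) is kept per
   column, day and window.
5. **Abundance** — band reflectivity converts to number density via
   `η (dB) = Z + β` with `β = 10 log10(10³ π⁵ |K_m|² / λ⁴)` (26.58 dB for
   the operational C-band constants), then `density = 10^(η/10) / σ` with σ
   the mean single-arthropod radar cross-section (cm², supplied explicitly).
   Vertical gradients, regional extrapolations and ground-trap validation
   regressions (standardized OLS, so the slope is the Pearson correlation)
   summarize the estimates.
6. **Trend model** — a hierarchical additive model of log₁₀(density + 1):
   smooths of year (globally and per radar), a 2-D spatial smooth, random
   intercepts (radar, month, grid cell), and smooths of temperature, rain,
   wind, land cover, night-time light and elevation, with double-penalty
   term selection, AR(1) pre-whitened errors and Moran's I residual
   correlograms.  The engine (`bioscatter.gam.PenalizedGAM`) is a
   scikit-learn-style estimator using penalized B-splines with REML
   smoothing selection.

A synthetic-scene module generates polar volumes (insect layers with
height-declining density and bimodal diel activity, precipitation cells,
bird-like targets), covariate rasters and trap counts with recorded truth,
so every stage is testable end-to-end.

## Worked example

```python
import pandas as pd
from bioscatter import (
    RadarSite, build_cvp_lattice, assign_gates_to_columns,
    SceneConfig, simulate_scan_volume, filter_volume,
    build_profile, RadarConstants, compute_beta,
)
from bioscatter.abundance import abundance_table

site = RadarSite(site_id="demo-wsr")
lattice = build_cvp_lattice(site)
print("lattice:", lattice.counts())

mapping = assign_gates_to_columns(lattice, site)
scene = SceneConfig(seed=1)
volume, truth, _ = simulate_scan_volume(
    scene, site, lattice, pd.Timestamp("2014-07-15 11:00"), mapping
)
filtered, counts = filter_volume(volume)
print("gate classes:", {k: v for k, v in counts.items() if v})

profiles = build_profile(filtered, lattice, mapping)
constants = RadarConstants(sigma=scene.sigma_true, beta=compute_beta(5.0, 0.93))
est = abundance_table(profiles[profiles.band_valid], constants)
band500 = est[est.band_lower_m == 500]
print(f"beta = {constants.beta:.2f} dB")
print(f"band-500 density: median {band500.density_per_km3.median():.3g} per km^3 "
      f"over {len(band500)} columns")
```

prints

```
lattice: {'retained': 127, 'corner_unprocessed': 1, 'central_clutter': 16, 'terrain_blocked': 0}
gate classes: {'missing': 133459, 'precipitation': 4294, 'bird_like': 44340, 'arthropod': 33907}
beta = 26.58 dB
band-500 density: median 7.36e+06 per km^3 over 124 columns
```

The lattice counts are the design arithmetic (144 columns, 127 retained);
the gate-class tally shows the filter removing clear-air background
("bird_like" here includes weak non-elongated echoes) and the sparse
mid-morning precipitation; the recovered band-500 median density is within
1.4% (median relative error) of the scene's painted truth at this noise
level.

A `bioscatter` command-line interface exposes the same stages
(`simulate`, `classify`, `profiles`, `windows`, `abundance`, `run-all`);
`bioscatter run-all --seed 5 --out out/` runs the pipeline end-to-end on a
seeded synthetic study and writes a provenance manifest.

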