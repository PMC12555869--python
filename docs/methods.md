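# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, in the spirit of a statistical methods appendix.

## Radar geometry and the CVP lattice

Beam-axis height uses the standard 4/3-effective-earth-radius refraction
model, `h = sqrt(r² + R′² + 2 r R′ sin θ) − R′` with `R′ = (4/3) × 6371 km`;
ground range uses the flat projection `g = r cos θ`, whose error against the
full spherical inversion is below 0.1% at the ≤ 30 km working ranges.  Gate
heights and the ten 200 m analysis bands (lower edges 100 … 1900 m,
half-open intervals) are referenced to the radar ground level, not sea
level, because the columns describe the airspace above each site.

The lattice is 12 × 12 columns of 2.5 km radius at 5 km spacing (tangent
circles) in a 60 × 60 km box.  Row 0 is the northernmost row and column 0
the westernmost; the "upper-right" (maximum easting and northing) cell is
the unprocessed corner.  A gate belongs to the column whose centre lies
within 2.5 km of its ground projection; because the circles are tangent,
the nearest centre is unique except on a measure-zero boundary, where ties
resolve to the lowest (row, col) for determinism.  Gates between circles
(near the diagonal corners of the spacing grid) belong to no column.

Terrain blockage samples the lowest-elevation ray toward each retained
centre every gate length (600 m) and flags the column if the terrain
surface reaches the beam-axis height anywhere along the ray.  This is a
deliberate simplification — no partial-beam blockage fractions — and the
per-column status is recorded so the rule can be audited.  Features
narrower than the sampling step can be missed; the rule is monotone in
terrain height.

## Echo classification

The depolarization ratio
`DR = 10 log10[(ζ + 1 − 2√ζ ρ)/(ζ + 1 + 2√ζ ρ)]`, `ζ = 10^(Z_DR/10)`,
is ≤ 0 dB, strictly decreasing in ρ_HV at fixed Z_DR, and floored at
−60 dB when the numerator underflows (ρ → 1 at ζ = 1); the floor sits far
below every threshold in use.  Classification applies a strict precedence:
missing → precipitation (DR < −12.5 dB) → extreme reflectivity
(Z > 45 dBZ) → arthropod (Z_DR > 3 dB) → bird-like.  Boundary conventions
are literal: a gate at exactly the DR threshold or exactly 45 dBZ is kept,
one at exactly 3 dB of Z_DR is excluded.  All three thresholds are
configurable per run (more elongated taxa justify a higher Z_DR cut) and
echoed into output metadata.

## Profiles

Reflectivity factor is power-additive, so band means are taken in linear
units (mm⁶ m⁻³) and reconverted to dBZ; by Jensen's inequality the linear
mean never falls below the dB mean.  Z_DR averages arithmetically in dB and
ρ_HV in natural units.  Gates are uniformly weighted within a column — no
range weighting, which would be an unverifiable elaboration.  Bands with
fewer than `min_gates` surviving gates (default 3; single-gate bands are
noise-prone) carry no value: a missing band is an instrumental absence,
never a zero abundance.

## Activity windows

Diel and annual mean-Z_DR series are fitted with penalized cyclic B-splines
(basis dimension 10 for the 24 h period, 20 for the 365 d period).  Windows
are the contiguous regions where the fitted curve exceeds half of its peak
above baseline (the curve minimum), rounded outward to whole hours or days,
one window per local maximum; maxima below that same half-amplitude are
treated as fitting wiggles.  The extraction rule is a design choice — the
operational analysis states the resulting windows (0800–1400 and 1800–2200
GMT; 15 April – 30 October) but not the criterion — so those fixed windows
are also available as presets and are the pipeline default.  Scan selection
takes, per column, day and window, the scan maximizing the unfiltered
band-500 m mean Z_DR (the share of elongated bioscatter peaks with
activity, so the unfiltered profile is the right selection signal); ties go
to the earliest scan.  Selecting a single scan per window avoids
double-counting individuals that stay airborne across consecutive scans.

## Abundance conversion

`η (dB) = Z (dBZ) + β` with
`β = 10 log10(10³ π⁵ |K_m|² / λ⁴)`; at λ = 5.0 cm and |K_m|² = 0.93 this is
26.58 dB, the operational C-band constant.  (The network's radars are
quoted at λ = 5.3 cm, which would give ≈ 25.57 dB; the printed constant is
treated as authoritative and the discrepancy documented rather than
resolved — β may be supplied directly or computed from a wavelength, and
both paths are logged.)  Linear reflectivity (cm² km⁻³) divided by the mean
single-arthropod radar cross-section σ (cm²) gives number density per km³;
multiplying by the band volume `V_h = π (2.5)² × 0.2 ≈ 3.927 km³` gives a
head count.  Density is independent of `V_h` by construction.  σ carries
the (unknown) taxon mix of the airspace and therefore has **no default**:
it must be supplied and is logged with every estimate table; in tests the
synthetic scene's `sigma_true` plays this role.

Trap validation z-scores both daily series before ordinary least squares,
making the slope equal to the Pearson correlation (the two instruments
sample incommensurate volumes); days with heavy rain are excluded outright.

## Synthetic scenes

The generator paints, per scan: an insect layer whose density declines
linearly with band (default 10⁷ km⁻³ at the lowest band, −10⁶ km⁻³ per
band), modulated by a two-Gaussian diel curve (peaks 11:00 and 20:00 GMT,
widths 1.5/1.2 h, amplitudes 1.0/0.8) and a flat-topped annual envelope
(super-Gaussian of order 6, centre day 197, half-width 87 d — at least half
activity May–September, near zero in winter); precipitation cells (Z
20–55 dBZ, Z_DR ≈ 0.8 dB, ρ_HV ≈ 0.99, hence DR ≈ −21 dB) on randomly
drawn rain days; bird-like point targets (Z_DR ≈ 2 dB — the 3 dB cut
removes most but deliberately not all); and a weak clear-air background.
Insect gates carry `Z = 10 log10(density σ_true) − β` exactly, so with
noise, occupancy sampling and layer decoupling switched off
(`SceneConfig.noiseless()`, which also removes contaminant targets) the
pipeline inverts the forward model to machine precision.  Gate *occupancy*
(the probability a gate holds insects, density / 1.5×10⁷ capped at 1) makes
the unfiltered band Z_DR track activity — the feature the window stage
detects — and a per-day lognormal jitter (sd 0.1 per band) decouples
vertical layers so trap-validation slopes genuinely decay with height.
Every random stream derives from the scene seed plus the scan timestamp, so
volumes are bit-reproducible.

What the generator does **not** emulate: physically detailed scattering
(no Mie/T-matrix cross-sections), storm morphology, bird migration
dynamics, beam broadening or sidelobes, and taxon mixtures (a single σ).
Passing tests therefore demonstrate the correctness and calibration of the
*pipeline* under its own assumptions, not the accuracy of radar entomology
on real atmospheres.

## The additive-model engine

`PenalizedGAM` is a Gaussian additive model: cubic B-spline bases on
equidistant knots with second-order difference penalties (equidistance
makes the penalty null space exactly the linear functions), tensor-product
surfaces with one penalty per margin, cyclic bases with wrapped difference
penalties, ridge-penalized factor dummies as random intercepts, and
varying-coefficient or per-level ("by") smooths.  Identifiability uses the
sum-to-zero constraint absorbed by a QR reparameterization.  Basis budgets
default to k = 8 for 1-D smooths and k = 30 (≈ 5 × 5 tensor, plus
constraint) for the spatial surface — modest sizes for ~10³-row tables.

Smoothing parameters minimize the restricted likelihood (REML), profiled
over the scale; the `log|S|₊` term is computed block-wise per term (the
summed penalty is block-diagonal), with block ranks fixed at a reference λ
so the objective stays smooth.  GCV is available as an alternative
criterion.  `select=True` adds a normalized projection penalty on each
smooth's penalty null space, so whole terms can shrink out of the model
(double-penalty selection).  The optimizer is L-BFGS-B over log₁₀ λ ∈
[−8, 10] with a wide finite-difference step (the objective is O(n log σ²),
so tiny steps drown in rounding noise), followed by coordinate-wise grid
polishing with long jumps — the restricted likelihood has plateaus spanning
many decades of λ in which gradient methods stall — and a restart.  The
profiled scale is floored at 10⁻⁹ of the response variance per residual
dof, which keeps the objective well-behaved on noise-free data.  The
engine reproduces R/mgcv REML fits on shared test data to within a few
percent RMSE (a cross-check in the test suite, never the implementation).

Temporal autocorrelation is handled by AR(1) pre-whitening within each
declared series (quasi-differencing, first element scaled by √(1−ρ²)).  ρ
is estimated by feasible GLS: the pooled lag-1 autocorrelation of pilot
residuals, corrected for the within-series fitted-mean bias (+(1+ρ)/T),
then refined by folding back the autocorrelation left in the pre-whitened
innovations.  A residual downward bias of a few hundredths remains because
the fitted smooths absorb part of the autocorrelated noise; this is shared
with the standard `start_value_rho` practice.  AR(1) whitening also costs
efficiency on covariates that are constant within a series — their
information is quasi-differenced away — which is the main practical limit
on recovering weak static effects (land-cover smooths) in the presence of
cell-level heterogeneity.

AIC is the Gaussian conditional form with effective degrees of freedom;
deviance explained and adjusted R² come from the unwhitened residuals.
Prediction standard errors use the Bayesian posterior covariance
(delta-method evaluation at the prediction design); covariates outside the
training range are flagged as extrapolation, with constant-value basis
clamping beyond the knots.  Random intercepts evaluate to the population
level (zero) for unseen or absent factor levels, which is how prediction
rasters are produced.

Moran's I correlograms use binary distance-band weights on column
centroids, the analytic expectation −1/(n−1), and one-sided permutation
p-values (199 permutations by default, seed recorded); p-values across
bins are reported unadjusted.  On tables with repeated measures per
column, residuals are averaged per column before the correlogram.

The candidate ladder has seven models, each nested in the next: (1) year
smooth; (2) + spatial smooth; (3) + random intercepts (radar, month, grid
cell); (4) + climate smooths (Tmax, rain, wind); (5) + land-cover smooths;
(6) + night-time light and elevation ("full"); (7) full + per-radar year
smooths.  Candidates are ranked by AIC; a candidate that fails to fit is
recorded and excluded rather than fatal.  The response is
log₁₀(density + 1) before Gaussian fitting (flag recorded): abundance
densities are continuous, strictly positive quantities spanning orders of
magnitude.

## Problem sizes

The test suite and acceptance checks run at sizes chosen to exercise every
code path while keeping a full run in minutes on one core: single-radar
scenes (8 sweeps × 360 azimuths × 75 gates), one- to three-day studies at
60–240 min scan spacing, 10⁵-gate filter calibrations, 20-replicate window
recovery, and 2 032-row trend tables (127 columns × 8 years × 2 scans).
The same code paths scale to multi-year, multi-radar archives; only the
inputs grow.

## Known limitations

- The terrain rule cannot reproduce site-specific obstruction lists; the
  84-column network figure is design arithmetic, not a terrain result.
- σ is a single network-wide constant; size/taxon decomposition is out of
  scope.
- The trend engine fits Gaussian identity models only, and random effects
  are intercepts (no random slopes).
- Window extraction assumes at most a handful of well-separated activity
  peaks; windows crossing midnight are reported on an unwrapped hour axis.
- The ALAN–urban collinearity variant (refitting with night-time light
  residualized on urban cover) is provided as a labelled variant, not a
  reproduction of any published re-analysis.
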