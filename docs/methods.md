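# Methods

This note records the models, defaults, and numerical choices behind each
`nucleomech` module, and what the synthetic generators do and do not
emulate.

## Rheology

**Model.** Stress relaxation at constant strain is fit with a two-element
Maxwell–Wiechert model

σ(t) = σ₀ · (p + a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂)),  p = 1 − a₁ − a₂,

with bounds a₁, a₂ ∈ [0, 1], τ₁, τ₂ ∈ (0, 100·t_max], and a soft penalty on
a₁ + a₂ > 1. Fitting uses bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, tolerances 1e-14) from a
grid of starts with τ ∈ {t_max/100, t_max/10, t_max}; ties are broken
toward the smaller fast time constant. The two time constants are
interchangeable by symmetry; results are reported with τ₁ ≤ τ₂.

**Half time.** τ½ is the unique root of σ(t)/σ₀ = 1/2, found by `brentq` on
[0, 100·max(τ₁, τ₂)]. When the fitted plateau p ≥ 0.5 the stress never
falls to half its initial value and τ½ is `None`, not an extrapolation.
For a single exponential, τ½ = τ·ln 2 exactly; the two reference materials
correspond to τ = 1442.695 s (τ½ ≈ 1000 s) and τ = 288.539 s (τ½ ≈ 200 s).

**Identifiability.** On (near-)constant data the split between plateau and
a vanishing-weight mode with τ ≫ t_max is not identifiable; the fitted
plateau is 1 only to ~1e-3. Time constants much larger than the record
length are likewise reported as fitted but are weakly constrained.

**Initial modulus.** The slope of stress vs strain over the 5–10% strain
window of a compression ramp (ordinary least squares on the in-window
points). **Frequency sweeps** are normalized by G′ interpolated at
ω = 1 rad/s in log-log coordinates.

## Morphometry

**Segmentation.** Maximum-intensity projection → Gaussian blur
(σ = 2 px) → Otsu threshold → largest connected component with holes
filled. Per-slice masks re-threshold each slice inside the projected
footprint at the single stack-wide in-mask Otsu value. A per-slice Otsu is
deliberately not used: on slices that are almost entirely nucleus it
degenerates into splitting the foreground noise and deletes real area.
Slices whose in-mask maximum does not exceed the threshold (above and below
the nucleus) contribute no area.

**Volume.** V = Σ_z A_z · Δz with A_z the per-slice area in µm² and Δz the
z-step (default 0.3 µm). This is a Riemann sum; on a 5×5×3 µm test
ellipsoid at default sampling it is accurate to ~4%.

**Compaction index.** Integrated in-mask intensity divided by V
(a.u. per µm³). It is linear in global intensity scaling and, by
construction, blind to how intensity is arranged within the mask: a clumped
and a uniform nucleus with equal total signal score the same.

**2-D segmentation.** Blur → Otsu → optional watershed on the smoothed
(σ = 1 px) Euclidean distance transform — smoothing prevents one marker per
plateau pixel on round nuclei — → minimum-area filter. Per-nucleus mean
channel intensities come from `ndi.mean` over the label map.

## Wrinkling

The index is the mean Gaussian-derivative gradient magnitude (σ = 2 px)
inside the eroded nucleoplasm of an intensity-normalized lamin image.
Normalization maps the 1st–99th in-mask percentiles to [0, 1], making the
index invariant to affine intensity changes. The erosion radius defaults to
max(0.1·R_eq, 5·σ), where R_eq is the equivalent radius of the nucleus
mask: the 10% term scales with the nucleus, the 5σ floor keeps the bright
rim's own gradient out of the measurement. On synthetic nuclei the index is
monotone in fold amplitude, sits at the noise floor for fold-free nuclei,
and varies < 6% across nucleus radii of 2–6 µm.
`validate_decorrelation` runs a seeded permutation test of the Pearson
correlation between index and nucleus area, to verify on a given dataset
that the score is not a size surrogate.

## FRAP

Traces are normalized by the mean of the prebleach frames (default 7 frames
at 0.74 s spacing; postbleach at 1 s). Recovery is fit with

I(t) = I_plateau − (I_plateau − I_bleach)·e^(−t/τᵣ)

via `curve_fit` from a deterministic initialization (first frame, mean of
the last 10%, τ₀ from the midpoint crossing). t½ = τᵣ·ln 2 by default
("midpoint" definition: time to reach halfway between bleach and plateau);
an "absolute" definition (time to reach I_plateau/2) is also available.
Mobile fraction = (I_plateau − I_bleach)/(1 − I_bleach) on normalized
traces, clipped to [0, 1.05]. Traces whose tail does not rise above the
first postbleach frame are reported as not recovered rather than fit. At
2% noise and 120 frames, τᵣ is recovered with < 0.1% bias and ~3% spread.

## Dynamics

**Motion correction.** The observed position of a tracer is modeled as
obs(t) = R(t)·p(t) + c(t), with c(t) the nuclear centroid track and R(t)
the nuclear rotation estimated from ≥ 2 (2-D) centered landmarks by the
Kabsch algorithm (SVD with determinant-sign correction). Correction applies
the inverse in the same order: subtract the centroid, then apply Rᵀ. The
mean rotation across frames is the polar projection (via SVD) of the
arithmetic mean of rotation matrices. The round trip on simulated motion is
exact to ~1e-15 µm.

**MSD.** Time-averaged over all ordered pairs at each lag:
MSD(τ=kΔt) = (1/(N−k)) Σ_i |p(i+k) − p(i)|². Per-lag sums use exact
(`math.fsum`) accumulation so results are bit-identical regardless of
evaluation order. `ensemble_msd` averages per-track curves, unweighted,
over the lags common to all tracks.

**Power-law fit.** log₁₀ MSD vs log₁₀ τ by ordinary least squares over the
first half of the lag range (at least 3 lags): α is the slope, D = 10^b the
intercept. Fits with R² ≤ 0.8 are rejected: α and D are still reported,
but the fit is flagged and the confinement time T = (1/D)^(1/α) is `None`,
and `ensemble_summary` excludes it.

**Per-track versus ensemble fitting.** On short tracks (~20 frames) the
per-track fit is noisy and, at α ≥ 1, biased: the median α is low by
~0.05 and the median D high by ~40%, because D is an extrapolation of each
noisy log-log line to τ = 1 s — a long lever arm when lags are minutes.
The generator is unbiased (ensemble E[MSD] matches D·τ^α to ~2%); the bias
is a property of the estimator, reproduced and quantified in the test
suite. Fitting the ensemble-averaged MSD recovers α within ~0.01 and D
within a few percent at 200 tracks, and is the recommended mode for group
comparisons; per-track fits remain available for distributional readouts
(e.g. fraction of confined loci), where comparisons should be made between
conditions fit the same way, not against absolute D values.

## Synthetic data (`simkit`)

Every generator takes a seed and returns its ground truth. Noise is
Gaussian unless stated. What they emulate, and don't:

- `gen_relaxation`: exact model curves plus multiplicative noise; no ringing
  or load-cell drift.
- `gen_nucleus_stack`: hard-edged ellipsoids with optional multiplicative
  smoothed "clumping" texture (normalized to mean 1 inside, preserving
  integrated intensity); no PSF blurring, z-attenuation, or partial-volume
  effects beyond voxelization.
- `gen_lamin_image`: a disk with a Gaussian rim (σ = 1.5 px) and interior
  plane-wave folds of fixed 12 px wavelength, so fold density is
  area-invariant; contrast is linear in fold amplitude. No out-of-focus
  light.
- `gen_frap_trace`: single-pool exponential recovery; no diffusion-limited
  early phase or acquisition bleaching.
- `gen_tracks`: fractional Brownian motion by Davies–Harte circulant
  embedding (Cholesky fallback), per-coordinate step variance
  (D/dim)·Δt^α; α = 2 is a constant random velocity per track. No
  localization error or blinking.
- `gen_nucleus_motion` + `compose_observed_tracks`: rigid rotation about a
  drifting center; no deformation.

## Reproducibility

All randomness flows through `numpy.random.default_rng` seeds;
`scripts/acceptance.py` derives per-curve seeds from a single `--seed` via
`SeedSequence.spawn`, reduced mod 2³¹. Pipeline runs record the resolved
config, its SHA-256 digest, the seed, and the package version in
`run_log.json`; reruns of the same config are byte-identical.
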