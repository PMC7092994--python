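# Methods

## The measurement chain and what each stage assumes

A breath-hold CVR session produces three time bases: gas partial pressures
sampled continuously at the nostril, a beat-resolved velocity trace from
transcranial Doppler, and a volume-resolved BOLD series at the repetition
time. The package reduces each to a common currency — metric values on a
uniform grid — and couples them.

**Gas metrics.** The nasal line introduces a transport delay, removed by
cross-correlating the gas record's respiration-phase proxy against a
respiration reference within ±`max_lag_s` (the proxy is the trace's own
respiration channel when present, otherwise −d(PCO₂)/dt, which rises during
inspiration). End expiration is the local maximum of PCO₂ closing the
alveolar plateau; end inspiration is the preceding local minimum. Detection
runs on PCO₂ only (its plateaus are sharpest) and PO₂ is read at the
PCO₂-derived timestamps, so both gases share one time base and within-breath
marker mismatch cannot occur. Peak finding uses a prominence threshold of
25% of the trace interquartile range and a 1.5 s minimum separation;
breaths with ΔPCO₂ < 1 mmHg are treated as shallow artifacts and dropped
(both configurable). Apneic epochs contain no markers; metric series are
bridged across each hold by the chord between the last pre-hold and first
post-hold breath, which is exactly linear interpolation between breath
timestamps. ToB is the spacing of consecutive end-expiration markers, so the
breath spanning a hold carries the hold in its ToB.

**Hemodynamics.** Velocity is despiked with a 0.1 s running median
(reflection at the edges), beats are found by prominence-constrained peak
search with the inter-beat interval bounded by a heart-rate range, and
cycles run trough to trough with the mean stamped at the cycle midpoint.
Inter-beat intervals longer than the slow bound are flagged as artifact
gaps and the overlapping cycles are excluded rather than interpolated.
Percent change is taken against the mean of the first 30 s (resting
baseline), making the series invariant to the insonation-angle-dependent
absolute scale. BOLD voxels are divided by their temporal mean (×100) and a
5th-order polynomial is removed; over a 10-minute record this attenuates
drift below ~0.008 Hz while leaving the task band (0.008–0.03 Hz)
essentially untouched (≤10% at 0.008 Hz, verified by sinusoid sweep). A
12-volume pre-equilibrium discard is the reader's job and is applied once.

**Coupling.** Both series are linearly interpolated onto a shared uniform
grid over their overlap (0.5 s for Doppler work, the TR for BOLD) and
correlated at zero lag. Fisher Z = atanh(r) is used for group statistics;
|r| = 1 saturates at atanh(1 − 10⁻¹⁵) with a flag rather than producing an
infinity. Group comparisons are two-sided paired t-tests of z(bER) against
z(other metric).

**Wavelet coherence.** The continuous Morlet transform (ω₀ = 6) is computed
by FFT on a dyadic grid of 12 scales per octave covering Fourier periods
4–256 s (Fourier period = scale · 4π/(ω₀+√(2+ω₀²))). Squared coherence is
|S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)) with the standard smoothing: a
Gaussian in time whose width equals the scale, then a 0.6-octave boxcar
across scale. The cone of influence is the e-folding time √2·s converted to
period. Significance is per scale: AR(1) coefficients are fitted to both
inputs by lag-1 autocorrelation (clipped at |φ| = 0.99), surrogate pairs
are generated with both series randomized, and the 95th percentile of
off-cone coherence pooled over time and surrogates is the threshold
(default 300 surrogates). Under independent AR(1) pairs the pointwise
exceedance of this threshold calibrates to ~5%.

**Time-averaged coherence (TAC).** Per scale and phase-lag quadrant, TAC is
the sum of significant off-cone coherence divided by the maximum possible
coherence at that scale — the count of off-cone points in the quadrant,
i.e. every point at coherence 1. Quadrants are half-open: the in-phase pair
0 ± π/2 is phase ∈ (−π/2, π/2], the anti-phase pair is its complement; the
positive-phase convention is "first series leads". Two alternatives are
exposed behind flags: a shared (all-quadrant) denominator, under which the
four quadrants partition the unrestricted TAC exactly, and a
threshold-sum normalization. Scales that never leave the cone are flagged
invalid and excluded from band means. Band summaries average TAC over
scales with frequency inside the band; the default 0.008–0.03 Hz band
touches periods ~33–125 s on the default grid.

**CVR mapping.** CVR is the OLS slope of detrended percent BOLD on the
regressor (with intercept), vectorized over voxels; t and two-sided p use
n − 2 degrees of freedom. Multiple comparisons are handled by cluster
extent: Gaussian null volumes are smoothed to a stated FWHM (a config
input, not estimated from data — default 8 mm for real acquisitions, 0 for
the synthetic generator whose noise is spatially independent), rescaled to
unit variance in the mask, thresholded two-sided at voxel p < 0.005, and
the (1 − α) quantile of the maximum face-connected (6-neighbor) cluster
size over iterations gives the minimum cluster volume; clusters exactly at
the threshold are retained. vCVR is the percentage of a region's voxels in
the significant mask. Group maps use voxelwise one-sample or paired t with
Benjamini–Hochberg FDR across in-mask voxels; zero-variance voxels are
flagged NaN and excluded from the FDR family.

## The synthetic generator

The generator is the package's study stand-in: its defaults are the
conditions reported for the MRI sessions, and cohort simulations draw
per-subject parameters directly from the published per-subject table
(`synthetic.MRI_SESSION_SUBJECTS`).

- **Protocol**: 60 s lead-in, six 30 s holds, gaps uniform on 60–90 s
  (seeded); the exogenous arm alternates +4/+8 mmHg hypercapnic steps with
  normocapnic gaps.
- **Breaths**: piecewise-linear trapezoids, one cycle per breath (period
  5 ± 0.4 s), with a slightly sloped alveolar plateau (0.8 mmHg) so the
  end-tidal point is a unique local extremum, as in real capnograms.
  Baselines default to P_ET_CO₂ 38.7, P_ET_O₂ 113.8 mmHg with swings 36.6
  and 32.7 mmHg (baseline bER 0.89).
- **Breath-depth noise**: a common per-breath ventilatory factor (SD 1.5%,
  matching the reported baseline swing variability of ~1–2%) scales both
  swings; bER cancels it by construction. Independent per-gas end-tidal
  jitter is 0.3 mmHg.
- **Holds**: the nasal sample is static during apnea (the trace holds the
  last expired value, minus a 0.5 mmHg sampling-line relaxation that keeps
  the pre-hold marker an extremum). Holds begin at the first breath
  boundary after the cue and last the cued duration ± 3 s (subjects hold
  "as long as they can"). The accumulated exchange — default drifts 0.30
  (CO₂) and 1.28 (O₂) mmHg per second of apnea, from the reported hold
  responses divided by hold duration — appears in full in the first
  post-hold expirate and then washes out. Washout is per-gas: end-tidal CO₂
  renormalizes within a few breaths (τ = 8 s) while the O₂ stores refill
  more slowly (τ = 18 s). Epoch-to-epoch drift variability uses CVs of 0.6
  (CO₂) and 0.35 (O₂), reflecting the reported hold-response scatter, which
  for CO₂ is comparable to its mean (some subjects are near
  non-responders). The first recovery breaths are deep, slow gasps (+30%
  cycle length, decaying with the O₂ washout).
- **Hemodynamic response**: velocity (or BOLD) follows the z-scored bER
  drive convolved with a delayed single-exponential kernel, delay 2 s,
  time constant 6 s, normalized to unit gain. The timing is set by the
  observation that the reported flow and BOLD changes reach their plateau
  (~40% ΔCBFv, ~2% gray-matter ΔBOLD) by the end of a 30 s hold, so the
  response must be mostly realized within the hold; the response still
  outlasts the hold because the gas excess itself washes out over tens of
  seconds. A slower kernel (e.g. delay 3 s, τ = 10 s) delays the simulated
  response ~12 s behind the drive, which contradicts those hold-end
  magnitudes and collapses the zero-lag ToB coupling.
- **Velocity**: baseline 60 cm/s, 1 Hz pulsatile template (systolic peak,
  dicrotic bump) with zero cycle mean so the beat average recovers the
  modulated mean exactly; coupling gain 15% per SD of drive (hold peaks of
  the z-scored drive are ~2.5 SD, giving ~40% excursions); additive noise
  2% of baseline.
- **BOLD**: voxel series 100·(1 + truth·(kernel∗regressor)/100) + AR(1)
  noise (φ = 0.3, marginal SD 2%, i.e. a temporal SNR of ~50). The default
  truth map gives gray-matter quadrants slope 2 and white-matter quadrants
  slope 1 (% per SD of drive), matching the reported ~2:1 gray/white
  response ratio. The quadrant parcellation stands in for a cortical
  parcellation; the truth map travels with the dataset for recovery tests.

What the generator does **not** emulate: pulsatile Doppler spectra and
insonation physics, motion and cardiac/respiratory aliasing artifacts in
BOLD, spatially correlated BOLD noise, vascular steal or negative CVR,
baseline drift in the gas analyzers, and any structured relationship
between respiration depth and the hemodynamic response other than the bER
drive itself. Passing tests therefore show that the pipeline recovers what
the generative model puts in — marker positions, configured baselines,
known slopes, calibrated error rates, and the direction of the group
orderings under a bER-driven coupling — not that the physiological
conclusions would hold on new recordings.

## Numerical choices and degenerate inputs

- Constant traces: marker detection warns and returns an empty table;
  correlation raises on zero variance; detrending returns zeros; group
  t-tests flag zero-variance voxels NaN.
- The bridged (hold-interpolated) metric series reuses plain linear
  interpolation between breath timestamps, so grid points at a breath
  timestamp reproduce the breath's value exactly.
- Wavelet scales whose period exceeds the record are truncated with a
  warning; thresholds at scales fully inside the cone are NaN and the TAC
  there is flagged invalid.
- Cluster retention is ≥ (a cluster exactly at the calibrated volume
  survives). Connectivity is face adjacency.
- All generators take one seed per call and are bit-reproducible; the
  pipeline manifest records seeds and content hashes of every output.

## Problem sizes

Tests and the acceptance script run the study at desk scale: 8×8×4 BOLD
grids (~475 volumes at TR 1.45 s), 16-subject cohorts parameterized from
the published table, 5–10 seeded cohorts for the ordering checks, 100–300
Monte Carlo surrogates for coherence significance, and 200–500 iterations
for cluster calibration (2000 is the default for real use). These sizes
were chosen so the full suite completes in a few minutes while keeping the
Monte Carlo standard errors well inside the asserted tolerances.

## Known limitations

- The delay-correction estimator assumes a quasi-periodic breathing signal
  and reports a boundary flag rather than failing when the true delay
  exceeds the search window; delays beyond half a breath period are
  ambiguous for strictly periodic breathing.
- The TAC normalization follows the count-based reading ("maximum possible
  coherence" = all valid points at 1); the threshold-sum alternative is
  available behind a flag but not used by default.
- Cluster calibration assumes stationary Gaussian noise at a stated
  smoothness; it does not estimate smoothness from residuals.
- Group inference runs voxelwise on a shared grid; spatial normalization
  across real subjects is out of scope (synthetic cohorts share a grid by
  construction).
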