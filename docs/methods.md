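# Methods

`oscbind` implements a complete neurophysiological inference chain for a
Go/Nogo feature-binding experiment — from epoched multichannel EEG through
Morlet band power, cluster-based permutation statistics, LCMV source
reconstruction, multivariate pattern analysis (within-band, temporal
generalization, and theta-to-alpha transfer), DBSCAN localization of
peak-decoding voxels, and regression of decoding accuracy onto a
behavioral binding effect. Because every stage is validated on synthetic
data with known ground truth, this note describes both the analysis
methods and the generative model, including the choices that were
genuinely open.

## Task and behavioral model

The task is a Go/Nogo design with stimulus features (letters, font
colors) that either overlap between Go and Nogo trials or do not. A
session has 196 Go and 84 Nogo trials per overlap condition (70:30
Go:Nogo), arranged in seven blocks with every condition equally frequent
per block and pseudorandomized within block; stimuli last 450 ms, the
response window is 1700 ms, and inter-trial intervals are drawn uniformly
from 700–1100 ms.

Behavioral outcomes per subject and condition (Go hit rate, Go RT, Nogo
false-alarm rate) are drawn from clipped Gaussians around condition
means. The overlapping Nogo false-alarm mean exceeds the non-overlapping
one by the configurable binding effect (default 35.3 percentage points,
with condition means 37.5 ± 17.1 % vs 2.2 ± 3.0 %); overlapping Go RTs
are slower by 11 ms on average. The overlap-condition spread scales
linearly with the planted binding effect so that a zero effect makes the
two conditions distributionally identical (a genuinely null null).

## Forward model

`make_leadfield` builds a regular voxel lattice (default 6×6×6 at 1 cm)
inside a homogeneous conducting sphere of radius 10 cm with sensors on a
Fibonacci lattice over the upper hemisphere. The gain of a unit dipole at
radius `b` observed at a surface electrode is the Legendre-series
solution

V = Σₙ (bⁿ⁻¹/Rⁿ⁺¹) [ (2n+1) q_r Pₙ(cos γ) + ((2n+1)/n) q_t Pₙ¹(cos γ) ],

summed until the (b/R)ⁿ terms vanish (no Condon–Shortley phase; the
1/(4πσ) factor is dropped as the units are arbitrary). The n = 1 limit
for a central dipole (V = 3 q·r̂ / R²) and the vanishing surface mean are
verified in the tests. A seeded random full-rank gain is available for
fast unit tests. A synthetic atlas labels voxels by octant region names;
the lowest z-plane is `cerebellar` and far-corner voxels `unlabeled`,
providing the excluded/included split (full-scale analyses with a real
atlas keep 1254 of 2020 voxels; the synthetic 6×6×6 grid keeps 176 of
216).

## Planted oscillatory effects

Each frequency band has a carrier (theta 5.0 Hz, alpha 10 Hz), a Gaussian
temporal envelope (sd 0.15 s) centered at the band's binding-peak latency
(theta 0.52 s, alpha 0.59 s after stimulus onset), and two spatial
components:

* **Uniform power shift.** Every voxel above the cerebellar plane
  carries a weak condition-dependent amplitude shift, positive for theta
  (overlapping > non-overlapping) and negative for alpha. This is the
  spatially extended univariate effect that sensor-level cluster
  statistics detect — analogous to condition differences spanning almost
  all electrodes — but it is deliberately weak at the single-trial level
  (amplitude ±0.15/2 on a base of 0.2).
* **Discriminative pattern.** Two 2×2×1 voxel blocks at diagonally
  opposite corners of the superficial grid plane carry a strong
  condition-dependent amplitude pattern (one block up, one down;
  amplitude ±1.2/2 on a base of 1.0). With `shared_pattern` the alpha
  effect uses the same blocks with the same signs, which is what
  theta-trained/alpha-tested transfer decoding can exploit; the
  orthogonal control places the alpha blocks on the other diagonal, so
  the two bands' condition-difference patterns have zero inner product.

Carrier phases are randomized per trial *and per voxel*, making sources
mutually incoherent, and a shared lognormal per-trial gain (sd 0.25)
modulates all sources. White Gaussian sensor noise is added and the
result is scaled into a realistic microvolt range.

Several of these choices respond to measured failure modes of the
LCMV+MVPA chain rather than to taste, and are worth recording:

* A fine-grained ± pattern inside one compact blob does not survive
  beamforming — the point spread of a ~20–60 channel montage at a 1 cm
  grid averages it away. The pattern must live at a spatial scale the
  beamformer resolves, hence the two separated blocks.
* With phase-coherent sources, leakage adds in amplitude and the
  spatially uniform component dominates every voxel estimate, producing
  *anti*-transfer (the bands' uniform shifts have opposite signs).
  Incoherent sources make leakage add in power and keep condition
  information local.
* Without the shared trial gain, filters at poorly resolved edge voxels
  act as spatial integrators that average away per-voxel amplitude
  jitter and out-decode the planted blocks; a trial-level gain common to
  all sources caps such aggregated features at the same ceiling.
* The theta carrier sits at 5.0 Hz rather than the 5.5 Hz band centre: a
  5-cycle wavelet at 8 Hz has spectral sd 1.6 Hz and passes ~30 % of a
  5.5 Hz carrier's amplitude, which alone produced spurious positive
  transfer in the orthogonal control; 5.0 Hz cuts this bleed about
  threefold. Residual bleed is why orthogonal-control transfer AUC
  hovers slightly off 0.5 rather than exactly at it.

## Preprocessing

Fixed order: zero-phase 4th-order Butterworth band-pass (0.5–40 Hz) with
a 50 Hz IIR notch → polyphase resampling (500 → 256 Hz for real data) →
average reference → selection of correctly withheld Nogo trials (no
response before 1500 ms) with artifact rejection (|amplitude| > 200 µV,
or peak-to-peak < 0.5 µV within any sliding 100 ms window) → baseline
correction over −200–0 ms. Zero-phase filtering was chosen because
causal IIR filtering would bias the peak-latency analyses; the filter
order is configurable since only the band edges are prescribed.
Epochs run from −2 to +2 s around stimulus onset at full scale; scaled
runs use −0.7 to +1.65 s, the minimum that keeps the 0–1 s analysis
window free of wavelet edge effects (see below).

## Time–frequency analysis

Complex Morlet wavelets with m = 5 cycles (temporal sd m/(2πf)); power is
the squared convolution magnitude. The implementation takes MNE's
wavelet construction; full-resolution decompositions go through MNE's
FFT convolution, while decimated source-level decompositions evaluate
the same convolution only at the kept samples via one BLAS matrix
product (exact agreement is a regression test). Samples within 3 σ_t of
an epoch edge are marked invalid per frequency (99.7 % of wavelet
energy) and excluded from statistics and peak searches. Band power
averages bins with centres inside 4–7 Hz (theta) or 8–12 Hz (alpha)
inclusive; the source-level grid is 2–15 Hz in 0.5 Hz steps (27 bins),
which requires the full 4 s epochs. Peak latencies are the largest local
maximum of the sign-adjusted binding difference (overlapping −
non-overlapping, times the band's effect sign) in 0–1 s, averaged over
the channels of the largest matching-sign sensor cluster; courses with
no interior maximum return the window argmax with a boundary flag.

## Cluster-based permutation statistics

Element statistics are paired t values (condition contrasts) or signed
Wilcoxon rank sums (AUC against chance; ranks of |d| are invariant under
sign flips, so permuted statistics are a single matrix product).
Supra-threshold (p < 0.05) same-signed elements merge over spatial
adjacency plus temporal contiguity; sensor-level clusters must contain
at least two distinct pairs of simultaneously supra-threshold
neighboring channels. The cluster statistic is the sum of element
statistics. Significance comes from the permutation distribution of the
maximal same-sign cluster statistic under subject-level sign flips
(1000 draws at full scale, 500 in scaled runs; exhaustive enumeration
when 2^n_subjects is small), with separate positive/negative searches
and doubling of the one-sided Monte-Carlo p — the floor at 1000 draws is
2/1001 ≈ 0.002. Sensor adjacency is a Delaunay triangulation of the
projected montage with long edges pruned; voxel adjacency is
6-connectivity; generalization matrices use 4-connectivity. Whether
sensor clustering spans channels × time jointly or time-averaged maps is
configurable; the joint mode is the default.

## Beamforming

Scalar LCMV: with regularized covariance C_r = C + 0.05·mean(diag C)·I,
per-voxel orientation is the principal eigenvector of (Lᵀ C_r⁻¹ L)⁻¹
(max-power orientation; single-orientation lead fields skip this step)
and w = (lᵀ C_r⁻¹ l)⁻¹ lᵀ C_r⁻¹, which satisfies w·l = 1. Numerically
singular voxels are flagged and excluded. One common filter per subject
is computed from all Nogo trials (avoiding condition-specific filter
bias); condition-specific covariance is selectable. The covariance may
be estimated from the time-locked average (the classical recipe for
phase-locked data) or pooled over single trials; the pipeline default is
single-trial covariance over the 0–1 s analysis window because the
generator's oscillations are purely induced — their average is zero, and
an average-based covariance would leave LCMV without interference
structure to null (verified: cross-talk then exceeds own-voxel gain).
Unlabeled and cerebellar voxels are excluded from source analysis.

## MVPA

All decoders are two-class L1-regularized linear SVMs (C = 1, liblinear
with a fixed random state) in 5-fold stratified cross-validation;
features are z-scored with training-fold statistics only, and AUC is
computed from decision values pooled over held-out folds. Temporal
decoding uses the voxel pattern per time sample; temporal generalization
trains at each time and tests at all times (test features standardized
with training-fold statistics of the test time); cross-band transfer
trains on theta features and tests on alpha features of held-out trials
(folds split once, so no trial is ever in both roles); spatial decoding
uses the band-power course at significant time samples as features,
yielding an AUC per voxel. Voxel maps are re-inserted into the full grid
with zeros at excluded positions, alongside a chance map with 0.5 at
included positions. Group tests against chance delegate to the cluster
machinery with the Wilcoxon element statistic. The "generalization
duration" is, per training time, the length of the contiguous
significant test-time run containing the diagonal cell (0 if the
diagonal is not significant), averaged over training times — the
contiguous-run reading of "duration around the diagonal".

## DBSCAN localization

The top 2 % of AUC values over included voxels (quantile computed over
included voxels only, since excluded positions carry the re-insertion
value 0; ties at the threshold all kept) are clustered with DBSCAN at
ε = 1.5 × grid spacing and min_samples = 2 ("at least one neighbor"),
which makes clusters exactly the connected components of the
ε-neighborhood graph; singletons are noise. Reports give member count,
mean AUC, centroid and atlas labels per cluster.

## Behavioral and brain–behavior statistics

Shapiro–Wilk screening; paired Wilcoxon signed-rank tests with exact
enumeration for n ≤ 25 (ties handled on the half-unit rank lattice) and
a continuity-corrected normal approximation beyond; Rosenthal's
r = Z/√n with n the number of pairs (this convention reproduces the
reference values −0.869 and −0.483 at n = 79 exactly and −0.581 within
the rounding of its Z). The binding effect is always overlapping minus
non-overlapping. The regression of per-subject binding effects on
per-cluster mean AUCs uses backward elimination: repeatedly drop the
predictor with the largest partial-F removal p while that p ≥ 0.10,
reporting standardized β, adjusted R², the model F test, Durbin–Watson,
VIF per predictor and standardized-residual extremes, plus the full
elimination trace. Exactly collinear designs raise an error naming the
offending predictors.

## Pipeline, problem sizes and determinism

`pipeline.run_all` executes simulate → preprocess → sensor statistics →
beamform → decode (×3) → clusters → regression → report, each stage
reading only prior-stage artifacts from the run directory, with a
manifest (config hash, outputs, timings) providing caching and stage
isolation. The master seed fans out through
`SeedSequence([seed, stage_index, subject_index])`, and identical
configurations reproduce identical artifacts.

Scaled-down problem sizes used throughout: 6×6×6 grid at 1 cm (176
included voxels), 40 Nogo trials per condition, 128 Hz sampling, epochs
−0.7 to +1.65 s, power decimated ×5. The validation suite uses the
20-channel montage with 15 subjects for null calibration (200
repetitions, 500 permutations) and the 60-channel full-scale montage
with 4 subjects per run for planted-effect recovery — 1 cm DBSCAN
localization genuinely needs the denser montage (with 20 channels the
top-percentile voxels land one grid step off the planted blocks). The
full-scale geometry (79 subjects, 60 channels, 256 Hz, 84 Nogo trials
per condition, 4 s epochs) is reached purely through configuration.

## What the synthetic data does and does not show

The generator emulates the *structure* of the study — trial design,
balanced conditions, band-specific opposite-signed power effects with
the stated peak latencies, a shared cross-band discriminative pattern,
and a behavioral binding effect — with known ground truth, so passing
tests demonstrate that the analysis chain is correct and well
calibrated: the cluster test holds its family-wise error rate under the
null, decoders sit at chance on exchangeable data, and planted effects
of every kind are recovered. It does not emulate realistic anatomy (no
BEM/template head model), 1/f background spectra, eye/muscle artifacts
(the ICA stage of real-data preprocessing is out of scope), correlated
noise between channels, or single-trial power distributions of real
EEG — so the tests say nothing about effect sizes or significance levels
to be expected on recordings, only about the correctness of the
machinery applied to them.

## Known limitations

* The homogeneous-sphere forward model ignores skull conductivity
  layering; gains are relative, not physical.
* Orientation selection uses the plain max-power criterion, which can
  misbehave for near-degenerate gain matrices (such voxels are flagged
  and dropped rather than repaired).
* The orthogonal-control transfer AUC is not exactly 0.5 because of
  residual spectral bleed between bands (see above).
* Backward elimination reproduces the partial-F removal rule only; tie
  handling of specific commercial implementations is not emulated.
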