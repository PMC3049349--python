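# Methods

## Model and statistics

Scalp field data are treated as a complete 4-D array (subjects ×
conditions × time × sensors); missing cells are not allowed, every map
is average-referenced (the spatial mean is subtracted), and units (µV,
fT) are metadata only — all statistics are unit-agnostic.

**Strength measures.** GFP is the population standard deviation of one
map across sensors. The effect strength `s` is the root of the summed
squared deviations of the effect's cell mean maps from their unweighted
grand mean, divided by the sensor count; it is zero iff all cell means
coincide and reduces, up to a constant, to the GFP of the difference map
for two cells. The TANCOVA statistic is the GFP of the covariance map
`β_j = Σ_i v_ij (b_i − b̄)`; the predictor is mean-centered so a constant
offset of `b` cannot leak the grand-mean topography into `β`. For
covariate × factor interactions, one covariance map is computed per
within-cell from the per-subject cell means centered across the
involved factor levels, and `s = sqrt(Σ_cells GFP(β_cell)²)`, which
reduces to the plain definition for the covariate main effect.

**Marginalization and centering.** Every effect is computed on the cell
grid of its involved factors (group axis first). Cells average over the
levels of non-involved factors with equal weight per level; within-only
effects average over all used subjects, group effects average within
group and then with equal weight across groups, so unbalanced groups do
not tilt the grand mean. Interaction cell means are multiply-centered
(the identity-minus-mean projector applied along every involved axis),
which makes `s` exactly zero on purely additive data — the defining
property of an interaction test. Main effects are centered by the grand
mean only, which is what the `s` formula itself does.

**Permutation schemes.** Each effect's null shuffles only the labels it
tests and leaves all other structure intact:

* within main effect: per subject, one random permutation of that
  factor's level labels, applied consistently across the other factor's
  levels (two levels: keep-or-swap per subject);
* within interaction: per subject, one random permutation of all
  included condition labels, tested on the centered cell means;
* between main effect: one global permutation of group labels across
  used subjects;
* mixed (group × within) interactions: both of the above
  simultaneously, tested on the centered interaction means;
* covariate terms: permutation of the covariate values across subjects,
  plus, for interaction terms, the per-subject within permutation.

Each scheme is exchangeable under its null hypothesis. The exact scheme
for mixed interactions is a design choice of this package (validated by
the calibration simulations below); other implementations of this
family of tests may permute differently.

**p-values.** `p = (1 + #{null ≥ observed}) / (1 + n_runs)`: ties count
against significance and `p` is never exactly zero (the observed data
is one realization of its own null). A randomization run draws *one*
shuffle and applies it to every time point, so the null matrix
preserves the temporal dependence structure of the data — a requirement
for the overall statistics below. Default `n_runs=1000` is adequate for
α = .05 (a warning is emitted below that); 5000 is recommended for
α = .01.

**Overall statistics.** The pseudo-P matrix ranks each run's statistic
against the remaining runs per time point
(`p′(r,t) = (1 + #{r′≠r : s(r′,t) ≥ s(r,t)}) / n_runs`, same ≥ tie
rule). The count test compares the observed number of sub-α time points
with the null counts derived from the pseudo-P rows. The duration
threshold summarizes each run by its *maximum* contiguous sub-α run
length (the familywise choice, analogous to cluster-size statistics)
and takes the shortest null-attained duration whose exceedance
frequency is ≤ α. Rounding up to an attained duration matters: a plain
positional quantile can land inside a heavy tie at short durations —
common with few time points — and then null runs exceed the threshold
far more often than α, destroying familywise control. With the attained
rule the exceedance probability is bounded by α by construction
(verified by simulation, see below). A consequence worth knowing: as
α → 1 nearly every null run attains the full window length, so the
threshold grows rather than shrinking to one sample; the threshold is
only meaningful for conventional α. Masked clusters are maximal
intervals with `p < α` (strict; boundary samples at exactly α are not
significant) of at least threshold length, reported in samples and ms.

**Normalization.** `l2` (recommended) scales every individual map to
unit GFP before any averaging, so significant effects reflect
topographic (qualitative) differences only; flat maps are an error that
names the offending subject/condition/sample. `dissimilarity` is the
legacy variant that normalizes the condition/group grand-mean maps
instead; it applies to TANOVA effects only — a grand-mean-level
normalization has no analogue for a covariance map, so covariate
effects ignore it. `none` leaves amplitudes in. Separate univariate
statistics on GFP itself are out of scope.

**TCT.** The statistic is the GFP of the across-subject mean map; the
null shuffles each subject's values across sensors (one permutation per
subject per run, reused across time). This is the summary form of the
consistency test: it asks whether subjects' maps add coherently, not
which variance component drives agreement. With `l2` normalization
(default) the test is driven purely by topographic agreement. The
statistic is invariant to re-referencing and to a common sensor
permutation applied to all subjects; the Monte-Carlo p is invariant to
the latter only in distribution. Duration masking reuses the machinery
above to mark periods of consistent topography.

**MDS.** Mean maps are centered across the map set (the covariance
structure of differences is what is displayed; the grand mean map
carries no effect information) and eigendecomposed; each map is
projected onto the top-2 orthonormal eigenvector maps. Signs follow a
fixed convention (largest-|loading| sensor positive) so figures
reproduce across platforms. Rank-1 sets get a zero second axis.

## Synthetic data

The generator mirrors the physics the statistics rely on: superposition
of sources, each a fixed average-referenced unit-GFP topography times
an amplitude time course (Gaussian pulse or boxcar) times per-cell /
per-group / covariate-linked / per-subject amplitude factors, plus
Gaussian sensor noise with squared-exponential spatial correlation over
a circular montage (volume conduction blurs real recordings in space;
white noise would be unrealistically easy to average away). Defaults —
12 subjects, 2×2 conditions, 40 samples at 250 Hz, 16 sensors, unit
noise SD, correlation length 0.5 montage units, subject amplitude SD
0.2–0.3 around 1 — are the toy scale every calibration below runs at.

What it does *not* emulate: realistic head-model leadfields, temporal
autocorrelation of background EEG, artifacts, latency jitter across
subjects, or heteroscedastic noise across sensors. Passing calibration
here therefore demonstrates correctness of the statistical machinery
under its own assumptions, not robustness to every property of real
recordings; the randomization logic itself makes no distributional
assumption beyond exchangeability, which these deviations do not break
for within-subject shuffles.

## Validation conditions and measured behavior

The test suite and `scripts/acceptance.py` recompute, per run:

* **Exact-oracle agreement** — 5 subjects × 2 conditions × 1 time
  point: the 2⁵ = 32 relabelings are enumerated exhaustively and the
  10 000-run Monte-Carlo p must agree within 3 MC standard errors.
* **Type-I calibration** — 200 pure-noise datasets × 500 runs, raw and
  L2: point-wise rejection at α = .05 stays within 3 SE of .05 for
  every effect (measured ≈ .045–.053).
* **Familywise error** — the fraction of null datasets with any
  duration-masked cluster stays ≤ α (measured ≈ .00–.02, conservative
  because of the attained-duration rounding).
* **Count-test p distribution** — measured super-uniform and unbiased
  (mean observed count equals the mean null count), but *discrete*: over
  40 time points the count takes few values, so the p-value CDF is a
  staircase touching the diagonal from below. A continuous-uniform KS
  test rejects this staircase by construction; the corresponding
  acceptance assertion documents this and fails honestly.
* **Power** — with a condition-difference source on samples 15–25 at an
  amplitude (0.18 of the noise SD) where Bonferroni-corrected
  sensor-wise t-tests detect < 50% of datasets, the duration-masked
  TANOVA detects > 90% — the whole-scalp test pools the effect across
  sensors instead of paying a 640-fold correction.
* **Recovery** — the TANCOVA covariance map correlates > 0.9 with the
  injected topography at high SNR (measured ≈ 1.00).
* **Structure** — interaction `s` at machine precision on additive
  data; TCT p at its floor for shared topographies with the inverse
  p–GFP relation; MDS equal to the full eigendecomposition; ASCII and
  session round trips lossless.

Problem sizes (200 datasets, 500 runs, the toy scale above) keep the
whole validation in the tens of seconds while leaving binomial standard
errors small enough for 3 SE bounds to be meaningful.

## Numerical and interface choices

* One user seed; each effect gets a deterministic substream, so a
  single effect reruns identically on its own. Results are bit-reproducible
  given seed and inputs.
* Time windows are half-open `[start, stop)` in samples; ms windows
  convert via the sampling rate, also half-open.
* Window-averaged analyses average maps per subject/condition first and
  then run the identical pipeline; a one-sample window reproduces the
  point-wise result at that sample with the same seed.
* ASCII import accepts runs of spaces/tabs, decimal points only; ragged
  rows and non-numeric tokens fail with the line number. Subjects are
  ordered by lexicographic file name, logged at import. The average
  reference is applied at import by default and can be skipped for MEG.
* Sessions are a versioned zip of a JSON manifest plus `.npy` arrays;
  arrays round-trip bit-exactly; a format-version mismatch is an
  explicit error.
* Condition exclusion that breaks the factorial crossing is rejected at
  design time; with two factors the included conditions must cover all
  level combinations equally often.

## Known limitations

* Up to two within-subject factors and one between-subject factor (or
  one covariate); no three-way within designs.
* The duration-threshold distribution uses the per-run maximum run
  length; summarizing over all epochs instead would estimate a
  different (non-familywise) quantity.
* The TCT here is the summary form described above; implementations
  built on an explicit variance decomposition may differ in detail.
* Montage geometry is used for display and noise simulation only;
  statistics treat sensors as exchangeable, so sensor-neighborhood
  information is deliberately unused.
* Frequency-domain analyses, microstate statistics, univariate GFP
  tests and native EEG file formats are out of scope.
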