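# Methods

This note documents the models, parameter choices, and numerical decisions
behind `nrfage`, in the order the pipeline runs them.

## Synthetic cohorts (`nrfage.synthetic`)

The generator emulates the statistical structure that the analysis assumes
of preterm evoked EEG, not neonatal biophysics.

**Maturity model.** Each infant carries a persistent Gaussian offset
(`maturity_offset_sd_weeks`, default 1.0 wk) between "neural maturity" and
PMA; maturity = PMA + offset for every session of that infant. This is what
makes brain-age *gaps* in the synthetic cohort biologically meaningful: the
EMG reflex is generated from maturity, not PMA, so a model that recovers
maturity should out-correlate PMA — mirroring the logic of the reflex
validity check.

**Evoked components.** For each modality, two components are injected at the
analysis channel (Oz for visual, Cz for tactile) on top of background:

- a *slow wave*: negative half-period raised cosine (visual: onset 0.10 s,
  width 0.50 s; tactile: onset 0.02 s, width 0.30 s) whose amplitude falls
  linearly from `snr x background RMS` at 28 wk maturity to exactly 0 at
  40 wk — the disappearing delta-wave response of the youngest infants;
- a *fast component*: damped sinusoid with negative first deflection
  (visual: 4 Hz, tau 0.15 s; tactile: 8 Hz, tau 0.06 s, negative peak near
  0.16 s), amplitude constant across age (0.7 of the slow-wave maximum) and
  latency decreasing linearly with maturity (visual 0.35 -> 0.25 s, tactile
  0.16 -> 0.12 s).

Waveform shapes are free choices (the source material for this analysis
shows morphology only graphically); they are chosen so that the visual
response falls inside the 0.1–1.0 s analysis window and the tactile response
inside 0–0.3 s. Trial-to-trial variability is a 10%-SD gain on each evoked
response. A per-recording latency shift (Gaussian, `latency_jitter_s` SD,
clipped to ±0.03 s so it stays inside the ±0.05 s Woody search range)
delays both components.

**Background.** 1/f-amplitude Gaussian noise, RMS 15 µV per channel.
`snr` is the ratio of the maximal slow-wave amplitude to this RMS
(default 2). Discontinuous tracé alternant, sleep states, and artifacts
are deliberately not modelled — no tested stage depends on them — so
passing tests demonstrate correct *machinery* and parameter recovery under
the stated statistical structure, not robustness to every property of real
neonatal EEG.

**Layout.** Defaults follow the study conditions the pipeline was designed
for: 2 kHz sampling; 12 stimuli per modality at 11 ± 1 s inter-stimulus
intervals; ~10 rest annotations placed in the late halves of inter-stimulus
gaps; one heel lance near the end of the recording; 1–2 sessions per infant
at weekly intervals; PMA uniform in 28–40 wk. The first stimulus sits 25 s
into the recording so high-pass edge transients never touch an epoch.

**EMG.** Baseline Gaussian noise (SD 5 µV) plus a reflex burst starting
0.4 s after the lance: amplitude-modulated noise under a flat-topped
envelope, with burst SD falling linearly 60 -> 12 µV and duration
5 -> 1 s across 28–40 wk maturity — both strictly decreasing, as reflex
withdrawal refines with maturation.

Everything is deterministic given the cohort seed (per-recording EMG seeds
are drawn from the cohort stream so `generate_emg` is reproducible in
isolation).

## Preprocessing (`nrfage.preprocess`)

Hamming windowed-sinc FIR filters, specified by passband edge and −6 dB
cutoff: low-pass 30 Hz (cutoff 33.75 Hz), high-pass 0.1 Hz (cutoff
0.05 Hz), and an additional 12 Hz low-pass (cutoff 13.5 Hz) on the
NRF-derivation branch only; magnitude extraction and brain age use the
0.1–30 Hz branch. Filter order follows the Hamming design rule
(transition width = 2 × |cutoff − edge|, N ≈ 3.3·fs/Δf, odd). Filters are
applied single-pass with group-delay compensation: zero phase with the
−6 dB-at-cutoff convention preserved (forward–backward filtering would
square the magnitude response), so evoked latencies are unbiased.

Epochs are half-open [t−1 s, t+1 s) around stimulus onset (exactly
2·fs samples; uniform trial lengths), baseline-corrected to [−0.5, 0) s.
Trials whose pre-stimulus |amplitude| strictly exceeds 150 µV are rejected
— the boundary case is kept; rejection is evaluated on the analysis channel
only, since only that channel is analysed and the manual whole-montage
artifact screen of cot-side practice is not automatable. A modality with
fewer than five clean trials is excluded; a recording is dropped only when
all its stimulus modalities are. When five or fewer rest annotations exist,
ten new ones are *added* at 10 s intervals before the first one (clipped to
the epochable range).

## Age-weighted averaging and Woody alignment (`nrfage.alignment`)

Weights are Gaussian in PMA distance, w(Δ) = exp(−Δ²/2σ²) with
σ = FWHM/(2√(2 ln 2)), FWHM 27 days, hard zero beyond 28 days; the
age-weighted template for a recording is Σwᵢxᵢ/Σwᵢ over all recordings
(self included, weight 1 — a documented toggle). Each recording's stimulus
average is aligned to its template by a Woody filter: the integer-sample
lag within ±0.05 s maximising the Pearson correlation (amplitude-invariant;
classic Woody filtering uses raw cross-correlation). Ties prefer the
smaller |lag|, so the correlation never falls below lag 0's. Two refinement
passes rebuild templates from aligned averages and re-derive each shift
from the *original* average, so shifts never compound; at 2 kHz the 0.5 ms
integer-lag resolution makes sub-sample interpolation unnecessary. Rest
averages are aligned to the same stimulus templates so the stimulus/rest
contrast stays fair. Shifted traces are padded with nearest edge values to
avoid discontinuities in later regressions.

## Cluster-based permutation test (`nrfage.cluster_stats`)

Per-sample paired t (df = n−1) between stimulus and rest responses on the
0–1 s window; threshold at the 97.5th percentile of the t distribution
(two-sided by sign-homogeneous clusters); cluster statistic = signed t mass
(the extent statistic is a noted alternative; mass is the common
convention). The null permutes condition labels per recording — a sign flip
of the paired difference — and records the maximum |mass| per permutation
(1000 by default); p = (1 + #{null ≥ |mass|})/(1 + N), never exactly 0.
Sign flips leave per-sample sums of squares invariant, so the permutation
t-series are computed from flipped means alone (one matrix product per
test). The NRF input windows are the fixed constants 0.1–1.0 s (visual) and
0–0.3 s (tactile), bracketing each modality's evoked cluster; the cluster
test on synthetic data is reported alongside rather than re-deriving them.

## NRF derivation and magnitudes (`nrfage.nrf`)

Aligned stimulus and rest averages, trimmed to the modality window, are
normalised to unit Euclidean norm (morphology, not amplitude, drives the
decomposition), stacked, and decomposed by PCA over the time dimension
(rows mean-centered per sample — a documented toggle). The smallest leading
set explaining >95% variance is retained; component signs are fixed so the
largest-|amplitude| sample is negative. All retained components are
regressed jointly (with intercept) onto each raw average; per component, a
two-sided paired t-test (α = 0.05, uncorrected — deliberately, as p-values
are a guide here) compares stimulus and rest betas, and significant
components become NRFs. Paired beta differences at floating-point noise
level (≤1e−8 of the beta scale) are treated as zero-variance and
non-significant, since the t statistic is scale-invariant and would
otherwise amplify rounding error into spurious selections.

A recording's NRF magnitude aligns its broadband 0–1 s average to the
zero-padded NRF (Woody, ±0.05 s) and takes the slope of a simple OLS of the
aligned response on the NRF over the NRF's window (intercept included:
broadband baselines are not zero-mean). Weekly age trends are OLS fits of
within-week mean magnitudes on integer PMA week (identity-link Gaussian
GLM), p-values uncorrected.

## Brain age (`nrfage.brain_age`)

Linear ε-insensitive SVR, ε = 0.15 wk and box constraint C = 1 (the
L1-soft-margin dual solved by libsvm). Features are z-scored within each
training fold (without this, NRF-magnitude scale differences dominate a
linear kernel); recordings missing a modality get training-fold column-mean
imputation. Evaluation: leave-one-infant-out CV (sessions of one infant
never span train and test); MAE with percentile-bootstrap 95% CI over
recording-level absolute errors (10,000 resamples); one-tailed permutation
p where each permutation exchanges whole infants' PMA label blocks between
infants with equal session counts and reruns the CV (p counts permutations
with MAE ≤ observed, +1 corrected). The null model predicts the
leave-one-infant-out mean PMA; the paired contrast of absolute errors gets
a bootstrap CI and a one-tailed sign-flip permutation p. The adjusted
brain-age gap is the OLS residual of gap ~ PMA (exactly uncorrelated with
PMA; centering when PMA is constant).

The mapping of "0.15 and 1" to ε and C, and whether features were
standardised, are genuinely open in the source description; both are
exposed in `SVRConfig` with the defaults above.

## EMG reflexes (`nrfage.emg_reflex`)

Band-pass 10–500 Hz (FIR cutoffs 8.75/562.5 Hz) plus zero-phase IIR
notches at k·50 Hz (k = 1..10, below Nyquist), epoch −5 to +15 s around the
lance, rectify. The reflex detector is a documented reconstruction (the
original algorithm lives in prior work and is not specified here): smooth
with a 50 ms moving average; threshold = baseline mean + 3 SD of the
smoothed −5..0 s baseline; start = first post-stimulus crossing sustained
≥100 ms within 2 s; end = first subsequent time the envelope stays below
threshold for 200 ms, tolerating 10% noise re-crossings (a strict all-below
rule lets a single 3σ excursion displace the offset by ~0.1 s); amplitude =
mean rectified value within [start, end]. Baseline movement screening is an
automated proxy for visual inspection: reject when the baseline envelope
exceeds 5× its median for ≥0.2 s. Correlations with PMA, brain age, and
adjusted gap are Pearson r with one-tailed p in the negative direction
(responses refine with maturity).

## Problem sizes and validation design

The validation suite chooses simulation scales that make each check sharp:

- Woody-shift recovery uses a latency-homogeneous cohort (one PMA, no
  maturity offsets, snr 100): in an age-spanning cohort the age-dependent
  latency drift between a recording and its age-weighted template is wanted
  signal, not alignment error, and at realistic snr the slow wave's flat
  correlation peak adds ~1-sample noise; the homogeneous near-noiseless
  cohort isolates the machinery, whose error floor (~0.5 sample) is the
  quantisation of continuous injected shifts onto the 2 kHz grid. Shifts
  are recovered up to the common latency origin, which is unidentifiable.
- Cluster-test calibration runs 500 null cohorts of 15 recordings × 1000
  samples with 500 permutations each; power uses a boxcar effect (a tapered
  bump has sub-threshold tails by construction and would test the taper
  rather than window recovery).
- The selection-exactness simulation gives the shared component identical
  paired loadings in stimulus and rest, making its paired t-test exactly
  degenerate: under any independent noise the non-stimulus component is a
  5%-level test by definition, so "exactly one selected in ≥95% of runs"
  would be a coin flip; the noisy false-positive rate is instead checked
  separately against α + 0.02 over 200 runs.
- The brain-age snr ladder (0.5, 1, 2, 4) regenerates cohorts from one
  seed (common random numbers), so only the evoked scale varies between
  rungs — a variance-reduction choice, not a tuned parameter.
- End-to-end brain-age checks run on the default cohort (30 infants,
  snr 2): ~48 recordings, 99 block permutations, 2000 bootstraps.

## Known limitations

- The synthetic slow wave and fast component are stylised; no claim is made
  that PCA on real data yields the same number or shape of NRFs (component
  counts here are larger because the synthetic latency continuum spreads
  variance over many components).
- The reflex detector reconstructs an unpublished algorithm; constants are
  config-exposed and the detector is validated against its own generative
  model only.
- Vigilance state, tracé alternant, and artifact morphology are not
  simulated; the ±150 µV rejection rule is exercised only by injected
  amplitude outliers.
- Exchangeability-block permutation exchanges label blocks within
  equal-session-count groups; infants with a unique session count keep
  their labels (the closest implementable reading of block exchangeability
  for unbalanced designs).
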