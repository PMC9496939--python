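# Methods

## The analysis problem

Fast periodic visual stimulation (FPVS) superimposes two image streams —
faces and houses — whose contrast is modulated sinusoidally at different
rates (6 and 7.5 Hz, counterbalanced over category). Because the visual
system entrains to each stream at its own rate, the EEG response to each
category is confined to the harmonics of its tagging frequency and can be
read directly off the amplitude spectrum. The package implements the whole
chain for a two-session (active treatment vs. placebo) cross-over design:

1. **Generation** of synthetic studies with the statistical structure the
   analysis assumes (`fpvs.simulate`),
2. **Preprocessing** of the raw recordings (`fpvs.preprocess`),
3. **Spectral quantification** of the tagged responses (`fpvs.spectral`),
4. **Scoring** of the orthogonal fixation-cross task (`fpvs.behavior`),
5. **Statistics**: mixed models, Bayes factors, posterior differences,
   reliability and power (`fpvs.stats`),
6. a CLI tying the stages together (`fpvs.cli`).

## Signal model of the generator

A session recording contains four 60-s stimulation sequences at 512 Hz on
64 scalp channels (BioSemi layout) plus 4 ocular channels. For each
category the response is a stack of `n_harmonics` sinusoids at k·f with
amplitudes decaying as `harmonic_decay^(k-1)` (default 0.5). The default
injects exactly two harmonics: harmonics beyond the second are then pure
noise, so the consecutive-failure selection rule (below) lands on K = 2 at
any noise level, which is the regime the quantification is designed for.

**Phases.** The steady-state response is locked to the stimulation, so the
phase of each (category, rate, harmonic) component is drawn once per
participant and reused across sequences and sessions. Time-domain averaging
of segments therefore adds signal coherently while noise cancels as 1/√m.
The amplitude measures themselves are phase-invariant (tested).

**Topography.** Each category has a signed per-channel amplitude map:
electrodes of the category's preferred regions of interest carry exactly
the target amplitude (faces: lateral occipito-temporal LOT/ROT; houses:
medial occipital MO; with secondary loading of each category on the other
regions), other channels fall off as a Gaussian of the unit-sphere distance
to the ROI centroids, and a constant is removed from the non-ROI channels
so every map sums to zero over the scalp. Zero-mean (dipolar) maps make the
common-average reference exact on signal — which is also what re-referenced
real data look like — and let the end-to-end recovery test close the loop
to within filter precision.

**Default cell means** (summed two-harmonic baseline-corrected amplitude,
µV): face (LOT 1.445, MO 1.575, ROT 2.010), house (LOT 0.995, MO 2.825,
ROT 1.210). These were chosen so that (a) the ROI marginal means are
(1.22, 2.20, 1.61), (b) the two stimulus marginals are equal (no stimulus
main effect), and (c) the face−house contrast is positive laterally and
negative medially with every pairwise direction of the target topography —
the empirical response structure of neurotypical adults in this paradigm.

**Variance structure.** Row response = cell mean + participant effect
u ~ N(0, 0.45²) (drawn once, shared across sessions — the source of
test-retest reliability) + session effect v ~ N(0, σ_w²) + row noise
e ~ N(0, 0.10²). σ_w is solved from
ρ = σ_b²/(σ_b² + σ_w² + σ_e²/6) so that per-stimulus session means
(averages of 6 rows) correlate at ρ = 0.90 between sessions. A treatment
effect δ (µV, default 0) is added under the active condition.

**Nuisance components.** Pink noise (1/f, SD 10 µV per channel), 10 Hz
alpha bursts over posterior channels (rate 0.05/s, 3 µV, 1-s Hanning
envelope), and biphasic 400-ms blinks (Poisson, participant rates
~N(0.09, 0.08²)/s truncated at 0) projected onto the vertical ocular pair
(±150 µV difference) and frontal scalp (≤50 µV). These are the dominant
nuisance components of real FPVS data. Not modeled: channel drift/pops,
muscle artifacts, line noise, spatially correlated background activity,
non-stationarity across the session. Passing tests therefore validate the
pipeline's arithmetic and statistical calibration under realistic SNR, not
robustness to every artifact class of real recordings.

**Behavior.** Each sequence has 15 fixation-cross color changes with a
minimum separation of 2.0 s (prevents ambiguous 0.1–2.0-s response
windows; the separation is a design choice, the original task only
randomizes). Hits occur with per-participant probability ~N(0.945, 0.02²),
at latency shift + lognormal (0.1 s + median 0.31 s, σ = 0.25, clipped to
[0.1, 2.0] s, mean ≈ 0.42 s); false alarms are Poisson at 0.01/s.

## Preprocessing

Fixed order: crop 68-s epochs (2 s before sequence onset to 66 s after) →
0.1–100 Hz 4th-order Butterworth → downsample to 256 Hz → blink ICA for
flagged participants → interpolation of listed bad channels → common
average reference over the 64 scalp channels.

* Filtering is zero-phase (forward–backward `sosfiltfilt`): amplitude
  spectra must not be confounded by group delay; the analytic check uses
  the squared analog Butterworth magnitude.
* Resampling is polyphase decimation (anti-aliased, linear phase).
* Blink detection: threshold crossings of the vertical ocular difference at
  4 scaled-MAD units with a 200-ms refractory period; participants whose
  rate exceeds the across-participant mean + 1.5 SD get one infomax ICA
  (runica family, seeded, on PCA-whitened concatenated epochs) and the
  single component with the largest back-projected variance removed.
* Interpolation replaces a bad channel by the inverse-distance-weighted
  mean of its three nearest good electrodes on the unit sphere, capped at
  3 channels (5% of 64).

## Spectral quantification

Epochs are cropped from stimulation onset to an integer number of 1.5 Hz
cycles — the common cycle of 6 and 7.5 Hz. Two modes exist:

* `nominal` (default): 15 203 samples = 59.3867 s, spectral resolution
  0.017 Hz. At this length neither 6 nor 7.5 Hz falls exactly on a bin
  center (6 Hz → bin 356.32), so a coherent tone loses ≈16% to scalloping;
  target bins are the nearest bins. This mode reproduces the published
  segment length verbatim.
* `exact-bin`: 15 360 samples = 60 s, placing both tags exactly on bin
  centers; injected amplitudes recover to < 0.1% and all recovery tests
  run in this mode.

Segments are averaged in the time domain per participant × treatment ×
stimulus × rate (2 segments each), then transformed to single-sided
amplitude spectra scaled so a bin-centered sinusoid of amplitude A reads A.

**Local noise bins.** For a target bin the candidate noise bins are the 22
bins at offsets ±2..±12 (immediate neighbours excluded). SNR and
baseline-corrected amplitude drop the two globally most extreme candidates
and use the remaining 20. The Z statistic
(target − noise mean)/noise SD (sample SD, n−1) instead uses the untrimmed
20 bins at ±2..±11: trimming the extremes shrinks the SD estimate by ~20%
and would inflate the nominal Z > 1.64 (p < .05) rule to a ~10% false-
positive rate; with the untrimmed set the empirical null rate on
group-averaged spectra is ≈0.06 (tested at ±0.02). A `shared` config
variant restores the single trimmed set everywhere, and `narrow` the
±2..±11-trimmed-to-18 reading.

**Harmonic selection** operates on the spectrum averaged across all
participants, conditions, and all 10 ROI electrodes, per tagging
frequency: harmonics are retained until two *consecutive* harmonics fail
Z > 1.64 (a lone dip does not stop the set), and multiples of 30 Hz —
shared by both streams — are excluded. The response measure is the sum of
baseline-corrected amplitudes over the retained harmonics, computed per
channel and averaged over each ROI (LOT: P7, P9, PO7; MO: Iz, Oz, O1, O2;
ROT: P8, P10, PO8).

**Individual significance**: per participant, 45-bin windows (22 flanks per
side) of the raw ROI-averaged spectrum centered at each retained harmonic
are summed elementwise across harmonics and the summed window's center is
Z-scored with the standard noise-bin rule.

## Statistics

* **Outliers**: |x − median| > 3 × 1.4826 × MAD of the response column.
  Constant data drop nothing; with MAD = 0 and non-identical values the
  deviants have infinite robust z and are dropped (warned either way).
* **Mixed model**: response ~ treatment × stimulus × ROI + session order
  (sum-to-zero coding), per-participant random intercept plus diagonal
  variance components for treatment, stimulus and ROI (lme4's
  `(1|participant) + (1|participant:factor)` structure). The treatment
  component is essential: treatment and session coincide within a
  participant, so it is what absorbs session-level noise and keeps the
  null treatment test at its nominal level (verified at 200 replicates).
  Estimation is REML via Powell (the boundary-prone variance surface
  defeats the gradient optimizers here), with an lbfgs retry; boundary
  estimates are reported as singular, not refitted. Type-III Wald F tests
  use residual (nobs − rank) denominator degrees of freedom — a documented
  approximation chosen over a Satterthwaite implementation, adequate at
  this design's sizes (hundreds of residual df; the fixed-effect estimate
  and SE are cross-validated against lme4 in the test suite).
* **Post-hocs**: Z tests on estimated marginal means (sum coding makes the
  EMM a design-row average), Holm-corrected within family (ROI main
  effect; stimulus-by-ROI cells).
* **Bayes factor** for the treatment factor: BIC approximation
  exp((BIC_reduced − BIC_full)/2) on ML fits, the reduced model dropping
  every fixed term containing treatment while keeping the random
  structure. This approximates a default-prior model comparison and is
  labeled as an approximation in every report.
* **Posterior differences**: per stimulus × ROI cell, per-participant
  OT−PL paired differences (averaged over rates) under a normal likelihood
  with the Jeffreys prior give a Student-t posterior for the mean
  difference; seeded draws are summarized by the mean and 95% highest-
  density interval (arviz).
* **Reliability**: Pearson r between session-1 and session-2 per-stimulus
  participant means.
* **Power**: within-factor repeated-measures power with m = 2 measurements:
  f = d/2, λ = n·m·f²/(1−ρ), power = P(F′(1, n−1; λ) > F_crit(α)). At
  n = 31, d = 0.3, ρ = 0.90 this gives 0.95; the formula is checked against
  a Monte-Carlo paired-test oracle.

## Problem sizes and numerical choices

Full-waveform studies are exercised end-to-end at n = 2 participants
(16 sequences, ~40 MB per session in memory) and via single sequences for
recovery tests; statistical calibration (type-I error, power matching,
Bayes factors, HDI coverage) runs on the amplitude-level generator at the
full n = 31 × 744-row scale over 150–200 replicate studies. The
consecutive-harmonic rule is demonstrated on 8 averaged segments at
realistic SNR. Determinism: every stochastic step derives from a single
seed through `numpy.random.SeedSequence` spawning; identical (config, seed)
reproduce datasets bit for bit.

Degenerate inputs are defined rather than crashed on: empty harmonic sets
quantify to 0 µV with a warning; a perfectly constant response yields an
all-null F table; a zero noise mean flags SNR as +∞; zero noise SD raises
(a Z score is undefined on a degenerate spectrum); a point-mass posterior
yields a zero-width HDI.

## Known limitations

* The nominal-mode crop length is honored verbatim even though it is not an
  integer number of 1.5 Hz cycles and leaves both tags off bin centers;
  exact-bin mode exists precisely to validate amplitude arithmetic.
* statsmodels' MixedLM provides no Satterthwaite/Kenward-Roger df; residual
  df makes the omnibus F tests slightly liberal at small denominator sizes
  (immaterial at 731 residual df, where the null calibration is verified
  empirically).
* The BIC Bayes factor and the t-posterior are approximations to full
  Bayesian model comparison; they are calibrated on synthetic data in the
  test suite (null BF < 1/3 in the vast majority of null studies, HDI
  coverage 0.92–0.98) but are not the original default-prior computation.
* The generator emulates measured response structure (amplitudes, their
  variance components, topography), not cortical physiology; EDF/BDF export
  is omitted (no EDF-writing backend available), though the reader side of
  the pipeline accepts any `Recording` built from such files.
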