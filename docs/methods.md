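# Methods

This note documents the models, numerical choices and known limitations of
`pvq`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and analysis protocol

Input is a mono sustained-vowel recording (PCM WAV).  The analysis
protocol is: take a 2-second segment centred on the recording midpoint
(odd leftover lengths bias one sample left), then decimate to 16 kHz with
polyphase resampling (the built-in Kaiser-windowed anti-alias FIR keeps
content below 7 kHz flat to well within 0.5 dB).  Whether segmentation
happens before or after decimation is immaterial for steady vowels; this
package segments first.  All features below operate on the 16 kHz segment.

## Feature families

### Traditional perturbation measures

*Cycle tracking.*  Frame-wise f0 is the peak of a length-normalized
autocorrelation within the 60–400 Hz lag range (covers adult voices).  Two
defences against period multiples: per frame, the smallest lag among local
peaks within 90% of the maximum wins; globally, the median period is
halved when the half-lag autocorrelation reaches 90% of the full-lag value
(cycle-alternating amplitude patterns otherwise favour 2·T0).  Cycle peaks
are then picked one per period marching outward from the global maximum,
each period refined to sub-sample precision by cross-correlating
neighbouring cycles over a ±2-sample search with parabolic interpolation —
the correlation window spans a whole period so additive noise averages
out.  The first and last cycles are trimmed (filter/onset transients).
Voicing requires an autocorrelation peak above 0.5; recordings with fewer
than half their frames voiced yield empty cycle marks.

*Jitter* is 100·mean|T_i − T_{i−1}|/mean(T) (%); *shimmer* is
mean|20·log10(A_{i+1}/A_i)| (dB); zero-amplitude pairs are excluded with a
warning.  Both need ≥ 3 cycles.

*HNR.*  The normalized autocorrelation peak r estimates the periodic
fraction of frame power, so per-frame HNR = 10·log10(r/(1−r)) dB; the
frame values and their mean are clamped to [−10, 40] dB (the upper clamp
prevents infinities on noiseless synthetic input).

*CPPS.*  1024-sample frames at a 2 ms hop; per frame the power cepstrum of
the dB magnitude spectrum is computed, smoothed by moving averages over 10
frames and 10 quefrency bins (the common smoothed-CPP spans), and
expressed in dB.  The prominence is the cepstral peak within the f0 band
(lags 1/400–1/60 s) minus a least-squares trend line fitted over
quefrencies from 1 ms to the maximum lag; frames are averaged.  Global
gain shifts only the zero-quefrency bin, so CPPS is amplitude-invariant.

### Gammatone filterbank cepstra (GFCC)

256-sample Hamming frames with 100-sample overlap (hop 156).  Frame power
spectra are weighted by 128 filters with 4th-order gammatone
squared-magnitude responses, |H(f)|² = [1+((f−fc)/b)²]⁻⁴ with
b = 1.019·ERB(fc), centres ERB-spaced over 50 Hz–8 kHz.  Log energies
(floored at 10⁻¹⁰ with a warning on silence) are decorrelated by an
orthonormal DCT-II.  Coefficient 0 (frame energy) is excluded; statics are
the frame means of c1..c30, deltas the frame means of their first-order
time differences — 60 features.  Keeping 30 coefficients is the unique
symmetric statics/deltas split yielding 60; it is the config key `n_gfcc`.

### LP-based LCQA features

20 ms non-overlapping frames; per frame an 18th-order LP model by the
autocorrelation method (Levinson recursion via `scipy.linalg.solve_toeplitz`,
a 10⁻⁹ diagonal ridge, bandwidth expansion γ = 0.996 for stability).  Five
descriptors per frame from the 512-bin LP model spectrum: spectral
flatness exp(mean log S)/mean S, excitation (residual) variance, signal
variance, spectral centroid, and spectral dynamics — the mean squared
difference of consecutive frames' log LP spectra, assigned to the later
frame (the first frame copies the second).  First differences of the five
(first delta replicated) give 10 per-frame series; their mean, population
variance, Fisher skew and excess kurtosis give the 40 features
`lcqa_01..40`, ordered descriptor-major.  Zero-energy frames are skipped
with a warning; fewer than 10 usable frames is an error.

### Modulation metrics

*SRMR.*  23 gammatone channels ERB-spaced from 125 Hz to Nyquist, applied
zero-phase in the frequency domain; per channel the temporal envelope is
the analytic-signal magnitude, resampled to 256 Hz (so envelope content
spans 0–128 Hz).  Envelope power spectra are integrated over 8 overlapping
2nd-order bandpass responses (Q = 2) log-spaced 4–128 Hz.  SRMR is the
total energy in bands 1–4 over bands 5–8 (denominator floored at 10⁻¹⁰);
it is exactly gain-invariant, and silence returns 0 with a warning.

*ModA.*  Four octave-wide acoustic bands (300–600–1200–2400–4800 Hz,
8th-order Butterworth-shaped magnitude responses); band envelopes are
resampled to 20 Hz (the polyphase anti-alias filter doubles as the 10 Hz
envelope lowpass).  Each envelope is normalized by its mean — the metric
reflects modulation *shape*, not loudness — and its zero-padded modulation
spectrum is integrated over 11 third-octave-wide bands log-spaced 0.5–8 Hz
(exact 1/3-octave spacing over that range would give 13 centres; the
11-centre grid preserves the stated range and count at a slightly wider
ratio).  The per-band area is the trapezoidal integral over log2
frequency; ModA is the mean of the four areas.

### Recurrence period density entropy (RPDE)

The signal, normalized to unit peak amplitude, is embedded with dimension
4 and delay 35 samples (≈ 2.2 ms at 16 kHz).  For each reference point the
close-returns time is the first re-entry into a ball of radius 0.12 (peak
units) *after first leaving it* — the exit requirement suppresses trivial
T = 1 mass.  Return times up to T_max = 1000 samples are histogrammed;
H_norm = −Σp·ln p / ln T_max ∈ [0, 1].  No recurrences ⇒ H_norm = 1 by
convention, with a warning.  Peak normalization (the usual voice-analysis
convention) was chosen over SD normalization after measurement: with an
SD-relative radius the white-noise entropy sits near 0.65 and is strongly
sensitive to the reference-point stride, violating the intended
noise/periodicity separation; with peak normalization noise scores ≈ 0.95,
a sinusoid ≈ 0.04, and halving the stride moves H_norm by < 0.005.
Reference points are subsampled by stride 2 on recordings ≥ 2 s.

## Synthetic cohort

The generator emulates sustained /a/ phonation: a band-limited pulse train
(harmonics at −12 dB/octave) with per-cycle periods T0(1+ε_i), passed
through three cascaded formant resonators ((700, 130), (1220, 170),
(2600, 250) Hz — standard male /a/).  The perturbation series ε_i and the
per-cycle dB gains are drawn Gaussian and *rescaled empirically* so the
realized jitter and shimmer equal their targets exactly.  Shimmer gains
multiply the filtered waveform, with the gain switch placed a quarter
period before each pulse so a pulse's entire formant response carries one
cycle amplitude (switching at the pulse instant saturates measured peaks
toward the smaller neighbouring amplitude).  Aspiration noise is white
noise shaped by the same formant cascade and scaled so the
periodic-to-aperiodic power ratio equals the target HNR exactly.

Cohort defaults (113 vowels): f0 ~ U(100, 220) Hz, jitter ~ U(0.1, 2.5) %,
shimmer ~ U(0.05, 1.5) dB, HNR ~ U(3, 30) dB — spanning near-normal to
severely dysphonic phonation.  The rater panel maps parameters to a mean
VAS via a logistic in a weighted sum of HNR, jitter and shimmer; the
weights give the three dimensions comparable perceptual variance over the
cohort ranges (perceived dysphonia integrates several acoustic dimensions
rather than tracking one), and are calibrated so the consensus mean ≈ 55
VAS and SD ≈ 18 VAS.  Three raters with biases (−5, 0, +5) VAS and
independent N(0, 8²) noise yield an average-consistency ICC near 0.9 —
good interrater reliability.  The quality map is an explicit simulator
choice, not a perceptual model.

What the generator does *not* emulate: vocal tremor and f0 drift,
diplophonia and subharmonic regimes, nonstationary onsets/offsets, room
acoustics and microphone variation, and any true listener psychology.
Tests passing on this cohort show the pipeline recovers known ground truth
and preserves expected orderings; they do not certify clinical accuracy.

## Modelling layer

All columns are standardized with training-partition statistics (stored,
never re-estimated at predict time; predictions run entirely from stored
arrays, so JSON serialization round-trips bit-exactly).  LR is OLS with
intercept, falling back to ridge (α = 1) with a warning when
underdetermined.  SVR uses an RBF kernel with C = 10, ε = 1 VAS unit and
kernel width 1/n_features — fixed config constants, no tuning loop.  PCA
keeps the smallest component count reaching 95% cumulative explained
variance on standardized data (standardization is required: the feature
families differ in scale by orders of magnitude).

Subset selection ranks features by |Pearson r| with y (ties by column
index, zero-variance columns get r = 0), then runs 2000 Monte Carlo
iterations: subset size uniform on 1..n, members sampled without
replacement with weight proportional to n − rank.  Each distinct subset is
scored once — memoized — by its mean validation MSE over a fixed panel of
10 seeded 75/25 splits of the training rows, fitted by intercept LR.  The
minimum-MSE subset wins (ties prefer smaller, then lexicographically
earlier subsets).  Scoring on a *fixed* split panel rather than one fresh
split per draw makes the objective a deterministic function of the subset,
which is what lets a Monte Carlo search provably coincide with exhaustive
enumeration once every subset has been visited; the suite verifies this
equivalence on 6-feature instances.  Selection never sees held-out rows —
an assertion enforces train/test disjointness in every repeated-split run.
A one-standard-error parsimony rule was evaluated and rejected: it neither
removes chance-correlated decoys (their advantage is a property of the
fixed noise realization, visible to any within-dataset split) nor helps
generalization, and it systematically underfits the composite model.

The composite metric is the canonical 42-column table (lcqa_01..40,
hnr_db, cpps_db) in fixed order.  Reported dimensionality reductions are
data-dependent diagnostics, not contracts.

## Evaluation statistics

σ̂ₛ uses the population (1/n) SD; at n ≈ 90 the 1/n vs 1/(n−1) difference
is below the 2-decimal reporting grain.  Every emitted report asserts
SDPE = σ̂ₛ·√(1−ρ²) to 10⁻¹⁰.  Steiger's Z uses the Fisher-transform form
with the pooled covariance term built from r₁₂ and the squared mean of the
two correlations; inputs must form a jointly realizable (positive
semi-definite) correlation triple, and corner cases where the asymptotic
covariance approximation degenerates (s ≥ 1) raise an input error rather
than returning NaN.  ICC comes from the two-way ANOVA mean squares:
consistency ICC(C,k) = (MSR−MSE)/MSR and absolute-agreement
ICC(A,k) = (MSR−MSE)/(MSR+(MSC−MSE)/m), average-measures conventions; the
suite cross-checks both against pingouin.  The paired t-test and Pearson p
(two-sided t with n−2 df) come from scipy.

`repeated_split_eval` draws a fresh seeded 80/20 split per repeat,
re-runs the *entire* pipeline (including selection) on the training
partition and scores both partitions; means over repeats are reported with
per-repeat values attached.

## Problem sizes and determinism

The test suite synthesizes its cohorts at the study scale (113 vowels,
2 s at 16 kHz) and averages over 20 repeated splits; single-vowel checks
use 2-second signals.  Everything is seeded: synthesis specs, cohort
draws (per-recording seeds spawned from the cohort seed), rater noise,
splits and subset search, so every number in the README and the test
suite reproduces bit-identically.

## Known limitations

- The traditional measures are native implementations, tested against the
  generator's ground truth; they are not drop-in replacements for any
  specific analysis program's numbers (absolute CPPS levels in particular
  depend on framing and smoothing conventions).
- SRMR and ModA follow the published constructions at the level of band
  counts, ranges and envelope rates, but filter shapes are magnitude-domain
  approximations; only order/invariance properties are guaranteed.
- RPDE toolbox parameter defaults vary across the literature; bounds and
  monotonicity, not point values, are the contract here.
- With 20 ms non-overlapping frames, LCQA statistics on 2-s vowels rest on
  ~100 frames; skew/kurtosis estimates are correspondingly noisy.
- The quality map linking acoustics to VAS is a simulator construct;
  correlations measured on the synthetic cohort say nothing quantitative
  about clinical listener panels.
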