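# Methods

This note records the generative model, the analysis conventions, and the
numerical choices the package makes, including everything a reader needs to
interpret the synthetic-study results.

## Synthetic polysomnography

**Hypnogram.** Stage sequences are drawn from a first-order Markov chain
over the five AASM stages (W, N1, N2, N3, REM) at one transition per 30-s
epoch. The default transition matrix was chosen so that (a) the stationary
stage mix is plausible for a full night (roughly 9% W, 9% N1, 46% N2, 15%
N3, 21% REM of epochs), (b) N3 occurs in relatively short bouts, keeping the
night-to-night variance of total N3 time small enough that a 20-pair study
has reasonable power, and (c) stable runs of N2 (the stimulation trigger)
occur early in essentially every night. This is a calibration of the
generator — it defines the study conditions and is not derived from any
dataset.

**N3-enhancement effect.** The stimulation condition multiplies every
transition probability *into* N3 by `n3_boost` from the trigger epoch
onward, renormalizing each row. The default `n3_boost = 1.11` yields a mean
relative whole-night N3 increase of about +13% over the sham draw of the
same random stream. The stimulation-night hypnogram is re-drawn from the
*same* pre-generated uniform stream with the boosted matrix active only
after the trigger, so the two passes are identical before stimulation
onset.

**EEG synthesis.** Each 30-s epoch is a sum of stage-specific narrow-band
sinusoids (uniform random frequency within the component band, uniform
phase, per channel) plus white noise: W has an 8–12 Hz alpha component; N1
theta; N2 spindle bursts (11–16 Hz) and a small slow component; N3 a large
0.5–1 Hz slow-oscillation component (RMS 60 μV → peak ≈ 85 μV, satisfying
the >75 μV slow-oscillation criterion) plus delta; REM low-amplitude theta
with slow EOG deflections. EMG amplitude decreases monotonically from W to
REM. The model validates at construction that N3's slow-wave component
dominates every other stage and that the slow-oscillation peak exceeds
75 μV. Per-epoch seeds are spawned from a `SeedSequence`, so recordings are
bit-reproducible.

**TES artifact.** Stimulation blocks add a 5000 μV 0.5 Hz sinusoid to every
channel — an idealization of amplifier saturation that is roughly 100×
larger than the physiological signal, making stimulated samples trivially
identifiable, exactly like the real artifact motivates the epoch-exclusion
rule.

**What the generator does not model.** Real sleep has ultradian cycle
structure (REM periods lengthen across the night), K-complexes,
micro-arousals, movement/sweat artifacts, inter-subject spectral
differences, and volume-conduction correlations between channels; the
channels here are independent draws from the same stage model. None of
these omissions are material to the pipeline logic the package tests.

## Protocol bookkeeping

Stimulation triggers after eight consecutive N2 epochs ("stable N2 for
4 min"). The protocol is five 300-s blocks separated by four 60-s rests.
Pauses freeze the protocol clock: intervals are split at the pause and the
remainder of the protocol shifts right, conserving the 1500 s of stimulated
time. Sham nights get placeholder schedules with identical geometry.

Every epoch overlapping a stimulation block (any overlap of the half-open
30-s interval) is excluded from all duration statistics. The *immediate*
window is the four rests plus the 300 s after the final block (540 s
maximum); intervals beginning at or after the first pause resumption are
dropped when `exclude_after_pause` is set. The *spectral* windows are the
300 s before the first block (pre) and the rests-plus-final-300-s with the
first 20 s of each removed (440 s usable post), which discards the
stimulation-offset transient.

## Spectral analysis

Within each window, maximal artifact-free runs (every analysis channel
within ±300 μV) of at least 5 s are selected; each is tapered with a Tukey
window (α = 0.2) and the tapered segments are concatenated. The Welch PSD
uses a Hanning window, 2.56-s segments, 1.28-s (50%) overlap, one-sided
density scaling, no detrending. Slow-wave band power is the mean PSD over
bins in [0.5, 1.0] Hz — at 64 Hz and 2.56-s segments a single native bin
falls in-band; `WelchSpec.nfft_factor` can zero-pad for a denser grid.
Regional power averages channel band powers over each of ten scalp regions;
relative power is the percent change from the pre- to the post-stimulation
window.

## Statistics

All contrasts are two-condition repeated-measures comparisons over the same
subjects, so the RM-ANOVA reduces exactly to F = t² with df (1, n−1). The
Wilcoxon signed-rank statistic is reported as T = min(W+, W−) with zero
differences dropped and average ranks for ties; p is exact (full 2ⁿ
enumeration) for n ≤ 12 without ties, otherwise a tie-corrected normal
approximation with continuity correction. The immediate-window contrasts
drop the subject who was awake during most of the stimulation-night window,
use a one-tailed test for N3 and two-tailed for N2, and always recompute
differences from the condition columns (the printed difference column of
the source table is internally inconsistent). `scipy`, `scikit-learn`, and
`pingouin` implementations are used only as test oracles; the shipped
statistics are computed by the package itself because the T statistic is an
acceptance surface.

## Sleep stager

The five-stage classifier is a 1-D convolutional network implemented in
numpy (no deep-learning framework is assumed): stacked stride-2
convolutions (im2col) with ReLU, global average pooling, one dense ReLU
layer, and a five-way softmax, trained with Adam on cross-entropy with
best-validation-accuracy checkpointing. Inputs are (5, 1920) blocks — four
bipolar derivations (C3-M2, C4-M1, EOGL-M2, EOGR-M1) plus EMG — at 64 Hz,
divided by a 50 μV scale. The full-scale architecture (10 layers, 384
filters) is configurable; the shipped experiments use a reduced preset
(4 layers, 32 filters) that trains in well under a minute on one CPU and
reaches kappa > 0.95 on held-out synthetic nights. A vectorized rule-based
scorer (band-power thresholds calibrated once against the default signal
model) provides a fast deterministic alternative for large studies.

## Problem sizes and runtime

One synthetic night is 8 h × 7 channels at 64 Hz (≈13 million samples,
generated in ~1 s). A 20-subject-pair study with rule-based staging runs in
~40 s; the acceptance script (table statistics + CNN training/evaluation +
three study replicates) takes a few minutes on one CPU.

## Limitations

The end-to-end recovery result is stochastic: with 20 pairs and the default
+13% effect, a minority of replicate seeds fall short of one-tailed
p < 0.05, which is expected at this power; the acceptance surface is
therefore "significant in the majority of replicates". The EDF writer
emits a minimal plain-EDF subset (integer sampling rates, whole-second
records, symmetric physical ranges) sufficient for round-tripping the
synthetic recordings, not a general EDF+ implementation.
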