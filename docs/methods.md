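# Methods

`neurotriage` implements a fast depression-screening pipeline for
3-channel prefrontal EEG (Fp1, Fpz, Fp2): variational mode decomposition
(VMD) of the band-passed signal, power-spectrum selection of the primary
intrinsic mode functions (IMFs), sample-entropy features on 1-s analysis
windows, and a gradient-boosted (LightGBM) classifier evaluated under a
time-ordered, leakage-aware protocol. This note records the model, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Signal model and preprocessing

Input is resting-state EEG, 3 channels at 250 Hz, 90 s per subject, in
microvolts, from EDF or CSV. Preprocessing applies a linear-phase FIR
band-pass of 1–45 Hz (window method, Hamming, order 250 — 1 s of taps at
250 Hz, giving a ~3 Hz transition band and >50 dB stopband per pass),
run forward–backward so the net phase is zero. Zero-phase filtering was
chosen because sample entropy is sensitive to waveform shape, which
group-delay distortion would corrupt; the cost is a doubled (squared)
magnitude response, which is immaterial inside a passband that is flat
to <1%. Recordings are cut into non-overlapping 1-s windows (windows
start at multiples of the step and are emitted only when fully inside
the recording), so a 55-subject cohort of 90-s recordings yields exactly
4,950 windows.

## Variational mode decomposition

VMD decomposes a signal x(t) into K band-limited modes u_k(t) with
center frequencies ω_k by minimizing the summed bandwidth of the
analytic, baseband-shifted modes subject to Σ_k u_k = x, relaxed with a
quadratic penalty α and Lagrange multiplier λ(t). The ADMM iteration
runs on the one-sided (analytic) spectrum:

    û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)
    ω_k ← ∫ ω |û_k|² dω / ∫ |û_k|² dω
    λ̂  ← λ̂ + τ (f̂ − Σ_k û_k)

with ω in normalized cycles/sample so α is comparable across sampling
rates. Numerical choices:

- **Defaults** K = 5, α = 2000, τ = 0, tol = 1e−7, max_iter = 500,
  uniform initialization of ω_k over [0, fs/4], no DC mode. These are
  the common defaults of the VMD literature; all are exposed in
  `VMDConfig`. τ = 0 relaxes exact reconstruction, which tolerates
  noise; the residual (input minus mode sum) is carried explicitly so
  additive closure is exact by construction regardless.
- **Boundary handling**: even (mirror) extension to twice the length
  before the FFT, trimmed after inversion, to suppress edge ringing on
  short segments.
- **Convergence** is Σ_k ‖u_k^{n+1} − u_k^n‖²/‖u_k^n‖² < tol; hitting
  max_iter clears a `converged` flag rather than raising, since a
  slightly unconverged decomposition is still usable downstream.
- **Canonical order**: modes are always returned sorted by ascending
  ω_k, whatever the initialization; two modes may legitimately converge
  to the same frequency (duplicates are allowed and documented).
- **Degenerate centroids**: if a mode's spectrum is identically zero
  (e.g. an all-zero input) its ω_k simply keeps its previous value.
- A **batched driver** decomposes many equal-length signals at once with
  a per-signal active mask, freezing each signal's state the iteration
  it converges, so batched and one-at-a-time results are bitwise
  identical; the feature stage relies on it for throughput.

## IMF selection

After decomposition the highest-frequency mode carries mostly broadband
noise whose frequency distribution differs from the physiological
modes, so only the primary IMFs are kept. "Primary" is operationalized
as the n_keep = 4 (of K = 5) modes with the lowest spectral centroids —
the power-weighted mean frequency of each mode's Welch spectrum (Hamming
segments of 125 samples, 50% overlap; the estimator is a
variance/resolution compromise for 1-s windows and is also sensible on
full recordings). An alternative energy-fraction rule (drop modes below
a configurable fraction of total power) is available behind a config
switch, default off. Dropped modes are folded into the residual so the
additive reconstruction stays exact.

## Decomposition scope

The default pipeline decomposes each *recording* once per channel and
then cuts the 1-s windows from the four retained IMF streams
(`features.vmd_scope = "recording"`). The alternative of decomposing
every 1-s window independently is implemented and reachable via
`vmd_scope = "window"`. The recording scope is the default because mode
identities are then stable across a subject's windows, and the per-window
entropy estimates are far less noisy: on the default synthetic cohort
the window-scope pipeline plateaus near 88% test accuracy while the
recording scope reaches ~95%. The recording scope also matches how a
screening device would run: decompose the incoming stream once,
then score each second.

## Sample entropy

SampEn(m, r) = −ln(A/B), where B counts ordered pairs of length-m
templates within Chebyshev distance r and A the same at length m + 1,
self-pairs excluded; both dimensions use the same Q − m templates (the
convention under which a constant series scores exactly 0). Defaults
m = 2, r = 0.2·sd — the field standard for physiological series — with
r computed from the sd of the specific IMF segment being scored, which
makes the feature exactly scale-invariant and keeps the tolerance
matched to each mode's scale. When no pair matches at either length the
value is undefined; the default surrogate is the attainable upper bound
ln((Q−m)(Q−m−1)), finite so downstream models never see infinities
(NaN available via an argument). The optimized implementation is
vectorized over the pair matrix and is verified against a literal
double-loop transcription to <1e−10 in the tests.

RMS and PSD features (means over non-overlapping 20-point sub-windows
of per-block RMS / total periodogram power) are provided for ablation
comparisons; the default feature set is SampEn only, giving
3 channels × 4 IMFs = 12 features per window.

## Classifier and evaluation protocol

LightGBM is the classification stage (gradient-boosted trees; its
objective adds the per-tree regularizer γT + ½λΣw_j² — exposed as
`reg_gamma`/`reg_lambda`, both 0 by default). Defaults: 50 leaves and
learning rate 0.01 (the argmax of the enumeration grid below), 4000
boosting rounds (sized for that small rate by validation accuracy — 200
rounds at lr 0.01 demonstrably underfits), `min_child_samples` = 5 so
trees can split on modest tables, single-threaded and deterministic for
a fixed seed. MDD is the positive class throughout, so recall measures
patient detection.

Adjacent 1-s windows of one subject are highly correlated, so a shuffled
split would leak near-duplicates into the test set. The protocol instead
orders the pooled windows chronologically — subjects are recorded in
separate, effectively parallel sessions, so the dataset-wide time axis is
time *within* the recording (all subjects' first seconds, then second
seconds, …) — and takes the first 50% as the training pool and the last
50% as the test set; the last 30% of the pool is the validation set for
hyperparameter search. Every subject appears on both sides of the split
(the task is "screen a known cohort's later minutes", not "generalize to
unseen subjects"), while adjacent windows never straddle the boundary.
All fractional splits use the floor convention with remainders to the
earlier part. After hyperparameter selection the final model is refit on
the full training pool (train + validation).

Hyperparameter search is exhaustive enumeration over
leaves {10, 20, 30, 40, 50, 100} × learning rate
{0.01, 0.005, 0.001, 0.0005, 0.0001}, scored by validation accuracy;
ties prefer fewer leaves, then the larger rate (the simpler,
faster-converging model), and the result is invariant to enumeration
order. Cross-validation uses contiguous time blocks of the training pool
(k = 5) by default — the stricter variant consistent with the adjacency
concern — with shuffled folds available via config. Metrics
(accuracy/precision/recall/F1, in percent) recompute exactly from the
stored confusion matrix; mean per-window inference time is recorded as
metadata only, since it is hardware-dependent.

## Synthetic cohort generator

The generator provides seeded cohorts with the statistical structure the
pipeline assumes, so the whole chain is testable without any data
download. Each subject's channel is a sum over the canonical bands
δ(1–4), θ(4–8), α(8–13), β(13–30 Hz) of one sinusoid per band — the
frequency drawn uniformly inside the band, independently per channel
(three distinct local oscillators), fixed for the whole recording so a
subject's windows stay correlated — plus 1/f (pink) noise synthesized by
frequency-domain 1/√f shaping of white noise, and white noise. Class
profiles: HC band amplitudes (δ, θ, α, β) = (4, 3, 3, 2) µV, MDD
(4, 3, 5, 4) µV — depressed patients carry more α/β power — with MDD's
white-noise floor 1.5× the control floor, reflecting the higher
broadband complexity reported in depressed EEG. The free scales were
fixed once at pink = 2.0 µV, white = 1.0 µV (HC), per-subject amplitude
jitter ±10%: background noise comparable to, but not dominating, the
rhythmic components is what resting prefrontal EEG looks like after
artifact cleaning. Sub-seeding is `seed + subject_index`.

Under these defaults the cohort satisfies three contracts (verified in
the tests over 50 seeds): mean α- and β-band power of MDD exceeds HC
with the δ gap smaller than the α gap; mean raw-signal sample entropy of
MDD exceeds HC; and the full pipeline separates the classes at ≥90%
test accuracy under the time-ordered split.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: real EEG rhythms are broadband and
nonstationary rather than fixed-frequency sinusoids; there are no
artifacts (eye blinks, EMG — the motivating dataset is already
artifact-cleaned); inter-channel correlation is limited to none beyond
class structure; and the class contrast is a stylized two-parameter
effect, not clinical heterogeneity. Accuracy on this cohort validates
the pipeline's mechanics and its sensitivity to band-power/complexity
contrasts; it is not evidence of clinical performance.

## Problem sizes

The test suite and the acceptance script run the full default study —
55 subjects × 90 s × 250 Hz (4,950 windows, 12 features) — in a few
minutes on one CPU; unit tests use small cohorts (4–8 subjects, 6–10 s)
and short signals. The VMD agreement checks against the literal per-bin
iteration use 20 random 1-s signals at a fixed iteration count, which
compares the iterates directly without waiting for convergence.

## Known limitations

- The EDF writer is a minimal 16-bit encoder (quantization ~0.01% of
  peak); it is round-trip tested against the `mne` reader but does not
  cover EDF+ annotations.
- VMD mode count K is fixed per run; no automatic selection of K.
- The evaluation protocol scores windows, not subjects; no
  subject-level aggregation (e.g. majority vote over a minute) is
  provided, though it would be the natural deployment rule.
- With `vmd_scope="window"` the per-window entropy estimates are noisy
  and accuracy drops by ~7 points on the synthetic cohort; the scope
  switch exists precisely to make that comparison reproducible.
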