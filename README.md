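# neurotriage

Fast depression screening from 3-channel prefrontal EEG (Fp1, Fpz, Fp2).

Clinics see many patients — often middle-aged or elderly — with
medically unexplained symptoms (fatigue, pain, gastrointestinal
complaints) that frequently trace back to depression, yet early cases
fail questionnaire-based criteria and go untreated. A portable 3-lead
EEG headset plus one second of signal is enough, in principle, to
pre-triage such patients. `neurotriage` is a tested, reusable
implementation of that screening pipeline for signal-processing and
computational-psychiatry researchers: it ships the full chain from raw
recordings (or a built-in synthetic cohort generator) to a classified
report, with every stage exposed as a library function.

## Method

For each subject, 90 s of resting-state EEG at 250 Hz is band-passed to
1–45 Hz (zero-phase FIR) and cut into 1-s windows. Each channel is
decomposed by **variational mode decomposition** (VMD) into K = 5
band-limited intrinsic mode functions u_k(t) with center frequencies
ω_k, solving

    min Σ_k ‖∂_t[(δ(t) + j/πt) * u_k(t)] e^{−jω_k t}‖²   s.t.  Σ_k u_k = x

by ADMM in the frequency domain (penalty α, multiplier λ). The four
lowest-spectral-centroid IMFs are retained per channel (power-spectrum
selection), and **sample entropy**

    SampEn(m, r) = −ln( A / B ),   m = 2,  r = 0.2·sd

is computed on each retained IMF per 1-s window, giving 12 features
(3 channels × 4 IMFs). A LightGBM classifier (50 leaves, learning rate
0.01, selected by exhaustive enumeration on a validation set) labels
each window HC or MDD. Evaluation is strictly time-ordered — early
halves of the recordings train, late halves test — so correlated
adjacent windows never leak across the split; metrics are
accuracy/precision/recall/F1 from the confusion matrix with MDD as the
positive class.

## Worked example

```python
from neurotriage import PipelineConfig, run_pipeline
from neurotriage.pipeline import CohortConfig

# 29 controls + 26 patients, 90 s at 250 Hz, fully synthetic and seeded
result = run_pipeline(PipelineConfig(cohort=CohortConfig(seed=0)))
r = result.report
print(f"windows={result.n_windows} features={result.n_features}")
print(f"test accuracy  {r.accuracy:.2f}%")
print(f"test precision {r.precision:.2f}%  recall {r.recall:.2f}%  F1 {r.f1:.2f}%")
cv = result.cv_report
print(f"5-fold CV accuracy {cv.mean['accuracy']:.2f} +/- {cv.sd['accuracy']:.2f}%")
```

prints (a few minutes on one CPU):

```
windows=4950 features=12
test accuracy  95.19%
test precision 94.57%  recall 95.30%  F1 94.93%
5-fold CV accuracy 94.63 +/- 1.52%
```

4,950 windows are the 55 subjects × 90 one-second windows; 12 features
are sample entropy on 4 retained IMFs × 3 channels. The test accuracy
is measured on the last 45 s of every subject after training on the
first 45 s (2,475 windows each side); the CV line is contiguous 5-fold
cross-validation inside the training pool. On this synthetic cohort the
classes differ in α/β-band power and broadband complexity, so the
numbers validate the pipeline's mechanics, not clinical performance
(see `docs/methods.md`).

The same pipeline runs from the shell:

```bash
neurotriage run  --config cfg.yaml --out out/      # full pipeline + report
neurotriage grid --config cfg.yaml --out out/      # leaves x rate enumeration
neurotriage cv   --config cfg.yaml --out out/      # contiguous k-fold CV
```

with `--input DIR --format csv --fs 250` to use your own recordings
instead of the synthetic cohort (one CSV/EDF file per subject, filename
prefix `HC`/`MDD` as label).

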