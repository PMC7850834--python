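# emdwave

EEG-based detection of **situational interest** — the transient engagement
state a student experiences during a lecture — from 8-channel scalp EEG.
The package is a tested library plus CLI for researchers in educational
neuroscience and biomedical signal processing who want to go from raw
multichannel recordings (EDF or delimited matrices) to a cross-validated
high/low-interest classification, or to reuse any single stage:
preprocessing, Welch band-power analysis, empirical mode decomposition,
wavelet subband energies, or the weighted-kNN classifier.

## The method

High and low situational interest differ primarily in frontal **delta**
(< 4 Hz) power.  The core feature extractor therefore combines two
decompositions so that *every* oscillatory mode contributes a
delta-sensitive quantity:

1. **EMD.** Each channel x(t) is sifted into intrinsic mode functions,
   x(t) = Σ_{j=1..n} c_j(t) + r_n(t), ordered high to low frequency.
2. **DWT per IMF.** Each c_j undergoes a 5-level db4 discrete wavelet
   transform, splitting it into details D1..D5 and approximation A5
   (the ≲ 4 Hz content at the rates used here).
3. **Feature.** The *relative energy* of A5 —
   100 · Σ A5² / (Σ A5² + Σ_j Dj²) — i.e. the percentage of the IMF's
   energy lying in the low-frequency band.  With 8 channels × 8 IMFs this
   gives 64 features per segment, each in [0, 100] and invariant to
   signal rescaling.

Two baseline feature sets share the interface: plain IMF energies
(Σ c_j², 64 features) and plain DWT subband energies (6 × 8 = 48).

Classification is weighted k-nearest neighbours: Euclidean distance
d(x, y) = √Σ(x_i − y_i)², vote weight w = 1/d², default k = all training
points (far points are negligible under 1/d², so k needs no tuning).
Evaluation reports accuracy, sensitivity and specificity with high
interest as the positive class, under leave-one-out or stratified k-fold
cross-validation.

A synthetic-data module generates labeled classroom-like EEG (band-limited
rhythm noise, eye blinks, 50 Hz mains, sensor noise) whose classes differ
by a controllable frontal-delta factor, so the whole pipeline is testable
without any recordings.

## Worked example

End-to-end on synthetic data — simulate 6 subjects per class (60 s at
250 Hz, frontal delta tripled in the low-interest class), preprocess
(50 Hz notch + 0.5–47 Hz FIR), extract the 64 hybrid features per
segment, and cross-validate wkNN leave-one-out:

```bash
emdwave run --out-dir demo-run --fs 250 --duration 60 \
            --n-per-class 6 --delta-effect 3 --seed 5
```

prints

```json
{
  "tp": 6,
  "fp": 0,
  "tn": 6,
  "fn": 0,
  "accuracy": 100.0,
  "sensitivity": 100.0,
  "specificity": 100.0
}
```

All 12 held-out segments are classified correctly (6 true positives =
high-interest, 6 true negatives = low-interest): the frontal-delta
contrast of a factor 3 in amplitude is easily separable.  With
`--delta-effect 1` (no class difference) the same command yields
chance-level accuracy.  `demo-run/` contains the 12 × 64 feature table
(`features.csv`), the metrics (`evaluation.json`) and a `manifest.json`
recording the exact configuration and seed, from which the run is
byte-for-byte reproducible.

The same stages are available as subcommands (`simulate`, `preprocess`,
`features`, `classify`) operating on EDF files on disk, and as plain
functions:

```python
from emdwave import (SyntheticSpec, generate_dataset, preprocess,
                     build_feature_table, cross_validate)

segs = [preprocess(s) for s in generate_dataset(SyntheticSpec(), 15, seed=11)]
table = build_feature_table(segs, method="hybrid")
print(cross_validate(table, scheme="loo").as_dict())
```

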