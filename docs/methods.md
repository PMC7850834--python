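# Methods

`emdwave` implements an EEG feature-extraction and classification pipeline
for detecting a student's situational interest (a transient, context-driven
engagement state) from 8-channel scalp EEG.  The discriminating physiology
it targets is frontal delta-band (< 4 Hz) power, which differs between
highly engaged and unengaged students during a lecture.  This note records
the models, the numerical choices made where the underlying procedures
leave them open, and the known limitations.

## Preprocessing

Recordings (channels × samples, microvolts) pass through:

1. **50 Hz notch** — second-order IIR notch, quality factor Q = 30
   (≈ 1.7 Hz −3 dB width), applied forward–backward (`filtfilt`) so the
   phase response is zero and the attenuation at 50 Hz is twice the
   single-pass design (well beyond 30 dB).
2. **0.5–47 Hz FIR band-pass** — linear-phase windowed-sinc (Hamming),
   order ⌈3.3·fs/Δf⌉ with a 1 Hz transition width, applied once by FFT
   convolution with the integer group delay compensated exactly.  A
   linear-phase filter applied this way is zero-phase; the Hamming sidelobe
   floor (≈ 53 dB) exceeds the 40 dB stopband requirement without a second
   pass, which halves the cost on 77 000-sample segments.  The per-channel
   mean is subtracted first; DC and sub-0.5 Hz drift fall in the stopband,
   so no separate detrending stage exists.
3. **Segment extraction** — annotated intervals are truncated *from their
   start* to a common standard length (default 154 s = 2 min 34 s, the
   least interval length across subjects in the intended use), giving
   exactly `round(154·fs)` samples per segment (77 000 at 500 Hz).
   Intervals shorter than the standard length are skipped with a warning
   rather than zero-padded.

Edges: both filters are non-LTI within one filter length of the signal
ends (reflection padding), so filter-order-wide edge regions are excluded
when filters are compared against each other in tests.

## Welch band powers

PSDs use Welch's averaged modified periodogram with a Hann window and
8 windows at 50 % overlap; the window length is
`floor(N / (1 + 7·0.5))` so the eight windows exactly tile the segment.
Windows are mean-detrended; scaling is one-sided density (µV²/Hz), so the
integrated PSD of a stationary signal approximates its variance.

Band powers integrate the broadband PSD over each rhythm band by
trapezoids, with the band edges included exactly via linear interpolation,
which makes band powers additive over adjacent bands.  Default edges:
delta 0.5–4, theta 5–7, alpha 8–12, beta 13–30, gamma 30–47 Hz (the
4–5, 7–8 and 12–13 Hz gaps are deliberate — they match the rhythm table
this pipeline standardises on; edges are configurable).  Integrating the
broadband PSD was chosen over filtering each band and then estimating its
PSD: for ideal filters the two agree, and the broadband route avoids
compounding filter-design artifacts.

Regional averages are arithmetic means over frontal (Fp1, Fp2, F3, F4),
temporal (T7, T8) and occipital (O1, O2) channels; T3/T4 are accepted as
aliases of T7/T8 (same 10–20 sites, older names).  Percent change is
`100·(condition − baseline)/baseline`, so a delta increase during the
lecture is a positive number.  (Definitions of this quantity in the
literature differ in sign; the convention here is fixed and documented
rather than silently matched to any one source.)

## Empirical mode decomposition

Sifting subtracts the mean of the upper and lower cubic-spline envelopes
of the extrema, `h_k = h_{k-1} − m_k`, until `h_k` is an intrinsic mode
function; the accepted IMF is removed and the remainder re-sifted, up to
`max_imfs = 8` modes (fixed at 8 so that every channel yields the same
8-slot feature block; remaining oscillation folds into the residue).
Reconstruction `Σ IMFs + residue = input` is exact by bookkeeping.

Choices the classical algorithm leaves open, as made here:

* **Stopping rule**: aggregate SD criterion
  `Σ(h_{k-1} − h_k)² / Σ h_{k-1}² < 0.2` *and* the IMF counting condition
  (|#extrema − #zero-crossings| ≤ 1), with a hard cap of 100 passes.  The
  aggregate ratio is more stable than the pointwise form on samples where
  `h_{k-1}` is near zero.
* **Envelopes**: not-a-knot cubic splines through the extrema; the two
  extrema nearest each edge are mirrored about the signal endpoints before
  fitting, the standard remedy for spline end-swing.
* **Plateaus**: the first sample of a flat run counts as the extremum.
* **Termination of the outer loop**: the remainder is treated as the
  residue as soon as it has fewer than two maxima or two minima, or its
  amplitude falls below 1e-12 of the input's.

Known limitation: EMD modes are only *approximately* orthogonal.  For
well-separated oscillations the total IMF energy stays within ~5 % of the
input energy, and the tests check that bound on multi-tone signals; on
broadband noise the mode-mixing leakage reaches 10–20 % regardless of the
stopping threshold, which is inherent to envelope sifting, not a defect of
this implementation.  Nothing downstream relies on orthogonality — the
hybrid features are per-IMF quantities.

## Discrete wavelet transform

Multilevel dyadic DWT via PyWavelets, default db4 (Daubechies, 4 vanishing
moments, 8-tap filters) at 5 levels, **periodized extension** so the
transform is orthogonal: perfect reconstruction and Parseval
(Σ coefficient energy = signal energy) hold to 1e-8 relative, and the
subband relative energies sum to exactly 100 %.  Symmetric extension is
available by flag for users who prefer it; it trades the exact energy
identities for reduced wrap-around.

Subband energy is the sum of squared coefficients of a block; relative
energy is that energy as a percentage of the total over {D1..DL, A_L}.

Two level→frequency conventions are exposed deliberately.  `level_band`
implements the rule `[f_m/2, f_m]`, `f_m = fs/2^(j+1)`, which at
fs = 500 Hz labels D5 as 3.91–7.81 Hz (theta) and A5 as ≤ 3.91 Hz
(delta); `dyadic_band` gives the textbook mapping one octave higher
(D1 = [fs/4, fs/2]).  Reference tables printed under the first rule
sometimes give the coarsest approximation a nonzero lower edge
(e.g. "1.91–3.91 Hz"); a dyadic approximation in fact spans 0–f_hi, and
`level_band` reports `[0, f_hi]`.  The feature pipeline operates on
coefficients, not band labels, so this labelling ambiguity does not affect
features.  An `auto_levels` helper picks the depth whose approximation
band fits inside 0–4 Hz for users who want A_L to isolate delta exactly at
their sampling rate (6 levels at 500 Hz).

## Hybrid EMD–wavelet energy features

Per channel: EMD into up to 8 IMFs → per IMF a 5-level db4 DWT → the
**relative energy of the coarsest approximation A5** (percent of that
IMF's coefficient energy) is the feature.  8 channels × 8 IMFs = 64
percentages per segment, ordered channel-major then IMF-major
(`Fp1_imf1_Arel, Fp1_imf2_Arel, …`).  Channels yielding fewer than 8 IMFs
contribute 0 (no energy) for the missing slots, and an all-zero IMF
contributes 0 rather than raising the undefined-percentage error — so the
classifier never sees missing values.  Because every feature is a
percentage, rows are invariant to rescaling the input signal, and no
feature standardisation is needed downstream.

The rationale: EMD orders modes from high to low frequency, and taking
each mode's low-frequency (approximation) share measures how much of that
mode sits in the delta range — yielding many delta-sensitive features
instead of the one or two that plain EMD (IMF energies, 64 features) or
plain DWT (6 subband energies × 8 channels = 48 features) provide.  Both
plain variants are implemented as baselines behind the same interface.

## Classification

Weighted k-nearest neighbours: Euclidean distance
`d(x, y) = √Σ(x_i−y_i)²`, vote weight `1/d²`.  The default `k="all"` uses
every training point — the reading under which k needs no manual choice,
since 1/d² makes far points negligible — with an integer `k` override.
Exact matches (d = 0) are the singular limit of 1/d²: they share a total
weight of 1 and decide by majority among themselves.  Weight-sum ties fall
back to the single nearest neighbour's label, then to the
lexicographically smaller label with a warning.  Features are used
unstandardised by default (relative energies already share the 0–100
scale); z-scoring is available by flag for the raw-energy baselines.

Evaluation: confusion counts with high interest as the positive class;
accuracy, sensitivity and specificity in percent, reported to 1 decimal.
Validation defaults to leave-one-out (deterministic, the natural choice at
n ≈ 20 subjects); seeded stratified k-fold is available.

A note on the null behaviour: under leave-one-out with a balanced table
and *no* class signal, the held-out sample's own class is always one
training example short, so wkNN is biased toward the opposite class and
null accuracy sits at or below chance (not exactly 50 %).  This is a known
property of LOO with prior-sensitive classifiers, visible in the
chance-level tests.

## Synthetic data

The generator emulates the statistical structure of classroom EEG that the
pipeline is designed to detect.  Each channel is a sum over rhythm bands
of band-limited Gaussian noise (white noise through the package's own FIR
band-pass, scaled to a per-band RMS target), plus eye-blink transients,
50 Hz mains and white sensor noise.  Defaults (the study conditions):
fs = 500 Hz, 8-channel 10–20 montage, 154 s segments; band RMS
delta 20, theta 10, alpha 15, beta 8, gamma 4 µV (a plausible eyes-open
resting profile with posterior-dominant alpha de-emphasised for a task
state); blinks at 10/min, 100 µV, bi-exponential pulses (50 ms rise,
300 ms decay) at Poisson times on Fp1/Fp2 only; 5 µV mains; 5 µV white
noise.  The class contrast is `delta_effect` (default 3): the low-interest
class carries that multiple of the delta amplitude on the four frontal
channels, emulating the stronger frontal delta increase observed in
unengaged students.

Seeding: a master `SeedSequence` is spawned per segment, so segments have
independent streams and the whole dataset is bit-reproducible from
`(spec, seed)`.

Not emulated: volume conduction and inter-channel correlation, 1/f
background, nonstationarity, inter-subject variability, and group-level
synchrony.  Passing tests on these data demonstrate that the
implementation recovers a frontal-delta class contrast it is pointed at;
they say nothing about classification accuracy on real classrooms.

## Problem sizes in the test suite

Unit tests run on short signals (2–30 s at 250 Hz).  The end-to-end
recovery tests use full-length study conditions — 154 s, 500 Hz,
8 channels — with 15 segments per class for the contrast arm
(delta_effect = 3) and 20 per class for the null arm (delta_effect = 1);
the chance band for the null is assessed on 40 leave-one-out predictions.
The EMD reconstruction and IMF-condition guarantees are checked on 100
random 512-sample signals; DWT identities on 20 random 1024-sample
signals; the wkNN implementation is checked against an exhaustive
brute-force re-implementation on 200 random 5-point training sets.

## Interest labels

Questionnaire scores (0–100) map to classes: > 77 high, < 69 low, the
closed band [69, 77] moderate.  Printed threshold descriptions leave 77
itself and non-integer scores in (76, 77) unassigned; the closed moderate
band makes the mapping total while changing no assigned score, erring
toward excluding borderline subjects.  Moderate subjects are excluded from
classification.
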