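# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The classification problem

Each heartbeat of a 12-lead ECG is assigned to one of ten classes: eight
myocardial-infarction localizations (A, AS, AL, I, IL, IP, IPL, P),
healthy (H), or other cardiac disease (O). The signs used are the ones
cardiologists read — ST-segment shift at the J point, abnormal Q waves,
and T-wave morphology — quantified per lead relative to the beat's own
baseline (the QRS-onset "I point"), plus a dense "ventricular activity"
vector covering the whole QT span. Localization information comes
entirely from *which leads* carry the abnormal values; no single-lead
feature can separate, say, anterior from inferior infarcts.

## Preprocessing

Per lead: multilevel DWT (db6, symmetric extension), depth
`min(9, ceil(log2(fs / 0.7)))` so the coarsest approximation holds only
sub-≈0.7–1 Hz content (at 1 kHz the capped depth of 9 gives a 0.98 Hz
approximation band). That approximation — baseline drift, and the
signal's DC with it — is zeroed. The two finest detail bands are
soft-thresholded with the universal threshold σ√(2 ln n), σ estimated
from the median absolute deviation of the finest band. Only the two
finest bands are touched so QRS morphology, which the rule features
depend on, passes through; a Welch-spectrum test asserts the 5–15 Hz
band survives within 10% on clean input. The basis and depth are free
choices exposed as parameters; nothing downstream assumes them.

## Delineation

R peaks: Mexican-hat CWT at scales corresponding to 5, 8, 11 and 15 Hz;
the per-sample product of coefficient magnitudes across scales sharpens
QRS events and suppresses anything not present at all scales. The
product is compared against 0.4× its rolling 2 s RMS (a relative
threshold — detection is invariant to amplitude scaling), local maxima
at least 200 ms apart are kept, and each is re-centred on the raw
signal's largest excursion within ±15 ms. The narrow re-centring window
matters: the product peak is already R-centred, and a wider window can
drift to a deep pathological Q.

Q/S: nearest local extremum of polarity opposite to R within 80 ms of
R, with a prominence floor of 2% of the R excursion so residual noise
ripples on the QRS flanks are not mistaken for the trough. QRS
onset/end: moving outward from the steepest point of the outer Q/S
flank, the first sample where |slope| falls below 10% of the maximum
QRS slope (capped at 50% of that flank's own peak slope, so broad
gentle waves — e.g. wide-QRS "other disease" beats — terminate at their
foot), searched at most 60 ms beyond Q/S; the 60 ms reach matters for
wide pathological Q waves, whose foot lies beyond 40 ms and whose tail
would otherwise bias the baseline read at the I point (and with it the
measured ST elevation) by ~0.05 mV. T wave: search window
[J + 80 ms, J + 0.6·RR]; T peak is the largest excursion relative to a
baseline estimated as the median of the last 30% of the window — past
the T end for physiologic RR, so it is immune both to Q-tail
contamination at the I point and to being pulled toward an elevated ST
plateau (a single-sample or whole-window baseline makes inverted-T or
post-plateau points win the excursion contest in edge cases). T
onset/end by a 40% slope-fraction rule anchored at the first
slope-magnitude peak adjacent to the T apex (anchoring at the
window-wide maximum can latch onto the next beat's P upstroke).

All constants live in `DelineatorConfig`. None are clinical claims;
each is validated against the generator's closed-form truth: on 200
noiseless beats spanning all ten archetypes, R/Q/J are recovered within
20 ms and T onset/end within 40 ms. Leads are delineated independently
and beats matched across leads by nearest R within 150 ms; beats
missing any lead are dropped whole (purity over yield — at default
settings roughly 5–10% of beats are dropped, mostly at record
boundaries).

## Features

The seven rule features are exact arithmetic on fiducial amplitudes and
positions (see README table). Two invariances are asserted in tests:
adding a constant to a lead changes nothing (every feature is a
difference or ratio of differences), and scaling a lead scales the four
mV-valued features while leaving the two ratios and the interval fixed.

The QT span [I point, T end] is resampled to exactly 1000 samples by
linear interpolation on a uniform grid including both endpoints.
Interpolation was chosen over zero-padding because the vector feeds a
wavelet compression: padding would inject an artificial step edge.

## Compression (1000 → 32 per lead)

* **DWT** (default): the vector is linearly resampled to 1024 points and
  decomposed five levels with db4 under periodization, making the
  level-5 approximation exactly 1024/2⁵ = 32 coefficients. Resampling +
  periodization is the one combination that honours "five levels of
  db4" and "exactly 32 outputs" simultaneously; detail coefficients are
  discarded because the approximation is the smooth, waveform-shaped
  part. Training-free and deterministic.
* **PCA**: top-32 right singular vectors of the centred training matrix.
* **LPP**: k-NN graph (k = 7) with heat-kernel weights
  exp(−‖xᵢ−xⱼ‖²/t), t defaulting to the mean squared neighbour
  distance; directions solve XᵀLX a = λ(XᵀDX + 10⁻⁸ I) a for the
  smallest eigenvalues, after a PCA pre-reduction to the data rank for
  conditioning.

Trainable compressors are fitted per lead and, during cross-validation,
inside each training fold only (a global-fit option exists for
replicating protocols that fitted once). Compression is per lead rather
than on the concatenated 12 000-vector so the fused width is
12 × (7 + 32) = 468.

## The booster

Newton boosting of regression trees on the softmax cross-entropy:
per round, gradients g = p − 1{class} and Hessians h = p(1−p) per class;
one tree per class per round with exact greedy split finding over
sorted feature values. Leaf weight w* = −G/(H+λ); split gain
½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ, accepted only if
positive; ties break toward the lowest feature index, then the lowest
threshold, making training fully deterministic given the column-
subsampling seed. Defaults (200 rounds, depth 6, learning rate 0.1,
λ = 1, γ = 0, column subsample 0.8) mirror common boosted-tree defaults
so the independent-library comparison in the test suite is meaningful.
Missing values are not supported — the feature stage never emits them.

Implementation notes: per-fit feature-major presorting shared by all
trees; children inherit the parent's sort order by stable filtering, so
each level costs O(n·d) with no re-sorting. The split scan is compared
against exhaustive enumeration on small tables (property-based) and the
end classifier against an external boosted-tree library on matched
hyperparameters.

## Evaluation

Confusion matrices use a fixed class order (A, AS, AL, I, IL, IP, IPL,
P, H, O). Per-class Se/Sp/+p/Acc are one-vs-rest percentages at full
precision; a zero-denominator metric is reported as NaN, never as 0.
Cross-validation is stratified at beat level (k = 10 by default) with
all fitting inside training folds; pooled-matrix metrics over held-out
predictions are primary, per-fold accuracies and their mean are also
reported. Beat-level folds match the protocol the pipeline emulates;
with real per-patient data they are optimistic, since beats of one
patient can appear on both sides of a split — patient-grouped folds are
the appropriate protocol there.

## The synthetic generator

Each beat is five Gaussian bumps (P, Q, R, S, T) plus an ST plateau with
raised-cosine edges; the plateau holds its full height from the J point
to T end (rise completes exactly at J, fall starts at T end), so the
J-point elevation equals the configured `st_offset` and recovery can be
asserted to ±0.05 mV. True fiducials are closed-form: QRS onset at
Q − 2σ_Q, J at S + 2σ_S, T onset/end at T ∓ 2σ_T. Timing jitter (±5–8%)
is shared across leads of a beat; amplitudes jitter ±10%.

Archetype magnitudes (normal Q −0.10 mV/σ 10 ms; abnormal Q −0.45 mV/
σ 20 ms; ST elevation +0.25 mV, or +0.15 mV when paired with an
inverted T so the T excursion still dominates the search window;
depression −0.20 mV; tall T 0.55 mV; inverted T −0.40 to −0.50 mV) are
plausibility choices, not measurements. Classes differ by which leads
carry which archetype, following the standard clinical groupings
(anterior → V1–V4, inferior → II/III/aVF, posterior → reciprocal
V1–V3 depression with tall R, and so on); the exact assignment is a
documented constant in `synthetic.LEAD_PATTERNS`.

What the generator does *not* emulate: P-wave variability, arrhythmia,
conduction blocks beyond a token wide-QRS "other" class, electrode
motion artifacts, inter-patient morphology correlation, or the
within-class heterogeneity of real infarcts. Passing the end-to-end
test therefore shows the pipeline's plumbing, feature arithmetic and
classifier are correct and that the intended signs are recoverable from
clean-ish signals — it is not evidence of clinical-grade accuracy on
real recordings.

## Problem sizes and study configuration

The bundled end-to-end study uses 2000 beats (200 per class, 20-beat
single-class records), 500 Hz, noise SD 0.02 mV, 0.1 mV baseline
wander, and the DWT compression backend; the booster runs 12 rounds at
depth 4, learning rate 0.3 (training log-loss is below 0.01 by round 8
on this data, so longer schedules only add runtime). Class defaults
remain the conservative 200×depth-6×0.1 schedule. The study seed drives
record generation, fold shuffling and column subsampling alike.

Records are 20 beats (16 s) rather than shorter because the denoiser's
decomposition depth — and with it the width of the zeroed drift band —
is capped by record length: at 8 s the band reaches ≈1 Hz and visibly
flattens the ST plateau (it subtracts the plateau's own low-frequency
lobe and leaves a spurious negative ledge after the T wave); at 16 s
the band is ≈0.5 Hz and the distortion halves. Short records remain
usable but carry more low-frequency feature bias.

## Known limitations

* The delineator assumes a dominant upright R in the analysed lead (the
  generator produces one); strongly negative-R leads rely on the
  polarity estimate from the local median.
* QT spans that collide with the next beat are dropped rather than
  truncated.
* WFDB support covers single-segment format-16 records (the PTB
  layout), not the full format zoo.
* Per-class morphology parameters are stylized; see the generator
  section above for the fidelity boundary.
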