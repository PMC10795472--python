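# Methods

`poreptm` analyses single-channel ionic-current recordings of an aerolysin
(K238A) nanopore sensing C-terminal α-synuclein peptides and their
post-translationally modified (PTM) variants. This note documents the models,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Signal model and event detection

A recording is a uniformly sampled current trace (pA). The open-pore baseline
is modelled as Gaussian with mean I₀ and SD σ₀ (defaults 72 ± 1.5 pA at
+100 mV in 1 M KCl, 10 kHz sampling). `fit_open_pore` histograms the trace
with Freedman–Diaconis bins, locates the local maximum with the highest mean
current — the open-pore mode, never a blockade mode — and fits a Gaussian to
the bin counts in a window of ±3σ̂ around it, where σ̂ is first estimated
from the peak's full width at half maximum. The FWHM-derived window is a
deliberate choice: a window of a few bins around the mode spans only a small
fraction of the peak and makes the fitted σ₀ unstable, while the ±3σ̂ window
uses the whole peak and recovers σ₀ of a 10⁵-sample baseline to better than
±0.05 pA. A constant trace is handled exactly (σ₀ = 0); a flat histogram is
an error.

Blockade events are maximal runs of samples below I₀ − kσ₀ (k = 3). Indexing
is half-open and 0-based; the dwell counts sub-threshold samples only, and
events touching either trace boundary are discarded because their dwell
cannot be measured. Per event we compute the dwell time (ms), the mean
residual current I, the relative current 100·I/I₀ (%), and the relative
noise σ/σ₀ (undefined, not infinite, when σ₀ = 0). Events are then filtered
to dwell 0.2–100.0 ms and relative current 0–40 %, boundaries inclusive —
discarding events too short, too long, or too shallow. At 10 kHz the 0.2 ms
lower bound also removes essentially all false events from baseline noise
(isolated 3σ crossings are one sample long).

## Local extrema

The classifier input is the sequence of turning points of the event's
samples. After collapsing plateaus (runs of equal values become one point at
the run midpoint), a hysteresis walk commits an extremum only once the signal
has reversed away from it by more than a prominence threshold δ; the first
and last points are never emitted. The resulting sequence strictly alternates
minima and maxima and every adjacent pair differs by more than δ. The
threshold defaults to 1·σ₀, suppressing pure-noise turning points while
keeping genuine level structure; it is exposed as configuration because no
de-noising rule is prescribed for the raw traces. Each extremum is emitted as
(time within event in s, relative current in %).

## Population fits

Two-level peptides (wt, nY136) show two relative-current populations; these
are summarized by a K-component Gaussian mixture (`fit_population_gaussians`,
EM with k-means++ initialization, 10 restarts, tolerance 10⁻⁸, seeded). K is
restricted to 1–3; the degenerate all-identical sample is handled exactly for
K = 1. On 10⁴ draws from 0.5·N(9.0, 2.0) + 0.5·N(17.1, 2.0) — the wt PI/PII
parameters — the component means are recovered within ±0.2.

## Classifier and assessor

Two networks read each event's rescaled extrema sequence:

* **classifier** — LSTM, state size 128, with no activation function on the
  state readout, followed by 6 fully connected hidden layers of width 256
  (ReLU) and a softmax output over the classes;
* **assessor** — a scaled-down reader (LSTM state 32, 3 hidden layers of
  width 64, tanh) with a single sigmoid output predicting whether the
  classifier's prediction is correct.

Features are rescaled by fixed factors f_t = 10³ (seconds → millisecond
scale) and f_c = 10⁻² (percent → unit scale) to speed up training. Events
with no extrema contribute a single sentinel pair (0, relative current), so
amplitude information is never lost; sequences longer than `max_len` keep
their head and are flagged. Variable lengths are handled by padding with a
mask that freezes the recurrent state, so predictions are invariant to the
padding length.

Both networks are trained **jointly** on a 3-part loss:
L = L_cls + L_assess + L_reinforce, with

* L_cls — classification cross-entropy (−log p_true, mean over the batch);
* L_assess — binary cross-entropy between the assessment score a and the
  prediction validity v (v = 1 iff the classifier's current argmax equals the
  label, recomputed each step);
* L_reinforce — the classification cross-entropy scaled per event by a.

By default the reinforcement term treats a as a constant scale (no gradient
flows to the assessor through it); `reinforce_through_assessor` enables the
alternative. The constant-scale default keeps the assessor's supervision
purely the validity signal, which makes its score interpretable as a
confidence.

Optimization is Adam with global-norm gradient clipping (5.0). The defaults
(lr 10⁻³, batch 256, ≤50 epochs, early stopping on validation total loss
with patience 10) suit datasets of ~10⁴⁺ events. **Small-data regime:** with
only a few thousand events, batch 256 yields so few optimizer steps per epoch
that the jointly trained pair oscillates — the classifier's accuracy swings
between epochs, the validity labels flip, and the assessor ends up tracking a
stale classifier (its score can even become anti-correlated with
correctness). The reduced-scale benchmark runs therefore use batch 32 and
lr 3·10⁻⁴ for ~30 epochs, which converges stably. All runs are seeded and
bit-reproducible.

Events are split chronologically — the first (in time) 75 % train, the last
25 % validate — never randomly, so that slow drifts in recording conditions
cannot leak across the split.

## Selection, evaluation, mixtures

A requested selection percentage p keeps the ⌈p/100·N⌉ events with the
highest assessment scores (stable ties), i.e. the percentage is translated
into a score threshold computed on the evaluation set itself. Accuracy versus
selection curves are averaged over independent simulate+train repeats
(default 5 seeds, grid {100, 75, 50, 25} %). Confusion matrices put actual
classes in columns and assigned classes in rows, normalized so each column
sums to 100 %. Mixture experiments follow the holdout protocol: the model is
trained on pure-class data only and applied to a simulated mixture;
assignment percentages are reported relative to all events, with a separate
unassigned bucket when p < 100 so totals are always 100 %.

## Quantification

The blockade frequency f_sig (events/s, counted after the standard filters)
is proportional to the analyte concentration: f_sig = k_on·[analyte]₀.
`fit_capture_rate` fits the slope by least squares **through the origin**
(the law has no intercept); a free-intercept fit is reported as a diagnostic
only. The slope SE comes from the residuals with n−1 degrees of freedom, and
`estimate_concentration` inverts the law with first-order error propagation.
Note that at high capture rates the realized event rate falls slightly below
nominal (pore occupancy; see below), which cancels in the inversion when the
calibration and the measurement share the pipeline.

## Synthetic recordings

The simulator is the canonical input source (no experimental recordings are
distributed): Gaussian baseline, Poisson event arrivals, per-class events
with one or two residual-current levels and log-normal dwell times. Defaults
are the measured study conditions — 72 ± 1.5 pA baseline, 10 kHz sampling —
and the per-peptide signatures use the published statistics: wt is two-level
with relative currents 9.0 ± 2.0 (PI, first in time) and 17.1 ± 2.0 (PII,
the higher residual current at the last fraction), fitted dwell times
2.58 ms (wt), 0.55 (pY125), 4.51 (nY125), 3.62 (pS129), 0.45 (pY125pS129),
5.18 (nY125nY133nY136), and the triple-nitrated peptide has the lowest
relative current of all, 7.2 ± 1.0.

Choices where the measurements are silent:

* **Dwell law** — log-normal (strictly positive, heavy right tail, the shape
  of typical nanopore dwell histograms), parameterized so the published
  fitted dwell is the median; log-scale SD 0.5 (≈ ×1.65 spread), a realistic
  breadth for single-peptide dwell distributions.
* **Level means without published values** (pY125, nY125, pS129, nY136,
  pY125pS129, nY125pS129) — placeholders respecting the published qualitative
  ordering (single level; all above 7.2; nY136 two-level like wt; nY125pS129
  between nY125 and pS129), flagged `placeholder=True` and overridable via
  `ClassSignature.with_levels`.
* **Within-event noise** — SD defaults to σ₀.
* **Two-level split** — PI then PII in time, 50/50 by default, configurable.
* **Arrivals** — Poisson; an arrival during an occupied window (event plus a
  10-sample guard gap) is rejected, keeping annotations unambiguous and
  non-overlapping. The realized event rate is therefore ~1–4 % below nominal
  at default occupancy — visible as a capture-rate recovery ratio relative to
  the annotated rate of 1.00 while the nominal-rate recovery is ~0.99.
* **Low-pass filter** — optional first-order smoothing after event
  insertion, disabled by default so ground truth stays exact.

What passing on these synthetics shows — and does not. The simulator
reproduces the *event statistics* (amplitudes, dwell laws, arrival process)
but not the within-event waveform physics: real two-level transitions,
bandwidth-limited rise times, 1/f noise, or baseline drift. Pipeline
correctness (detection equivalence, feature recovery, loss/selection
mechanics, quantification) transfers directly to real data; the specific
classification accuracies measured here do not — they reflect the synthetic
class geometry, not the experimental separability (the published experimental
accuracies, e.g. 94 % for 3 classes at 50 % selection, were obtained on
~5·10⁵ real events and are not reproducible without those recordings).

## Benchmark scales

Test and acceptance runs are sized for a desktop CPU: 2-class recovery uses
2000 events/class, the 8-class selection benchmark 2400 events over 5
simulate+train seeds, mixtures 2000+ events per repeat, detection equivalence
50 traces of 10⁵ samples, and calibration 4 concentrations spanning two
orders of magnitude at 300 s each. The 8-class benchmark overrides the class
levels with a distinct grid (means 6–34 %, SD 2 %, ~2σ neighbour separation)
so that the task is learnable yet leaves the assessor a real
coverage/accuracy trade-off to exploit.

## Known limitations

* Multi-level step segmentation (CUSUM/HMM level finding) is out of scope —
  the classifier consumes extrema, not fitted levels.
* Vendor acquisition formats (ABF, Nanion) are not parsed; traces enter as
  CSV/NumPy/HDF5.
* No k_on value is published for these peptides; calibration constants must
  come from user data or simulation.
* The assessor's usefulness degrades if training is stopped while the
  classifier is still moving (see the small-data regime above).
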