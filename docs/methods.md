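# Methods

This note documents the model implemented by `emgseq`, the synthetic data
it is validated on, and the numerical and design choices that were
genuinely open.

## Signal model and acquisition conventions

The package operates on *envelopes*: rectified, low-pass-filtered EMG
amplitudes as produced directly by commercial sensors (non-negative,
slowly varying, 0–5 V). Conventions throughout: time in milliseconds from
acquisition start, 0-based sample indexing, half-open windows
`[start, end)`, 1 kHz sampling, 4 s acquisitions with at least 500 ms of
initial rest. Voltages are persisted with 6 decimal digits, below the
sensor noise floor.

## Onset detection

`TH_Low = μ + xσ` with μ, σ estimated from the first 500 ms of every
acquisition, **pooled over all six channels and all acquisitions of a
dataset**. Pooling is a deliberate choice: the rest-noise level is a
property of the sensor/skin interface and is treated as homogeneous across
channels; a per-channel variant would add six nuisance parameters without
changing any downstream contract. σ uses the sample estimator (ddof = 1).

A crossing counts only if the envelope exceeds `TH_Low` on every sample of
a 50 ms window; the SoA is reported at the *first* sample of that window,
so the 300 ms transient window starts at the earliest evidence of
activation. The SoA is per-acquisition (minimum over channels). Channels
with no sustained crossing anywhere in the acquisition are Not Active.

The multiplier is tuned over x ∈ {2, 5, 10, 15}: the false-activation rate
of a candidate is the fraction of acquisitions with a sustained crossing
starting inside the first 100 ms (rest by protocol), and the smallest
candidate with a rate below 5% is selected. Because a crossing at larger x
implies one at smaller x, rates are non-increasing in x by construction.

## TH_High ladders and the representative-vector search

Per task, the starting candidate per channel is 80% of the envelope peak in
`[SoA, SoA + 300 ms)`, averaged over the task's acquisitions; acquisitions
in which the channel is Not Active do not enter the average (their
per-acquisition value would be the sentinel), and a channel active in no
acquisition receives the sentinel `NA_VALUE = 10 V`, which no envelope can
reach — NA handling therefore needs no special cases anywhere downstream:
a sentinel threshold simply never crosses.

"Decreased by 10% at each iteration" is implemented multiplicatively
(×0.9 per step). This is the only reading under which the 50%-of-peak
floor admits exactly five steps (80, 72, 64.8, 58.32, 52.49, then
47.2 < 50) and it reproduces the printed candidate set 80/72/64.8% of the
peak for three steps. Ladder entries at or below `TH_Low` become the
sentinel. `n_steps` outside 2..5 is rejected.

The search enumerates one candidate per channel — `n_steps^6` combinations
for full ladders; channels whose ladder is entirely the sentinel collapse
to a single entry, so the count is `n_steps^(#non-NA channels)`. For each
combination every acquisition is encoded (see below) and the combination
whose modal sequence has the highest count wins. The enumeration scans
each ladder from highest to lowest candidate, and ties keep the first
(i.e. most conservative, highest-threshold) maximizer; within a
combination, a tie between two equally frequent sequences resolves by
numeric sequence code, which is arbitrary but deterministic. The
implementation vectorizes the enumeration (precomputed first-crossing
indices per candidate, stable argsort over channels); a naive pure-Python
re-enumeration serves as an independent oracle in the tests.

`TH_High` crossings use the instantaneous first sample above threshold,
with no sustain window: the sustain rule guards the low threshold only.
The modal sequence is computed over full length-6 sequences; truncation to
three elements happens downstream in the feature refinement.

## Sequence encoding and features

A sequence ranks channels by first `TH_High` crossing inside the 300 ms
window; entries are channel numbers 1–6, channels that never cross encode
0 and occupy only trailing positions. Simultaneous crossings (same sample)
tie-break by lower channel number. Lowering one channel's threshold can
only move that channel earlier — a monotonicity property the tests check.

The classification feature encodes each acquisition under all four tasks'
representative vectors in the fixed order (Spherical, Tip, Platform,
Point), keeps each sequence's first three entries, and concatenates them
into 12 integers in 0..6. Integer codes are fed to the classifiers
directly; a one-hot expansion (12 × 7 indicators) is available via the
`one_hot` hyperparameter but is off by default, since the default
experiments show no need for it. Acquisitions without a detected SoA are
routed to "Rest" upstream and never reach the four-class classifier.

## Classifiers

* **NLR** — one-vs-all logistic regression on interaction-expanded
  features (the original entries plus all pairwise products of distinct
  entries: 12 → 78), argmax of class probabilities (0.5 threshold in the
  binary case), features standardized.
* **SVM** — RBF kernel by default. The method description names a linear
  kernel in one place and RBF in another; the more specific later
  statement wins, and `kernel="linear"` remains available.
* **ANN** — multilayer perceptron, logistic activations, 1–5 hidden layers
  of equal width (default 20); the depth is selected by seeded stratified
  5-fold validation on the training split (folds capped by the smallest
  class when data are scarce).
* **LDA** — one-vs-all linear discriminants; degenerate class covariance
  triggers a shrinkage refit and is noted in the model metadata.

The split is stratified per task with `|train| = round(0.8 n)` under a
seeded permutation; all training is deterministic given the seed.

## Baselines and evaluation

* **ETS**: per-channel envelope bin means over the 300 ms transient window.
  The default 10 ms bins give 180 features (down from 1800 raw samples),
  chosen for classifier conditioning at 160 training rows; `bin_ms = 1`
  recovers the literal raw-sample reading.
* **ESS**: the steady-state anchor is the global maximum sample over all
  channels (earliest instant, lowest channel on ties); features are the
  six per-channel MAVs over 100 ms from the anchor. One window per
  acquisition is used; emitting multiple strided windows would mix
  non-independent rows into the training set.
* **Timing comparison**: `t_seq` = latency of the last (≤ 3rd) activation
  of the partial sequence; `t_ess` = anchor latency; both from the SoA.
* **Method comparison**: Shapiro–Wilk on the paired accuracy differences
  (α = 0.05) routes to a paired t-test (normal) or a two-sided
  Mann–Whitney U-test (otherwise). The U-test is applied unpaired, in its
  conventional named form, although the inputs are paired per dataset;
  zero-variance differences short-circuit (p = 1 for identical vectors).
* **Online simulation**: each trial is scanned for its SoA; every
  `TH_High` crossing under any task vector is an event. A classification
  fires at each event once some task vector has accumulated three
  crossings, and once more at the end of the 300 ms window (so two-channel
  gestures are still decided); the first correct output completes the
  trial, MST is measured from the ground-truth movement onset, and trials
  with no correct output before the recording ends fail. The event-driven
  cadence and the timeout rule are design choices; a fixed-clock loop
  would only quantize the same decisions.

## Synthetic data generator

The generator emulates the acquisition protocol: 6 channels, 1 kHz, 4 s,
≥ 500 ms rest, 50 repetitions per gesture, 4 gestures plus Rest, with
movement onset drawn uniformly in [500, 700] ms so the SoA varies across
repetitions.

* **Rest noise** is stationary AR(1) (first-order low-passed white noise)
  with mean 0.012 V and sd 0.0007 V, the average printed rest statistics
  of the sensor setup, clipped at 0 V. The correlation time defaults to
  100 ms, on the smoothing scale of a commercial envelope sensor. This
  matters: with correlated noise, sustained 50 ms excursions above
  μ + 2σ occur at a low but nonzero rate, so the x-tuning experiment shows
  a genuinely decreasing false-activation profile; with near-white noise
  every rate would be identically zero and the tuning step would be
  vacuous.
* **Activations** rise logistically (10→90% over `rise_time`, default
  70 ms), shifted and rescaled to be exactly zero at the channel's onset.
  Plateau amplitudes (0.8–1.8 V by gesture/channel) carry a
  per-acquisition scale jitter and a slow multiplicative temporal jitter
  (cv 0.05), plus a sinusoidal "effort overshoot" bump peaking at +20% at
  mid-plateau. The bump models the common mid-contraction effort peak and
  guarantees, by construction, that the global envelope maximum (the ESS
  anchor) falls long after the third activation and at least 100 ms before
  the recording ends — so the sequence decision precedes the steady-state
  anchor in every acquisition, and the MAV window always fits.
* **Gesture profiles**: distinct activation orders with delays ~30/105/190
  ms for the first three channels (jitter sd 10 ms, far from order-swap
  range), "Point" recruiting two channels and "Spherical" five (the last
  two outside the transient window). Envelope amplitudes and rise times
  per task are not published anywhere; defaults are chosen for class
  separability, not fidelity to any subject.

**What passing tests show — and what they do not.** The synthetic study
has cleanly separated activation orders, stationary Gaussian-derived
noise, and no electrode shift, limb-position effect, fatigue or
co-contraction variability. Perfect or near-perfect held-out accuracy on
it validates the *implementation* (thresholding, search, encoding,
training are correct and internally consistent) and the qualitative claims
(transient decisions precede the steady state; sequences are repeatable
under the right thresholds). It does not predict accuracy on recorded
human data, where published results for this family of methods are in the
~85–95% range.

## Problem sizes

Default experiment sizes were picked so the full validation suite runs in
well under a minute of compute per subject: the end-to-end study uses 10
simulated subjects × 200 acquisitions at `#step = 4` (4096 combinations ×
40 training acquisitions per task, vectorized), and the false-activation
experiment uses 200 rest acquisitions.

## Known limitations

* The generator produces envelopes only; raw EMG, motor-unit dynamics and
  electrode artifacts are out of scope.
* `x` selection on synthetic data typically picks the smallest candidate
  (rates fall to zero quickly under Gaussian tails); the default x = 15 is
  kept as the operating point for threshold computation.
* The ANN depth search refits up to 25 MLPs and is the slowest path;
  depth can be pinned via `hyperparams={"hidden_layers": k}`.
* `compare_methods` inherits the named tests' assumptions; with fewer than
  ~5 datasets the normality gate is essentially uninformative.
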