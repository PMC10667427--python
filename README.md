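# emgseq

Hand-gesture classification from the **transient state** of surface EMG
envelopes, using **muscular activation sequences** as time-domain features.

Myoelectric prosthesis control usually classifies gestures from features of
the EMG steady state, which forces the controller to wait until the signal
flattens. `emgseq` implements an alternative: during a voluntary
contraction the forearm muscles recruit in a task-specific *order*, and
that order — read from six envelope channels during the first 300 ms after
onset — is itself a compact, amplitude-robust classification feature. The
package targets researchers in myoelectric pattern recognition who want a
fully testable, self-contained implementation of the approach, including a
synthetic envelope generator with ground truth so that every stage can be
validated without access to recorded subjects.

## Method

Six envelope channels (0–5 V, 1 kHz) are acquired for 4 s per repetition,
starting from ≥ 500 ms of rest. The pipeline is:

1. **Onset (double threshold).** A dataset-level low threshold
   `TH_Low = μ + xσ` is computed from the pooled rest-phase mean and
   standard deviation; a channel crosses only if it exceeds `TH_Low`
   throughout a 50 ms window. The Start of Activation (SoA) is the earliest
   sustained crossing; channels that never cross are flagged Not Active
   (NA). The multiplier `x` is tuned so that the false-activation rate —
   sustained crossings inside the first 100 ms of rest — stays below 5%
   (`x = 15` with the default noise statistics).
2. **High thresholds (`TH_High`).** Per task and channel, the starting
   candidate is 80% of the envelope peak within 300 ms of the SoA, averaged
   over acquisitions; candidates decrease multiplicatively by 10% per step
   while above 50% of the peak (so at most 5 steps: 80, 72, 64.8, 58.3,
   52.5%) and above `TH_Low`. NA channels get a sentinel above full scale.
3. **Representative-vector search.** All `#step^6` threshold combinations
   are enumerated; each acquisition is encoded as the sequence of channel
   numbers ordered by `TH_High` crossing time (trailing zeros for channels
   that never cross). The combination whose modal sequence is most repeated
   becomes the task's representative `TH_High` vector (a 4 × 6 matrix over
   tasks).
4. **Feature refinement.** Each acquisition is encoded under all four task
   vectors; the first three elements of each sequence are concatenated into
   a 1 × 12 integer feature.
5. **Classification.** NLR (one-vs-all logistic regression with pairwise
   interaction terms), SVM (RBF), MLP-ANN (logistic activations, 1–5 equal
   hidden layers) and one-vs-all LDA, trained on a stratified 80/20 split.
6. **Baselines & evaluation.** ETS (binned transient envelope) and ESS
   (steady-state MAV at the first absolute envelope peak) feature sets;
   normality-gated method comparison (Shapiro–Wilk routing to paired t-test
   or Mann–Whitney U); online simulation reporting the motion completion
   rate (MCR) and motion selection time (MST, movement onset to first
   correct classification).

## Worked example

```python
import emgseq as E

recs = E.generate_dataset(E.default_profiles(), E.default_noise(),
                          reps_per_gesture=50, seed=7, subject_id="S1")
res = E.SequenceClassifier(recs, n_steps=4, classifier="nlr").fit(seed=0)
print(res.summary())
```

prints

```
Muscular activation sequence classifier
=======================================================
recordings: 200   usable gesture acquisitions: 200   dropped (no SoA): 0
rest: mu = 0.0120 V, sigma = 0.00070 V, x = 15 -> TH_Low = 0.0225 V
features: sequence12   #step = 4   classifier: NLR   seed = 0
split: 160 train / 40 test (fraction 0.8, stratified by task)

Representative TH_High matrix (V):
             emg1    emg2    emg3    emg4   emg5    emg6
Spherical  1.1829      NA      NA  1.5714     NA  0.9159
Tip            NA  0.9518  0.8312      NA  1.382      NA
Platform   1.4103      NA  1.1149      NA     NA  1.1735
Point      0.9317      NA  1.2139      NA     NA      NA

Modal sequences (train):
   Spherical: (4, 1, 6, 0, 0, 0)  (count 40)
         Tip: (2, 5, 3, 0, 0, 0)  (count 40)
    Platform: (6, 3, 1, 0, 0, 0)  (count 40)
       Point: (3, 1, 0, 0, 0, 0)  (count 40)

train accuracy: 100.0%   held-out accuracy: 100.0%
per-class held-out accuracy: Platform: 100%, Point: 100%, Spherical: 100%, Tip: 100%
```

The rest statistics recover the generator's noise model (0.012 V mean,
0.0007 V sd), so `TH_Low = 0.012 + 15 × 0.0007 = 0.0225 V`. Each gesture's
modal sequence is its ground-truth activation order (e.g. channel 4, then
1, then 6 for "Spherical"; trailing zeros are channels that stay quiet),
repeated in all 40 training acquisitions, and the 12-element features
separate the four gestures perfectly on the held-out 20%. Continuing,

```python
tc = res.timing_comparisons()                     # sequence vs steady state
onl = res.simulate_online(E.make_trial_stream(
    E.default_profiles(), E.default_noise(), attempts_per_task=5, seed=99))
```

shows the sequence decision preceding the steady-state anchor by 1523 ms on
average (minimum 507 ms) and an online run completing 100% of motions with
mean selection times of 248–309 ms per task.

A command-line interface mirrors the library:
`emgseq simulate | onset | thresholds | train | evaluate | compare`
(see `emgseq --help`).

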