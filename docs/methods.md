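# Methods

## Problem setting

`emgfusion` implements and evaluates a pipeline for recognizing seven hand
gestures (rest, fist, index pinch, wrist flexion, wrist extension, fingers
opening, thumbs up) from 4-channel surface EMG recorded from the paretic
arm of subacute stroke patients. The scientific question it operationalizes
is whether *bilateral data fusion* — adding the same patients' non-paretic
arm recordings to the training set, while always testing on paretic
recordings of held-out patients — improves subject-wise generalization when
labelled paretic data is scarce.

Because the underlying clinical recordings are private, the package ships a
synthetic cohort simulator that emulates the acquisition setup and the
statistical structure of paired paretic / non-paretic recordings. All
claims validated by the test suite are claims about the pipeline and about
this simulator, not about clinical EMG (see *What the simulator does and
does not capture*).

## Cohort model

The cohort table (packaged as `data/table1_cohort.csv`) records 25
patients: 19 measured once (session `single`) and 6 measured twice
(sessions `A` and `B`, at least ten days apart). Longitudinal dataset A is
all `single` records plus the `A` measurements; dataset B substitutes the
`B` measurements, so each dataset contains every patient exactly once.
Validation enforces adult age, Fugl-Meyer upper-extremity (FMA-UE) scores
in 0–66 and positive onset days; exact duplicate rows are collapsed with a
warning (the transcription source prints one row twice).

The printed aggregate "median 16.0 ± 8.6 days" for onset is not exactly
recomputable from the table under any single convention; the computed
dataset-A mean ± sample SD is 15.9 ± 8.7 and the median 13.0. `summarize`
reports computed values and does not chase the discrepancy (the printed
"median ± SD" figures behave like mean ± sample SD).

## Signal simulator

Each repetition is 750 samples at 1 kHz (0.75 s), 4 channels (flexor carpi
radialis, flexor carpi ulnaris, thenar, extensor digitorum communis),
hard-clipped at ±1.5 mV like the acquisition device. Per channel:

    s(t) = clip( a_ch(t) · c_ch(t) + n_floor · w(t), ±1.5 mV )

* `c_ch` — white Gaussian noise bandpass-filtered to 20–300 Hz and scaled
  to unit RMS (the conventional surface-EMG energy band), so synthetic
  signals pass the preprocessing filter largely unchanged.
* `a_ch(t)` — a trapezoidal activation envelope (gesture-specific
  rise/hold/fall fractions, jittered per repetition) times gesture
  channel gains (mV) times per-subject log-normal channel multipliers.
* `n_floor` — 0.02 mV broadband floor noise.

Gesture gains follow the muscle groups each gesture recruits under this
montage (documented in `make_default_templates`); rest is floor noise only.

**Subject anatomy.** Each subject carries stable parameters shared by both
arms: log-normal channel-gain multipliers (σ = 0.5) and a diagonally
dominant row-stochastic channel-mixing matrix (electrode placement /
tissue crosstalk, mean off-diagonal mass 0.4). These create
subject-specific signatures; because they are shared across arms, a test
subject's non-paretic recordings are genuinely informative about their
paretic signal geometry — one of the two mechanisms by which fusion can
help.

**Paresis model.** The paretic arm applies, on top of the anatomy:

* attenuation `α` of voluntary drive (α = 0.6 for a cohort-average
  subject),
* co-contraction leakage `λ` mixing flexor and extensor envelopes
  (λ = 0.3 nominal) — the abnormal flexor–extensor coupling seen after
  stroke,
* 4–8 Hz multiplicative tremor amplitude modulation (depth 0.2 nominal,
  random phase per repetition),
* *synergy collapse* (total fraction 0.6 at nominal severity): the
  intended channel-gain pattern is pulled toward an abnormal mass-synergy
  pattern, preserving total drive. 35% of the collapse points at a
  subject-stable synergy; 65% is erratic — random strength and direction
  every repetition. The variance-dominated split is
  deliberate: trial-varying degradation scatters paretic repetitions
  around the true class archetypes, which is precisely the regime in which
  additional clean examples of those archetypes (the non-paretic data) aid
  a small-data classifier — the second fusion mechanism,
* tonic involuntary baseline activity (spasticity-like; also present at
  rest, making rest vs weak attempts confusable),
* elevated floor noise (×1.5 nominal), larger trial-to-trial gain jitter
  and envelope jitter.

Severity scales linearly with the patient's motor deficit: the nominal
parameters above describe a subject at the cohort-nominal FMA-UE of 37/66;
a severe patient (FMA-UE 8) is roughly twice as degraded. Severity is
floored at 0.85 of nominal — FMA-UE grades gross motor function, and even
patients with high scores show clearly abnormal subacute EMG activation
patterns, so EMG-pattern degradation never vanishes. This ties simulated
difficulty to the packaged clinical scores while keeping every
cross-validation fold off ceiling. The calibration anchor was the
published 3-gesture baseline operating point (paretic-only subject-wise
accuracy in the low-to-mid 70s); the packaged defaults land the simulated
baseline within about one point of it.

**Protocol emulation.** For every (patient, arm, gesture) a raw attempt
count is drawn uniformly in 10–20 and the first 10 repetitions are kept,
giving exactly balanced classes (deterministic balancing). Repetitions can
be concatenated into continuous session streams with 0.5 s rest-noise gaps
and 0-based start markers; stream length and gap choice are package
conventions (the acquisition protocol's inter-gesture timing is not
specified anywhere authoritative).

All randomness derives from one integer seed via `numpy` `SeedSequence`
keys `(seed, subject, session, arm, gesture)`, so outputs are
bit-reproducible and arms of one subject can share anatomy while differing
in noise.

## Preprocessing

Butterworth bandpass 20–300 Hz; the order is not dictated by the source
protocol, so order 4 is used — standard surface-EMG practice — applied
forward-backward (zero phase) because classification is offline and phase
distortion of envelopes is undesirable. Filtering happens on whole
recordings (or streams) before segmentation. Segments are contiguous
half-open `[start, start+750)` windows.

Amplitude normalization divides each channel by its mean absolute value
(MAV) computed per (subject, session, arm, channel) over all of that
group's segments. This granularity preserves between-gesture amplitude
contrast (class information) while removing subject- and arm-level scale —
including most of the paretic attenuation, which is why the simulator's
difficulty comes from pattern degradation rather than amplitude. A
per-segment variant exists behind a flag. Divisors below 1e-12 are replaced
by 1 and flagged. No other features are extracted; the network consumes
normalized time series.

## Network

A 1D CNN-LSTM with, in the reference topology: two causal convolutions
(24 then 48 filters, kernel 6), each followed by ReLU and layer
normalization over channels; global average pooling over time; LSTM(64)
with dropout 0.3; LSTM(32) with dropout 0.2; a dense layer with one unit
per gesture class; softmax. Note the pooling stage sits *before* the
recurrent stack, which collapses the time axis to a single step and turns
the LSTMs into gated dense layers. This layer order is reproduced
deliberately as `paper_literal` (the default) rather than silently "fixed";
two ablation variants are available: `lstm_last` (no pooling, last LSTM
output classifies) and `gap_after_lstm` (pooling moved after the LSTM
stack). The implementation is pure NumPy with hand-written
forward/backward passes, verified against numerical differentiation for
all three variants.

Training: Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 0.002 decayed
×0.1 every 100 epochs, global-norm gradient clipping at 1, mini-batches of
32, shuffling every epoch, up to 300 epochs with no early stopping.
Validation checks every 150 optimizer iterations on a 10% class-stratified
held-out fraction are monitoring only (the split fraction is a package
convention). Weights initialize Glorot-uniform (orthogonal recurrent
matrices, forget-gate bias 1) from the training seed, making runs
bit-reproducible. Loss is categorical cross-entropy. Ties in argmax
prediction resolve to the lowest class index.

## Cross-validation and fusion protocol

Splitting is subject-wise and repeated: per iteration the subjects are
shuffled and the first `n_folds × test_subjects_per_fold` are partitioned
into disjoint test groups (defaults: 100 iterations × 10 folds × 2 test
subjects). A classic partition of 25 subjects into 10 folds of 2 is
impossible; repeated random disjoint draws satisfy both the fold count and
the 23-train / 2-test split simultaneously, and are fully configurable.
Each fold trains an independent model seeded from (seed, iteration, fold).

Conditions:

* `paretic_only` — train on paretic segments of the 23 training subjects;
* `fused` — additionally include non-paretic segments of *all* subjects,
  including the held-out two. The non-paretic arm is never tested, so this
  wider reading leaks no test data; a flag restricts fusion to training
  subjects only.

The test set is always the paretic segments of the held-out subjects. A
leakage audit over the full 1000-plan default grid (test-key/train-key
intersections, non-paretic keys in test sets) backs this invariant.

## Metrics and statistics

ACC is overall agreement (trace/total); SENS, SP and F1 are unweighted
macro means of per-class one-vs-rest values, all in percent; 0/0 ratios
define to 0. The published tables do not state their averaging convention
and show ACC well above macro SENS — the standard definitions used here
reproduce that ordering only under imbalance, so the discrepancy is
documented rather than reverse-engineered. ROC curves sweep thresholds over
unique scores (ties grouped); trapezoidal AUC then equals the Mann–Whitney
probability that a positive outranks a negative (ties ½), which the test
suite verifies by pair counting. Pooled cross-validation scores give one
ROC/AUC per gesture.

Conditions are compared per metric by a two-sided unpaired Student t-test
(equal-variance pooling; Welch behind a flag) over the per-fold metric
values — the sample unit is a package convention, the source not stating
whether fold-level or iteration-level values were compared. Significance
tiers: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001. No
multiple-testing correction, matching raw-p reporting. Gesture sub-models:
2G {rest, wrist extension}, 3G {+thumbs up}, 4G {rest, fist, wrist
flexion, wrist extension}, 5G {rest, index pinch, wrist flexion, wrist
extension, thumbs up}, 6G {all but fist}, 7G {all}, 6G-NR {all but rest},
each suffixed -A/-B by dataset.

## Validation problem sizes

The validation benchmarks (`emgfusion.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) run the pipeline at sizes chosen for a
single CPU:

* learnability: one clean subject (no paresis), 7 classes × 20
  repetitions, 100 epochs, 25% stratified holdout; passes at ≥ 90%
  held-out accuracy.
* fusion benefit: 12 dataset-A patients with the default paresis model,
  3-gesture subset, 2 iterations × 3 folds × 2 held-out subjects (6
  independent splits per condition), 15 epochs, repeated over 5 master
  seeds; the statistic is in how many seeds the fused condition's mean
  accuracy exceeds the paretic-only condition's, alongside the mean
  accuracies themselves.
* leakage audit: the full 100 × 10 default fold plan (key bookkeeping
  only, no training).

Full-scale experiments (100 iterations, 300 epochs, all 14 sub-models) use
exactly the same code paths via `FusionExperiment` or the CLI; only the
sizes differ.

## What the simulator does and does not capture

Captured: device constraints (rate, range, clipping), band-limited sEMG
spectra, balanced repetition protocol, subject-specific anatomy shared
across arms, severity-graded paresis linked to clinical scores, paired
paretic/non-paretic structure, between-subject heterogeneity that makes
subject-wise CV meaningfully harder than record-wise CV.

Not captured: motor-unit action-potential physiology (no MUAP trains or
recruitment/firing-rate structure), electrode lift-off and motion
artifacts, mains interference, fatigue and within-session drift,
non-stationary tremor spectra, true muscle-synergy dynamics, or any
relation between gestures beyond channel-gain geometry. Passing tests
therefore demonstrate that the pipeline, protocol and statistics behave
correctly and that the fusion mechanism operates under the assumed
statistical structure — not that the same effect sizes would be measured
on clinical recordings.

## Known limitations

* The reference topology's pooling-before-LSTM degenerates the recurrent
  stack; the ablation variants exist precisely to quantify that choice.
* NumPy training is single-threaded BLAS-bound; ~40–60 ms per optimizer
  step at batch 32 × 750 samples. Full-scale runs (1000 folds × 300
  epochs) are compute-days; the package parallelizes naturally across
  folds at the process level since every fold is seeded independently.
* The t-test treats per-fold metrics as independent samples; folds share
  training subjects, so p-values are optimistic — a caveat inherited from
  the evaluated protocol itself.
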