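# Methods

This note documents the models, conventions, and design choices behind
the package, the way a simulation or statistics library documents its
internals: what is computed, under which assumptions, and what the
synthetic validation does and does not demonstrate.

## Data model

A *trial* is one unbroken 100 Hz time series: per sample, two 60×21
grids of cell pressures (kPa, one per foot), a class label
(Non-FOG / FOG / Pre-FOG), and an activity state (walking / turning /
standing / undefined). Trials are never concatenated — sequence models
see each trial as its own series. A *session* is a participant's set of
trials plus the list of annotated freeze episodes `[onset, end)` in
seconds; a participant is a *freezer* iff the session contains at least
one episode.

Grid orientation is not dictated by the data format, so the package
fixes one convention: row 0 is the heel (posterior), rows increase
toward the toes; column 0 is medial. All downstream quantities except
the sign of the COP axes are orientation-invariant. The cell pitch is
5.08 mm.

Freeze annotations arrive at video rate (30 Hz) and are mapped to the
sample grid by snapping onset and end to the nearest 100 Hz timestamp,
so every sample carries exactly one label.

## Features

Sixteen features per timestep, eight per foot: COP x/y (mm, grid
centroid × pitch), COP x/y velocity (cm/s, first difference over
0.01 s), COP x/y acceleration (cm/s², second difference), total GRF
(kPa-sum over all cells), and the per-foot fraction of the two-foot GRF
sum. No filtering anywhere: the differences are raw, which is what a
microcontroller computing features sample-by-sample would produce.

Degenerate cases require conventions the sensor data do not dictate:

* **Swing phase.** COP is undefined while a foot is unloaded. The last
  defined COP is held through the gap (zero velocity), and a validity
  mask flags those samples plus the sample whose difference spans the
  gap. Holding avoids injecting large artificial spikes into the
  unfiltered velocity/acceleration at every swing — a zeroing or
  interpolating convention would change the feature statistics
  substantially. Models are trained and evaluated on the held values.
* **Boundaries.** Velocity at t = 0 and acceleration at t ∈ {0, 1} are
  set to 0 so the feature matrix keeps full length T and stays aligned
  with the per-sample labels.
* **Unloaded both feet.** GRF fractions are (0.5, 0.5) when the total
  is zero, flagged invalid.

Useful invariants, all tested: fractions sum to 1 wherever load exists;
scaling all pressures by a constant leaves COP, its derivatives, and
fractions unchanged while scaling GRF linearly; cumulative-summing the
velocity recovers COP displacement to numerical precision.

## Balancing

Each freeze episode in the training split yields one contiguous
training instance: the target block plus non-target context at a 1:1
ratio when possible, half before and half after the block (before
rounded down, after up, when the block length is odd). A shortfall on
one side — trial boundary or a neighboring episode — is compensated on
the other; when the gaps around an episode cannot supply enough
context, the instance keeps all available context and stays imbalanced
toward the target class. Context between close episodes may be used by
both neighbors. In prediction mode the target block is the episode plus
its own Pre-FOG window, and a neighboring episode's Pre-FOG samples are
never valid context (that would leak target-class samples into the
non-target side). Validation data are never balanced.

The Pre-FOG window is min(episode duration, 2 s), truncated at the
trial start and at the end of any earlier episode; FOG labels are never
overwritten.

## Classifier

Stacked LSTM (tanh cell activation, sigmoid gates), every layer
returning its full sequence, then a time-distributed dense layer with 2
units and softmax: one class distribution per timestep. The recurrence
is strictly causal, so prefix predictions equal the prefix of
full-sequence predictions — tested, since real-time viability rests on
it. The per-timestep decision is the argmax (threshold 0.5), the
natural reading of per-sample classification.

Training: Adam with β₁ = 0.9 and β₂ = 0.999, mean cross-entropy over
the timesteps of an instance, batch size 1 (so variable-length
instances need no padding), learning rate 0.01 halved every 5 epochs.
Reference configurations: detection 2×16 units for 30 epochs
(alternative 3×32); prediction uses the same architectures with fixed
early stopping at 4 epochs (2-layer) or 3 epochs (3-layer). The epoch
counts are fixed a priori rather than chosen on held-out folds, which
would leak.

Implementation choices where the protocol is silent: instance
presentation order is reshuffled every epoch under the run seed
(batch-size-1 training is order-sensitive, and seeding keeps runs
reproducible); the hidden state is reset between instances, which are
independent sub-sequences; the forget-gate bias initializes at +1 and
other weights uniform in ±1/√H, standard initialization for small
LSTMs; z-score SDs are floored at 1e-8 so constant features normalize
to zero. A non-finite training loss aborts with a diagnostic rather
than continuing silently. The whole network, including backpropagation
through time, is numpy: at ~4k parameters there is nothing for a GPU
framework to accelerate, and bit-reproducibility on one platform comes
free.

Normalization statistics are pooled over every sample of the training
split's balanced instances and are refit whenever the split changes
(each cross-validation fold); they are stored with the model so
classification is self-contained.

## Evaluation

Datapoint-level confusion counts over *all* samples of the held-out
participant's trials give sensitivity, specificity, precision, and F1
(harmonic mean of sensitivity and precision); any metric with a zero
denominator is flagged undefined and excluded from aggregation. Fold
aggregates are mean and **population** SD (divide by n) — the
convention that matches how such per-fold tables are summarized.
Percent time frozen is (TP+FP)/total for the model and (TP+FN)/total
for the truth; the latter is label prevalence, independent of any model.

An episode counts as detected when at least one positively classified
sample falls inside its true window. Latency is measured from the start
of the maximal contiguous predicted run containing the earliest
in-window hit, so a run that begins before the true onset yields a
negative latency (the freeze was anticipated). A run spanning two true
episodes is credited to the first; a later episode covered only by an
already-credited run gets its latency from its first in-window sample.
Undetected episodes are excluded from latency averages and reported as
counts.

Error breakdowns distribute FP and FN over activity states (shares sum
to 100% when any exist) and report per-state FP rates; a restricted
evaluation over active states only (walking + turning) quantifies how
much specificity is lost to standing, which balanced training sets
barely contain. The all-non-freezer protocol trains on every freezer
and validates on participants who never froze: sensitivity is undefined
there and model percent-time-frozen reduces to the FP rate.

## Synthetic cohort

No public dataset of labeled plantar-pressure FOG recordings exists, so
the package ships a seeded simulator that emulates the statistical
structure the pipeline assumes, not biomechanics beyond what the 16
features can sense:

* **Walking**: alternating stance (65% of the gait cycle, feet half a
  cycle apart) and swing; during stance the COP advances heel→toe and
  the load follows a smooth profile; during swing the foot is exactly
  unloaded. Cadence 0.9 cycles/s per foot, peak load 900 kPa-sum.
* **Turning**: the same stepping with COP excursion tightened to 45%
  and a 30/−30% load asymmetry between feet.
* **Standing**: static bilateral midfoot loading.
* **Freezing**: both feet stay loaded while the COP oscillates at a
  per-episode trembling frequency drawn from 3–8 Hz with 3 mm
  amplitude and anti-phase load shifting between feet — trembling in
  place with no anterior progression.
* **Pre-freeze**: over the 2 s before onset, step amplitude and cadence
  ramp linearly down to 25%, a minimal instantiation of gait
  deterioration entering a freeze.
* Each trial opens with an `undefined` lead-in containing one bilateral
  stomp-like spike, exercising the undefined-state bookkeeping.

Episode counts per trial are Poisson (mean 2); durations are log-normal
(μ = 0.8, σ = 0.6 on the log scale, truncated at 0.3 s: median ≈ 2.2 s,
right-skewed like clinically observed freeze durations). Episodes are
placed inside walking segments with guard gaps wider than the Pre-FOG
window; draws that cannot fit are dropped. Labels and states are exact
by construction. Frames are rendered as compact Gaussian pressure blobs
(σ = 2.5 cells, support cut at 2% of peak) with 1 kPa per-cell sensor
noise on loaded cells; cells of an unloaded foot are exact zeros.

The default cohort is 11 participants — 7 freezers and 4 non-freezers —
with 3 trials of ~31 s each, sizes chosen so the complete
cross-validation study runs in minutes on one CPU while still giving
every fold multiple episodes. By design the simulated freeze signature
is separable: a threshold on anterior COP speed alone reaches >80%
balanced accuracy on freeze vs walking samples (a tested generator
property). Consequently the end-to-end results on synthetic data verify
that the pipeline — features, balancing, normalization, training,
causal inference, episode scoring — works and that the learning problem
it poses is solvable; they say nothing about sensitivity or specificity
on real patients, where the freeze signature is far subtler and more
heterogeneous. What does transfer is the arithmetic: metric and
aggregation operators reproduce published worked examples exactly.

## Known limitations

* The simulator does not model gait-initiation freezes, festination,
  shuffling, or sensor artifacts (drift, saturation, broken cells); all
  freezes are of the trembling type during ongoing gait.
* Standing is nearly indistinguishable from freezing for models trained
  on balanced instances that contain almost no standing context — an
  expected failure mode that the active-only evaluation quantifies
  rather than hides.
* Hold-last COP during swing is a convention; real systems might prefer
  per-foot validity gating.
* Batch-size-1 training is inherently order-sensitive; different seeds
  give slightly different folds even on identical data (runs under one
  seed are bit-reproducible).
* The three-class prediction formulation (Non-FOG / Pre-FOG / FOG as
  separate outputs) is out of scope; prediction here is the binary
  merged-target setup.
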