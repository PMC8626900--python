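# fogait

Detection and prediction of freezing of gait (FOG) from plantar-pressure
insole data with per-timestep LSTM models.

FOG is an episodic inability to step forward that affects many people with
advanced Parkinson's disease and is a major cause of falls. Cueing systems
can shorten or prevent freezes, but they need a detector that recognizes a
freeze as it starts — ideally before — from unobtrusive sensors. This
package implements a complete pipeline that works from pressure-sensing
insoles alone: two 60×21 grids of cell pressures (kPa) per timestep at
100 Hz, one grid per foot.

It is written for researchers in movement-disorder digital biomarkers and
wearable gait analysis who want a tested, reproducible reference
implementation of this approach, including a synthetic gait simulator so
every stage runs without access to clinical recordings.

## Method

From each pair of pressure frames, 16 features are computed per timestep,
with no signal filtering:

* centre of pressure **COPx, COPy** per foot (mm): the pressure-weighted
  centroid of the cell grid times the 5.08 mm cell pitch;
* COP velocity **vx, vy** per foot (cm/s): first difference over the
  0.01 s sample interval;
* COP acceleration **ax, ay** per foot (cm/s²): first difference of the
  velocity;
* total ground reaction force **GRF** per foot (kPa-sum over all 1260
  cells) and each foot's **fraction** of the two-foot total.

The classifier is a stack of LSTM layers (tanh activation, each layer
returning its full sequence) with a time-distributed 2-unit softmax head,
so every timestep receives its own FOG / Non-FOG decision — no windowing,
and the recurrence is causal, as a real-time system requires. Training
uses Adam (β₁ = 0.9, β₂ = 0.999), cross-entropy loss, batch size 1
(variable-length sequences), and a learning rate starting at 0.01 and
halving every 5 epochs. The reference detection model has 2 layers of 16
units trained for 30 epochs (~17 KB of weights); prediction models stop
early (4 epochs for 2-layer, 3 for 3-layer) and relabel the min(d, 2 s)
window before each freeze of duration d as Pre-FOG, merging it with FOG
into the target class.

Because freezing is rare, the training set is balanced episode-wise: each
freeze episode becomes one contiguous training instance holding the
episode plus an equal amount of non-freeze context, split half before and
half after when available. Validation data are never balanced. Evaluation
is leave-one-freezer-out: per fold, feature-wise z-score normalization is
refit on the training split, and the model classifies every sample of the
held-out participant's trials. Reported measures are datapoint
sensitivity/specificity/precision/F1 (fold mean ± population SD),
episode detection latency (signed; negative = anticipated), percent time
frozen, activity-state breakdowns of errors, and specificity on
participants who never froze.

## Worked example

Datapoint metrics from a held-out participant's confusion counts
(2,868 of 3,454 freeze samples and 76,729 of 82,943 non-freeze samples
classified correctly):

```
$ python examples/worked_metrics.py
sensitivity  83.0%   (2868 of 3454 freeze samples)
specificity  92.5%   (76729 of 82943 non-freeze)
precision    31.6%   (freeze calls that were real)
F1           0.46

percent time frozen: model 10.5% vs true 4.0%
```

High sensitivity and specificity coexist with poor precision because
freeze samples are a small minority of each trial — the central caveat
when reading per-datapoint FOG metrics.

End-to-end on synthetic data (reduced cohort, shortened schedule,
`examples/train_and_evaluate.py`):

```
held-out  sens%   spec%   episodes detected
     P01   99.2    86.1   2/2
     P02   99.2    87.1   2/2
     P03   99.4    81.8   6/6
     P04   99.3    86.2   3/3

mean over folds: sensitivity 99.3% (SD 0.1), specificity 85.3% (SD 2.1)
episodes detected: 13/13, mean latency -0.06 s (negative = anticipated before true onset)
non-freezer specificity: 87.1% (false-alarm check on participants who never froze)
```

The synthetic freeze signature is deliberately separable, so these
numbers validate the pipeline's mechanics, not clinical performance; see
`docs/methods.md`.

Other examples: `simulate_cohort.py` (cohort generation and episode
statistics), `extract_features.py` (the 16 features on walking vs
freezing samples), `balance_instances.py` (episode-wise balancing,
including boundary and adjacent-episode cases).

## Command line

The same stages are available as subcommands operating on a run
directory of HDF5 trial containers and JSON manifests:

```
fogait simulate --run-dir runs/demo --seed 1
fogait label    --run-dir runs/demo --mode detection
fogait features --run-dir runs/demo
fogait train    --run-dir runs/demo --layers 2 --units 16
fogait crossval --run-dir runs/demo --active-only
fogait report   --run-dir runs/demo
```

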