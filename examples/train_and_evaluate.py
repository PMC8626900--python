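"""Train the per-timestep LSTM and evaluate it leave-one-freezer-out.

Uses a reduced cohort (4 freezers + 2 non-freezers, shorter trials) and a
shortened training schedule so the example finishes in about a minute;
scripts/acceptance.py runs the full default cohort with the reference
30-epoch schedule.
"""

from fogait import SimConfig, generate_cohort
from fogait.evaluation import lopo_cv, non_freezer_validation
from fogait.model import ModelConfig

cohort = generate_cohort(
    SimConfig(
        n_participants=6,
        freezer_fraction=4 / 6,
        trials_per_participant=2,
        seed=2,
    )
)

config = ModelConfig(n_layers=2, units=16, epochs=8)  # reference: 30 epochs
folds, agg = lopo_cv(cohort, mode="detection", config=config, master_seed=2)

print("held-out  sens%   spec%   episodes detected")
for f in folds:
    print(f"{f.held_out:>8}  {f.metrics['sensitivity_pct']:5.1f}  "
          f"{f.metrics['specificity_pct']:6.1f}   {f.n_detected}/"
          f"{f.n_detected + f.n_undetected}")

sens, sens_sd = agg["sensitivity_pct"]
spec, spec_sd = agg["specificity_pct"]
print(f"\nmean over folds: sensitivity {sens:.1f}% (SD {sens_sd:.1f}), "
      f"specificity {spec:.1f}% (SD {spec_sd:.1f})")
print(f"episodes detected: {agg['n_detected']}/{agg['n_episodes']}, "
      f"mean latency {agg['mean_latency_s']:+.2f} s "
      "(negative = anticipated before true onset)")

nf = non_freezer_validation(cohort, mode="detection", config=config, master_seed=2)
print(f"non-freezer specificity: {nf['metrics']['specificity_pct']:.1f}% "
      "(false-alarm check on participants who never froze)")
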