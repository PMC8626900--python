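"""Generate a synthetic cohort and summarize its freeze episodes.

Builds the default 11-participant cohort (7 freezers, 4 non-freezers) of
100 Hz plantar-pressure trials and prints, per participant, the episode
count and duration statistics — the kind of cohort table a clinical gait
study reports.
"""

from fogait import SimConfig, generate_cohort
from fogait.labeling import episode_statistics

cohort = generate_cohort(SimConfig(seed=1))

print(f"{'participant':>11} {'freezer':>8} {'episodes':>9} "
      f"{'mean dur (s)':>13} {'total dur (s)':>14}")
for manifest, trials in cohort:
    s = episode_statistics(manifest)
    mean = "-" if s["mean_duration_s"] is None else f"{s['mean_duration_s']:.2f}"
    print(f"{manifest.participant_id:>11} {str(manifest.is_freezer):>8} "
          f"{s['n_episodes']:>9} {mean:>13} {s['total_duration_s']:>14.2f}")

trial = cohort[0][1][0]
print(f"\neach trial: {trial.n_samples} samples at 100 Hz "
      f"({trial.duration_s:.0f} s), two 60x21 kPa frames per sample")
print("labels are exact by construction: FOG wherever the simulated freeze "
      "(trembling COP, both feet loaded) was injected")
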