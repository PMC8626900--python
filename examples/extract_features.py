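"""Extract the 16 per-timestep plantar-pressure features from one trial.

Shows the feature matrix a detection model consumes: per foot the COP x/y
position (mm), COP velocity (cm/s), COP acceleration (cm/s^2), total GRF
(sum of cell pressures, kPa) and the per-foot share of the two-foot GRF.
No filtering is applied — these are raw first differences, as a real-time
wearable would compute them.
"""

import numpy as np

from fogait import FEATURE_NAMES, SimConfig, extract_features, generate_session

manifest, trials = generate_session(SimConfig(seed=3), "P01", is_freezer=True)
trial = trials[0]
fs = extract_features(trial)

print(f"trial {trial.trial_id}: feature matrix {fs.values.shape}, "
      f"{(~fs.valid).sum()} samples flagged (COP held across an unloaded foot)")

left_loaded = fs.values[:, 12] > 0
walking = np.flatnonzero((trial.states == 0) & left_loaded)[800:803]
fog = np.flatnonzero(trial.labels == 1)[5:8]
for name, idx in [("walking", walking), ("freezing", fog)]:
    print(f"\n{name} samples:")
    for t in idx:
        row = fs.values[t]
        print(f"  t={trial.timestamps[t]:6.2f}s  COPy_L={row[1]:6.1f} mm  "
              f"vy_L={row[5]:7.1f} cm/s  GRF_L={row[12]:7.0f}  "
              f"frac_L={row[14]:.2f}")

vy = np.abs(fs.values[:, [5, 7]]).max(axis=1)
fog_mask = trial.labels == 1
walk_mask = (trial.states == 0) & ~fog_mask
print(f"\nmedian anterior COP speed: walking {np.median(vy[walk_mask]):.1f} "
      f"cm/s vs freezing {np.median(vy[fog_mask]):.1f} cm/s")
print("freezing suppresses forward COP progression — the signature the "
      "classifier learns")
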