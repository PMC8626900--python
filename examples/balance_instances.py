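"""Build balanced training instances around each freeze episode.

Freezing is rare, so training on whole trials would drown the target
class. Instead, each episode becomes one contiguous training instance:
the freeze samples plus an equal amount of surrounding non-freeze
context, half before and half after when available.
"""

import numpy as np

from fogait import (
    FogEpisode,
    apply_prefog,
    build_training_instances,
    map_video_labels,
)

timestamps = np.arange(3000) * 0.01  # one 30 s trial
episodes = [
    FogEpisode(5.0, 9.0, "demo"),    # 4 s freeze, ample context
    FogEpisode(10.0, 12.0, "demo"),  # close on the heels of the first
    FogEpisode(28.5, 30.0, "demo"),  # runs into the end of the trial
]

labels = map_video_labels(episodes, timestamps)
print("detection instances (target = FOG):")
for inst in build_training_instances(labels, episodes, timestamps, "detection"):
    print(f"  samples [{inst.start:5d}, {inst.stop:5d})  "
          f"target {inst.n_target:4d}  context {inst.n_nontarget:4d}"
          + ("  (imbalanced: context exhausted)"
             if inst.n_nontarget < inst.n_target else ""))

labels_pred = apply_prefog(labels, episodes, timestamps)
print("\nprediction instances (target = Pre-FOG + FOG, 2 s rule):")
for inst in build_training_instances(
    labels_pred, episodes, timestamps, "prediction"
):
    print(f"  samples [{inst.start:5d}, {inst.stop:5d})  "
          f"target {inst.n_target:4d}  context {inst.n_nontarget:4d}")
print("\nvalidation data are never balanced: models classify every sample "
      "of a held-out trial")
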