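"""Datapoint-level metrics from a published worked example.

A held-out participant's per-sample confusion counts (2,868 of 3,454
freeze samples and 76,729 of 82,943 non-freeze samples classified
correctly) illustrate why precision stays poor even when sensitivity and
specificity are high: freeze samples are a small minority of a trial.
"""

from fogait.evaluation import ConfusionCounts, metrics, percent_time_frozen

counts = ConfusionCounts(tp=2868, tn=76729, fp=6214, fn=586)
m = metrics(counts)

print(f"sensitivity  {m['sensitivity_pct']:.1f}%   (2868 of 3454 freeze samples)")
print(f"specificity  {m['specificity_pct']:.1f}%   (76729 of 82943 non-freeze)")
print(f"precision    {m['precision_pct']:.1f}%   (freeze calls that were real)")
print(f"F1           {m['f1']:.2f}")

model_pct, true_pct = percent_time_frozen(counts)
print(f"\npercent time frozen: model {model_pct:.1f}% vs true {true_pct:.1f}%")
print("the model overestimates time frozen because false positives add to "
      "its numerator; the true value is just the label prevalence")
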