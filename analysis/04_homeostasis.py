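#!/usr/bin/env python
"""Longitudinal homeostasis analyses on the V1 enucleation study.

Tracks inactive fractions over time, baseline-normalised amplitude changes
per functional class (TNF-dependent strengthening of network-correlated
spines), and the within-spine frequency(12 h) vs amplitude(48 h) relation.
Writes results/homeostasis/.
"""

from pathlib import Path

import pandas as pd

from spinecalc.pipeline import (class_proportions, classify_baseline,
                                load_bundle_sessions)
from spinecalc.population import (add_normalized_changes, align_longitudinal,
                                  freq_amp_coupling, inactive_fraction)

OUT = Path("results/homeostasis")
OUT.mkdir(parents=True, exist_ok=True)

sessions, rois, region = load_bundle_sessions(Path("results/bundles/V1-enucleation"))
baseline = [s for s in sessions if s.timepoint_hr < 0.0]
classes = classify_baseline(baseline, region)
labels = classes.set_index("spine_id").label

metrics = pd.concat([s.metrics for s in sessions], ignore_index=True)
table = align_longitudinal(metrics, labels)
table.to_csv(OUT / "longitudinal.csv", index=False)

timepoints = sorted(table.timepoint_hr.unique())
print("inactive fraction over time (all included spines):")
for tp in timepoints:
    print(f"  t={tp:+6.0f} h: {inactive_fraction(table, tp):5.1f}%")

print("\ninactive fraction at 12 h by baseline class:")
for lab in ("visually_responsive", "network_correlated", "unclassified"):
    print(f"  {lab:<22} {inactive_fraction(table, 12.0, label=lab):5.1f}%")

t = add_normalized_changes(table[table.persistent], "mean_amplitude",
                           (-24.0, -1.0))
rows = []
print("\nbaseline-normalised amplitude change of persistent spines:")
for lab in ("visually_responsive", "network_correlated", "unclassified"):
    for tp in (12.0, 24.0, 48.0):
        sub = t[(t.label == lab) & (t.timepoint_hr == tp)]
        ch = sub.mean_amplitude_pct_change.dropna()
        rows.append({"label": lab, "timepoint_hr": tp, "mean": ch.mean(),
                     "sem": ch.sem(), "n": len(ch)})
print(pd.DataFrame(rows).pivot(index="label", columns="timepoint_hr",
                               values="mean").round(1).to_string())
pd.DataFrame(rows).to_csv(OUT / "group_changes.csv", index=False)

print("\nfrequency(12 h) vs amplitude(48 h) across persistent spines:")
for lab in ("visually_responsive", "network_correlated", "unclassified"):
    sub = table[table.label == lab]
    try:
        res = freq_amp_coupling(sub, 12.0, 48.0, (-24.0, -1.0))
        print(f"  {lab:<22} r={res['r']:+.3f} p={res['p']:.3f} "
              f"({res['method']}, n={res['n']})")
    except ValueError as exc:
        print(f"  {lab:<22} skipped ({exc})")
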