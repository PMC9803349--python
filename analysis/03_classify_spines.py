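#!/usr/bin/env python
"""Functional classification of the simulated V1 and RSC populations.

Classifies every spine from its baseline sessions (network correlation,
stimulus correlation, time-locking vs the dummy-stimulus chance level) and
compares the recovered class proportions and per-spine labels against the
generator's ground truth.  Writes results/classification/.
"""

import json
from pathlib import Path

import pandas as pd

from spinecalc.pipeline import class_proportions, classify_baseline, load_bundle_sessions

OUT = Path("results/classification")
OUT.mkdir(parents=True, exist_ok=True)

MAPPING = {"visual": "visually_responsive", "auditory": "auditory_responsive",
           "network_only": "network_correlated", "unclassified": "unclassified"}

for preset in ("V1-enucleation", "RSC-dark"):
    sessions, rois, region = load_bundle_sessions(Path("results/bundles") / preset)
    baseline = [s for s in sessions if s.timepoint_hr < 0.0] or sessions[:2]
    classes = classify_baseline(baseline, region)
    classes.to_csv(OUT / f"classes_{region}.csv", index=False)
    props = class_proportions(classes)
    (OUT / f"summary_{region}.json").write_text(json.dumps(props, indent=1))

    merged = classes.merge(rois[["spine_id", "true_class"]], on="spine_id")
    inc = merged[merged.label != "excluded"]
    acc = (inc.true_class.map(MAPPING) == inc.label).mean()
    print(f"{region}: "
          f"visual {props['pct_visually_responsive']:.1f}%  "
          f"auditory {props['pct_auditory_responsive']:.1f}%  "
          f"network {props['pct_network_correlated']:.1f}%  "
          f"unclassified {props['pct_unclassified']:.1f}%  "
          f"network-significant {props['pct_network_significant']:.1f}%")
    print(f"    excluded {props['n_excluded']} spines; "
          f"agreement with ground truth on included spines: {100 * acc:.1f}%")
    print("    confusion (rows true, cols assigned):")
    print(pd.crosstab(merged.true_class, merged.label).to_string(), "\n")
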