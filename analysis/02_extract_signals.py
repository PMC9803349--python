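#!/usr/bin/env python
"""Spine-specific signal extraction and event detection on the V1 bundle.

Runs drift removal, ΔF/F, robust dendritic subtraction and event detection
on every session of the simulated V1 enucleation study, then reports how
well the bleed slope alpha is recovered and what the detected activity
looks like.  Writes results/extraction/{alpha,metrics,events}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spinecalc.pipeline import load_bundle_sessions

BUNDLE = Path("results/bundles/V1-enucleation")
OUT = Path("results/extraction")
OUT.mkdir(parents=True, exist_ok=True)

sessions, rois, region = load_bundle_sessions(BUNDLE)

alpha = pd.DataFrame({
    "spine_id": sessions[0].spine_ids,
    "alpha_hat": sessions[0].alphas,
    "converged": sessions[0].alpha_converged,
}).merge(rois[["spine_id", "alpha_true"]], on="spine_id")
alpha.to_csv(OUT / "alpha.csv", index=False)

err = (alpha.alpha_hat - alpha.alpha_true).abs()
print(f"bleed slope recovery over {len(alpha)} spines: "
      f"median |err| = {err.median():.4f}, 90th pct = {err.quantile(0.9):.4f}")

metrics = pd.concat([s.metrics for s in sessions], ignore_index=True)
metrics.to_csv(OUT / "metrics.csv", index=False)
ev_rows = [(es.spine_id, es.session_id, e.onset_s, e.peak_s, e.offset_s,
            e.amplitude)
           for s in sessions for es in s.event_series for e in es.events]
pd.DataFrame(ev_rows, columns=["spine_id", "session_id", "onset_s", "peak_s",
                               "offset_s", "amplitude"]) \
    .to_csv(OUT / "events.csv", index=False)

base = metrics[metrics.timepoint_hr < 0]
print(f"baseline sessions: {base.frequency.mean():.3f} Hz mean event rate, "
      f"mean event area {base.mean_amplitude.mean():.3f} dF/F*s, "
      f"{100 * base.active.mean():.1f}% of spine-sessions active")
print(f"wrote {len(ev_rows)} events -> {OUT}")
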