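#!/usr/bin/env python
"""Generate the demonstration session bundles used by the analysis scripts.

Writes two small synthetic studies (deterministic, with ground truth) under
results/bundles/: a V1 baseline/enucleation study and an RSC dark-exposure
study.  The full-scale canonical fixtures are regenerated on the fly by
scripts/acceptance.py; these bundles are deliberately small so the later
scripts run in seconds.
"""

from pathlib import Path

from spinecalc.config import build_config
from spinecalc.synthgen import assign_population, generate_session, write_bundle

OUT = Path("results/bundles")
N = 250
SEED = 20221214

for preset in ("V1-enucleation", "RSC-dark"):
    cfg = build_config(None, preset, {"n_spines": N, "seed": SEED})
    truth = assign_population(cfg)
    sessions = [generate_session(cfg, truth, tp) for tp in cfg.timepoints]
    out = write_bundle(OUT / preset, cfg, truth, sessions, fmt="h5")
    n_ev = sum(t.size for _tm, ev, _s in sessions for t in ev.spine_times)
    print(f"{preset}: {N} spines x {len(sessions)} sessions "
          f"({sessions[0][0].n_samples} samples each), "
          f"{n_ev} ground-truth events -> {out}")
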