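# spinecalc

Analysis of longitudinal two-photon calcium imaging of dendritic spines:
spine-specific signal extraction, event detection, functional
classification, and homeostatic-plasticity analyses — together with a
synthetic-recording generator so that every stage is validated by
parameter recovery against known ground truth.

## The scientific problem

In sensory cortex, individual dendritic spines report their synaptic
inputs through calcium transients. After sensory deprivation (monocular
enucleation, dark exposure, ear plugging), some synapses homeostatically
strengthen. Which ones? Answering this requires, per spine and per
session:

1. **Isolating the spine's own signal.** A spine ROI mixes the synaptic
   signal with the dendrite's global (back-propagating action potential)
   signal. After rolling-8th-percentile baseline correction and ΔF/F, the
   contamination is removed by robust regression:

       ΔF/F_spine-specific = ΔF/F_spine − α · ΔF/F_dendrite

   with α the slope of an IRLS/Tukey-bisquare fit of spine vs dendrite
   ΔF/F.
2. **Detecting events.** Supra-threshold (15% ΔF/F) runs of the
   spine-specific trace; per session the mean event area ("amplitude",
   ΔF/F·s), the event frequency (Hz), the summed area (integral), and an
   active/inactive flag.
3. **Classifying spines from baseline sessions.** A spine is *visually /
   auditory responsive* when its trace correlates significantly and
   positively with the binarised stimulus track **and** the fraction of
   presentations with a time-locked event onset (within 500 ms) exceeds
   its chance level — measured per spine with a dummy stimulus track laid
   over dark-epoch recording — or when it passes a sparse-noise
   receptive-field test; *network-correlated* when it instead correlates
   positively with the leave-one-out population average trace;
   *unclassified* when neither. Significance uses a circular-shift
   permutation null computed in one FFT pass (calcium traces are too
   autocorrelated for parametric p-values).
4. **Longitudinal analyses.** Baseline-normalised percent changes per
   functional class, inactive/persistent tracking, dendritic clustering
   against a position-shuffle null, frequency-vs-amplitude coupling,
   orientation selectivity, and global dendritic response correlations.

The package is aimed at researchers analysing spine-resolved calcium
recordings, and at anyone who wants a fully synthetic, ground-truthed
testbed for such pipelines.

## Worked example

Simulate a small V1 study (250 spines, two baseline sessions, enucleation
at 0 h, post sessions at 12/24/48 h) and run the full pipeline:

```bash
spinecalc simulate --preset V1-enucleation --seed 20221214 --n-spines 250 \
    --out results/bundles/V1-enucleation
python analysis/03_classify_spines.py
python analysis/04_homeostasis.py
```

prints (abridged):

```
V1: visual 24.9%  auditory 0.0%  network 64.3%  unclassified 10.8%  network-significant 89.2%
    excluded 9 spines; agreement with ground truth on included spines: 99.6%

inactive fraction over time (all included spines):
  t=   -24 h:   0.0%
  t=    -1 h:   0.0%
  t=   +12 h:  21.6%
  t=   +24 h:  12.0%
  t=   +48 h:   6.8%

baseline-normalised amplitude change of persistent spines:
timepoint_hr         12.0  24.0  48.0
label
network_correlated   30.0  53.8  86.8
unclassified          4.2  -1.0   4.4
visually_responsive -19.3 -22.9 -20.8
```

Reading this: the classifier recovers the planted class mixture
(24/65/11%) almost exactly, with 89% of spines significantly coupled to
the network signal. After enucleation, ~21% of spines fall silent at 12 h
and recover over two days; persistent *network-correlated* spines grow
their response amplitudes while identified *visually responsive* spines do
not (their evoked responses are gone and what remains is network-driven)
— the homeostatic-strengthening pattern the generator encodes. The
measured +30/+54/+87% exceed the underlying ×1.1/1.2/1.3 amplitude
scalings because the area-above-threshold metric amplifies near-threshold
changes (see `docs/methods.md`).

The same machinery runs from Python:

```python
from spinecalc.config import build_config
from spinecalc.pipeline import run_study

cfg = build_config(None, "RSC-baseline", {"n_spines": 400, "seed": 1})
res = run_study(cfg)
print(res.proportions)   # class percentages among included spines
```

## Repository layout

- `src/spinecalc/` — the library: `config` (presets, deprivation models),
  `schedule` (stimulus schedules), `synthgen` (ground-truthed recording
  generator), `preprocess` (baseline, ΔF/F, robust subtraction), `events`
  (detection, metrics), `classify` (correlations, time-locking,
  sparse-noise test, decision rule), `population` (longitudinal and group
  analyses), `pipeline` (orchestration), `cli`, `targets` (canonical
  fixture benchmarks).
- `analysis/01…05_*.py` — narrative drivers that simulate demonstration
  studies and run each analysis stage, writing tables under `results/`.
- `tests/` — unit, property (hypothesis) and recovery tests.
- `docs/methods.md` — models, parameter choices, and limitations.

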