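# Methods

`spinecalc` analyses longitudinal two-photon calcium recordings of
dendritic spines at the level of extracted ROI traces, and ships a
synthetic-recording generator with known ground truth so that every stage
of the analysis can be validated by parameter recovery. This note records
the models, the defaults and why they were chosen, and the known
limitations.

## Signal model and extraction

A spine ROI's raw fluorescence is modelled as

    F_spine(t) = F0 · (1 + s(t) + α · d(t) + ε(t)) + drift(t)

where `s` is the spine-specific ΔF/F signal (synaptic calcium), `d` the
dendritic shaft signal that bleeds into the spine ROI (back-propagating
action potentials, bAPs), `α` the bleed slope, `ε` white measurement noise,
and `drift` a slow additive baseline wander. The paired dendrite ROI
carries `d` with its own noise and drift.

Extraction proceeds in three steps:

1. **Rolling-percentile baseline.** The 8th percentile of the raw
   fluorescence in a ±15 s window is the baseline F0(t); subtracting it
   removes slow drift. Windows shrink at the trace edges (no padding). The
   implementation maintains a sorted sliding window (numba), is exact to
   `np.percentile` semantics, and costs ~4 ms per 600 s trace.
2. **ΔF/F** = (F − F0(t)) / max(F0(t), 0.01·median F). The floor guards
   against degenerate baselines; for any plausible trace the transform is
   scale-invariant. *Known residuals:* a drift of amplitude A and period T
   leaves ≈ A·(2π/T)·12.6 s behind (the percentile sits ~12.6 s "behind"
   a ramp), and in dense-activity stretches the 8th percentile sits
   slightly above F0, compressing ΔF/F by up to ~20% (relevant for the
   sparse-noise epoch) and leaving the quiet level of spine-specific
   traces ~0.01–0.03 below zero, increasingly so at high α.
3. **Robust dendritic subtraction.** `α` is the slope of an iteratively
   reweighted least-squares regression (Tukey bisquare, tuning constant
   4.685 on an MAD residual scale, intercept included and discarded,
   ≤50 iterations, slope tolerance 1e-8) of spine ΔF/F on dendrite ΔF/F;
   the spine-specific trace is `spine − α·dendrite`, exactly. The batch
   implementation vectorises the IRLS across spines; a test cross-checks
   single fits against `statsmodels` RLM. Identifiability requires that
   the spine's own events are not systematically coincident with the
   dendrite's (see the generator's bAP model below); under the default
   conditions the median |α̂ − α| is ≈ 0.02–0.03.

## Event detection and activity metrics

Events are maximal contiguous supra-threshold runs of the spine-specific
trace; onset/peak/offset are the first/argmax/last supra-threshold sample.
Per event the **amplitude** is the trapezoidal area of
(trace − threshold)⁺ over the run (ΔF/F·s); per session the **frequency**
is events per second over the whole session, the **integral** the summed
area, and a spine is **active** when it has ≥1 event. No minimum duration
or refractory period is imposed; single-sample events are allowed.

**Threshold.** The operative default is the fixed 15% ΔF/F criterion. The
adaptive alternative (3.5 × whole-trace RMS) self-censors on sustained
activity: with ~0.26 Hz events and a 1.8 s decay the transients themselves
dominate the RMS (≈0.3–0.4 ΔF/F), putting 3.5×RMS above every transient
peak. `rms`, `max(0.15, 3.5·RMS)` and a MAD-based robust variant remain
available via configuration.

**Detection smoothing.** Before thresholding, the trace is smoothed with a
centred 1/3 s boxcar. Without it, noise chatter at the slow decay-tail
threshold crossing fragments each transient into ~2–3 "events". The boxcar
preserves transient area; the residual chatter approximately offsets the
onset loss from transient merging (two events closer than the
supra-threshold tail share one run/onset), keeping detected onset
statistics close to the true event statistics at the default conditions.
*Consequences that remain:* the absolute mean event area is biased ~25–35%
low by tail fragmentation (session-to-session ratios — the quantities the
longitudinal analyses use — are unaffected), and the area-above-threshold
metric is convex in the underlying event amplitude near threshold, so a
×1.3 scaling of true amplitudes reads out as roughly +60–70% in mean event
area at the default 0.2 ΔF/F amplitudes. Parameter-recovery tests therefore
compare the pipeline against a noise-free ground-truth oracle run through
the same metric, not against the nominal scaling factor.

## Functional classification

Classification uses the baseline (pre-deprivation) sessions only.

* **Stimulus correlation.** Pearson r between the spine-specific trace and
  a binarised stimulation track (1 during presentations). Sub-second
  presentations (auditory bursts) are extended to 2 s ON in the track —
  a GCaMP6s transient outlasts a 0.5 s burst, so the literal track carries
  almost no signal. The correlation is evaluated over the modality's
  epochs plus the dark epochs (other modalities' evoked activity would
  count against the track), with a 5 s decay guard after excluded epochs.
* **Significance.** The default p-value is an empirical two-sided
  circular-shift permutation test: r is computed at every circular lag of
  the trace in one FFT pass and p is the rank of |r₀| in that null.
  Calcium traces are strongly autocorrelated (~2 s), so the parametric
  t-test p (available as an option, and the field's conventional default)
  is anti-conservative by a factor of 5–10 here. The dark epoch matters
  for the null: it breaks the 6 s periodicity of the grating blocks, which
  would otherwise make shifted copies re-align with the track.
* **Time-locking.** A presentation is time-locked when ≥1 detected event
  onset falls within 500 ms of its onset. Each spine's chance level is
  measured with a dummy presentation track (same count and inter-onset
  statistics as the real one) laid over the dark epochs. "Above chance"
  is a one-sided binomial exceedance test (α = 0.01) of the real
  time-locked count against the spine's dummy rate (floored at the
  population mean rate); the stored `fp_threshold_pct` is the critical
  percentage, so the decision is literally
  `timelocked_pct > fp_threshold_pct`. A raw comparison against the noisy
  dummy percentage would misroute ~40% of chance-level spines
  (P(X>Y) ≈ 0.4 for iid binomials with equal rates).
* **Sparse noise.** Per stimulus frame, a local ΔF/F (baseline = mean of
  the preceding 1.0 s) yields two features: the one-frame forward
  difference at the frame onset and at +133 ms (nearest frame to +100 ms
  at 15 Hz). A bivariate Gaussian is fitted by sample moments with
  iterative re-exclusion of >4 SD outliers, started from a median/MAD fit
  (responsive trials otherwise mask themselves: with ~12% responsive
  trials the 4 SD ellipse scales with the responses). Trials beyond 4 SD
  with a positive onset derivative are responsive. The responder decision
  compares the responsive-trial count with a one-sided binomial bound; in
  the pipeline the null rate is estimated empirically from dummy trial
  grids in the dark (pooled across the population, α = 0.002), because
  spontaneous transient rises make the trial-outlier rate exceed the
  χ²-implied 3.3e-4 and a per-spine 480-trial estimate is Poisson-noisy.
* **Decision rule** (mutually exclusive): visually responsive if the
  gratings correlation is significantly positive AND time-locking is above
  chance, OR the spine is sparse-noise responsive; auditory responsive
  (RSC) by the same rule on the auditory track; otherwise
  network-correlated if the correlation with the leave-one-out network
  signal (unweighted mean of all other spines' spine-specific traces over
  all conditions) is significantly positive; otherwise unclassified; and
  excluded when a non-sensory spine's time-locking exceeds its chance
  threshold without a significant stimulus correlation. No multiple-
  testing correction is applied across spines. A generic behavioural-
  regressor correlation hook (pupil, whisker, ...) uses the same
  correlation machinery.

## Longitudinal and population analyses

Included spines are active at ≥1 timepoint; persistent spines at all
timepoints; labels are fixed from baseline. Percent changes are
`100·(x_t − mean(baseline))/mean(baseline)`, so the baseline mean maps to
0% exactly; spines with missing or non-positive baselines are flagged and
omitted from group means. Inactive fractions are computed over included
spines, optionally per baseline class. Frequency–amplitude coupling
correlates the normalised frequency change at 12 h with the normalised
amplitude change at 48 h across persistent spines (Pearson if both pass
Shapiro–Wilk normality, else Spearman; the method is reported).

Dendritic clustering: the match probability of spines n positions apart on
a branch, against a within-branch position-shuffle null (1000 shuffles,
fixed seed); distances are reported up to the 90th percentile of branch
lengths. For position-independent labels the curve sits at Σ_c p_c².

OSI: eight direction-wise mean evoked event areas are folded into four
orientations (opposite directions averaged);
OSI = (R_pref − R_orth)/(R_pref + R_orth). The formula is the standard
preferred/orthogonal contrast; scale-invariant, undefined (NaN) for
all-zero responses.

Global dendritic responses: per branch, the mean ΔF/F of the branch's
dendrite ROIs is event-detected like a spine trace and the evoked
amplitude is the mean area of events whose onset falls inside a stimulus
presentation window; changes are baseline-normalised and correlated with
the mean spine change on the same branch, per class.

## The synthetic-data generator

The generator emulates the study conditions at the ROI-trace level:
15 Hz sampling; sessions of drifting gratings (8 directions in 45° steps,
3 s on / 3 s grey, 5 randomised blocks), optionally sparse noise (frames
every 250 ms, 8–12 non-overlapping 8° black/white squares) and auditory
white-noise bursts (0.5 s, uniform 3–5 s intervals), plus a 6 min dark
epoch; identical paradigm structure at every timepoint. V1 studies image
at −24, −1, 12, 24, 48 h around deprivation; RSC studies at −1, 0, 48 h.

Per spine and session the event train is: Poisson background at 0.113 Hz;
for coupled spines (all but the unclassified class) each event of a
region-wide latent network train (0.25 Hz) inherited independently with
probability 0.6; for sensory-responsive spines stimulus-locked events
(latency U(0, 0.4 s)) with probability 0.8 at the preferred direction,
falling off with a broad orientation-tuned profile
(w(Δ) = e^{κ(cosΔ−1)} + 0.7·e^{κ(−cosΔ−1)}, κ = 1.2; OSI ≈ 0.3–0.5), or
0.8 per auditory burst. Sparse responders (all visual spines plus a small
network-only contingent sized so that 97% of sparse responders are also
grating-responsive) respond to 12.5% of frames. Event amplitudes are
lognormal (mean 0.2 ΔF/F, cv 0.2); stimulus-evoked events are drawn 1.8×
larger (compound evoked responses — this also gives the stimulus
correlation the power the recovery checks require). Traces are the event
trains convolved with a unit-peak difference-of-exponentials kernel
(rise 0.18 s, decay 1.8 s; GCaMP6s-like), plus bleed, noise
(σ = 0.025 ΔF/F) and drift (0.1 F-units, 600 s period) on a baseline
F0 ~ U(1.5, 3); α ~ U(0.2, 0.8) per spine; branches hold 8–15 spines with
positions independent of class.

**The branch (bAP) signal** is deliberately only partially coupled to any
one spine: the cell fires on 10% of latent events, adds its own 0.12 Hz
background, and gives direction-tuned evoked responses at a
branch-preferred direction (probability 0.6). If instead the dendrite
train contained every latent/evoked event, a coupled spine's inherited
events would be a strict thinning of the dendrite's — bleed slope and
coupling would be collinear and no regression could separate them (the
bisquare fit absorbs the coupling into α, error ≈ +0.15).

**Deprivation.** Enucleation permanently deletes visual evoked events and
silences spines class-dependently at 12 h (visual 0.35, network-only 0.17,
unclassified 0.15 → population ≈ 0.21), with nested reactivation of 40% by
24 h and 70% by 48 h. Dark exposure and ear plugging are reversible
(stimulus responses present at the 48 h test). Network-correlated spines'
event amplitudes scale ×1.1/1.2/1.3 at 12/24/48 h (RSC: ×1.3 at 48 h),
modulated by a branch-level gain (N(1, 0.25), clipped at 0) that also
scales the branch's dendritic amplitudes — this branch-shared component is
what couples global dendritic changes to network-spine changes. A
TNF-α-blockade flag forces all scalings to 1. Sham does nothing.

**Calibrated defaults.** Quantities the source conditions do not pin down
(event amplitude scale, noise SD, smoothing, drift) were chosen — once —
so that the detected-event statistics reproduce the analytic
dummy-stimulus false-positive level 1 − e^{−λ/2} ≈ 5.5% at λ = 0.113 Hz:
near-threshold amplitudes keep supra-threshold tails short (merging loss
~10%), which residual chatter approximately returns. Noise and drift are
low enough that silenced spines stay below the 15% threshold (a noise SD
of 0.05 would put the threshold at 3σ and flood silenced spines with false
events; drift of 0.2 F-units at 360 s leaves a percentile residual that
does the same).

## What the synthetic tests do and do not show

Passing recovery tests demonstrate that the pipeline is internally
consistent: it reads back the population quantities the generator planted,
at realistic SNR, with the documented detector biases. They do not
demonstrate performance on real recordings, where motion artefacts,
z-drift, neuropil contamination, non-Poisson event statistics,
indicator nonlinearity and saturation, and behavioural covariates all
exist and are not modelled. The generator also assumes exact spine
identity across sessions (no tracking errors) and stationary mice
throughout.

## Numerical choices and degenerate inputs

Percentiles follow `np.percentile` linear interpolation exactly. The IRLS
falls back to unit weights if the bisquare zeroes every sample, and errors
on zero-variance regressors. Correlations error on constant tracks and on
traces shorter than the track. `timelocked_pct` requires ≥1 presentation;
the sparse test ≥50 trials; the network signal ≥3 spines. OSI is NaN for
all-zero responses. Event areas extend half a sample into the flanking
sub-threshold samples so a rectangular pulse of width w has area exactly
(h − θ)·w. All randomness flows from explicit seeds via `SeedSequence`;
identical (config, seed) re-runs are bit-identical.
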