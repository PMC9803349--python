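"""End-to-end orchestration: preprocess -> events -> classify -> population.

`run_study` drives the whole pipeline on a synthetic study (or
`run_pipeline` on an on-disk session bundle): per session it converts raw
ROI fluorescence to drift-corrected ΔF/F, removes the dendritic bleed by
robust subtraction, detects events and computes activity metrics; baseline
sessions feed the functional classification; all sessions feed the
longitudinal homeostasis analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import events as _events
from . import population as _population
from . import preprocess as _preprocess
from .config import GeneratorConfig
from .schedule import StimulusSchedule, binarize_stimulus, dummy_track_onsets
from .synthgen import GroundTruth, assign_population, generate_session

log = logging.getLogger("spinecalc")

__all__ = [
    "PipelineConfig",
    "SessionResult",
    "StudyResult",
    "process_session",
    "classify_baseline",
    "class_proportions",
    "run_study",
    "run_pipeline",
    "evoked_direction_amplitudes",
    "branch_evoked_amplitude",
    "branch_evoked_change",
]


@dataclass
class PipelineConfig:
    """Analysis-side knobs (the generator has its own config)."""

    threshold_policy: str = "fixed"  # fixed 15% ΔF/F; rms / max / mad available
    smooth_window_s: float = _events.DEFAULT_SMOOTH_S
    correlation_method: str = "circular"  # or "parametric"
    alpha: float = 0.05
    timelock_alpha: float = 0.01  # exceedance test for "above chance" locking
    timelock_window_s: float = 0.5
    per_epoch_alpha: bool = False  # robust slope per epoch instead of full session
    track_min_on_s: float = 2.0  # extend brief stimuli in the correlation track
    sparse_alpha: float = 0.002  # sparse-responder decision, vs empirical null
    dummy_seed: int = 7919

    def to_dict(self):
        return asdict(self)


@dataclass
class SessionResult:
    """Processed single session for a set of spines."""

    timepoint_hr: float
    sampling_rate: float
    spine_ids: list[str]
    spine_specific: np.ndarray  # (n, T)
    dend_dff: np.ndarray
    alphas: np.ndarray
    alpha_iters: np.ndarray
    alpha_converged: np.ndarray
    event_series: list
    metrics: pd.DataFrame
    schedule: StimulusSchedule

    @property
    def duration_s(self) -> float:
        return self.spine_specific.shape[1] / self.sampling_rate


def _dff_matrix(raw: np.ndarray, fs: float) -> np.ndarray:
    out = np.empty_like(raw, dtype=np.float64)
    for i in range(raw.shape[0]):
        out[i] = _preprocess.compute_dff(raw[i], fs).samples
    return out


def process_session(spine_raw: np.ndarray, dend_raw: np.ndarray, fs: float,
                    spine_ids: list[str], timepoint_hr: float,
                    schedule: StimulusSchedule,
                    pcfg: PipelineConfig | None = None) -> SessionResult:
    """Preprocess and detect events for one session.

    ``spine_raw`` / ``dend_raw`` are (n_spines, T) raw fluorescence arrays,
    row i of ``dend_raw`` being the dendrite ROI paired with spine i.
    """
    pcfg = pcfg or PipelineConfig()
    sdff = _dff_matrix(spine_raw, fs)
    ddff = _dff_matrix(dend_raw, fs)
    if pcfg.per_epoch_alpha:
        alphas = np.empty(sdff.shape[0])
        iters = np.zeros(sdff.shape[0], dtype=int)
        conv = np.ones(sdff.shape[0], dtype=bool)
        sspec = np.empty_like(sdff)
        for ep in schedule.epochs:
            a = int(round(ep.start_s * fs))
            b = int(round(ep.end_s * fs))
            al, it, cv = _preprocess.robust_slope_batch(sdff[:, a:b], ddff[:, a:b])
            sspec[:, a:b] = sdff[:, a:b] - al[:, None] * ddff[:, a:b]
            alphas, iters, conv = al, np.maximum(iters, it), conv & cv
    else:
        alphas, iters, conv = _preprocess.robust_slope_batch(sdff, ddff)
        sspec = sdff - alphas[:, None] * ddff

    series = []
    rows = []
    sid = f"t{timepoint_hr:g}"
    for i, spine_id in enumerate(spine_ids):
        es = _events.extract_events(sspec[i], fs, spine_id=spine_id,
                                    session_id=sid,
                                    threshold_policy=pcfg.threshold_policy,
                                    smooth_window_s=pcfg.smooth_window_s)
        series.append(es)
        m = _events.session_metrics(es)
        m["timepoint_hr"] = timepoint_hr
        m["alpha"] = alphas[i]
        rows.append(m)
    return SessionResult(timepoint_hr=timepoint_hr, sampling_rate=fs,
                         spine_ids=list(spine_ids), spine_specific=sspec,
                         dend_dff=ddff, alphas=alphas, alpha_iters=iters,
                         alpha_converged=conv, event_series=series,
                         metrics=pd.DataFrame(rows), schedule=schedule)


# ---------------------------------------------------------------------------
# baseline classification
# ---------------------------------------------------------------------------


def _concat_sessions(sessions: list[SessionResult]):
    """Concatenate spine-specific traces, event onsets and session offsets."""
    X = np.concatenate([s.spine_specific for s in sessions], axis=1)
    n = X.shape[0]
    offsets = np.cumsum([0.0] + [s.duration_s for s in sessions[:-1]])
    ev_onsets = [np.concatenate([s.event_series[i].onsets() + off
                                 for s, off in zip(sessions, offsets)])
                 for i in range(n)]
    return X, ev_onsets, offsets


def classify_baseline(sessions: list[SessionResult], region: str,
                      pcfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Classify every spine from its baseline sessions.

    Returns one row per spine with the full diagnostics (stimulus and network
    correlations, time-locked percentages, per-spine false-positive rates and
    critical thresholds, sparse-noise responsiveness) and the label.
    """
    pcfg = pcfg or PipelineConfig()
    fs = sessions[0].sampling_rate
    spine_ids = sessions[0].spine_ids
    X, ev_onsets, offsets = _concat_sessions(sessions)
    n, _T = X.shape

    modalities = [("vis", "gratings")]
    if region == "RSC":
        modalities.append(("aud", "auditory"))

    diag = pd.DataFrame({"spine_id": spine_ids})

    r_net, p_net = _classify.network_correlation_batch(
        X, method=pcfg.correlation_method)
    diag["r_net"], diag["p_net"] = r_net, p_net

    for tag, modality in modalities:
        track = np.concatenate([
            binarize_stimulus(s.schedule, modality, s.spine_specific.shape[1],
                              fs, min_on_s=pcfg.track_min_on_s)
            for s in sessions])
        # correlate over this modality's epochs plus the dark epochs: other
        # stimuli's evoked activity would count against the track, and the
        # dark epoch breaks the periodicity of the stimulation blocks, which
        # the circular-shift null needs to decorrelate shifted copies
        mask = np.zeros(track.size, dtype=bool)
        guard_s = 5.0  # let excluded-stimulus transient tails decay
        pos = 0
        for s in sessions:
            ns = s.spine_specific.shape[1]
            for ep in s.schedule.epochs:
                if ep.modality in (modality, "dark"):
                    a = pos + int(round(ep.start_s * fs))
                    b = pos + int(round(ep.end_s * fs))
                    mask[a:min(b, pos + ns)] = True
            for ep in s.schedule.epochs:
                if ep.modality not in (modality, "dark"):
                    a = pos + int(round(ep.start_s * fs))
                    b = pos + int(round((ep.end_s + guard_s) * fs))
                    mask[a:min(b, pos + ns)] = False
            pos += ns
        r, p = _classify.correlate_batch(X[:, mask], track[mask],
                                         method=pcfg.correlation_method)
        diag[f"r_stim_{tag}"], diag[f"p_stim_{tag}"] = r, p

        pres = np.concatenate([s.schedule.onsets(modality) + off
                               for s, off in zip(sessions, offsets)])
        dummy = np.concatenate([
            dummy_track_onsets(s.schedule, modality,
                               seed=pcfg.dummy_seed + k) + off
            for k, (s, off) in enumerate(zip(sessions, offsets))])
        locked = np.array([_classify.timelocked_pct(ev_onsets[i], pres,
                                                    pcfg.timelock_window_s)
                           for i in range(n)])
        fp = np.array([_classify.false_positive_threshold(
            ev_onsets[i], dummy, pcfg.timelock_window_s) for i in range(n)])
        pop_fp = float(np.mean(fp))
        thr = np.array([_classify.above_chance_threshold_pct(
            fp[i], pres.size, population_fp_pct=pop_fp,
            alpha=pcfg.timelock_alpha) for i in range(n)])
        diag[f"timelocked_{tag}_pct"] = locked
        diag[f"fp_{tag}_pct"] = fp
        diag[f"fp_threshold_{tag}_pct"] = thr

    sparse_onsets = np.concatenate([s.schedule.onsets("sparse_noise") + off
                                    for s, off in zip(sessions, offsets)])
    if sparse_onsets.size >= _classify.MIN_SPARSE_TRIALS:
        # empirical trial-outlier null: dummy sparse trials in the dark
        null_onsets = np.concatenate([
            dummy_track_onsets(s.schedule, "sparse_noise",
                               seed=pcfg.dummy_seed + 101 + k) + off
            for k, (s, off) in enumerate(zip(sessions, offsets))])
        real_counts = np.zeros(n, dtype=int)
        null_counts = np.zeros(n, dtype=int)
        n_null = 0
        for i in range(n):
            rf, nf = _classify.sparse_trial_outliers(X[i], sparse_onsets, fs,
                                                     null_onsets)
            real_counts[i], null_counts[i] = rf.sum(), nf.sum()
            n_null = nf.size
        from scipy import stats as _st
        p0 = float(_st.chi2.sf(_classify.MAHALANOBIS_CUT ** 2, df=2))
        pooled = float(null_counts.sum()) / max(n * n_null, 1)
        flags = np.array([
            _classify.sparse_responder_decision(
                int(real_counts[i]), sparse_onsets.size,
                max(p0, pooled, null_counts[i] / max(n_null, 1)),
                alpha=pcfg.sparse_alpha)
            for i in range(n)])
        diag["sparse_noise_responsive"] = flags
        diag["sparse_trial_count"] = real_counts

    diag["label"] = [
        _classify.classify_spine(row, region=region).label
        for row in diag.to_dict("records")
    ]
    return diag


def class_proportions(classes: pd.DataFrame) -> dict:
    """Per-class percentages among included (non-excluded) spines, plus the
    percentage with a significant positive network correlation."""
    inc = classes[classes.label != "excluded"]
    n = len(inc)
    out = {f"pct_{lab}": 100.0 * float((inc.label == lab).sum()) / n
           for lab in _classify.LABELS if lab != "excluded"}
    out["pct_network_significant"] = 100.0 * float(
        ((inc.r_net > 0) & (inc.p_net < 0.05)).sum()) / n
    out["n_included"] = n
    out["n_excluded"] = int((classes.label == "excluded").sum())
    return out


# ---------------------------------------------------------------------------
# evoked responses (OSI, global dendritic analysis)
# ---------------------------------------------------------------------------


def evoked_direction_amplitudes(session: SessionResult, spine_index: int
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Mean event area per grating direction for one spine in one session.

    An event counts toward a presentation when its onset falls inside the
    presentation window (onset .. onset + duration + 0.5 s).
    """
    es = session.event_series[spine_index]
    onsets = es.onsets()
    amps = np.array([e.amplitude for e in es.events])
    pres = session.schedule.presentations("gratings")
    dirs = sorted({p.attributes["direction"] for p in pres})
    means = []
    for d in dirs:
        vals = []
        for p in pres:
            if p.attributes["direction"] != d:
                continue
            m = (onsets >= p.onset_s) & (onsets <= p.onset_s + p.duration_s + 0.5)
            vals.extend(amps[m])
        means.append(np.mean(vals) if vals else 0.0)
    return np.array(dirs, dtype=float), np.array(means)


def branch_evoked_amplitude(session: SessionResult, rois: pd.DataFrame,
                            modality: str = "gratings",
                            pcfg: PipelineConfig | None = None) -> pd.Series:
    """Per-branch global dendritic evoked amplitude: mean area of dendrite
    events whose onset falls in a stimulus presentation window.

    The branch trace is the mean of the branch's paired-dendrite ROI ΔF/F
    series (the ROIs share the branch signal and differ only in noise).
    """
    pcfg = pcfg or PipelineConfig()
    fs = session.sampling_rate
    pres = session.schedule.presentations(modality)
    windows = [(p.onset_s, p.onset_s + p.duration_s + 0.5) for p in pres]
    out = {}
    branch_of = rois.set_index("spine_id")["branch_id"]
    groups = pd.Series(session.spine_ids).map(branch_of)
    for b in sorted(groups.unique()):
        idx = np.flatnonzero(groups.to_numpy() == b)
        dend = session.dend_dff[idx].mean(axis=0)
        es = _events.extract_events(dend, fs,
                                    threshold_policy=pcfg.threshold_policy,
                                    smooth_window_s=pcfg.smooth_window_s)
        amps = [e.amplitude for e in es.events
                if any(a <= e.onset_s <= bb for a, bb in windows)]
        out[b] = float(np.mean(amps)) if amps else np.nan
    return pd.Series(out, name="branch_evoked")


def branch_evoked_change(sessions: list[SessionResult], rois: pd.DataFrame,
                         baseline_timepoints: tuple | list,
                         timepoint_hr: float, modality: str = "gratings",
                         pcfg: PipelineConfig | None = None) -> pd.Series:
    """Normalised % change of the global dendritic evoked amplitude per branch."""
    per_tp = {s.timepoint_hr: branch_evoked_amplitude(s, rois, modality, pcfg)
              for s in sessions}
    df = pd.DataFrame(per_tp)
    base = df[list(baseline_timepoints)].mean(axis=1)
    change = 100.0 * (df[timepoint_hr] - base) / base
    change[base <= 0] = np.nan
    return change


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    config: GeneratorConfig
    truth: GroundTruth | None
    classes: pd.DataFrame
    proportions: dict
    metrics: pd.DataFrame  # all sessions
    longitudinal: pd.DataFrame
    sessions: list[SessionResult] = field(default_factory=list)


def run_study(cfg: GeneratorConfig, pcfg: PipelineConfig | None = None,
              keep_sessions: bool = False, classify_spines: bool = True,
              baseline_timepoints: list[float] | None = None) -> StudyResult:
    """Simulate a study from ``cfg`` and run the full pipeline on it.

    Baseline sessions (timepoints before the deprivation onset, or all
    timepoints for a sham/baseline run) feed classification; every session
    contributes activity metrics to the longitudinal table.
    """
    pcfg = pcfg or PipelineConfig()
    truth = assign_population(cfg)
    onset = cfg.deprivation.onset_hr if cfg.deprivation.paradigm != "sham" else np.inf
    if baseline_timepoints is None:
        baseline_timepoints = [t for t in cfg.timepoints if t < onset]
        if not baseline_timepoints:
            baseline_timepoints = list(cfg.timepoints)

    kept: list[SessionResult] = []
    all_metrics = []
    baseline_sessions = []
    for tp in cfg.timepoints:
        traces, _ev, sched = generate_session(cfg, truth, tp)
        res = process_session(traces.spine_traces, traces.dend_traces,
                              cfg.sampling_rate, traces.spine_ids, tp, sched,
                              pcfg)
        log.info("processed session t=%g hr: %d spines, %.0f s", tp,
                 len(res.spine_ids), res.duration_s)
        all_metrics.append(res.metrics)
        if tp in baseline_timepoints:
            baseline_sessions.append(res)
        if keep_sessions:
            kept.append(res)
        del traces

    if classify_spines:
        classes = classify_baseline(baseline_sessions, cfg.region, pcfg)
        props = class_proportions(classes)
        labels = classes.set_index("spine_id")["label"]
    else:
        classes = pd.DataFrame({"spine_id": baseline_sessions[0].spine_ids})
        props = {}
        labels = None

    metrics = pd.concat(all_metrics, ignore_index=True)
    longitudinal = _population.align_longitudinal(metrics, labels)
    return StudyResult(config=cfg, truth=truth, classes=classes,
                       proportions=props, metrics=metrics,
                       longitudinal=longitudinal,
                       sessions=kept if keep_sessions else baseline_sessions)


# ---------------------------------------------------------------------------
# on-disk bundles (CLI path)
# ---------------------------------------------------------------------------


def load_bundle_sessions(bundle_dir: str | Path,
                         pcfg: PipelineConfig | None = None
                         ) -> tuple[list[SessionResult], pd.DataFrame, str]:
    """Read an on-disk session bundle and preprocess every session.

    Returns (sessions, rois, region).
    """
    from .schedule import EpochSchedule, Presentation
    from .synthgen import read_bundle

    pcfg = pcfg or PipelineConfig()
    bundle = read_bundle(bundle_dir)
    rois = bundle["rois"]
    region = str(rois.region.iloc[0])
    sessions = []
    for tp in sorted(bundle["sessions"]):
        sess = bundle["sessions"][tp]
        eps = []
        for e in bundle["schedule"][str(tp)]:
            eps.append(EpochSchedule(
                modality=e["modality"], start_s=e["start_s"],
                duration_s=e["duration_s"],
                presentations=[Presentation(p["onset_s"], p["duration_s"],
                                            p.get("attributes", {}))
                               for p in e["presentations"]]))
        sched = StimulusSchedule(
            epochs=eps,
            session_duration_s=sum(e["duration_s"]
                                   for e in bundle["schedule"][str(tp)]))
        res = process_session(sess["spines"], sess["dendrites"],
                              sess["sampling_rate"], sess["spine_ids"], tp,
                              sched, pcfg)
        sessions.append(res)
    return sessions, rois, region


def run_pipeline(bundle_dir: str | Path, outdir: str | Path,
                 region: str | None = None,
                 pcfg: PipelineConfig | None = None) -> Path:
    """Run preprocess -> events -> classify -> population on a session bundle
    and write stage outputs plus a manifest."""
    pcfg = pcfg or PipelineConfig()
    sessions, rois, bundle_region = load_bundle_sessions(bundle_dir, pcfg)
    region = region or bundle_region
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    baseline = [s for s in sessions if s.timepoint_hr < 0.0] or sessions
    classes = classify_baseline(baseline, region, pcfg)
    props = class_proportions(classes)
    metrics = pd.concat([s.metrics for s in sessions], ignore_index=True)
    table = _population.align_longitudinal(
        metrics, classes.set_index("spine_id")["label"])

    ev_rows = []
    for s in sessions:
        for es in s.event_series:
            for e in es.events:
                ev_rows.append((es.spine_id, es.session_id, e.onset_s,
                                e.peak_s, e.offset_s, e.amplitude))
    pd.DataFrame(ev_rows, columns=["spine_id", "session_id", "onset_s",
                                   "peak_s", "offset_s", "amplitude"]) \
        .to_csv(outdir / "events.csv", index=False)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    classes.to_csv(outdir / "classes.csv", index=False)
    table.to_csv(outdir / "longitudinal.csv", index=False)
    pd.DataFrame({
        "spine_id": sessions[0].spine_ids,
        "alpha": sessions[0].alphas,
        "n_iter": sessions[0].alpha_iters,
        "converged": sessions[0].alpha_converged,
    }).to_csv(outdir / "alpha.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(props, indent=1))
    manifest = {
        "bundle": str(bundle_dir),
        "pipeline_config": pcfg.to_dict(),
        "n_spines": len(sessions[0].spine_ids),
        "timepoints": [s.timepoint_hr for s in sessions],
        "rows": {"events": len(ev_rows), "metrics": len(metrics),
                 "classes": len(classes), "longitudinal": len(table)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
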