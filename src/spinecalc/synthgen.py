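"""Synthetic multi-session spine/dendrite recordings with known ground truth.

The generator emulates the study's recordings at the level of extracted ROI
traces.  Per session and spine it draws:

* a homogeneous Poisson background event train (default 0.113 Hz),
* inherited events from a region-wide latent "network" train (0.25 Hz),
  each inherited independently with the spine's coupling weight,
* stimulus-locked events for sensory-responsive spines (direction-tuned for
  gratings, burst-locked for auditory, per-trial for sparse noise),

convolves them with a GCaMP6s-like difference-of-exponentials kernel, and
renders spine and paired dendrite ROI traces.  The dendrite ROI carries the
branch-level global signal (latent plus all evoked events of spines on the
branch — the back-propagating action-potential proxy), a fraction alpha of
which bleeds into each spine ROI.  Gaussian measurement noise and slow
sinusoidal drift are added on top of a positive baseline F0.

Deprivation paradigms silence spines class-dependently at the first
post-deprivation session (with partial reactivation later), optionally delete
the deprived modality's evoked events, and scale event amplitudes of
network-correlated spines (blocked when TNF-α signalling is inhibited).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import CLASSES, GeneratorConfig, GRATING_DIRECTIONS
from .schedule import StimulusSchedule, make_schedule

__all__ = [
    "GroundTruth",
    "SessionEvents",
    "TraceMatrix",
    "transient_kernel",
    "assign_population",
    "simulate_events",
    "render_traces",
    "generate_session",
    "generate_study",
    "write_bundle",
    "read_bundle",
]


# ---------------------------------------------------------------------------
# kernel and tuning
# ---------------------------------------------------------------------------


def transient_kernel(sampling_rate: float, rise_s: float = 0.18,
                     decay_s: float = 1.8, length_factor: float = 10.0
                     ) -> np.ndarray:
    """Difference-of-exponentials transient sampled at ``sampling_rate``,
    normalised so its continuous-time peak equals 1."""
    t = np.arange(0.0, length_factor * decay_s, 1.0 / sampling_rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    t_peak = (rise_s * decay_s / (decay_s - rise_s)) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def direction_tuning(cfg: GeneratorConfig, delta_deg: np.ndarray) -> np.ndarray:
    """Relative response probability versus angular offset from preferred.

    Orientation-tuned with a direction preference: w(Δ) =
    exp(kappa(cosΔ-1)) + balance*exp(kappa(-cosΔ-1)), normalised to w(0)=1.
    """
    d = np.deg2rad(np.asarray(delta_deg, dtype=float))
    k, b = cfg.tuning_kappa, cfg.tuning_direction_balance
    w = np.exp(k * (np.cos(d) - 1.0)) + b * np.exp(k * (-np.cos(d) - 1.0))
    w0 = 1.0 + b * np.exp(-2.0 * k)
    return w / w0


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# population ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-spine construction-defined truth for a synthetic study."""

    spines: pd.DataFrame  # one row per spine
    branch_gain: dict[int, float]
    branch_pref: dict[int, int]  # branch-preferred grating direction (deg)
    silenced: pd.DataFrame  # (spine_id, timepoint_hr, silenced)
    config: GeneratorConfig

    def true_class(self) -> pd.Series:
        return self.spines.set_index("spine_id")["true_class"]

    def is_silenced(self, timepoint_hr: float) -> pd.Series:
        sub = self.silenced[self.silenced.timepoint_hr == timepoint_hr]
        return sub.set_index("spine_id")["silenced"]


def assign_population(cfg: GeneratorConfig) -> GroundTruth:
    """Assign classes, branch layout, coupling, alpha, baselines, tuning.

    Class counts are deterministic (rounded mixture fractions) so the fixture
    realises the configured proportions exactly up to integer rounding; the
    assignment of classes to branch positions is random and independent of
    position.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 1001)))
    n = cfg.n_spines

    # deterministic class counts (largest-remainder rounding)
    raw = {c: cfg.class_mixture.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    rem = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)[:rem]:
        counts[c] += 1
    labels = np.concatenate([np.full(counts[c], i)
                             for i, c in enumerate(CLASSES)])
    labels = labels[rng.permutation(n)]
    true_class = np.array(CLASSES, dtype=object)[labels]

    # branches of 8-15 spines, positions independent of class
    lo, hi = cfg.branch_size_range
    sizes = []
    while sum(sizes) < n:
        sizes.append(int(rng.integers(lo, hi + 1)))
    sizes[-1] = n - sum(sizes[:-1])
    if sizes[-1] < 2 and len(sizes) > 1:  # fold a runt branch into the previous
        sizes[-2] += sizes[-1]
        sizes.pop()
    branch_id = np.concatenate([np.full(s, b) for b, s in enumerate(sizes)])
    position = np.concatenate([np.arange(s) for s in sizes])

    responsive = np.isin(true_class, ("visual", "auditory"))
    coupled = true_class != "unclassified"
    has_sparse = any(e.modality == "sparse_noise" for e in cfg.session_layout)
    sparse_resp = np.zeros(n, dtype=bool)
    if has_sparse:
        vis = np.flatnonzero(true_class == "visual")
        sparse_resp[vis] = True
        # a few network-only spines respond to sparse noise but not gratings,
        # setting the configured sparse/gratings responder overlap
        n_only = int(round(vis.size * (1.0 / cfg.sparse_overlap - 1.0)))
        net = np.flatnonzero(true_class == "network_only")
        sparse_resp[rng.choice(net, size=min(n_only, net.size), replace=False)] = True

    spines = pd.DataFrame({
        "spine_id": [f"sp{i:05d}" for i in range(n)],
        "dendrite_roi_id": [f"dn{i:05d}" for i in range(n)],
        "branch_id": branch_id.astype(int),
        "position_index": position.astype(int),
        "region": cfg.region,
        "true_class": true_class,
        "coupling_weight": np.where(coupled, cfg.coupling_weight, 0.0),
        "alpha_true": rng.uniform(*cfg.alpha_range, n),
        "f0_spine": rng.uniform(*cfg.f0_range, n),
        "f0_dendrite": rng.uniform(*cfg.f0_range, n),
        "pref_direction": np.where(
            true_class == "visual",
            rng.choice(GRATING_DIRECTIONS, n), -1).astype(int),
        "sparse_responder": sparse_resp,
    })

    gains = rng.normal(1.0, cfg.branch_scale_sd, len(sizes)).clip(min=0.0)
    branch_gain = {b: float(g) for b, g in enumerate(gains)}
    branch_pref = {b: int(d) for b, d in
                   enumerate(rng.choice(GRATING_DIRECTIONS, len(sizes)))}

    # deprivation: silencing and nested reactivation
    dep = cfg.deprivation
    post = [t for t in cfg.timepoints if t >= dep.onset_hr] \
        if dep.paradigm != "sham" else []
    rows = []
    if post and dep.inactivation_prob_by_class:
        p_sil = np.array([dep.inactivation_prob_by_class.get(c, 0.0)
                          for c in true_class])
        sil0 = rng.random(n) < p_sil
        u = rng.random(n)  # nested reactivation: active again at t if u < curve[t]
        first = min(post)
        for t in post:
            if t == first:
                sil_t = sil0
            else:
                frac = dep.reactivation_curve.get(t, 0.0)
                sil_t = sil0 & (u >= frac)
            rows.extend(zip(spines.spine_id, [t] * n, sil_t))
    silenced = pd.DataFrame(rows, columns=["spine_id", "timepoint_hr", "silenced"]) \
        if rows else pd.DataFrame(columns=["spine_id", "timepoint_hr", "silenced"])

    return GroundTruth(spines=spines, branch_gain=branch_gain,
                       branch_pref=branch_pref, silenced=silenced, config=cfg)


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------


@dataclass
class SessionEvents:
    """Ground-truth event trains for one session."""

    timepoint_hr: float
    duration_s: float
    latent_times: np.ndarray
    spine_times: list[np.ndarray]  # per spine, sorted
    spine_amps: list[np.ndarray]
    spine_origin: list[np.ndarray]  # 'b' background / 'l' latent / 'e' evoked / 's' sparse
    dend_times: dict[int, np.ndarray]  # per branch
    dend_amps: dict[int, np.ndarray]

    def events_frame(self, truth: GroundTruth) -> pd.DataFrame:
        recs = []
        for i, sid in enumerate(truth.spines.spine_id):
            for t, a, o in zip(self.spine_times[i], self.spine_amps[i],
                               self.spine_origin[i]):
                recs.append((sid, self.timepoint_hr, t, a, o))
        return pd.DataFrame(
            recs, columns=["spine_id", "timepoint_hr", "time_s", "amplitude", "origin"])


def _poisson_times(rng: np.random.Generator, rate: float, duration: float
                   ) -> np.ndarray:
    k = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, k))


def simulate_events(cfg: GeneratorConfig, schedule: StimulusSchedule,
                    truth: GroundTruth, timepoint_hr: float) -> SessionEvents:
    """Draw ground-truth event trains for one session at ``timepoint_hr``."""
    if timepoint_hr not in cfg.timepoints:
        raise ValueError(f"timepoint {timepoint_hr} not in config.timepoints")
    si = cfg.timepoints.index(timepoint_hr)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 2001, si)))
    T = schedule.session_duration_s
    n = cfg.n_spines
    sp = truth.spines
    dep = cfg.deprivation
    deprived_now = dep.paradigm != "sham" and timepoint_hr >= dep.onset_hr

    latent = _poisson_times(rng, cfg.latent_rate, T)

    grat_pres = schedule.presentations("gratings")
    grat_onsets = np.array([p.onset_s for p in grat_pres])
    grat_dirs = np.array([p.attributes["direction"] for p in grat_pres])
    aud_onsets = schedule.onsets("auditory")
    sparse_onsets = schedule.onsets("sparse_noise")

    silenced = (truth.is_silenced(timepoint_hr).to_numpy()
                if deprived_now and len(truth.silenced) else np.zeros(n, bool))

    times_l, amps_l, orig_l = [], [], []
    for i in range(n):
        cls = sp.true_class.iloc[i]
        parts, origins = [], []

        bg = _poisson_times(rng, cfg.background_rate, T)
        parts.append(bg)
        origins.append(np.full(bg.size, "b"))

        w = sp.coupling_weight.iloc[i]
        if w > 0 and latent.size:
            inh = latent[rng.random(latent.size) < w]
            parts.append(inh)
            origins.append(np.full(inh.size, "l"))

        evoked_removed = (deprived_now and dep.remove_evoked)
        if cls == "visual" and grat_onsets.size and not (
                evoked_removed and dep.deprived_modality == "gratings"):
            delta = grat_dirs - sp.pref_direction.iloc[i]
            p = cfg.stim_response_prob * direction_tuning(cfg, delta)
            hit = rng.random(p.size) < p
            ev = grat_onsets[hit] + rng.uniform(0.0, cfg.latency_jitter_s,
                                                int(hit.sum()))
            parts.append(ev)
            origins.append(np.full(ev.size, "e"))
        if cls == "auditory" and aud_onsets.size and not (
                evoked_removed and dep.deprived_modality == "auditory"):
            hit = rng.random(aud_onsets.size) < cfg.stim_response_prob
            ev = aud_onsets[hit] + rng.uniform(0.0, cfg.latency_jitter_s,
                                               int(hit.sum()))
            parts.append(ev)
            origins.append(np.full(ev.size, "e"))

        t_i = np.concatenate(parts) if parts else np.empty(0)
        o_i = np.concatenate(origins) if origins else np.empty(0, dtype="U1")
        a_i = _lognormal(rng, cfg.event_amp_mean, cfg.event_amp_cv, t_i.size)
        a_i[o_i == "e"] *= cfg.evoked_amp_scale

        if sp.sparse_responder.iloc[i] and sparse_onsets.size and not (
                evoked_removed and dep.deprived_modality == "gratings"):
            hit = rng.random(sparse_onsets.size) < cfg.sparse_hit_prob
            ev = sparse_onsets[hit]
            t_i = np.concatenate([t_i, ev])
            o_i = np.concatenate([o_i, np.full(ev.size, "s")])
            a_i = np.concatenate(
                [a_i, _lognormal(rng, cfg.sparse_amp_mean, cfg.sparse_amp_cv,
                                 ev.size)])

        if silenced[i]:
            t_i, a_i, o_i = np.empty(0), np.empty(0), np.empty(0, dtype="U1")

        if deprived_now and not dep.tnf_blocked:
            scale = dep.scaling(cls, timepoint_hr)
            if scale != 1.0:
                gain = truth.branch_gain[int(sp.branch_id.iloc[i])]
                a_i = a_i * (1.0 + (scale - 1.0) * gain)

        order = np.argsort(t_i)
        times_l.append(t_i[order])
        amps_l.append(a_i[order])
        orig_l.append(o_i[order])

    # branch-level global (bAP) trains: the cell fires on a fraction of the
    # latent network events, has its own background spikes, and responds to
    # the stimulus with branch-level direction tuning.  It is deliberately
    # only partially coupled to any one spine's event train: a fully shared
    # train would make spine coupling and dendritic bleed collinear and the
    # bleed slope unidentifiable.
    dend_times: dict[int, np.ndarray] = {}
    dend_amps: dict[int, np.ndarray] = {}
    net_scale = dep.scaling("network_only", timepoint_hr) if deprived_now else 1.0
    evoked_removed = deprived_now and dep.remove_evoked
    for b in sp.branch_id.unique():
        parts_b = [latent[rng.random(latent.size) < cfg.bap_latent_prob],
                   _poisson_times(rng, cfg.dend_background_rate, T)]
        if grat_onsets.size and not (evoked_removed
                                     and dep.deprived_modality == "gratings"):
            delta = grat_dirs - truth.branch_pref[int(b)]
            p = cfg.branch_response_prob * direction_tuning(cfg, delta)
            hit = rng.random(p.size) < p
            parts_b.append(grat_onsets[hit]
                           + rng.uniform(0.0, cfg.latency_jitter_s, int(hit.sum())))
        if aud_onsets.size and cfg.region == "RSC" and not (
                evoked_removed and dep.deprived_modality == "auditory"):
            hit = rng.random(aud_onsets.size) < cfg.branch_auditory_prob
            parts_b.append(aud_onsets[hit]
                           + rng.uniform(0.0, cfg.latency_jitter_s, int(hit.sum())))
        t_b = np.sort(np.concatenate(parts_b))
        a_b = _lognormal(rng, cfg.dend_amp_mean, cfg.dend_amp_cv, t_b.size)
        if deprived_now and not dep.tnf_blocked and net_scale != 1.0:
            a_b = a_b * (1.0 + (net_scale - 1.0) * truth.branch_gain[int(b)])
        dend_times[int(b)] = t_b
        dend_amps[int(b)] = a_b

    return SessionEvents(timepoint_hr=timepoint_hr, duration_s=T,
                         latent_times=latent, spine_times=times_l,
                         spine_amps=amps_l, spine_origin=orig_l,
                         dend_times=dend_times, dend_amps=dend_amps)


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------


@dataclass
class TraceMatrix:
    """Time-aligned raw fluorescence for all spine and dendrite ROIs."""

    time_s: np.ndarray
    spine_traces: np.ndarray  # (n_spines, n_samples), raw F
    dend_traces: np.ndarray
    spine_ids: list[str]
    dend_ids: list[str]
    sampling_rate: float
    timepoint_hr: float = 0.0
    schedule: StimulusSchedule | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.time_s.size


def _bin_events(times: np.ndarray, amps: np.ndarray, n: int, fs: float
                ) -> np.ndarray:
    out = np.zeros(n)
    if times.size:
        idx = np.clip(np.round(times * fs).astype(int), 0, n - 1)
        np.add.at(out, idx, amps)
    return out


def render_traces(cfg: GeneratorConfig, truth: GroundTruth,
                  ev: SessionEvents, schedule: StimulusSchedule | None = None
                  ) -> TraceMatrix:
    """Render raw spine/dendrite ROI fluorescence traces for one session.

    spine raw = F0s * (1 + own-signal + alpha * dendrite-signal + noise) + drift
    dendrite raw = F0d * (1 + dendrite-signal + noise) + drift
    Bit-identical for identical (config, seed, timepoint).
    """
    fs = cfg.sampling_rate
    si = cfg.timepoints.index(ev.timepoint_hr)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 3001, si)))
    n_samp = int(round(ev.duration_s * fs))
    n = cfg.n_spines
    kern = transient_kernel(fs, cfg.kernel.rise_s, cfg.kernel.decay_s)
    sp = truth.spines

    branch_sig = {}
    for b in ev.dend_times:
        deltas = _bin_events(ev.dend_times[b], ev.dend_amps[b], n_samp, fs)
        branch_sig[b] = fftconvolve(deltas, kern)[:n_samp]

    spine_deltas = np.zeros((n, n_samp))
    for i in range(n):
        spine_deltas[i] = _bin_events(ev.spine_times[i], ev.spine_amps[i],
                                      n_samp, fs)
    own = fftconvolve(spine_deltas, kern[None, :], axes=1)[:, :n_samp]

    t = np.arange(n_samp) / fs

    def drift_wave(k):
        phase = rng.uniform(0, 2 * np.pi, k)
        period = np.full(k, cfg.drift.period_s)
        return cfg.drift.amplitude * np.sin(
            2 * np.pi * t[None, :] / period[:, None] + phase[:, None])

    alpha = sp.alpha_true.to_numpy()[:, None]
    f0s = sp.f0_spine.to_numpy()[:, None]
    f0d = sp.f0_dendrite.to_numpy()[:, None]
    bsig = np.stack([branch_sig[int(b)] for b in sp.branch_id])

    spine_raw = f0s * (1.0 + own + alpha * bsig
                       + rng.normal(0.0, cfg.noise_sd, (n, n_samp))) \
        + drift_wave(n)
    dend_raw = f0d * (1.0 + bsig
                      + rng.normal(0.0, cfg.noise_sd, (n, n_samp))) \
        + drift_wave(n)

    return TraceMatrix(time_s=t, spine_traces=spine_raw, dend_traces=dend_raw,
                       spine_ids=list(sp.spine_id), dend_ids=list(sp.dendrite_roi_id),
                       sampling_rate=fs, timepoint_hr=ev.timepoint_hr,
                       schedule=schedule)


def generate_session(cfg: GeneratorConfig, truth: GroundTruth,
                     timepoint_hr: float
                     ) -> tuple[TraceMatrix, SessionEvents, StimulusSchedule]:
    si = cfg.timepoints.index(timepoint_hr)
    sched = make_schedule(cfg, si)
    ev = simulate_events(cfg, sched, truth, timepoint_hr)
    traces = render_traces(cfg, truth, ev, schedule=sched)
    return traces, ev, sched


def generate_study(cfg: GeneratorConfig):
    """Yield (traces, events, schedule) per timepoint; population drawn once."""
    truth = assign_population(cfg)
    for tp in cfg.timepoints:
        yield truth, generate_session(cfg, truth, tp)


# ---------------------------------------------------------------------------
# session bundle IO
# ---------------------------------------------------------------------------


def write_bundle(outdir: str | Path, cfg: GeneratorConfig, truth: GroundTruth,
                 sessions: list[tuple[TraceMatrix, SessionEvents, StimulusSchedule]],
                 fmt: str = "h5") -> Path:
    """Write a session bundle: traces (h5 or csv), rois.csv, schedule.json,
    ground_truth.csv, config.yaml."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.spines.to_csv(outdir / "rois.csv", index=False)

    sched_json = {}
    for tm, _ev, sched in sessions:
        sched_json[str(tm.timepoint_hr)] = [
            {
                "modality": e.modality,
                "start_s": e.start_s,
                "duration_s": e.duration_s,
                "presentations": [
                    {"onset_s": p.onset_s, "duration_s": p.duration_s,
                     "attributes": {k: v for k, v in p.attributes.items()
                                    if k != "squares"}}
                    for p in e.presentations
                ],
            }
            for e in sched.epochs
        ]
    (outdir / "schedule.json").write_text(json.dumps(sched_json, indent=1))

    frames = [ev.events_frame(truth) for _tm, ev, _s in sessions]
    pd.concat(frames, ignore_index=True).to_csv(outdir / "ground_truth.csv",
                                                index=False)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    if fmt == "h5":
        import h5py

        with h5py.File(outdir / "traces.h5", "w") as f:
            for tm, _ev, _s in sessions:
                g = f.create_group(f"t{tm.timepoint_hr}")
                g.create_dataset("time_s", data=tm.time_s)
                g.create_dataset("spines", data=tm.spine_traces,
                                 compression="gzip")
                g.create_dataset("dendrites", data=tm.dend_traces,
                                 compression="gzip")
                g.attrs["sampling_rate"] = tm.sampling_rate
                g.attrs["spine_ids"] = ",".join(tm.spine_ids)
                g.attrs["dend_ids"] = ",".join(tm.dend_ids)
    else:
        for tm, _ev, _s in sessions:
            df = pd.DataFrame({"time_s": tm.time_s})
            for j, rid in enumerate(tm.spine_ids):
                df[rid] = tm.spine_traces[j]
            for j, rid in enumerate(tm.dend_ids):
                df[rid] = tm.dend_traces[j]
            df.to_csv(outdir / f"traces_t{tm.timepoint_hr}.csv", index=False)
    return outdir


def read_bundle(bundle_dir: str | Path) -> dict:
    """Read a bundle written by :func:`write_bundle` (h5 traces)."""
    import h5py

    bundle_dir = Path(bundle_dir)
    for fname in ("rois.csv", "schedule.json"):
        if not (bundle_dir / fname).exists():
            raise FileNotFoundError(f"bundle is missing {fname}")
    rois = pd.read_csv(bundle_dir / "rois.csv")
    schedule_json = json.loads((bundle_dir / "schedule.json").read_text())
    out = {"rois": rois, "schedule": schedule_json, "sessions": {}}
    h5path = bundle_dir / "traces.h5"
    if h5path.exists():
        with h5py.File(h5path, "r") as f:
            for key in f:
                g = f[key]
                out["sessions"][float(key[1:])] = {
                    "time_s": g["time_s"][:],
                    "spines": g["spines"][:],
                    "dendrites": g["dendrites"][:],
                    "sampling_rate": float(g.attrs["sampling_rate"]),
                    "spine_ids": str(g.attrs["spine_ids"]).split(","),
                    "dend_ids": str(g.attrs["dend_ids"]).split(","),
                }
    else:
        for p in sorted(bundle_dir.glob("traces_t*.csv")):
            df = pd.read_csv(p)
            tp = float(p.stem.replace("traces_t", ""))
            spine_ids = [c for c in df.columns if c.startswith("sp")]
            dend_ids = [c for c in df.columns if c.startswith("dn")]
            out["sessions"][tp] = {
                "time_s": df["time_s"].to_numpy(),
                "spines": df[spine_ids].to_numpy().T,
                "dendrites": df[dend_ids].to_numpy().T,
                "sampling_rate": 1.0 / float(np.median(np.diff(df["time_s"]))),
                "spine_ids": spine_ids,
                "dend_ids": dend_ids,
            }
    gt_path = bundle_dir / "ground_truth.csv"
    if gt_path.exists():
        out["ground_truth"] = pd.read_csv(gt_path)
    return out
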