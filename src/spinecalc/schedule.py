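"""Stimulus schedules: drifting gratings, sparse noise, auditory bursts, dark.

A session is a sequence of epochs.  Gratings blocks present the eight
directions (0–315° in 45° steps) in random order, 3 s on / 3 s grey by
default.  Sparse-noise frames change every 250 ms, each a set of 8–12
non-overlapping black or white 8° squares.  Auditory epochs present 65 dB
white-noise bursts with uniform 3–5 s intervals.  Dark epochs contain no
presentations.  The same paradigm structure is used at every timepoint of a
run; presentation randomisation is reproducible from (seed, session index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeneratorConfig, GRATING_DIRECTIONS

__all__ = [
    "Presentation",
    "EpochSchedule",
    "StimulusSchedule",
    "make_schedule",
    "binarize_stimulus",
    "dummy_track_onsets",
]


@dataclass
class Presentation:
    onset_s: float
    duration_s: float
    # gratings: {"direction": deg}; sparse: {"squares": [(x, y, size, polarity)]}
    attributes: dict = field(default_factory=dict)


@dataclass
class EpochSchedule:
    modality: str
    start_s: float
    duration_s: float
    presentations: list[Presentation]

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def onsets(self) -> np.ndarray:
        return np.array([p.onset_s for p in self.presentations], dtype=float)


@dataclass
class StimulusSchedule:
    epochs: list[EpochSchedule]
    session_duration_s: float

    def by_modality(self, modality: str) -> list[EpochSchedule]:
        return [e for e in self.epochs if e.modality == modality]

    def presentations(self, modality: str) -> list[Presentation]:
        return [p for e in self.by_modality(modality) for p in e.presentations]

    def onsets(self, modality: str) -> np.ndarray:
        ps = self.presentations(modality)
        return np.array([p.onset_s for p in ps], dtype=float)


def _gratings_epoch(cfg: GeneratorConfig, start: float, duration: float,
                    rng: np.random.Generator) -> EpochSchedule:
    cycle = cfg.grating_on_s + cfg.grating_off_s
    pres: list[Presentation] = []
    t = start
    block = 0
    while t + 8 * cycle <= start + duration + 1e-9:
        dirs = rng.permutation(np.array(GRATING_DIRECTIONS))
        for d in dirs:
            pres.append(
                Presentation(onset_s=t, duration_s=cfg.grating_on_s,
                             attributes={"direction": int(d), "block": block})
            )
            t += cycle
        block += 1
    return EpochSchedule("gratings", start, duration, pres)


def _sparse_epoch(cfg: GeneratorConfig, start: float, duration: float,
                  rng: np.random.Generator) -> EpochSchedule:
    n_frames = int(round(duration / cfg.sparse_frame_s))
    lo, hi = cfg.sparse_squares
    pres = []
    for i in range(n_frames):
        n_sq = int(rng.integers(lo, hi + 1))
        squares = []
        occupied: list[tuple[float, float]] = []
        # random non-overlapping square centres on a nominal 100°x60° field
        while len(squares) < n_sq:
            x = float(rng.uniform(0, 100))
            y = float(rng.uniform(0, 60))
            if all(abs(x - ox) >= cfg.sparse_square_deg
                   or abs(y - oy) >= cfg.sparse_square_deg
                   for ox, oy in occupied):
                occupied.append((x, y))
                squares.append((x, y, cfg.sparse_square_deg,
                                int(rng.integers(0, 2)) * 2 - 1))
        pres.append(
            Presentation(onset_s=start + i * cfg.sparse_frame_s,
                         duration_s=cfg.sparse_frame_s,
                         attributes={"squares": squares, "frame": i})
        )
    return EpochSchedule("sparse_noise", start, duration, pres)


def _auditory_epoch(cfg: GeneratorConfig, start: float, duration: float,
                    rng: np.random.Generator) -> EpochSchedule:
    lo, hi = cfg.auditory_gap_range_s
    pres = []
    t = start + float(rng.uniform(lo, hi))
    while t + cfg.auditory_burst_s <= start + duration:
        pres.append(Presentation(onset_s=t, duration_s=cfg.auditory_burst_s,
                                 attributes={"level_db": 65}))
        t += float(rng.uniform(lo, hi))
    return EpochSchedule("auditory", start, duration, pres)


def make_schedule(cfg: GeneratorConfig, session_index: int) -> StimulusSchedule:
    """Build the stimulus schedule for one session.

    Epoch structure and durations are identical across sessions; the
    randomised content (grating order, sparse frames, burst times) is a pure
    function of (config seed, session index).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.seed, 7001, session_index))
    )
    epochs: list[EpochSchedule] = []
    t = 0.0
    for ep in cfg.session_layout:
        if ep.modality == "gratings":
            epochs.append(_gratings_epoch(cfg, t, ep.duration_s, rng))
        elif ep.modality == "sparse_noise":
            epochs.append(_sparse_epoch(cfg, t, ep.duration_s, rng))
        elif ep.modality == "auditory":
            epochs.append(_auditory_epoch(cfg, t, ep.duration_s, rng))
        else:  # dark
            epochs.append(EpochSchedule("dark", t, ep.duration_s, []))
        t += ep.duration_s
    return StimulusSchedule(epochs=epochs, session_duration_s=t)


def binarize_stimulus(schedule: StimulusSchedule, modality: str,
                      n_samples: int, sampling_rate: float,
                      min_on_s: float = 0.0) -> np.ndarray:
    """Binary stimulation track: 1 during presentations of ``modality``.

    Same length as the trace it will be correlated with.  ``min_on_s``
    extends presentations briefer than that to ``min_on_s`` of ON time, so
    that a correlation against slow-indicator traces can see responses to
    sub-second stimuli (the calcium transient outlasts a 0.5 s burst).
    """
    track = np.zeros(n_samples, dtype=np.float64)
    for p in schedule.presentations(modality):
        i0 = int(np.floor(p.onset_s * sampling_rate))
        dur = max(p.duration_s, min_on_s)
        i1 = int(np.ceil((p.onset_s + dur) * sampling_rate))
        track[max(i0, 0):min(i1, n_samples)] = 1.0
    return track


def dummy_track_onsets(schedule: StimulusSchedule, modality: str,
                       seed: int) -> np.ndarray:
    """Dummy presentation onsets laid over the dark epochs.

    Replicates the real track's presentation count and inter-onset statistics,
    shifted into the dark epochs (wrapping across dark epochs when needed) so
    that per-spine chance levels of stimulus time-locking can be measured on
    stimulus-free activity.
    """
    dark = schedule.by_modality("dark")
    if not dark:
        raise ValueError("schedule has no dark epoch; cannot build a dummy track")
    real = schedule.onsets(modality)
    if real.size == 0:
        raise ValueError(f"no {modality!r} presentations in schedule")
    gaps = np.diff(real)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 7002)))
    # rebuild an onset sequence with the same inter-onset gaps, permuted,
    # starting a short random offset into the dark span
    seq = np.concatenate([[float(rng.uniform(0.0, 2.0))],
                          rng.permutation(gaps)]).cumsum()
    spans = [(e.start_s, e.end_s) for e in dark]
    total_dark = sum(b - a for a, b in spans)
    seq = np.mod(seq, total_dark)  # wrap to keep every dummy onset in the dark
    seq.sort()
    onsets = np.empty_like(seq)
    for i, s in enumerate(seq):
        for a, b in spans:
            if s < b - a:
                onsets[i] = a + s
                break
            s -= b - a
    return onsets
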