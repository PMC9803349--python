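"""Study configuration: generator parameters, deprivation models, presets.

The generator emulates the two-photon spine-imaging study conditions:
awake-mouse recordings at 15 Hz, drifting-grating / sparse-noise / auditory /
dark epochs, Poisson background events per spine, a shared network latent
event train with per-spine coupling, GCaMP6s-like transient kernels,
dendritic signal bleed into spine ROIs, slow baseline drift, and
sensory-deprivation paradigms (enucleation, dark exposure, ear plugging)
with class-dependent silencing and TNF-α-dependent amplitude scaling of
network-correlated spines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Any

CLASSES = ("visual", "auditory", "network_only", "unclassified")
MODALITIES = ("gratings", "sparse_noise", "auditory", "dark")
PARADIGMS = ("enucleation", "dark_exposure", "ear_plug", "sham")

GRATING_DIRECTIONS = tuple(range(0, 360, 45))  # eight directions, 45° steps


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


@dataclass
class KernelParams:
    """Difference-of-exponentials calcium transient, normalised to unit peak."""

    rise_s: float = 0.18
    decay_s: float = 1.8

    def validate(self) -> None:
        if not (0 < self.rise_s < self.decay_s):
            raise ConfigError("kernel: need 0 < rise_s < decay_s")


@dataclass
class DriftParams:
    """Additive slow sinusoidal baseline wander, in fluorescence units."""

    amplitude: float = 0.1
    period_s: float = 600.0

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("drift.amplitude must be >= 0")
        if self.period_s < 120.0:
            raise ConfigError("drift.period_s must be >= 120 s")


@dataclass
class Epoch:
    modality: str
    duration_s: float

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigError(f"unknown epoch modality {self.modality!r}")
        if self.duration_s <= 0:
            raise ConfigError("epoch duration must be positive")


@dataclass
class DeprivationModel:
    """Effect of a deprivation paradigm on spine event trains.

    ``inactivation_prob_by_class`` silences spines (all events removed) at the
    first post-deprivation timepoint; ``reactivation_curve`` maps later
    timepoints (hours) to the cumulative fraction of silenced spines active
    again.  ``amp_scaling_by_class`` multiplies event amplitudes per
    post-deprivation timepoint; ``tnf_blocked`` forces all scalings to 1
    (dominant-negative TNF-α injection).  ``remove_evoked`` deletes the
    deprived modality's stimulus-locked events after onset (irreversible
    deprivation such as enucleation).
    """

    paradigm: str = "sham"
    onset_hr: float = 0.0
    deprived_modality: str = "gratings"
    inactivation_prob_by_class: dict[str, float] = field(default_factory=dict)
    reactivation_curve: dict[float, float] = field(default_factory=dict)
    amp_scaling_by_class: dict[str, dict[float, float]] = field(default_factory=dict)
    tnf_blocked: bool = False
    remove_evoked: bool = False

    def validate(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")
        for c, p in self.inactivation_prob_by_class.items():
            if c not in CLASSES:
                raise ConfigError(f"inactivation_prob_by_class: unknown class {c!r}")
            if not 0 <= p <= 1:
                raise ConfigError("inactivation probabilities must be in [0,1]")
        for f in self.reactivation_curve.values():
            if not 0 <= f <= 1:
                raise ConfigError("reactivation fractions must be in [0,1]")
        for c, curve in self.amp_scaling_by_class.items():
            if c not in CLASSES:
                raise ConfigError(f"amp_scaling_by_class: unknown class {c!r}")
            for s in curve.values():
                if s <= 0:
                    raise ConfigError("amplitude scaling factors must be > 0")
        if self.paradigm == "sham":
            if self.remove_evoked or any(
                p > 0 for p in self.inactivation_prob_by_class.values()
            ):
                raise ConfigError("sham implies no inactivation and no evoked removal")
            for curve in self.amp_scaling_by_class.values():
                if any(s != 1.0 for s in curve.values()):
                    raise ConfigError("sham implies all amplitude scalings equal 1.0")

    def scaling(self, cls: str, timepoint_hr: float) -> float:
        if self.tnf_blocked or self.paradigm == "sham":
            return 1.0
        if timepoint_hr < self.onset_hr:
            return 1.0
        return self.amp_scaling_by_class.get(cls, {}).get(timepoint_hr, 1.0)


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic multi-session spine recording."""

    seed: int = 20221214
    n_spines: int = 200
    region: str = "V1"
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "visual": 0.24,
            "auditory": 0.0,
            "network_only": 0.65,
            "unclassified": 0.11,
        }
    )
    sampling_rate: float = 15.0
    session_layout: list[Epoch] = field(
        default_factory=lambda: [Epoch("gratings", 240.0), Epoch("dark", 360.0)]
    )
    timepoints: list[float] = field(default_factory=lambda: [-24.0, -1.0])

    # event statistics
    background_rate: float = 0.113  # Hz, Poisson per spine
    stim_response_prob: float = 0.8  # at the preferred direction
    latency_jitter_s: float = 0.4
    coupling_weight: float = 0.6
    latent_rate: float = 0.25  # Hz, shared network event train
    kernel: KernelParams = field(default_factory=KernelParams)
    event_amp_mean: float = 0.20  # ΔF/F
    event_amp_cv: float = 0.2
    evoked_amp_scale: float = 1.8  # stimulus-evoked events are compound, larger
    dend_amp_mean: float = 0.5  # ΔF/F, dendritic (bAP) transients
    dend_amp_cv: float = 0.2

    # direction tuning of grating-responsive spines: relative response
    # probability w(Δ) = exp(kappa (cosΔ - 1)) + balance * exp(kappa (-cosΔ - 1)),
    # normalised to 1 at the preferred direction.
    tuning_kappa: float = 1.2
    tuning_direction_balance: float = 0.7

    # sparse-noise responses
    sparse_hit_prob: float = 0.125  # per-trial response probability
    sparse_amp_mean: float = 1.0
    sparse_amp_cv: float = 0.2
    sparse_overlap: float = 0.97  # fraction of sparse responders also grating-responsive

    # branch-level (bAP) global signal: a cell fires on a fraction of the
    # latent network events, has background spikes of its own, and gives
    # direction-tuned evoked responses at its branch-preferred direction
    bap_latent_prob: float = 0.1
    dend_background_rate: float = 0.12  # Hz
    branch_response_prob: float = 0.6  # at the branch preferred direction
    branch_auditory_prob: float = 0.3  # RSC branches, per auditory burst

    # trace rendering
    noise_sd: float = 0.025  # ΔF/F units, per ROI
    drift: DriftParams = field(default_factory=DriftParams)
    f0_range: tuple[float, float] = (1.5, 3.0)
    alpha_range: tuple[float, float] = (0.2, 0.8)

    # stimulus timing
    grating_on_s: float = 3.0
    grating_off_s: float = 3.0
    grating_blocks: int = 5
    auditory_burst_s: float = 0.5
    auditory_gap_range_s: tuple[float, float] = (3.0, 5.0)
    sparse_frame_s: float = 0.25
    sparse_squares: tuple[int, int] = (8, 12)
    sparse_square_deg: float = 8.0

    # dendritic branch layout
    branch_size_range: tuple[int, int] = (8, 15)
    branch_scale_sd: float = 0.25  # branch-level spread of homeostatic scaling

    deprivation: DeprivationModel = field(default_factory=DeprivationModel)

    def validate(self) -> None:
        if self.region not in ("V1", "RSC"):
            raise ConfigError(f"region must be V1 or RSC, got {self.region!r}")
        mix = self.class_mixture
        unknown = set(mix) - set(CLASSES)
        if unknown:
            raise ConfigError(f"class_mixture: unknown classes {sorted(unknown)}")
        if any(p < 0 for p in mix.values()):
            raise ConfigError("class_mixture entries must be nonnegative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mixture must sum to 1 (within 1e-9)")
        if self.region == "V1" and mix.get("auditory", 0.0) != 0.0:
            raise ConfigError("auditory proportion must be 0 in region V1")
        for name in (
            "sampling_rate",
            "background_rate",
            "latent_rate",
            "event_amp_mean",
            "dend_amp_mean",
            "sparse_amp_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.dend_background_rate < 0:
            raise ConfigError("dend_background_rate must be >= 0")
        for name in ("stim_response_prob", "coupling_weight", "sparse_hit_prob",
                     "sparse_overlap", "bap_latent_prob", "branch_response_prob",
                     "branch_auditory_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0,1]")
        if self.latency_jitter_s < 0 or self.noise_sd < 0:
            raise ConfigError("latency_jitter_s and noise_sd must be >= 0")
        if not self.session_layout:
            raise ConfigError("session_layout must contain at least one epoch")
        for ep in self.session_layout:
            ep.validate()
        if not self.timepoints:
            raise ConfigError("timepoints must be non-empty")
        lo, hi = self.branch_size_range
        if not (2 <= lo <= hi):
            raise ConfigError("branch_size_range must satisfy 2 <= lo <= hi")
        self.kernel.validate()
        self.drift.validate()
        self.deprivation.validate()

    @property
    def session_duration_s(self) -> float:
        return sum(ep.duration_s for ep in self.session_layout)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_V1_MIXTURE = {"visual": 0.24, "auditory": 0.0, "network_only": 0.65, "unclassified": 0.11}
_RSC_MIXTURE = {
    "visual": 0.187,
    "auditory": 0.159,
    "network_only": 0.574,
    "unclassified": 0.08,
}

_V1_LAYOUT = [Epoch("gratings", 240.0), Epoch("dark", 360.0)]
_V1_SPARSE_LAYOUT = [Epoch("gratings", 240.0), Epoch("sparse_noise", 60.0), Epoch("dark", 360.0)]
_RSC_LAYOUT = [Epoch("gratings", 240.0), Epoch("auditory", 120.0), Epoch("dark", 360.0)]

_V1_INACTIVATION = {"visual": 0.35, "network_only": 0.17, "unclassified": 0.15}
_REACTIVATION = {24.0: 0.4, 48.0: 0.7}
_NET_SCALING_V1 = {"network_only": {12.0: 1.10, 24.0: 1.20, 48.0: 1.30}}
_NET_SCALING_RSC = {"network_only": {48.0: 1.30}}


def _enucleation(tnf: bool = False) -> DeprivationModel:
    return DeprivationModel(
        paradigm="enucleation",
        onset_hr=0.0,
        deprived_modality="gratings",
        inactivation_prob_by_class=dict(_V1_INACTIVATION),
        reactivation_curve=dict(_REACTIVATION),
        amp_scaling_by_class={k: dict(v) for k, v in _NET_SCALING_V1.items()},
        tnf_blocked=tnf,
        remove_evoked=True,
    )


def _rsc_deprivation(paradigm: str, modality: str, tnf: bool = False) -> DeprivationModel:
    return DeprivationModel(
        paradigm=paradigm,
        onset_hr=0.0,
        deprived_modality=modality,
        inactivation_prob_by_class={},
        reactivation_curve={},
        amp_scaling_by_class={k: dict(v) for k, v in _NET_SCALING_RSC.items()},
        tnf_blocked=tnf,
        remove_evoked=False,  # reversible: stimulus responses return at test time
    )


def _presets() -> dict[str, GeneratorConfig]:
    return {
        "V1-baseline": GeneratorConfig(
            region="V1",
            class_mixture=dict(_V1_MIXTURE),
            session_layout=[replace(e) for e in _V1_LAYOUT],
            timepoints=[-24.0, -1.0],
        ),
        "V1-sparse": GeneratorConfig(
            region="V1",
            class_mixture=dict(_V1_MIXTURE),
            session_layout=[replace(e) for e in _V1_SPARSE_LAYOUT],
            timepoints=[-24.0, -1.0],
        ),
        "V1-enucleation": GeneratorConfig(
            region="V1",
            class_mixture=dict(_V1_MIXTURE),
            session_layout=[replace(e) for e in _V1_LAYOUT],
            timepoints=[-24.0, -1.0, 12.0, 24.0, 48.0],
            deprivation=_enucleation(),
        ),
        "V1-enucleation-TNF": GeneratorConfig(
            region="V1",
            class_mixture=dict(_V1_MIXTURE),
            session_layout=[replace(e) for e in _V1_LAYOUT],
            timepoints=[-24.0, -1.0, 12.0, 24.0, 48.0],
            deprivation=_enucleation(tnf=True),
        ),
        "RSC-baseline": GeneratorConfig(
            region="RSC",
            class_mixture=dict(_RSC_MIXTURE),
            session_layout=[replace(e) for e in _RSC_LAYOUT],
            timepoints=[-1.0, 0.0],
        ),
        "RSC-dark": GeneratorConfig(
            region="RSC",
            class_mixture=dict(_RSC_MIXTURE),
            session_layout=[replace(e) for e in _RSC_LAYOUT],
            timepoints=[-1.0, 0.0, 48.0],
            deprivation=_rsc_deprivation("dark_exposure", "gratings"),
        ),
        "RSC-earplug": GeneratorConfig(
            region="RSC",
            class_mixture=dict(_RSC_MIXTURE),
            session_layout=[replace(e) for e in _RSC_LAYOUT],
            timepoints=[-1.0, 0.0, 48.0],
            deprivation=_rsc_deprivation("ear_plug", "auditory"),
        ),
        "RSC-dark-TNF": GeneratorConfig(
            region="RSC",
            class_mixture=dict(_RSC_MIXTURE),
            session_layout=[replace(e) for e in _RSC_LAYOUT],
            timepoints=[-1.0, 0.0, 48.0],
            deprivation=_rsc_deprivation("dark_exposure", "gratings", tnf=True),
        ),
        "sham": GeneratorConfig(
            region="V1",
            class_mixture=dict(_V1_MIXTURE),
            session_layout=[replace(e) for e in _V1_LAYOUT],
            timepoints=[-24.0, -1.0, 12.0, 24.0, 48.0],
            deprivation=DeprivationModel(paradigm="sham"),
        ),
    }


PRESET_NAMES = tuple(_presets().keys())


def build_config(
    region: str | None = None,
    preset_name: str = "V1-baseline",
    overrides: dict[str, Any] | None = None,
) -> GeneratorConfig:
    """Return a fully populated, validated :class:`GeneratorConfig`.

    ``overrides`` maps field names to replacement values (nested dataclasses
    may be replaced wholesale, or via a dict merged over the preset value for
    ``class_mixture``-style dict fields).  Identical (region, preset,
    overrides) always yields an identical config.
    """
    presets = _presets()
    if preset_name not in presets:
        raise ConfigError(
            f"unknown preset {preset_name!r}; valid presets: {sorted(presets)}"
        )
    cfg = presets[preset_name]
    if region is not None and region != cfg.region:
        raise ConfigError(
            f"preset {preset_name!r} is defined for region {cfg.region}, got {region!r}"
        )
    for key, value in (overrides or {}).items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown override field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
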