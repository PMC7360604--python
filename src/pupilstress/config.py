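"""Study design vocabulary and validated configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: Within-subject emotion-regulation conditions, in canonical order.
CONDITIONS: tuple[str, ...] = (
    "view_neutral",
    "view_negative",
    "intensify",
    "reappraisal",
    "distraction",
)

STRESS_GROUPS: tuple[str, ...] = ("stress", "control")
HORMONE_GROUPS: tuple[str, ...] = ("MALE", "FELU", "FEOC")


class ConfigError(ValueError):
    """A configuration field is outside its documented bounds."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class TrialTiming:
    """Per-trial screen durations in milliseconds."""

    cue_ms: float = 750.0
    fixation_ms: float = 2500.0
    picture_ms: float = 5000.0
    rating_ms: float = 5000.0
    n_rating_screens: int = 3
    iti_ms: float = 2000.0

    @property
    def picture_onset_ms(self) -> float:
        return self.cue_ms + self.fixation_ms

    @property
    def trial_span_ms(self) -> float:
        return (
            self.cue_ms
            + self.fixation_ms
            + self.picture_ms
            + self.n_rating_screens * self.rating_ms
            + self.iti_ms
        )

    def validate(self) -> None:
        for name in ("cue_ms", "fixation_ms", "picture_ms", "rating_ms", "iti_ms"):
            _require(getattr(self, name) >= 0, f"timing.{name}", "must be >= 0")
        _require(self.picture_ms > 0, "timing.picture_ms", "must be > 0")


def _default_arousal_amp() -> dict[str, float]:
    # mm of pupil dilation attributable to emotional arousal of the picture
    return {
        "view_neutral": 0.05,
        "view_negative": 0.35,
        "intensify": 0.35,
        "reappraisal": 0.35,
        "distraction": 0.35,
    }


def _default_effort_amp() -> dict[str, float]:
    # mm attributable to cognitive regulation effort (zero for passive viewing)
    return {
        "view_neutral": 0.0,
        "view_negative": 0.0,
        "intensify": 0.25,
        "reappraisal": 0.20,
        "distraction": 0.15,
    }


def _default_arousal_means() -> dict[str, float]:
    return {
        "view_neutral": 2.2,
        "view_negative": 6.3,
        "intensify": 7.0,
        "reappraisal": 5.3,
        "distraction": 5.3,
    }


def _default_valence_means() -> dict[str, float]:
    return {
        "view_neutral": 5.4,
        "view_negative": 2.5,
        "intensify": 1.9,
        "reappraisal": 3.4,
        "distraction": 3.4,
    }


def _default_success_means() -> dict[str, float]:
    return {
        "view_neutral": 3.2,
        "view_negative": 3.2,
        "intensify": 3.8,
        "reappraisal": 3.0,
        "distraction": 3.0,
    }


def _default_cortisol_delta() -> dict[str, float]:
    # stress-group baseline-to-peak cortisol increase (nmol/l) per hormone group
    return {"MALE": 13.96, "FELU": 4.55, "FEOC": 4.48}


def _default_saa_delta() -> dict[str, float]:
    # stress-group alpha-amylase increase (U/l) per hormone group
    return {"MALE": 115.98, "FELU": 102.85, "FEOC": 116.92}


def _default_das_spike() -> dict[str, float]:
    # negative-affect increase immediately post stressor per hormone group
    return {"MALE": 0.51, "FELU": 0.60, "FEOC": 0.35}


@dataclass
class EffectParams:
    """Generating means/SDs for every simulated measurement channel.

    Group effects are expressed relative to the control groups; setting the
    ``stressed_male_*`` shifts and the per-group deltas to zero yields a null
    study with no systematic group differences.
    """

    # pupil signal components (mm)
    tonic_mean: float = 4.0
    tonic_sd: float = 0.3
    arousal_amp: dict[str, float] = field(default_factory=_default_arousal_amp)
    effort_amp: dict[str, float] = field(default_factory=_default_effort_amp)
    stressed_male_effort_boost: float = 0.15
    arousal_ramp_center_ms: float = 1000.0
    arousal_ramp_scale_ms: float = 250.0
    effort_onset_delay_ms: float = 500.0

    # per-trial ratings
    arousal_means: dict[str, float] = field(default_factory=_default_arousal_means)
    valence_means: dict[str, float] = field(default_factory=_default_valence_means)
    success_means: dict[str, float] = field(default_factory=_default_success_means)
    rating_sd: float = 1.2
    stressed_male_arousal_shift: float = -0.8
    stressed_male_valence_shift: float = 0.8
    stressed_male_success_shift: float = 0.6

    # saliva (cortisol nmol/l, alpha-amylase U/l)
    cortisol_baseline_mean: float = 6.0
    cortisol_baseline_sd: float = 1.5
    cortisol_delta: dict[str, float] = field(default_factory=_default_cortisol_delta)
    cortisol_control_decline: float = 0.6
    cortisol_noise_sd: float = 0.5
    saa_baseline_mean: float = 80.0
    saa_baseline_sd: float = 20.0
    saa_delta: dict[str, float] = field(default_factory=_default_saa_delta)
    saa_noise_sd: float = 15.0

    # DAS affect (1-5 scale)
    das_negative_base: float = 1.4
    das_positive_base: float = 2.5
    das_spike: dict[str, float] = field(default_factory=_default_das_spike)
    das_noise_sd: float = 0.15

    def validate(self) -> None:
        for name in (
            "tonic_sd",
            "rating_sd",
            "cortisol_baseline_sd",
            "cortisol_noise_sd",
            "saa_baseline_sd",
            "saa_noise_sd",
            "das_noise_sd",
        ):
            _require(getattr(self, name) >= 0, f"effect_params.{name}", "SD must be >= 0")
        for name in ("arousal_amp", "effort_amp", "arousal_means", "valence_means", "success_means"):
            mapping = getattr(self, name)
            for cond in CONDITIONS:
                _require(cond in mapping, f"effect_params.{name}", f"missing condition {cond!r}")
        for name in ("cortisol_delta", "saa_delta", "das_spike"):
            mapping = getattr(self, name)
            for grp in HORMONE_GROUPS:
                _require(grp in mapping, f"effect_params.{name}", f"missing group {grp!r}")

    def null_effects(self) -> "EffectParams":
        """Copy with all between-group effects removed (type-I error runs)."""
        out = EffectParams(**{**asdict(self)})
        out.stressed_male_effort_boost = 0.0
        out.stressed_male_arousal_shift = 0.0
        out.stressed_male_valence_shift = 0.0
        out.stressed_male_success_shift = 0.0
        out.cortisol_delta = {g: 0.0 for g in HORMONE_GROUPS}
        out.saa_delta = {g: 0.0 for g in HORMONE_GROUPS}
        out.das_spike = {g: 0.0 for g in HORMONE_GROUPS}
        return out


@dataclass
class ArtifactParams:
    """Rates and shapes of injected recording artifacts."""

    noise_sd: float = 0.05           # per-eye Gaussian sample noise, mm
    blink_rate_hz: float = 0.0       # blinks per second of recording
    blink_duration_median_ms: float = 120.0
    blink_duration_sigma: float = 0.6  # lognormal sigma of blink durations
    spike_rate_hz: float = 0.0       # isolated dilation-speed spikes per second
    spike_amp_mm: float = 3.0
    out_of_range_rate_hz: float = 0.0  # samples pushed outside the feasible band
    out_of_range_value_mm: float = 9.5

    def validate(self) -> None:
        for name in ("noise_sd", "blink_rate_hz", "spike_rate_hz", "out_of_range_rate_hz"):
            _require(getattr(self, name) >= 0, f"artifact_params.{name}", "must be >= 0")
        _require(self.blink_duration_median_ms > 0, "artifact_params.blink_duration_median_ms", "must be > 0")
        _require(self.blink_duration_sigma >= 0, "artifact_params.blink_duration_sigma", "must be >= 0")

    @classmethod
    def clean(cls) -> "ArtifactParams":
        """Noise-free, artifact-free recordings."""
        return cls(noise_sd=0.0)


@dataclass
class StudyConfig:
    """Full specification of one synthetic study."""

    n_per_cell: int = 20
    sampling_rate: float = 30.0
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 10
    timing: TrialTiming = field(default_factory=TrialTiming)
    effect_params: EffectParams = field(default_factory=EffectParams)
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_per_cell >= 2, "n_per_cell", "must be >= 2")
        _require(self.sampling_rate > 0, "sampling_rate", "must be > 0")
        _require(self.trials_per_condition >= 1, "trials_per_condition", "must be >= 1")
        _require(
            tuple(self.conditions) == CONDITIONS,
            "conditions",
            f"must be the fixed vocabulary {CONDITIONS}",
        )
        self.timing.validate()
        self.effect_params.validate()
        self.artifact_params.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        if "timing" in data and isinstance(data["timing"], Mapping):
            data["timing"] = TrialTiming(**data["timing"])
        if "effect_params" in data and isinstance(data["effect_params"], Mapping):
            data["effect_params"] = EffectParams(**data["effect_params"])
        if "artifact_params" in data and isinstance(data["artifact_params"], Mapping):
            data["artifact_params"] = ArtifactParams(**data["artifact_params"])
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        try:
            cfg = cls(**data)
        except TypeError as exc:  # unknown field
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PreprocessParams:
    """Pupil preprocessing thresholds and filter settings."""

    cutoff_hz: float = 6.0
    fir_taps: int = 31
    range_lo_mm: float = 1.5
    range_hi_mm: float = 9.0
    mad_multiplier: float = 16.0
    max_gap_ms: float = 100.0
    baseline_ms: float = 300.0
    auc_start_ms: float = 2000.0
    auc_end_ms: float = 5000.0
    min_valid: int = 5
    strict_eyes: bool = False      # True: require both eyes per sample
    speed_scope: str = "trial"     # "trial" or "participant" thresholds

    def validate(self) -> None:
        _require(self.cutoff_hz > 0, "cutoff_hz", "must be > 0")
        _require(self.fir_taps >= 3 and self.fir_taps % 2 == 1, "fir_taps", "must be odd and >= 3")
        _require(self.range_lo_mm < self.range_hi_mm, "range_lo_mm", "must be < range_hi_mm")
        _require(6.0 <= self.mad_multiplier <= 30.0, "mad_multiplier", "must be within [6, 30]")
        _require(self.max_gap_ms > 0, "max_gap_ms", "must be > 0")
        _require(self.baseline_ms > 0, "baseline_ms", "must be > 0")
        _require(self.auc_start_ms < self.auc_end_ms, "auc_start_ms", "must be < auc_end_ms")
        _require(self.min_valid >= 1, "min_valid", "must be >= 1")
        _require(self.speed_scope in ("trial", "participant"), "speed_scope", "must be 'trial' or 'participant'")
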