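"""Synthetic study generator.

Emulates a 2 (stress/control) x 3 (MALE/FELU/FEOC) between-subjects design
with five within-subject emotion-regulation conditions. Pupil traces carry
two additive dilation components — an emotional-arousal ramp and a delayed
cognitive-effort ramp — on top of a participant-specific tonic level, with
optional blinks, speed spikes and out-of-range artifacts. Saliva, affect
(DAS) and per-trial rating tables follow the same group-effect structure.

All randomness derives from ``StudyConfig.seed`` through one spawned stream
per participant, split per table, so any table can be regenerated alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ArtifactParams,
    CONDITIONS,
    ConfigError,
    EffectParams,
    HORMONE_GROUPS,
    STRESS_GROUPS,
    StudyConfig,
)

SALIVA_TIMEPOINTS: tuple[str, ...] = ("baseline", "+2", "+15", "+45")
DAS_TIMEPOINTS: tuple[str, ...] = ("baseline", "+2", "+45")
DAS_NEGATIVE_FACTORS: tuple[str, ...] = (
    "sadness", "anger", "disgust", "contempt", "fear", "shame", "guilt",
)
DAS_POSITIVE_FACTORS: tuple[str, ...] = ("joy", "surprise", "interest")

#: Post-baseline saliva profile shapes (fraction of the configured delta).
_CORTISOL_STRESS_PROFILE = {"+2": 0.4, "+15": 1.0, "+45": 0.6}
_CORTISOL_CONTROL_PROFILE = {"+2": -0.3, "+15": -0.6, "+45": -1.0}
_SAA_STRESS_PROFILE = {"+2": 1.0, "+15": 0.35, "+45": 0.1}

# clean-signal physiological band; chosen inside the default feasible range
_PUPIL_BAND_MM = (1.6, 8.9)


@dataclass(frozen=True)
class Participant:
    id: str
    stress_group: str
    hormone_group: str

    def __post_init__(self) -> None:
        if self.stress_group not in STRESS_GROUPS:
            raise ConfigError(f"stress_group: unknown label {self.stress_group!r}")
        if self.hormone_group not in HORMONE_GROUPS:
            raise ConfigError(f"hormone_group: unknown label {self.hormone_group!r}")


@dataclass
class PupilTrialSim:
    """One simulated event-locked trial (times relative to trial start)."""

    t_ms: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    clean_mm: np.ndarray
    condition: str
    cue_ms: float
    fixation_ms: float
    picture_onset_ms: float


@dataclass
class StudyDataset:
    """All tables of one simulated study plus the generating truth."""

    config: StudyConfig
    roster: pd.DataFrame
    pupil_samples: pd.DataFrame | None
    events: pd.DataFrame | None
    saliva: pd.DataFrame | None
    das: pd.DataFrame | None
    ratings: pd.DataFrame | None
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every table as UTF-8 CSV plus the truth file as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(outdir / "roster.csv", index=False)
        for name in ("pupil_samples", "events", "saliva", "das", "ratings"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=float)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: relaxation time constant after picture offset (ms)
_OFFSET_DECAY_TAU_MS = 500.0


def _trial_clean_signal(
    t_rel_pic_ms: np.ndarray,
    tonic: float,
    arousal_amp: float,
    effort_amp: float,
    params: EffectParams,
    picture_ms: float = np.inf,
) -> np.ndarray:
    """Tonic + arousal ramp + delayed effort ramp, clipped to the band.

    After picture offset the summed component relaxes back to tonic with an
    exponential decay, so the trace stays physiologically smooth.
    """
    t = np.minimum(t_rel_pic_ms, picture_ms)  # freeze ramps at offset
    arousal = arousal_amp * _logistic(
        (t - params.arousal_ramp_center_ms) / params.arousal_ramp_scale_ms
    )
    effort = effort_amp * _logistic(
        (t - params.arousal_ramp_center_ms - params.effort_onset_delay_ms)
        / params.arousal_ramp_scale_ms
    )
    component = arousal + effort
    # components only act from picture onset onwards
    component[t_rel_pic_ms < 0] = 0.0
    past = t_rel_pic_ms > picture_ms
    if np.any(past):
        component[past] *= np.exp(-(t_rel_pic_ms[past] - picture_ms) / _OFFSET_DECAY_TAU_MS)
    sig = tonic + component
    return np.clip(sig, *_PUPIL_BAND_MM)


def _effort_amplitude(participant: Participant, condition: str, params: EffectParams) -> float:
    amp = params.effort_amp[condition]
    if (
        condition == "reappraisal"
        and participant.stress_group == "stress"
        and participant.hormone_group == "MALE"
    ):
        amp += params.stressed_male_effort_boost
    return amp


def simulate_pupil_trial(
    config: StudyConfig,
    participant: Participant,
    condition: str,
    rng: np.random.Generator,
    tonic: float | None = None,
) -> PupilTrialSim:
    """Simulate one binocular event-locked trial covering cue+fixation+picture.

    Blink gaps are inserted as NaN runs in both eyes; spike and out-of-range
    artifacts perturb single samples, per ``config.artifact_params``.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition: unknown label {condition!r}")
    timing = config.timing
    effect = config.effect_params
    art = config.artifact_params
    if tonic is None:
        tonic = effect.tonic_mean + effect.tonic_sd * rng.standard_normal()
        tonic = float(np.clip(tonic, *_PUPIL_BAND_MM))

    dt = 1000.0 / config.sampling_rate
    span = timing.cue_ms + timing.fixation_ms + timing.picture_ms
    t_ms = np.arange(0.0, span, dt)
    pic_on = timing.picture_onset_ms
    clean = _trial_clean_signal(
        t_ms - pic_on,
        tonic,
        effect.arousal_amp[condition],
        _effort_amplitude(participant, condition, effect),
        effect,
    )

    left = clean + art.noise_sd * rng.standard_normal(t_ms.size)
    right = clean + art.noise_sd * rng.standard_normal(t_ms.size)
    left, right = _inject_artifacts(t_ms, left, right, art, config.sampling_rate, rng)
    return PupilTrialSim(
        t_ms=t_ms,
        left_mm=left,
        right_mm=right,
        clean_mm=clean,
        condition=condition,
        cue_ms=0.0,
        fixation_ms=timing.cue_ms,
        picture_onset_ms=pic_on,
    )


def _inject_artifacts(
    t_ms: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    art: ArtifactParams,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = t_ms.size
    duration_s = n / fs
    # blinks: Poisson count, lognormal duration around the configured median
    n_blinks = rng.poisson(art.blink_rate_hz * duration_s)
    for _ in range(n_blinks):
        dur_ms = np.exp(
            np.log(art.blink_duration_median_ms) + art.blink_duration_sigma * rng.standard_normal()
        )
        start = rng.integers(0, n)
        length = max(1, int(round(dur_ms * fs / 1000.0)))
        left[start : start + length] = np.nan
        right[start : start + length] = np.nan
    # isolated large jumps (tracker glitches) on both eyes
    n_spikes = rng.poisson(art.spike_rate_hz * duration_s)
    for _ in range(n_spikes):
        idx = rng.integers(0, n)
        jump = art.spike_amp_mm * rng.choice((-1.0, 1.0))
        left[idx] += jump
        right[idx] += jump
    # implausible absolute values
    n_oor = rng.poisson(art.out_of_range_rate_hz * duration_s)
    for _ in range(n_oor):
        idx = rng.integers(0, n)
        left[idx] = art.out_of_range_value_mm
        right[idx] = art.out_of_range_value_mm
    return left, right


def _condition_sequence(config: StudyConfig, rng: np.random.Generator) -> list[str]:
    """Blocked trial order: each condition once per half, in blocks."""
    tpc = config.trials_per_condition
    conds = list(config.conditions)
    if tpc % 2 == 0:
        seq: list[str] = []
        half = tpc // 2
        for _ in range(2):
            order = list(rng.permutation(conds))
            for c in order:
                seq.extend([c] * half)
        return seq
    flat = [c for c in conds for _ in range(tpc)]
    return list(rng.permutation(flat))


def _simulate_participant_pupil(
    config: StudyConfig,
    participant: Participant,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continuous session recording plus the per-trial event table."""
    timing = config.timing
    effect = config.effect_params
    art = config.artifact_params
    dt = 1000.0 / config.sampling_rate

    tonic = effect.tonic_mean + effect.tonic_sd * rng.standard_normal()
    tonic = float(np.clip(tonic, *_PUPIL_BAND_MM))
    sequence = _condition_sequence(config, rng)

    lead_ms = 1000.0
    span = timing.trial_span_ms
    total_ms = lead_ms + len(sequence) * span + lead_ms
    t_ms = np.arange(0.0, total_ms, dt)
    clean = np.full(t_ms.size, tonic)

    ev_rows = []
    for i, cond in enumerate(sequence):
        start = lead_ms + i * span
        cue = start
        fix = start + timing.cue_ms
        pic = start + timing.picture_onset_ms
        ev_rows.append(
            {
                "participant": participant.id,
                "trial": i + 1,
                "condition": cond,
                "cue_ms": cue,
                "fix_ms": fix,
                "pic_ms": pic,
            }
        )
        # extend past picture offset so the component decays smoothly
        sel = (t_ms >= cue) & (t_ms < pic + timing.picture_ms + 8 * _OFFSET_DECAY_TAU_MS)
        clean[sel] = _trial_clean_signal(
            t_ms[sel] - pic,
            tonic,
            effect.arousal_amp[cond],
            _effort_amplitude(participant, cond, effect),
            effect,
            picture_ms=timing.picture_ms,
        )

    left = clean + art.noise_sd * rng.standard_normal(t_ms.size)
    right = clean + art.noise_sd * rng.standard_normal(t_ms.size)
    left, right = _inject_artifacts(t_ms, left, right, art, config.sampling_rate, rng)

    samples = pd.DataFrame(
        {
            "participant": participant.id,
            "t_ms": t_ms,
            "left_mm": left,
            "right_mm": right,
        }
    )
    return samples, pd.DataFrame(ev_rows)


def simulate_saliva(
    config: StudyConfig, participant: Participant, rng: np.random.Generator
) -> pd.DataFrame:
    """Four-timepoint cortisol/sAA series for one participant.

    Stress groups follow a cortisol profile peaking at +15 (with the
    configured per-group delta) and an sAA profile peaking at +2; controls
    decline slightly (cortisol) or stay flat (sAA). Concentrations are
    clamped strictly positive.
    """
    effect = config.effect_params
    stressed = participant.stress_group == "stress"
    cort_base = max(0.5, effect.cortisol_baseline_mean + effect.cortisol_baseline_sd * rng.standard_normal())
    saa_base = max(1.0, effect.saa_baseline_mean + effect.saa_baseline_sd * rng.standard_normal())
    cort_delta = effect.cortisol_delta[participant.hormone_group]
    saa_delta = effect.saa_delta[participant.hormone_group]

    rows = []
    for tp in SALIVA_TIMEPOINTS:
        if tp == "baseline":
            cort, saa = cort_base, saa_base
        elif stressed:
            cort = cort_base + _CORTISOL_STRESS_PROFILE[tp] * cort_delta
            saa = saa_base + _SAA_STRESS_PROFILE[tp] * saa_delta
        else:
            cort = cort_base + _CORTISOL_CONTROL_PROFILE[tp] * effect.cortisol_control_decline
            saa = saa_base
        if tp != "baseline":
            cort += effect.cortisol_noise_sd * rng.standard_normal()
            saa += effect.saa_noise_sd * rng.standard_normal()
        rows.append(
            {
                "participant": participant.id,
                "timepoint": tp,
                "cortisol_nmoll": max(0.05, cort),
                "saa_ul": max(0.5, saa),
            }
        )
    return pd.DataFrame(rows)


def simulate_ratings_and_das(
    config: StudyConfig,
    participant: Participant,
    rng: np.random.Generator,
    sequence: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial integer ratings plus the three-timepoint DAS table.

    Ratings are Gaussian draws around condition means (stressed males get
    the configured reappraisal shifts), rounded and clamped to scale bounds.
    """
    effect = config.effect_params
    if sequence is None:
        sequence = _condition_sequence(config, rng)

    stressed_male = participant.stress_group == "stress" and participant.hormone_group == "MALE"
    rows = []
    for i, cond in enumerate(sequence):
        a_mu = effect.arousal_means[cond]
        v_mu = effect.valence_means[cond]
        s_mu = effect.success_means[cond]
        if stressed_male and cond == "reappraisal":
            a_mu += effect.stressed_male_arousal_shift
            v_mu += effect.stressed_male_valence_shift
            s_mu += effect.stressed_male_success_shift
        a = int(np.clip(round(a_mu + effect.rating_sd * rng.standard_normal()), 1, 9))
        v = int(np.clip(round(v_mu + effect.rating_sd * rng.standard_normal()), 1, 9))
        s = int(np.clip(round(s_mu + effect.rating_sd * rng.standard_normal()), 1, 5))
        rows.append(
            {
                "participant": participant.id,
                "trial": i + 1,
                "condition": cond,
                "arousal": a,
                "valence": v,
                "success": s,
            }
        )
    ratings = pd.DataFrame(rows)

    stressed = participant.stress_group == "stress"
    spike = effect.das_spike[participant.hormone_group] if stressed else 0.0
    das_rows = []
    for tp in DAS_TIMEPOINTS:
        row: dict = {"participant": participant.id, "timepoint": tp}
        if tp == "baseline":
            neg_mu = effect.das_negative_base
        elif tp == "+2":
            neg_mu = effect.das_negative_base + spike
        else:  # +45: back to (slightly below) baseline
            neg_mu = effect.das_negative_base - 0.05
        for f in DAS_NEGATIVE_FACTORS:
            row[f] = float(np.clip(neg_mu + effect.das_noise_sd * rng.standard_normal(), 1.0, 5.0))
        for f in DAS_POSITIVE_FACTORS:
            row[f] = float(
                np.clip(effect.das_positive_base + effect.das_noise_sd * rng.standard_normal(), 1.0, 5.0)
            )
        das_rows.append(row)
    return ratings, pd.DataFrame(das_rows)


def make_roster(config: StudyConfig) -> list[Participant]:
    """Equal-n roster over the 2 x 3 design, ids P001..P{6n}."""
    roster = []
    idx = 1
    for sg in STRESS_GROUPS:
        for hg in HORMONE_GROUPS:
            for _ in range(config.n_per_cell):
                roster.append(Participant(id=f"P{idx:03d}", stress_group=sg, hormone_group=hg))
                idx += 1
    return roster


def simulate_study(
    config: StudyConfig,
    tables: tuple[str, ...] = ("pupil", "saliva", "das", "ratings"),
) -> StudyDataset:
    """Simulate a complete study: roster plus the requested tables.

    Deterministic given ``config.seed``. ``tables`` may be restricted (e.g.
    ``("ratings",)``) to skip the costly continuous pupil recordings in
    Monte-Carlo loops; the per-participant RNG streams are independent per
    table, so restricting tables does not change the ones generated.
    """
    config.validate()
    unknown = set(tables) - {"pupil", "saliva", "das", "ratings"}
    if unknown:
        raise ConfigError(f"tables: unknown table(s) {sorted(unknown)}")

    roster = make_roster(config)
    root = np.random.SeedSequence(config.seed)
    per_participant = root.spawn(len(roster))

    pupil_parts, event_parts, saliva_parts, das_parts, rating_parts = [], [], [], [], []
    for participant, ss in zip(roster, per_participant):
        pupil_ss, saliva_ss, rating_ss = ss.spawn(3)
        if "pupil" in tables:
            rng = np.random.default_rng(pupil_ss)
            samples, events = _simulate_participant_pupil(config, participant, rng)
            pupil_parts.append(samples)
            event_parts.append(events)
        if "saliva" in tables:
            saliva_parts.append(simulate_saliva(config, participant, np.random.default_rng(saliva_ss)))
        if "ratings" in tables or "das" in tables:
            rng = np.random.default_rng(rating_ss)
            ratings, das = simulate_ratings_and_das(config, participant, rng)
            if "ratings" in tables:
                rating_parts.append(ratings)
            if "das" in tables:
                das_parts.append(das)

    def _concat(parts):
        return pd.concat(parts, ignore_index=True) if parts else None

    roster_df = pd.DataFrame(
        {
            "participant": [p.id for p in roster],
            "stress_group": [p.stress_group for p in roster],
            "hormone_group": [p.hormone_group for p in roster],
        }
    )
    truth = {"config": config.to_dict()}
    return StudyDataset(
        config=config,
        roster=roster_df,
        pupil_samples=_concat(pupil_parts),
        events=_concat(event_parts),
        saliva=_concat(saliva_parts),
        das=_concat(das_parts),
        ratings=_concat(rating_parts),
        truth=truth,
    )
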