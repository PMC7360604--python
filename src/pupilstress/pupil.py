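"""Pupil preprocessing: raw binocular samples to per-condition AUCg.

Pipeline order: average eyes -> FIR smooth -> segment trials -> range
filter -> dilation-speed MAD filter -> gap handling / interpolation ->
baseline correction -> AUCg -> per-condition aggregation. Missing samples
are NaN throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import CONDITIONS, ConfigError, PreprocessParams

logger = logging.getLogger(__name__)

DISCARD_REASONS = ("none", "out_of_range", "long_gap", "too_short")


class PreprocessError(ValueError):
    pass


@dataclass
class TrialTrace:
    """One event-locked pupil segment, times relative to picture onset (ms)."""

    trial: int
    condition: str
    t_ms: np.ndarray
    diameter_mm: np.ndarray
    status: str = "valid"
    discard_reason: str = "none"
    baseline_value: float = np.nan
    corrected: bool = False

    @property
    def valid(self) -> bool:
        return self.status == "valid"

    def discard(self, reason: str) -> "TrialTrace":
        if reason not in DISCARD_REASONS or reason == "none":
            raise ValueError(f"bad discard reason {reason!r}")
        return replace(self, status="discarded", discard_reason=reason)


def average_eyes(left: np.ndarray, right: np.ndarray, strict: bool = False) -> np.ndarray:
    """Binocular mean; falls back to the single available eye unless strict."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise PreprocessError(f"eye series length mismatch: {left.shape} vs {right.shape}")
    if strict:
        return (left + right) / 2.0
    stacked = np.vstack([left, right])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        out = np.nanmean(stacked, axis=0)
    return out


def fir_lowpass_taps(sampling_rate: float, cutoff_hz: float = 6.0, n_taps: int = 31) -> np.ndarray:
    """Linear-phase windowed-sinc low-pass kernel, unit DC gain."""
    if cutoff_hz >= sampling_rate / 2.0:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({sampling_rate / 2.0} Hz)"
        )
    return sps.firwin(n_taps, cutoff_hz, fs=sampling_rate)


def smooth_fir(
    series: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = 6.0,
    n_taps: int = 31,
) -> np.ndarray:
    """Zero-phase FIR low-pass, applied per contiguous valid segment.

    Missing (NaN) samples stay missing. Segments are reflect-padded so the
    output has the input length; segments shorter than the kernel use a
    reduced odd tap count, and 1-2 sample segments pass through unfiltered.
    """
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    valid = ~np.isnan(series)
    if not valid.any():
        return out
    # contiguous valid runs
    edges = np.flatnonzero(np.diff(valid.astype(int)) != 0) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [series.size]))
    for s, e in zip(starts, ends):
        if not valid[s]:
            continue
        seg = series[s:e]
        taps = n_taps
        if seg.size < taps:
            taps = seg.size if seg.size % 2 == 1 else seg.size - 1
        if taps < 3:
            out[s:e] = seg
            continue
        kernel = fir_lowpass_taps(sampling_rate, cutoff_hz, taps)
        pad = taps // 2
        padded = np.pad(seg, pad, mode="reflect")
        # symmetric odd-length kernel + 'valid' convolution on the padded
        # segment == forward filtering with group-delay compensation
        out[s:e] = np.convolve(padded, kernel, mode="valid")
    return out


def segment_trials(
    t_ms: np.ndarray,
    diameter_mm: np.ndarray,
    events: pd.DataFrame,
    params: PreprocessParams | None = None,
    picture_ms: float = 5000.0,
) -> list[TrialTrace]:
    """Cut one trace per event row: 300 ms pre picture onset to offset.

    Trials whose window is not fully covered by the recording are returned
    discarded with reason ``too_short`` (never a fatal error).
    """
    params = params or PreprocessParams()
    t_ms = np.asarray(t_ms, dtype=float)
    diameter_mm = np.asarray(diameter_mm, dtype=float)
    traces: list[TrialTrace] = []
    for row in events.itertuples(index=False):
        cond = row.condition
        if cond not in CONDITIONS:
            raise PreprocessError(f"unknown condition label {cond!r} in events")
        onset = float(row.pic_ms)
        lo, hi = onset - params.baseline_ms, onset + picture_ms
        sel = (t_ms >= lo) & (t_ms <= hi)
        rel = t_ms[sel] - onset
        trace = TrialTrace(
            trial=int(row.trial),
            condition=cond,
            t_ms=rel,
            diameter_mm=diameter_mm[sel].copy(),
        )
        if rel.size == 0 or lo < t_ms[0] or hi > t_ms[-1]:
            trace = trace.discard("too_short")
        traces.append(trace)
    return traces


def apply_range_filter(trace: TrialTrace, lo_mm: float = 1.5, hi_mm: float = 9.0) -> TrialTrace:
    """Discard the whole trial if any sample leaves [lo, hi] (inclusive-keep)."""
    if not trace.valid:
        return trace
    x = trace.diameter_mm
    with np.errstate(invalid="ignore"):
        bad = (x < lo_mm) | (x > hi_mm)
    if np.any(bad & ~np.isnan(x)):
        return trace.discard("out_of_range")
    return trace


def dilation_speeds(t_ms: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-sample dilation speed: max of the two one-sided |slopes| (mm/ms).

    Slopes toward missing neighbours are undefined; a sample with no valid
    neighbour on either side gets NaN speed.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    back = np.full(n, np.nan)
    fwd = np.full(n, np.nan)
    if n >= 2:
        dt = np.diff(t_ms)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.abs(np.diff(x)) / dt
        back[1:] = slope
        fwd[:-1] = slope
    both = np.vstack([back, fwd])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # no valid neighbour
        speed = np.nanmax(both, axis=0)
    speed[np.isnan(x)] = np.nan
    return speed


def mad_threshold(speeds: np.ndarray, k: float) -> float:
    """median(d) + k * MAD(d) over defined speeds; raw MAD, no constant."""
    d = speeds[~np.isnan(speeds)]
    if d.size == 0:
        return np.inf
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    return med + k * mad


def flag_dilation_speed_outliers(
    trace: TrialTrace,
    mad_multiplier: float = 16.0,
    threshold: float | None = None,
) -> TrialTrace:
    """Set samples whose dilation speed exceeds median + k*MAD to missing.

    ``threshold`` overrides the per-trace threshold (used for the
    per-participant scope option). If MAD is zero nothing is flagged unless
    a speed strictly exceeds the median.
    """
    if not 6.0 <= mad_multiplier <= 30.0:
        raise ConfigError(f"mad_multiplier: {mad_multiplier} outside [6, 30]")
    if not trace.valid:
        return trace
    speeds = dilation_speeds(trace.t_ms, trace.diameter_mm)
    if threshold is None:
        threshold = mad_threshold(speeds, mad_multiplier)
    x = trace.diameter_mm.copy()
    with np.errstate(invalid="ignore"):
        x[speeds > threshold] = np.nan
    return replace(trace, diameter_mm=x)


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (end exclusive) of consecutive True runs."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def handle_gaps(
    trace: TrialTrace,
    max_gap_ms: float = 100.0,
    sampling_rate: float = 30.0,
) -> TrialTrace:
    """Interpolate short missing runs; discard trials with long/edge gaps.

    Gap duration = run length x (1000/fs) ms. Gaps strictly longer than
    ``max_gap_ms`` (major blinks) discard the trial, as do leading/trailing
    gaps, which have no flanking samples to interpolate from.
    """
    if not trace.valid:
        return trace
    x = trace.diameter_mm.copy()
    missing = np.isnan(x)
    if not missing.any():
        return trace
    if missing.all():
        return trace.discard("long_gap")
    sample_ms = 1000.0 / sampling_rate
    runs = _missing_runs(missing)
    for start, end in runs:
        dur = (end - start) * sample_ms
        # strict "> max_gap_ms" with a float guard so 3 samples at 30 Hz
        # (nominally exactly 100 ms) are kept
        if dur > max_gap_ms + 1e-9 * max(1.0, max_gap_ms):
            return trace.discard("long_gap")
        if start == 0 or end == x.size:
            return trace.discard("long_gap")
    good = ~missing
    x[missing] = np.interp(trace.t_ms[missing], trace.t_ms[good], x[good])
    return replace(trace, diameter_mm=x)


def baseline_correct(trace: TrialTrace, baseline_ms: float = 300.0) -> TrialTrace:
    """Subtract the mean of the [-baseline_ms, 0) window; idempotent."""
    if not trace.valid:
        return trace
    sel = (trace.t_ms >= -baseline_ms - 1e-6) & (trace.t_ms < 0.0)
    window = trace.diameter_mm[sel]
    window = window[~np.isnan(window)]
    if window.size == 0:
        return trace.discard("long_gap")
    baseline = float(np.mean(window))
    return replace(
        trace,
        diameter_mm=trace.diameter_mm - baseline,
        baseline_value=baseline if not trace.corrected else trace.baseline_value,
        corrected=True,
    )


def compute_aucg(
    trace: TrialTrace,
    window_ms: tuple[float, float] = (2000.0, 5000.0),
) -> float:
    """Signed trapezoidal area (mm*s) of the corrected dilation over the window.

    "Ground" is the zero line established by baseline correction, so
    negative dilation subtracts from the area.
    """
    if not trace.corrected:
        raise PreprocessError("compute_aucg requires a baseline-corrected trace")
    lo, hi = window_ms
    sel = (trace.t_ms >= lo - 1e-6) & (trace.t_ms <= hi + 1e-6)
    t = trace.t_ms[sel]
    x = trace.diameter_mm[sel]
    if t.size < 2:
        raise PreprocessError("AUCg window contains fewer than 2 samples")
    if np.isnan(x).any():
        raise PreprocessError("AUCg window contains missing samples")
    return float(np.trapezoid(x, t / 1000.0))


def preprocess_trace(
    trace: TrialTrace,
    params: PreprocessParams,
    sampling_rate: float,
    speed_threshold: float | None = None,
) -> TrialTrace:
    """Range filter -> speed filter -> gaps -> baseline for one segment."""
    trace = apply_range_filter(trace, params.range_lo_mm, params.range_hi_mm)
    trace = flag_dilation_speed_outliers(trace, params.mad_multiplier, threshold=speed_threshold)
    trace = handle_gaps(trace, params.max_gap_ms, sampling_rate)
    trace = baseline_correct(trace, params.baseline_ms)
    return trace


def preprocess_recording(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    params: PreprocessParams | None = None,
    sampling_rate: float = 30.0,
    picture_ms: float = 5000.0,
) -> list[TrialTrace]:
    """Full single-participant pipeline from raw binocular samples.

    ``samples`` columns: t_ms, left_mm, right_mm; ``events`` columns:
    trial, condition, pic_ms (cue/fix onsets are carried but unused here).
    """
    params = params or PreprocessParams()
    params.validate()
    t_ms = samples["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t_ms) <= 0):
        raise PreprocessError("sample times must be strictly increasing")
    mono = average_eyes(
        samples["left_mm"].to_numpy(dtype=float),
        samples["right_mm"].to_numpy(dtype=float),
        strict=params.strict_eyes,
    )
    mono = smooth_fir(mono, sampling_rate, params.cutoff_hz, params.fir_taps)
    traces = segment_trials(t_ms, mono, events, params, picture_ms=picture_ms)

    threshold = None
    if params.speed_scope == "participant":
        all_speeds = np.concatenate(
            [dilation_speeds(tr.t_ms, tr.diameter_mm) for tr in traces if tr.valid]
        ) if any(tr.valid for tr in traces) else np.array([])
        threshold = mad_threshold(all_speeds, params.mad_multiplier)

    return [preprocess_trace(tr, params, sampling_rate, threshold) for tr in traces]


def aggregate_condition(
    traces: list[TrialTrace],
    participant: str,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Mean AUCg per condition over valid trials (one participant).

    Cells with fewer than ``min_valid`` valid trials get NaN. Columns:
    participant, condition, mean_aucg, n_valid_trials.
    """
    params = params or PreprocessParams()
    window = (params.auc_start_ms, params.auc_end_ms)
    per_cond: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for tr in traces:
        if tr.valid:
            per_cond[tr.condition].append(compute_aucg(tr, window))
    rows = []
    for cond in CONDITIONS:
        vals = per_cond[cond]
        n = len(vals)
        rows.append(
            {
                "participant": participant,
                "condition": cond,
                "mean_aucg": float(np.mean(vals)) if n >= params.min_valid else np.nan,
                "n_valid_trials": n,
            }
        )
    return pd.DataFrame(rows)


def ln_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """ln(x + shift) with shift = 1 - min(x) when any x <= 0, else 0.

    Returns the transformed array and the shift actually used (logged by
    the pipeline); NaNs pass through.
    """
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    shift = 0.0
    if finite.size and np.min(finite) <= 0.0:
        shift = 1.0 - float(np.min(finite))
    with np.errstate(invalid="ignore"):
        return np.log(values + shift), shift


def qc_table(traces_by_participant: dict[str, list[TrialTrace]]) -> pd.DataFrame:
    """Trial-level QC rows: participant, trial, condition, status, reason, baseline."""
    rows = []
    for pid, traces in traces_by_participant.items():
        for tr in traces:
            rows.append(
                {
                    "participant": pid,
                    "trial": tr.trial,
                    "condition": tr.condition,
                    "status": tr.status,
                    "discard_reason": tr.discard_reason,
                    "baseline_mm": tr.baseline_value,
                }
            )
    return pd.DataFrame(rows)


def preprocess_study(
    pupil_samples: pd.DataFrame,
    events: pd.DataFrame,
    params: PreprocessParams | None = None,
    sampling_rate: float = 30.0,
    picture_ms: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-participant pipeline: returns (QC table, ConditionAUC table).

    The ConditionAUC table carries ln_aucg computed over the whole analysis
    set with a single shared shift (NaN where the cell is missing).
    """
    params = params or PreprocessParams()
    traces_by_participant: dict[str, list[TrialTrace]] = {}
    auc_parts = []
    for pid, ev in events.groupby("participant", sort=False):
        sub = pupil_samples[pupil_samples["participant"] == pid]
        traces = preprocess_recording(sub, ev, params, sampling_rate, picture_ms)
        traces_by_participant[pid] = traces
        auc_parts.append(aggregate_condition(traces, pid, params))
        n_bad = sum(not tr.valid for tr in traces)
        if n_bad:
            logger.info("participant %s: %d/%d trials discarded", pid, n_bad, len(traces))
    cond_auc = pd.concat(auc_parts, ignore_index=True)
    ln_vals, shift = ln_transform(cond_auc["mean_aucg"].to_numpy())
    cond_auc["ln_aucg"] = ln_vals
    if shift:
        logger.info("ln transform applied with shift %.6g", shift)
    return qc_table(traces_by_participant), cond_auc
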