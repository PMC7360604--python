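"""Endocrine and affect summaries: baseline-to-peak deltas, DAS negative
affect, and Welch t statistics computed from summary cells (mean/SEM/n)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import DAS_NEGATIVE_FACTORS


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class SummaryCell:
    """Group summary of a delta variable: mean, SEM and (optional) n."""

    mean: float
    sem: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise SummaryError("sem must be >= 0")
        if self.n is not None and self.n < 2:
            raise SummaryError("n must be >= 2")


#: Published group summaries of baseline-to-peak deltas (mean, SEM) used as
#: generator defaults and as inputs to the summary-statistic t tests.
TABLE1_SUMMARY: dict[tuple[str, str, str], SummaryCell] = {
    ("stress", "MALE", "cortisol"): SummaryCell(13.96, 1.87),
    ("stress", "FELU", "cortisol"): SummaryCell(4.55, 1.06),
    ("stress", "FEOC", "cortisol"): SummaryCell(4.48, 1.07),
    ("control", "MALE", "cortisol"): SummaryCell(-1.61, 1.82),
    ("control", "FELU", "cortisol"): SummaryCell(-0.43, 1.34),
    ("control", "FEOC", "cortisol"): SummaryCell(-1.01, 1.16),
    ("stress", "MALE", "saa"): SummaryCell(115.98, 21.29),
    ("stress", "FELU", "saa"): SummaryCell(102.85, 26.51),
    ("stress", "FEOC", "saa"): SummaryCell(116.92, 26.64),
    ("control", "MALE", "saa"): SummaryCell(22.86, 12.29),
    ("control", "FELU", "saa"): SummaryCell(-1.91, 25.84),
    ("control", "FEOC", "saa"): SummaryCell(67.84, 27.34),
    ("stress", "MALE", "das"): SummaryCell(0.51, 0.13),
    ("stress", "FELU", "das"): SummaryCell(0.60, 0.14),
    ("stress", "FEOC", "das"): SummaryCell(0.35, 0.09),
    ("control", "MALE", "das"): SummaryCell(-0.12, 0.13),
    ("control", "FELU", "das"): SummaryCell(-0.13, 0.14),
    ("control", "FEOC", "das"): SummaryCell(-0.07, 0.10),
}


def delta_response(values: Sequence[float] | Mapping[str, float]) -> float:
    """Baseline-to-peak delta: max over post-baseline samples minus baseline.

    Accepts an ordered sequence (first element = baseline) or a mapping with
    a ``"baseline"`` key. Signed: negative when every post sample is below
    baseline. NaN post samples are ignored.
    """
    if isinstance(values, Mapping):
        if "baseline" not in values:
            raise SummaryError("missing baseline sample")
        baseline = float(values["baseline"])
        post = [float(v) for k, v in values.items() if k != "baseline"]
    else:
        seq = [float(v) for v in values]
        if len(seq) < 2:
            raise SummaryError("need baseline and at least one post-baseline sample")
        baseline, post = seq[0], seq[1:]
    if math.isnan(baseline):
        raise SummaryError("missing baseline sample")
    post = [v for v in post if not math.isnan(v)]
    if not post:
        raise SummaryError("need at least one post-baseline sample")
    return max(post) - baseline


def delta_at_timepoint(values: Mapping[str, float], timepoint: str) -> float:
    """Fixed-timepoint alternative to the peak definition."""
    if "baseline" not in values:
        raise SummaryError("missing baseline sample")
    if timepoint not in values:
        raise SummaryError(f"missing timepoint {timepoint!r}")
    return float(values[timepoint]) - float(values["baseline"])


def das_negative_affect(factors: Mapping[str, float]) -> float:
    """Mean of the seven negative DAS factors; positive factors are ignored."""
    vals = []
    for name in DAS_NEGATIVE_FACTORS:
        if name not in factors or (
            isinstance(factors[name], float) and math.isnan(factors[name])
        ):
            raise SummaryError(f"missing DAS factor {name!r}")
        vals.append(float(factors[name]))
    return float(np.mean(vals))


def welch_t_from_summary(a: SummaryCell, b: SummaryCell) -> tuple[float, float | None]:
    """Welch t and Welch-Satterthwaite df from two summary cells.

    t = (a.mean - b.mean) / sqrt(a.sem^2 + b.sem^2). The df requires per-cell
    n; when either n is absent the df is returned as None (t is always
    computable from means and SEMs alone).
    """
    va, vb = a.sem**2, b.sem**2
    denom = va + vb
    if denom == 0:
        raise SummaryError("both SEMs are zero; t undefined")
    t = (a.mean - b.mean) / math.sqrt(denom)
    df: float | None = None
    if a.n is not None and b.n is not None:
        df = denom**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return t, df


def delta_table(
    saliva: pd.DataFrame,
    das: pd.DataFrame,
    roster: pd.DataFrame,
    peak_timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-participant deltas for cortisol, sAA and DAS negative affect.

    ``peak_timepoint`` switches from the default peak definition to a fixed
    post-baseline timepoint (applied to the saliva analytes only).
    Columns: participant, stress_group, hormone_group, delta_cortisol,
    delta_saa, delta_das.
    """
    rows = []
    das_scores: dict[tuple[str, str], float] = {}
    for row in das.itertuples(index=False):
        rec = row._asdict()
        das_scores[(rec["participant"], rec["timepoint"])] = das_negative_affect(rec)

    for pid, sub in saliva.groupby("participant", sort=False):
        cort = {r.timepoint: r.cortisol_nmoll for r in sub.itertuples(index=False)}
        saa = {r.timepoint: r.saa_ul for r in sub.itertuples(index=False)}
        if peak_timepoint is not None:
            d_cort = delta_at_timepoint(cort, peak_timepoint)
            d_saa = delta_at_timepoint(saa, peak_timepoint)
        else:
            d_cort = delta_response(cort)
            d_saa = delta_response(saa)
        das_series = {
            tp: das_scores[(pid, tp)]
            for tp in ("baseline", "+2", "+45")
            if (pid, tp) in das_scores
        }
        d_das = delta_response(das_series) if len(das_series) >= 2 else np.nan
        rows.append(
            {
                "participant": pid,
                "delta_cortisol": d_cort,
                "delta_saa": d_saa,
                "delta_das": d_das,
            }
        )
    out = pd.DataFrame(rows)
    return out.merge(roster, on="participant", how="left")[
        ["participant", "stress_group", "hormone_group", "delta_cortisol", "delta_saa", "delta_das"]
    ]


def group_delta_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Mean/SEM/n per stress x hormone cell for each delta variable.

    Mirrors the published table layout: one row per cell, columns per
    analyte.
    """
    rows = []
    for (sg, hg), sub in deltas.groupby(["stress_group", "hormone_group"], sort=False):
        row = {"stress_group": sg, "hormone_group": hg, "n": len(sub)}
        for var in ("delta_cortisol", "delta_saa", "delta_das"):
            vals = sub[var].dropna().to_numpy()
            row[f"{var}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{var}_sem"] = (
                float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summary_cell_from_values(values: Sequence[float]) -> SummaryCell:
    """SummaryCell of raw observations (mean, SEM = sd/sqrt(n), n)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise SummaryError("need at least 2 observations")
    return SummaryCell(
        mean=float(np.mean(arr)),
        sem=float(np.std(arr, ddof=1) / math.sqrt(arr.size)),
        n=int(arr.size),
    )
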