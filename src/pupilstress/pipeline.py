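"""End-to-end orchestration: simulate -> preprocess -> summarize -> test.

Every stage reads/writes delimited-text tables under the run directory and
the whole run is summarized in a machine-readable JSON report. Identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import CONDITIONS, ConfigError, PreprocessParams, StudyConfig
from .endocrine import delta_table, group_delta_summary
from .pupil import preprocess_study
from .simulate import simulate_study
from .stats import (
    StatsError,
    mixed_anova,
    pearson_corr,
    stressed_male_reappraisal_test,
)

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    outdir: str = "run_out"
    study: StudyConfig = field(default_factory=StudyConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    alpha: float = 0.05
    tables: tuple[str, ...] = ("pupil", "saliva", "das", "ratings")
    subset: dict = field(default_factory=dict)  # e.g. {"stress_group": ["control"]}
    peak_timepoint: str | None = None           # fixed-timepoint delta mode
    use_ln_aucg: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must be in (0, 1)")
        self.study.validate()
        self.preprocess.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "study" in data and isinstance(data["study"], Mapping):
            data["study"] = StudyConfig.from_dict(data["study"])
        if "preprocess" in data and isinstance(data["preprocess"], Mapping):
            data["preprocess"] = PreprocessParams(**data["preprocess"])
        if "tables" in data:
            data["tables"] = tuple(data["tables"])
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg


def _apply_subset(roster: pd.DataFrame, subset: dict) -> pd.DataFrame:
    out = roster
    for col, allowed in subset.items():
        if col not in roster.columns:
            raise ConfigError(f"subset: unknown column {col!r}")
        out = out[out[col].isin(list(allowed))]
    if out.empty:
        raise ConfigError("subset: selector matches no participants")
    return out


def _between_factors(roster: pd.DataFrame) -> list[str]:
    """Between factors that still have >= 2 levels after subsetting."""
    return [
        col
        for col in ("stress_group", "hormone_group")
        if roster[col].nunique() > 1
    ]


def _anova_record(name: str, res) -> dict:
    rec = {
        "name": name,
        "n_subjects": res.n_subjects,
        "mauchly_w": res.mauchly_w,
        "mauchly_p": res.mauchly_p,
        "epsilon_gg": res.epsilon_gg,
        "effects": res.table.to_dict(orient="records"),
    }
    return rec


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    data_dir = outdir / "data"
    out_tables = outdir / "tables"
    out_tables.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": _version(),
        "seed": config.study.seed,
        "alpha": config.alpha,
        "parameters": {
            "study": config.study.to_dict(),
            "preprocess": asdict(config.preprocess),
            "subset": config.subset,
            "peak_timepoint": config.peak_timepoint,
        },
        "stages": {},
    }

    # --- stage: simulate ---------------------------------------------------
    ds = simulate_study(config.study, tables=config.tables)
    ds.write(data_dir)
    roster = ds.roster
    report["stages"]["simulate"] = {
        "participants": int(len(roster)),
        "trials_per_participant": len(config.study.conditions) * config.study.trials_per_condition,
    }

    if config.subset:
        roster = _apply_subset(roster, config.subset)
    keep = set(roster["participant"])
    between = _between_factors(roster)
    report["subset_participants"] = int(len(roster))
    report["between_factors"] = between

    # --- stage: preprocess pupil ------------------------------------------
    cond_auc = None
    if ds.pupil_samples is not None:
        samples = ds.pupil_samples[ds.pupil_samples["participant"].isin(keep)]
        events = ds.events[ds.events["participant"].isin(keep)]
        qc, cond_auc = preprocess_study(
            samples,
            events,
            config.preprocess,
            sampling_rate=config.study.sampling_rate,
            picture_ms=config.study.timing.picture_ms,
        )
        qc.to_csv(out_tables / "pupil_qc.csv", index=False)
        cond_auc.to_csv(out_tables / "condition_aucg.csv", index=False)
        by_reason = qc[qc["status"] == "discarded"]["discard_reason"].value_counts().to_dict()
        report["stages"]["preprocess"] = {
            "trials_total": int(len(qc)),
            "trials_valid": int((qc["status"] == "valid").sum()),
            "trials_discarded": int((qc["status"] == "discarded").sum()),
            "discarded_by_reason": {k: int(v) for k, v in sorted(by_reason.items())},
        }

    # --- stage: summarize endocrine/affect --------------------------------
    deltas = None
    if ds.saliva is not None and ds.das is not None:
        saliva = ds.saliva[ds.saliva["participant"].isin(keep)]
        das = ds.das[ds.das["participant"].isin(keep)]
        deltas = delta_table(saliva, das, roster, peak_timepoint=config.peak_timepoint)
        summary = group_delta_summary(deltas)
        deltas.to_csv(out_tables / "deltas.csv", index=False)
        summary.to_csv(out_tables / "delta_summary.csv", index=False)
        report["stages"]["summarize"] = {
            "participants": int(len(deltas)),
            "delta_summary": summary.to_dict(orient="records"),
        }

    # --- stage: statistical tests -----------------------------------------
    tests: dict = {}
    ratings = None
    if ds.ratings is not None:
        ratings = ds.ratings[ds.ratings["participant"].isin(keep)]
        per_cond = (
            ratings.groupby(["participant", "condition"], sort=False)[["arousal", "valence", "success"]]
            .mean()
            .reset_index()
            .merge(roster, on="participant")
        )
        for dv in ("arousal", "valence", "success"):
            res = mixed_anova(per_cond, dv=dv, within="condition", subject="participant", between=between)
            tests[f"anova_{dv}"] = _anova_record(dv, res)
        if {"stress_group", "hormone_group"} <= set(between):
            t, df, p = stressed_male_reappraisal_test(ratings, roster, dv="arousal")
            tests["stressed_male_reappraisal_arousal"] = {"t": t, "df": df, "p": p}

    if cond_auc is not None:
        dv = "ln_aucg" if config.use_ln_aucg else "mean_aucg"
        pupil_long = cond_auc.dropna(subset=[dv]).merge(roster, on="participant")
        try:
            res = mixed_anova(pupil_long, dv=dv, within="condition", subject="participant", between=between)
            tests["anova_pupil"] = _anova_record("pupil_aucg", res)
        except StatsError as exc:
            tests["anova_pupil"] = {"error": str(exc)}

    if ds.saliva is not None:
        saliva = ds.saliva[ds.saliva["participant"].isin(keep)].merge(roster, on="participant")
        for analyte, col in (("cortisol", "cortisol_nmoll"), ("saa", "saa_ul")):
            res = mixed_anova(saliva, dv=col, within="timepoint", subject="participant", between=between)
            tests[f"anova_{analyte}_time"] = _anova_record(analyte, res)

    if deltas is not None and ratings is not None:
        corr = {}
        males = roster[roster["hormone_group"] == "MALE"]["participant"]
        male_deltas = deltas[deltas["participant"].isin(males)]
        male_success = (
            ratings[ratings["participant"].isin(males)]
            .groupby(["participant", "condition"], sort=False)["success"]
            .mean()
            .reset_index()
        )
        for cond in CONDITIONS:
            sub = male_success[male_success["condition"] == cond].merge(
                male_deltas, on="participant"
            )
            try:
                r, p, n = pearson_corr(sub["delta_cortisol"].to_numpy(), sub["success"].to_numpy())
                corr[cond] = {"r": r, "p": p, "n": n}
            except StatsError as exc:
                corr[cond] = {"error": str(exc)}
        tests["corr_delta_cortisol_success_males"] = corr

    report["stages"]["test"] = tests

    # conservation check: discards + valid == total
    pre = report["stages"].get("preprocess")
    if pre is not None:
        assert pre["trials_valid"] + pre["trials_discarded"] == pre["trials_total"]

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def subset_analysis(config: RunConfig, selector: dict) -> dict:
    """Run the pipeline on a participant subset (e.g. control-only).

    Between factors reduced to a single level by the selector are removed
    from the ANOVA models; the within-factor structure is preserved.
    """
    sub_cfg = RunConfig(
        outdir=str(Path(config.outdir) / "subset"),
        study=config.study,
        preprocess=config.preprocess,
        alpha=config.alpha,
        tables=config.tables,
        subset=selector,
        peak_timepoint=config.peak_timepoint,
        use_ln_aucg=config.use_ln_aucg,
    )
    return run_pipeline(sub_cfg)
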