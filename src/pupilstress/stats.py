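"""Mixed-design repeated-measures ANOVA and companion inference tools.

The ANOVA is a split-plot decomposition: between-subjects effects are
tested against subject-within-cell variation, within-involved effects
against the condition-by-subject residual. Sums of squares are Type III
(sum-to-zero coding, model-comparison), so unequal between-cell sizes are
handled the way standard commercial packages do. Sphericity is assessed
with Mauchly's test on orthonormal contrasts of the pooled within-cell
covariance, and Greenhouse-Geisser corrected dfs/p-values accompany every
within-involved effect.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.linalg import helmert
from statsmodels.stats.diagnostic import lilliefors

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design-matrix helpers


def _sum_to_zero(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n x (L-1), last level coded -1."""
    n = codes.size
    out = np.zeros((n, n_levels - 1))
    for j in range(n_levels - 1):
        out[codes == j, j] = 1.0
    out[codes == n_levels - 1, :] = -1.0
    return out


def _interaction(blocks: list[np.ndarray]) -> np.ndarray:
    """Column-wise products across coded blocks (full interaction columns)."""
    cols = blocks[0]
    for nxt in blocks[1:]:
        cols = np.hstack([cols[:, [i]] * nxt for i in range(cols.shape[1])])
    return cols


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# sphericity


def gg_epsilon(within_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a k x k within-level covariance.

    Computed from the double-centered covariance and clipped to
    [1/(k-1), 1]. Degenerate (zero) centered covariance falls back to the
    lower bound with a warning.
    """
    s = np.asarray(within_cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise StatsError("within_cov must be a k x k matrix with k >= 2")
    k = s.shape[0]
    lower = 1.0 / (k - 1)
    row = s.mean(axis=0)
    grand = s.mean()
    centered = s - row[None, :] - row[:, None] + grand
    denom = (k - 1) * float(np.sum(centered**2))
    if denom <= 0 or not np.isfinite(denom):
        logger.warning("degenerate within covariance; epsilon set to lower bound %.4g", lower)
        return lower
    eps = float(np.trace(centered)) ** 2 / denom
    return float(np.clip(eps, lower, 1.0))


def mauchly_test(within_cov: np.ndarray, n_subjects: int) -> tuple[float, float]:
    """Mauchly's sphericity W with chi-square approximation.

    ``n_subjects`` enters the approximation as n-1 (for pooled covariances
    pass error-df + 1). Returns (nan, nan) for k < 3, where the test is not
    applicable.
    """
    s = np.asarray(within_cov, dtype=float)
    k = s.shape[0]
    if k < 3:
        return (math.nan, math.nan)
    c = helmert(k, full=False)  # (k-1) x k orthonormal contrasts
    m = c @ s @ c.T
    tr = float(np.trace(m))
    if tr <= 0:
        return (math.nan, math.nan)
    det = float(np.linalg.det(m))
    w = det / (tr / (k - 1)) ** (k - 1)
    w = min(max(w, np.finfo(float).tiny), 1.0)
    nm1 = n_subjects - 1
    dd = 1.0 - (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1) * nm1)
    chi2 = -nm1 * dd * math.log(w)
    dof = k * (k - 1) // 2 - 1
    p = float(sst.chi2.sf(chi2, dof))
    return (float(w), p)


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass
class MixedAnovaResult:
    """ANOVA table plus sphericity diagnostics."""

    table: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    epsilon_gg: float
    n_subjects: int
    dropped_subjects: list


def _pivot_complete(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> tuple[pd.DataFrame, list]:
    levels = list(pd.unique(data[within]))
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean", sort=False)
    wide = wide.reindex(columns=levels)
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        logger.warning(
            "dropping %d participant(s) with incomplete within-factor data: %s",
            len(incomplete),
            incomplete,
        )
        wide = wide.drop(index=incomplete)
    return wide, incomplete


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: list[str] | tuple[str, ...] = (),
) -> MixedAnovaResult:
    """Split-plot ANOVA with any number of crossed between-subjects factors.

    ``data`` is long-format with one value per subject x within-level
    (duplicates are averaged; subjects missing a level are dropped with a
    warning). Every effect row carries uncorrected and GG-corrected
    dfs/p-values (GG applied to within-involved effects only) and partial
    eta squared.
    """
    between = list(between)
    wide, dropped = _pivot_complete(data, dv, within, subject)
    n = wide.shape[0]
    k = wide.shape[1]
    if n < 2:
        raise StatsError("need at least 2 complete subjects")
    if k < 2:
        raise StatsError("within factor needs at least 2 levels")

    # between-factor codes per subject (must be constant within subject)
    bcodes: list[np.ndarray] = []
    blevels: list[list] = []
    for factor in between:
        per_subj = data.groupby(subject, sort=False)[factor].agg(pd.unique)
        if per_subj.map(len).max() > 1:
            raise StatsError(f"between factor {factor!r} varies within a subject")
        labels = per_subj.map(lambda v: v[0]).reindex(wide.index)
        levs = list(pd.unique(labels))
        if len(levs) < 2:
            raise StatsError(f"between factor {factor!r} has a single level; drop it")
        blevels.append(levs)
        bcodes.append(labels.map({lv: i for i, lv in enumerate(levs)}).to_numpy())

    # empty-cell check
    n_cells = 1
    if between:
        cell_index = np.zeros(n, dtype=int)
        for codes, levs in zip(bcodes, blevels):
            cell_index = cell_index * len(levs) + codes
        n_cells = int(np.prod([len(lv) for lv in blevels]))
        counts = np.bincount(cell_index, minlength=n_cells)
        if np.any(counts == 0):
            raise StatsError("empty between-subjects cell")
    else:
        cell_index = np.zeros(n, dtype=int)

    y = wide.to_numpy(dtype=float)
    subj_means = y.mean(axis=1)

    # --- between stratum (on subject means, SS scaled by k) ----------------
    bblocks = [_sum_to_zero(codes, len(levs)) for codes, levs in zip(bcodes, blevels)]
    between_effects: list[tuple[str, np.ndarray, int]] = []
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(range(len(between)), r):
            name = ":".join(between[i] for i in combo)
            cols = _interaction([bblocks[i] for i in combo])
            between_effects.append((name, cols, cols.shape[1]))

    intercept = np.ones((n, 1))
    xb_full = np.hstack([intercept] + [cols for _, cols, _ in between_effects]) if between_effects else intercept
    rss_b_full = _rss(subj_means, xb_full)
    ss_err_between = rss_b_full * k
    df_err_between = n - n_cells
    if between_effects and df_err_between <= 0:
        raise StatsError("no residual degrees of freedom in the between stratum")

    rows = []
    for name, cols, df_eff in between_effects:
        others = [c for nm, c, _ in between_effects if nm != name]
        x_red = np.hstack([intercept] + others) if others else intercept
        ss = (_rss(subj_means, x_red) - rss_b_full) * k
        ss = max(ss, 0.0)
        ms_eff = ss / df_eff
        ms_err = ss_err_between / df_err_between
        f = ms_eff / ms_err if ms_err > 0 else math.inf
        p = float(sst.f.sf(f, df_eff, df_err_between))
        rows.append(
            {
                "effect": name,
                "stratum": "between",
                "ss": ss,
                "ss_error": ss_err_between,
                "df1": float(df_eff),
                "df2": float(df_err_between),
                "F": f,
                "p_unc": p,
                "epsilon_gg": math.nan,
                "df1_gg": float(df_eff),
                "df2_gg": float(df_err_between),
                "p_gg": p,
                "partial_eta_sq": ss / (ss + ss_err_between) if (ss + ss_err_between) > 0 else 0.0,
            }
        )

    # --- within stratum (subject-centered long data) -----------------------
    z = (y - subj_means[:, None]).ravel(order="C")
    w_codes = np.tile(np.arange(k), n)
    w_block = _sum_to_zero(w_codes, k)
    rep_bblocks = [np.repeat(b, k, axis=0) for b in bblocks]
    rep_between_effects = []
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(range(len(between)), r):
            name = ":".join(between[i] for i in combo)
            rep_between_effects.append((name, _interaction([rep_bblocks[i] for i in combo])))

    within_effects: list[tuple[str, np.ndarray, int]] = [(within, w_block, k - 1)]
    for name, cols in rep_between_effects:
        inter = _interaction([cols, w_block])
        within_effects.append((f"{name}:{within}", inter, inter.shape[1]))

    nk = n * k
    intercept_w = np.ones((nk, 1))
    xw_full = np.hstack(
        [intercept_w]
        + [cols for _, cols in rep_between_effects]
        + [cols for _, cols, _ in within_effects]
    )
    rss_w_full = _rss(z, xw_full)
    ss_err_within = rss_w_full
    df_err_within = (n - n_cells) * (k - 1)
    if df_err_within <= 0:
        raise StatsError("no residual degrees of freedom in the within stratum")

    # sphericity from the pooled within-cell covariance
    pooled = np.zeros((k, k))
    wsum = 0
    for c in range(n_cells):
        sub = y[cell_index == c]
        if sub.shape[0] >= 2:
            pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False, ddof=1)
            wsum += sub.shape[0] - 1
    if wsum == 0:
        raise StatsError("cannot pool within-cell covariance (all cells have n < 2)")
    pooled /= wsum
    eps = gg_epsilon(pooled) if k >= 3 else 1.0
    mw, mp = mauchly_test(pooled, wsum + 1)

    ms_err_w = ss_err_within / df_err_within
    for name, cols, df_eff in within_effects:
        others = [c for nm, c, _ in within_effects if nm != name]
        x_red = np.hstack(
            [intercept_w] + [c for _, c in rep_between_effects] + others
        )
        ss = max(_rss(z, x_red) - rss_w_full, 0.0)
        f = (ss / df_eff) / ms_err_w if ms_err_w > 0 else math.inf
        p = float(sst.f.sf(f, df_eff, df_err_within))
        df1_gg = eps * df_eff
        df2_gg = eps * df_err_within
        p_gg = float(sst.f.sf(f, df1_gg, df2_gg))
        rows.append(
            {
                "effect": name,
                "stratum": "within",
                "ss": ss,
                "ss_error": ss_err_within,
                "df1": float(df_eff),
                "df2": float(df_err_within),
                "F": f,
                "p_unc": p,
                "epsilon_gg": eps,
                "df1_gg": df1_gg,
                "df2_gg": df2_gg,
                "p_gg": p_gg,
                "partial_eta_sq": ss / (ss + ss_err_within) if (ss + ss_err_within) > 0 else 0.0,
            }
        )

    table = pd.DataFrame(rows)
    return MixedAnovaResult(
        table=table,
        mauchly_w=mw,
        mauchly_p=mp,
        epsilon_gg=eps,
        n_subjects=n,
        dropped_subjects=dropped,
    )


# ---------------------------------------------------------------------------
# post-hoc tests


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    if np.mean(a) == np.mean(b) and np.var(a) == 0 and np.var(b) == 0:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = sst.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, 0.0):
        return 0.0, float(diff.size - 1), 1.0
    res = sst.ttest_rel(a, b)
    return float(res.statistic), float(diff.size - 1), float(res.pvalue)


def bonferroni_posthoc(
    cells: dict[str, np.ndarray],
    family: list[tuple],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise t tests with Bonferroni-corrected p-values.

    ``family`` entries are ``(label_a, label_b)`` or
    ``(label_a, label_b, kind)`` with kind in {"welch", "paired"}
    (default "welch"). p_bonferroni = min(1, m * p_raw) with m the family
    size (defaults to len(family)). Cells with n < 2 skip the contrast with
    a warning.
    """
    if not family:
        raise StatsError("contrast family is empty")
    m = family_size if family_size is not None else len(family)
    rows = []
    for entry in family:
        a_label, b_label = entry[0], entry[1]
        kind = entry[2] if len(entry) > 2 else "welch"
        a = np.asarray(cells[a_label], dtype=float)
        b = np.asarray(cells[b_label], dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            logger.warning("skipping contrast %s vs %s: cell with n < 2", a_label, b_label)
            continue
        if kind == "paired":
            if a.size != b.size:
                raise StatsError(f"paired contrast {a_label} vs {b_label} needs equal n")
            t, df, p = _paired_t(a, b)
        elif kind == "welch":
            t, df, p = _welch_t(a, b)
        else:
            raise StatsError(f"unknown contrast kind {kind!r}")
        rows.append(
            {
                "contrast": f"{a_label} vs {b_label}",
                "kind": kind,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": min(1.0, m * p),
                "alpha_adjusted": alpha / m,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assumption checks, correlation, difference scores


def assumption_checks(cells: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Normality (Lilliefors-corrected KS) per cell plus Levene across cells.

    Recommends a log transform when any cell rejects normality; flags
    "shift required" when a transform is recommended but values are not all
    positive.
    """
    ks = {}
    any_reject = False
    all_positive = True
    for label, vals in cells.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 4:
            ks[label] = math.nan
            continue
        _, p = lilliefors(arr, dist="norm")
        ks[label] = float(p)
        if p < alpha:
            any_reject = True
        if np.any(arr <= 0):
            all_positive = False
    arrays = [np.asarray(v, dtype=float) for v in cells.values()]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) >= 2 and all(a.size >= 2 for a in arrays):
        if all(np.ptp(a) == 0 for a in arrays):
            lev_stat, lev_p = 0.0, 1.0  # no spread anywhere: trivially homogeneous
        else:
            lev_stat, lev_p = sst.levene(*arrays, center="mean")
    else:
        lev_stat, lev_p = math.nan, math.nan
    return {
        "ks_p": ks,
        "levene_stat": float(lev_stat) if not math.isnan(float(lev_stat)) else math.nan,
        "levene_p": float(lev_p) if not math.isnan(float(lev_p)) else math.nan,
        "log_transform_recommended": any_reject and all_positive,
        "shift_required": any_reject and not all_positive,
    }


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with two-sided p on complete pairs; n >= 3 required."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise StatsError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance; correlation undefined")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p), int(n)


def difference_scores(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    reference: str = "view_negative",
) -> pd.DataFrame:
    """Per-subject difference scores against a reference within-level.

    Each non-reference level's value becomes value - reference value; the
    reference level is removed. Subjects without a reference observation
    are dropped with a warning. Non-key columns (group labels) are carried
    through.
    """
    out_parts = []
    dropped = []
    for pid, sub in data.groupby(subject, sort=False):
        ref_rows = sub[sub[within] == reference]
        if ref_rows.empty or ref_rows[dv].isna().all():
            dropped.append(pid)
            continue
        ref_val = float(ref_rows[dv].mean())
        rest = sub[sub[within] != reference].copy()
        rest[dv] = rest[dv] - ref_val
        out_parts.append(rest)
    if dropped:
        logger.warning("difference_scores: dropped %d subject(s) without reference level", len(dropped))
    if not out_parts:
        raise StatsError("no subjects with the reference level present")
    return pd.concat(out_parts, ignore_index=True)


def stressed_male_reappraisal_test(
    ratings: pd.DataFrame,
    roster: pd.DataFrame,
    dv: str = "arousal",
) -> tuple[float, float, float]:
    """Welch t of stress vs control males on mean reappraisal ratings.

    This is the focal follow-up contrast of the analysis: per-participant
    mean of ``dv`` in the reappraisal condition, compared between stressed
    and control males. Returns (t, df, p).
    """
    merged = ratings.merge(roster, on="participant", how="left")
    males = merged[(merged["hormone_group"] == "MALE") & (merged["condition"] == "reappraisal")]
    per_subj = males.groupby(["participant", "stress_group"], sort=False)[dv].mean().reset_index()
    a = per_subj.loc[per_subj["stress_group"] == "control", dv].to_numpy()
    b = per_subj.loc[per_subj["stress_group"] == "stress", dv].to_numpy()
    if a.size < 2 or b.size < 2:
        raise StatsError("need >= 2 males per stress group")
    # first-minus-second convention: (control, stress), so a lowered
    # stressed-male arousal yields a positive t
    return _welch_t(a, b)
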