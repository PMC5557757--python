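"""The study's statistical battery.

Pooled-variance two-sample t with Cohen's d (from summary statistics, so
printed group tables can be re-analyzed directly), 2 × K mixed-design
ANOVA with partial η², Bonferroni-corrected pairwise post-hocs,
Mann-Whitney U with the normal approximation, Pearson correlation with
the t-transform p-value, and the Benjamini-Hochberg false-discovery-rate
procedure in its strict ``p < q`` step-up form (q = Q·i/m).

Conventions
-----------
* Student (equal-variance) t, never Welch: df = n1 + n2 − 2.
* sign(t) = sign(mean2 − mean1); Cohen's d uses the pooled SD and is
  reported as a magnitude.
* Mixed ANOVA: univariate split-plot sums of squares; between error =
  subjects within groups, within/interaction error = level × subjects
  within groups.  No sphericity correction is applied (flagged in the
  result metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata


# --------------------------------------------------------------------------
# two-sample t

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean1: float
    mean2: float
    n1: int
    n2: int


def pooled_t_test(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> TTestResult:
    """Classical equal-variance two-sample t from summary statistics.

    t = (mean2 − mean1) / SE with the pooled SD; Cohen's d is the
    pooled-SD standardized |mean difference|.  A zero pooled SD with equal
    means yields t = 0 by convention; with unequal means it is an error.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    diff = mean2 - mean1
    if pooled_var == 0.0:
        if diff != 0.0:
            raise ValueError("zero pooled SD with unequal means")
        return TTestResult(0.0, df, 1.0, 0.0, mean1, mean2, n1, n2)
    pooled_sd = math.sqrt(pooled_var)
    se = pooled_sd * math.sqrt(1.0 / n1 + 1.0 / n2)
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    d = abs(diff) / pooled_sd
    return TTestResult(t, df, p, d, mean1, mean2, n1, n2)


def t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled t from raw samples (moments are computed, then delegated)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_t_test(float(x.mean()), float(x.std(ddof=1)), x.size,
                         float(y.mean()), float(y.std(ddof=1)), y.size)


# --------------------------------------------------------------------------
# mixed-design ANOVA

@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss: float
    ss_error: float


@dataclass(frozen=True)
class MixedAnovaResult:
    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    ss_total: float
    ss_between_subjects: float
    ss_within_subjects: float
    sphericity_corrected: bool = False  # uncorrected dfs, by design

    @property
    def effects(self) -> Mapping[str, EffectResult]:
        return {"between": self.between, "within": self.within,
                "interaction": self.interaction}


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str) -> MixedAnovaResult:
    """2 × K (or G × K) mixed-design ANOVA with partial η² per effect.

    ``data`` is long format with one row per subject × within-level.
    Requires complete within-level data per subject; a missing cell is an
    error naming the subject and level.  The split-plot decomposition is
    exact: SS_total = SS_between_subjects + SS_within_subjects, with the
    between-subject part split into group + subjects-within-groups and the
    within-subject part into level + group×level + level×subjects-within-
    groups.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    for subj, row in wide.iterrows():
        for level in levels:
            if pd.isna(row[level]):
                raise ValueError(f"subject {subj!r} is missing within-level {level!r}")
    group_of = data.groupby(subject)[between].first()
    groups = sorted(group_of.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 between-subject groups")
    counts = group_of.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 subjects")

    y = wide.to_numpy(dtype=float)                    # subjects × levels
    g = group_of.loc[wide.index].to_numpy()
    n_subj, k = y.shape
    n_g = {gr: int((g == gr).sum()) for gr in groups}
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = {gr: y[g == gr].mean() for gr in groups}
    cell_means = {gr: y[g == gr].mean(axis=0) for gr in groups}
    level_means = sum(n_g[gr] * cell_means[gr] for gr in groups) / n_subj

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * sum(n_g[gr] * (group_means[gr] - grand) ** 2 for gr in groups))
    ss_subj_within = ss_between_subjects - ss_group

    ss_within_subjects = float(((y - subj_means[:, None]) ** 2).sum())
    ss_level = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_inter = float(sum(
        n_g[gr] * ((cell_means[gr] - group_means[gr] - level_means + grand) ** 2).sum()
        for gr in groups))
    ss_err_within = ss_within_subjects - ss_level - ss_inter

    n_groups = len(groups)
    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_level = k - 1
    df_err_w = df_subj * df_level
    df_inter = df_group * df_level

    def effect(name, ss, df_num, ss_err, df_den) -> EffectResult:
        ms, ms_err = ss / df_num, ss_err / df_den
        if ms_err == 0.0:
            F = 0.0 if ss == 0.0 else float("inf")
        else:
            F = ms / ms_err
        p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return EffectResult(name, float(F), df_num, df_den, p, float(pes),
                            float(ss), float(ss_err))

    return MixedAnovaResult(
        between=effect(between, ss_group, df_group, ss_subj_within, df_subj),
        within=effect(within, ss_level, df_level, ss_err_within, df_err_w),
        interaction=effect(f"{between}*{within}", ss_inter, df_inter,
                           ss_err_within, df_err_w),
        ss_total=ss_total,
        ss_between_subjects=ss_between_subjects,
        ss_within_subjects=ss_within_subjects)


def bonferroni_pairwise(data: pd.DataFrame, dv: str, within: str, subject: str,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests for every within-level pair, Bonferroni-adjusted.

    The raw p of each pair is multiplied by the number of pairs (capped at
    1).  Subjects missing either level of a pair would make the samples
    unpaired, so complete data is assumed (as in `mixed_anova`).
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    if len(levels) < 2:
        raise ValueError("need at least 2 within-subject levels")
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rows = []
    for a, b in pairs:
        res = sps.ttest_rel(wide[a], wide[b])
        p_adj = min(1.0, float(res.pvalue) * len(pairs))
        rows.append({"level_a": a, "level_b": b, "t": float(res.statistic),
                     "df": len(wide) - 1, "p_raw": float(res.pvalue),
                     "p_adj": p_adj, "significant": p_adj < alpha})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class MWUResult:
    U: float
    U_other: float
    z: float
    p: float
    n1: int
    n2: int
    tie_corrected: bool


def mwu_z_from_u(U: float, n1: int, n2: int, tie_term: float = 0.0,
                 continuity: bool = False) -> float:
    """Normal-approximation z for a given U.

    ``tie_term`` is Σ(t³ − t) over tie groups (0 without tie information);
    the variance is n1·n2/12 · ((n+1) − tie_term/(n(n−1))).
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    num = U - mu
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    return float(num / math.sqrt(var))


def mann_whitney(x: Sequence[float], y: Sequence[float], *,
                 tie_correction: bool = True,
                 continuity: bool = False) -> MWUResult:
    """Rank-sum Mann-Whitney U with midranks and normal-approximation p.

    U is reported for the first sample; U + U' = n1·n2 always.  Midrank
    tie correction defaults ON and the continuity correction OFF.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # midranks
    r1 = float(ranks[:n1].sum())
    U1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    tie_term = 0.0
    if tie_correction:
        _, t_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(t_counts.astype(float) ** 3 - t_counts))
    z = mwu_z_from_u(U1, n1, n2, tie_term=tie_term, continuity=continuity)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return MWUResult(U=float(U1), U_other=float(n1 * n2 - U1), z=z, p=min(p, 1.0),
                     n1=n1, n2=n2, tie_corrected=tie_correction)


# --------------------------------------------------------------------------
# Pearson correlation

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r·√(n−2)/√(1−r²) on n−2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the t transform")
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * float(sps.t.sf(abs(t), n - 2))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=x.size, p=0.0)
    return CorrelationResult(r=r, n=x.size, p=pearson_p_from_r(r, x.size))


# --------------------------------------------------------------------------
# Benjamini-Hochberg FDR (strict p < q step-up rule)

def bh_fdr(p_values: Sequence[float], Q: float = 0.05,
           labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg critical values q = Q·i/m and the step-up decision.

    Ranks the p-values ascending (i = 1..m), computes each critical value
    q = Q·i/m, finds the largest p with p < q (strict inequality) and
    declares it and every smaller p significant.  Tied p-values share the
    decision of the highest-ranked tied member.  Rows are returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = Q * ranks / m
    p_sorted = p[order]
    q_sorted = Q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p_sorted < q_sorted)
    if passing.size:
        p_cut = p_sorted[passing.max()]
        significant = p <= p_cut
    else:
        significant = np.zeros(m, dtype=bool)
    return pd.DataFrame({
        "label": list(labels) if labels is not None else [str(i) for i in range(m)],
        "p": p, "rank": ranks, "m": m, "Q": Q, "q": q,
        "significant": significant,
    })
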