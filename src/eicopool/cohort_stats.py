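"""Cohort-level tests for a two-arm, two-timepoint intervention.

Baseline genotype differences (independent t), within-genotype change
(paired t), the diet-genotype interaction (repeated-measures GLM for two
timepoints, equivalent to an independent t on change scores), and one-way
tertile ANOVA with Bonferroni pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    no_change: bool = False


@dataclass(frozen=True)
class InteractionResult:
    """Diet-genotype interaction from the two-timepoint repeated-measures GLM.

    With two timepoints and two groups the GLM interaction F equals the
    squared pooled-variance t on change scores; both are emitted and must
    agree.
    """

    F: float
    df_num: int
    df_den: int
    p: float
    t_change: float
    p_change: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame | None  # columns: group_a, group_b, t, p_raw, p_bonferroni


def independent_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sample t-test; pooled-variance Student form by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError(f"both groups need n >= 2, got {len(a)} and {len(b)}")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def paired_outcome(
    cohort_values: pd.DataFrame, baseline: str, followup: str
) -> pd.DataFrame:
    """Wide per-subject outcome table from a long (subject, timepoint, value) one.

    Keeps only subjects complete at both timepoints (listwise completeness)
    and adds the change column (followup - baseline).
    """
    wide = cohort_values.pivot_table(
        index=["subject_id", "genotype"], columns="timepoint", values="value"
    ).reset_index()
    for tp in (baseline, followup):
        if tp not in wide.columns:
            raise StatsError(f"timepoint {tp!r} absent from the outcome table")
    wide = wide.dropna(subset=[baseline, followup])
    wide["change"] = wide[followup] - wide[baseline]
    return wide


def paired_t(changes) -> TestResult:
    """One-sample t of within-subject changes against zero.

    All-zero changes are reported with the documented no-change convention
    (t = 0, p = 1) rather than an undefined statistic.
    """
    d = np.asarray(changes, dtype=float)
    if len(d) < 3:
        raise StatsError(f"need >= 3 complete pairs, got {len(d)}")
    if np.all(d == 0.0):
        return TestResult(t=0.0, df=len(d) - 1, p=1.0, no_change=True)
    res = stats.ttest_1samp(d, 0.0)
    return TestResult(t=float(res.statistic), df=len(d) - 1, p=float(res.pvalue))


def diet_genotype_interaction(outcome: pd.DataFrame) -> InteractionResult:
    """Interaction of diet (time) and genotype from the split-plot GLM.

    ``outcome`` must carry columns (genotype, change) for exactly two
    genotypes — use :func:`paired_outcome` to build it.  The GLM interaction
    contrast for a two-timepoint design is the difference of mean change
    scores; its F (1, N-2) equals the squared pooled t.  More than two
    timepoints are not supported.
    """
    if "change" not in outcome.columns:
        raise StatsError("outcome table lacks a 'change' column; build with paired_outcome")
    groups = sorted(outcome["genotype"].unique())
    if len(groups) != 2:
        raise StatsError(f"interaction requires exactly 2 genotypes, got {groups}")
    d1 = outcome.loc[outcome["genotype"] == groups[0], "change"].to_numpy()
    d2 = outcome.loc[outcome["genotype"] == groups[1], "change"].to_numpy()
    if len(d1) < 3 or len(d2) < 3:
        raise StatsError("need >= 3 complete pairs per genotype")
    n1, n2 = len(d1), len(d2)
    # split-plot decomposition of the time-varying stratum: the interaction
    # sum of squares is the (weighted) contrast of cell change means, the
    # error stratum is the within-group spread of changes (halved, since each
    # change aggregates two repeated measures)
    ss_int = (d1.mean() - d2.mean()) ** 2 / (1.0 / n1 + 1.0 / n2) / 2.0
    ss_err = (((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()) / 2.0
    df_den = n1 + n2 - 2
    if ss_err == 0.0:  # e.g. a time-invariant variable: no-change convention
        F = 0.0 if ss_int == 0.0 else math.inf
        p = 1.0 if ss_int == 0.0 else float(np.nextafter(0, 1))
    else:
        F = ss_int / (ss_err / df_den)
        p = float(stats.f.sf(F, 1, df_den))
    if ss_err == 0.0:
        t_change = 0.0 if ss_int == 0.0 else math.copysign(math.inf, d1.mean() - d2.mean())
        p_change = p
    else:
        tt = independent_t(d1, d2)
        t_change, p_change = tt.t, tt.p
    return InteractionResult(
        F=float(F), df_num=1, df_den=df_den, p=p, t_change=t_change, p_change=p_change
    )


def tertile_anova(
    values_by_group: dict[str, np.ndarray], pairwise: bool = True
) -> AnovaResult:
    """One-way fixed-effects ANOVA over tertile groups.

    Pairwise comparisons use t-tests on the pooled within-group mean square
    (the ANOVA error term) with a Bonferroni factor of 3, matching the
    standard all-pairs adjustment for three strata.
    """
    if len(values_by_group) != 3:
        raise StatsError(f"expected 3 tertile groups, got {len(values_by_group)}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for label, arr in arrays.items():
        if len(arr) < 2:
            raise StatsError(f"tertile {label!r} has n={len(arr)}; need >= 2")
    groups = sorted(arrays)
    data = [arrays[g] for g in groups]
    n_total = sum(len(a) for a in data)
    k = len(data)
    grand = np.concatenate(data).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in data)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in data)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, float(np.nextafter(0, 1))
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    table = None
    if pairwise:
        mse = ss_within / df_w if df_w > 0 else math.nan
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = data[i], data[j]
                if mse == 0.0:
                    t = 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
                    praw = 1.0 if t == 0.0 else float(np.nextafter(0, 1))
                else:
                    t = (a.mean() - b.mean()) / math.sqrt(mse * (1 / len(a) + 1 / len(b)))
                    praw = 2.0 * stats.t.sf(abs(t), df_w)
                rows.append(
                    {
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "t": t,
                        "p_raw": praw,
                        "p_bonferroni": min(1.0, 3.0 * praw),
                    }
                )
        table = pd.DataFrame(rows)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p, pairwise=table)
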