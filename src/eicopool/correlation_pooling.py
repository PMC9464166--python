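"""Pathway-level pooled correlation inference.

The core statistic: Spearman correlations between each eicosanoid and the
composite inflammation score are Fisher r-to-z transformed, pooled by
(precursor, pathway) group within each genotype-by-timepoint cell, and the
pooled mean z is tested against zero with a one-sample t across the group's
analytes.  Timepoint differences of the same z's are tested with a paired t.
A permutation alternative, preserving the inter-analyte correlation
structure, quantifies the quality of the t approximation.

Two standard-error conventions for a single correlation are carried as
metadata: ``as-printed`` |1-r|/sqrt(n-2), and the textbook ``pearson-se``
sqrt(1-r^2)/sqrt(n-2).  Neither enters the pooled t statistic, which uses the
empirical spread of z across analytes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SE_CONVENTIONS = ("as-printed", "pearson-se")

#: family size for pathway-group tests: 7 group-level tests per genotype
#: (LA-ALL, LA-LOX, LA-CYP, AA-ALL, AA-LOX, AA-CYP, AA-COX) x 2 timepoints
DEFAULT_FAMILY_SIZE = 14

MIN_PAIRS = 4


class CorrelationError(ValueError):
    pass


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationRecord:
    """One analyte-versus-score Spearman correlation with its Fisher z."""

    analyte: str
    precursor: str
    pathway: str
    genotype: str
    timepoint: str
    r: float
    z: float
    se: float
    n: int
    se_convention: str = "as-printed"


@dataclass(frozen=True)
class GroupKey:
    """Pooling cell: precursor, pathway (or "ALL"), genotype, timepoint."""

    precursor: str
    pathway: str  # a pathway label or "ALL"
    genotype: str
    timepoint: str

    def matches(self, rec: CorrelationRecord) -> bool:
        return (
            rec.precursor == self.precursor
            and (self.pathway == "ALL" or rec.pathway == self.pathway)
            and rec.genotype == self.genotype
            and rec.timepoint == self.timepoint
        )


@dataclass(frozen=True)
class PooledGroupResult:
    key: GroupKey
    mean_z: float
    pooled_r: float      # tanh(mean_z), the headline back-transform
    mean_r: float        # raw mean of r, also emitted
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    n_analytes: int
    degenerate: bool = False


@dataclass(frozen=True)
class TimepointContrast:
    key: GroupKey
    z_differences: tuple[float, ...]
    t: float
    df: int
    p: float
    no_change: bool = False


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, int]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Mid-ranks (average ranks) are used for ties; the coefficient is the
    Pearson correlation of the ranks.  Returns (r, n); r is NaN when either
    variable has zero rank variance (flagged-undefined, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_PAIRS:
        raise CorrelationError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, n
    return float(np.corrcoef(rx, ry)[0, 1]), n


def partial_pearson_age(x, y, age) -> tuple[float, int]:
    """Pearson correlation of x and y with age partialled out.

    Computed as the correlation of the residuals of x and y on age (with
    intercept); equals the closed form
    (r_xy - r_xa r_ya) / sqrt((1 - r_xa^2)(1 - r_ya^2)).
    Falls back to the plain Pearson correlation (with a warning) when age is
    constant.  NaN when either residual has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(age)
    x, y, age = x[ok], y[ok], age[ok]
    n = len(x)
    if n < 5:
        raise CorrelationError(f"need >= 5 complete triples, got {n}")
    if np.ptp(age) == 0:
        warnings.warn("age is constant; falling back to the plain Pearson correlation")
        return float(np.corrcoef(x, y)[0, 1]), n
    design = np.column_stack([np.ones(n), age])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        return math.nan, n
    return float(np.corrcoef(rx, ry)[0, 1]), n


def fisher_z(r: float) -> float:
    """Fisher r-to-z: z = atanh(r) = 0.5 ln((1+r)/(1-r)); requires |r| < 1."""
    if not abs(r) < 1.0:
        raise CorrelationError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return math.atanh(r)


def fisher_z_inv(z: float) -> float:
    """Inverse Fisher transform: r = tanh(z)."""
    return math.tanh(z)


def correlation_se(r: float, n: int, convention: str = "as-printed") -> float:
    """Standard error of a single correlation under a named convention.

    ``as-printed``: |1 - r| / sqrt(n - 2);  ``pearson-se``: the textbook
    sqrt(1 - r^2) / sqrt(n - 2).  The two coincide at r = 0.
    """
    if n < 3:
        raise CorrelationError(f"need n >= 3 for a correlation SE, got {n}")
    if convention == "as-printed":
        return abs(1.0 - r) / math.sqrt(n - 2)
    if convention == "pearson-se":
        if abs(r) > 1.0:
            raise CorrelationError(f"|r| must be <= 1, got {r}")
        return math.sqrt(1.0 - r * r) / math.sqrt(n - 2)
    raise CorrelationError(
        f"unknown SE convention {convention!r}; expected one of {SE_CONVENTIONS}"
    )


def bonferroni(p_raw: float, family_size: int) -> float:
    """Bonferroni adjustment: min(1, family_size * p_raw)."""
    if family_size < 1:
        raise CorrelationError(f"family_size must be >= 1, got {family_size}")
    return min(1.0, family_size * p_raw)


# --------------------------------------------------------------------------
# building records from a scored cohort
# --------------------------------------------------------------------------

def correlate_panel(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    panel,
    se_convention: str = "as-printed",
) -> list[CorrelationRecord]:
    """Analyte-vs-score Spearman correlations per genotype-by-timepoint cell.

    ``scores`` is the (subject_id, genotype, timepoint, at_insc) table;
    ``cohort`` the tidy table carrying eicosanoid concentrations; ``panel``
    an EicosanoidPanelSpec.  Missing values are handled by pairwise deletion;
    analytes with undefined correlation (zero rank variance) are dropped.
    """
    if se_convention not in SE_CONVENTIONS:
        raise CorrelationError(
            f"unknown SE convention {se_convention!r}; expected one of {SE_CONVENTIONS}"
        )
    eic = cohort[cohort["family"] == "eicosanoid"]
    wide = eic.pivot_table(
        index=["subject_id", "timepoint"], columns="variable", values="value"
    )
    s = scores.set_index(["subject_id", "timepoint"])
    records: list[CorrelationRecord] = []
    cells = scores[["genotype", "timepoint"]].drop_duplicates().itertuples(index=False)
    for genotype, timepoint in sorted(cells):
        mask = (scores["genotype"] == genotype) & (scores["timepoint"] == timepoint)
        idx = pd.MultiIndex.from_frame(
            scores.loc[mask, ["subject_id", "timepoint"]]
        )
        x = s.loc[idx, "at_insc"].to_numpy()
        for analyte, precursor, pathway in panel.analytes:
            if analyte not in wide.columns:
                raise CorrelationError(f"cohort lacks eicosanoid {analyte!r}")
            y = wide.reindex(idx)[analyte].to_numpy()
            r, n = spearman(x, y)
            if math.isnan(r):
                continue
            records.append(
                CorrelationRecord(
                    analyte=analyte,
                    precursor=precursor,
                    pathway=pathway,
                    genotype=genotype,
                    timepoint=timepoint,
                    r=r,
                    z=fisher_z(r),
                    se=correlation_se(r, n, se_convention),
                    n=n,
                    se_convention=se_convention,
                )
            )
    return records


# --------------------------------------------------------------------------
# pooling and contrasts
# --------------------------------------------------------------------------

def _one_sample_t(values: np.ndarray) -> tuple[float, int, float, bool]:
    """One-sample t against zero; handles the zero-spread degeneracy."""
    k = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    df = k - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, False
        return math.copysign(math.inf, mean), df, float(np.nextafter(0, 1)), True
    t = mean / (sd / math.sqrt(k))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p), False


def pool_group(
    records: list[CorrelationRecord],
    key: GroupKey,
    family_size: int = DEFAULT_FAMILY_SIZE,
) -> PooledGroupResult:
    """Pool a pathway group's Fisher z's and test the mean against zero.

    mean_z is the arithmetic mean of the analyte z values; the test is a
    one-sample t across the group's k analytes (df = k - 1); the headline
    pooled correlation is tanh(mean_z), with the raw mean of r also emitted.
    """
    sel = [rec for rec in records if key.matches(rec)]
    if len(sel) < 2:
        raise CorrelationError(
            f"group {key} has {len(sel)} analyte(s); pooling requires >= 2"
        )
    z = np.array([rec.z for rec in sel])
    if not np.isfinite(z).all():
        raise CorrelationError(f"group {key} contains non-finite z values")
    t, df, p, degenerate = _one_sample_t(z)
    mean_z = float(z.mean())
    return PooledGroupResult(
        key=key,
        mean_z=mean_z,
        pooled_r=fisher_z_inv(mean_z),
        mean_r=float(np.mean([rec.r for rec in sel])),
        t=t,
        df=df,
        p_raw=p,
        p_bonferroni=bonferroni(p, family_size),
        n_analytes=len(sel),
        degenerate=degenerate,
    )


def contrast_timepoints(
    records_t0: list[CorrelationRecord],
    records_t1: list[CorrelationRecord],
    key: GroupKey,
) -> TimepointContrast:
    """Paired t on per-analyte z differences (follow-up minus baseline).

    Both record lists must cover the same analyte set for the group.  When
    every difference is exactly zero the result is the documented no-change
    convention: t = 0, p = 1.
    """
    sel0 = {r.analyte: r for r in records_t0 if key.matches(replace_tp(r, key.timepoint))}
    sel1 = {r.analyte: r for r in records_t1 if key.matches(replace_tp(r, key.timepoint))}
    if set(sel0) != set(sel1):
        only0 = sorted(set(sel0) - set(sel1))
        only1 = sorted(set(sel1) - set(sel0))
        raise CorrelationError(
            f"analyte sets differ between timepoints for {key}: "
            f"baseline-only {only0}, follow-up-only {only1}"
        )
    analytes = sorted(sel0)
    if len(analytes) < 2:
        raise CorrelationError(f"group {key} has {len(analytes)} analyte(s); need >= 2")
    d = np.array([sel1[a].z - sel0[a].z for a in analytes])
    if np.all(d == 0.0):
        return TimepointContrast(
            key=key, z_differences=tuple(d), t=0.0, df=len(d) - 1, p=1.0, no_change=True
        )
    t, df, p, _ = _one_sample_t(d)
    return TimepointContrast(key=key, z_differences=tuple(d), t=t, df=df, p=p)


def replace_tp(rec: CorrelationRecord, timepoint: str) -> CorrelationRecord:
    """Record with its timepoint relabelled (used to match a contrast key)."""
    from dataclasses import replace

    return replace(rec, timepoint=timepoint)


def pool_all_groups(
    records: list[CorrelationRecord],
    family_size: int = DEFAULT_FAMILY_SIZE,
    min_analytes: int = 2,
    include_other: bool = False,
) -> list[PooledGroupResult]:
    """Pool every (precursor, pathway-or-ALL, genotype, timepoint) cell.

    Groups with fewer than ``min_analytes`` members are skipped (a group of
    one cannot be pooled); ALL pools every pathway of a precursor.  By
    default the unlabelled OTHER pathway is folded into ALL but not reported
    as a group of its own — the reported surface is then the 7 group tests
    per genotype and timepoint pair that the default family size of 14
    corresponds to.  ``include_other`` adds OTHER groups explicitly.
    """
    results = []
    cells = sorted({(r.genotype, r.timepoint) for r in records})
    precs = sorted({r.precursor for r in records})
    for genotype, timepoint in cells:
        for precursor in precs:
            paths = sorted(
                {
                    r.pathway
                    for r in records
                    if r.precursor == precursor
                    and r.genotype == genotype
                    and r.timepoint == timepoint
                    and (include_other or r.pathway != "OTHER")
                }
            )
            for pathway in ["ALL"] + paths:
                key = GroupKey(precursor, pathway, genotype, timepoint)
                k = sum(1 for r in records if key.matches(r))
                if k < min_analytes:
                    continue
                results.append(pool_group(records, key, family_size))
    return results


# --------------------------------------------------------------------------
# permutation alternative
# --------------------------------------------------------------------------

def permutation_null(
    x, y_panel, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation p-value for the pooled mean z of one analyte panel.

    Subject labels of ``x`` (the score) are permuted jointly against the
    intact ``y_panel`` (n subjects x k analytes), preserving the
    inter-analyte correlation structure.  Returns (empirical p, observed
    mean_z) with p = (1 + #{|mean_z*| >= |mean_z|}) / (n_perm + 1).
    """
    if n_perm < 199:
        raise CorrelationError(f"n_perm must be >= 199, got {n_perm}")
    x = np.asarray(x, dtype=float)
    Y = np.asarray(y_panel, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(x):
        raise CorrelationError("y_panel must be n x k with n matching x")
    n, k = Y.shape
    if n < MIN_PAIRS:
        raise CorrelationError(f"need >= {MIN_PAIRS} subjects, got {n}")
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    rY = np.apply_along_axis(stats.rankdata, 0, Y)
    zx = (rx - rx.mean()) / rx.std(ddof=1)
    zY = (rY - rY.mean(axis=0)) / rY.std(axis=0, ddof=1)

    def mean_z(perm_zx: np.ndarray) -> float:
        r = perm_zx @ zY / (n - 1)
        r = np.clip(r, -0.999999999, 0.999999999)
        return float(np.arctanh(r).mean())

    observed = mean_z(zx)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(mean_z(zx[perm])) >= abs(observed):
            count += 1
    return (1 + count) / (n_perm + 1), observed


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """One row per CorrelationRecord, for CSV output."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "precursor": r.precursor,
                "pathway": r.pathway,
                "genotype": r.genotype,
                "timepoint": r.timepoint,
                "r": r.r,
                "z": r.z,
                "se": r.se,
                "n": r.n,
                "se_convention": r.se_convention,
            }
            for r in records
        ]
    )


def pooled_to_frame(results: list[PooledGroupResult]) -> pd.DataFrame:
    """One row per PooledGroupResult, for CSV output."""
    return pd.DataFrame(
        [
            {
                "precursor": g.key.precursor,
                "pathway": g.key.pathway,
                "genotype": g.key.genotype,
                "timepoint": g.key.timepoint,
                "mean_z": g.mean_z,
                "pooled_r": g.pooled_r,
                "mean_r": g.mean_r,
                "t": g.t,
                "df": g.df,
                "p_raw": g.p_raw,
                "p_bonferroni": g.p_bonferroni,
                "n_analytes": g.n_analytes,
                "degenerate": g.degenerate,
            }
            for g in results
        ]
    )
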