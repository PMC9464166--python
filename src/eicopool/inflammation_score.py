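"""Targeted-expression normalization and the composite inflammation score.

Gene counts from a targeted RNA panel are normalized to percent of the
subject's total aligned reads, Z-transformed per gene over the scoring
population, and averaged across the gene panel into a per-subject composite
adipose-tissue inflammation score (AT-InSc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import TOTAL_READS_VARIABLE


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionMatrix:
    """Subjects-by-genes read counts plus per-subject total aligned reads."""

    counts: pd.DataFrame  # index: subject (or (subject, timepoint)), columns: genes
    totals: pd.Series

    def validate(self) -> None:
        if self.counts.isna().any().any():
            raise ScoreError("counts contain missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ScoreError("negative counts")
        if not self.counts.index.equals(self.totals.index):
            raise ScoreError("counts and totals index mismatch")
        zero = self.totals.index[self.totals <= 0].tolist()
        if zero:
            raise ScoreError(f"zero total aligned reads for subjects {zero[:5]}")


@dataclass(frozen=True)
class InflammationScore:
    """Per-subject composite score with the per-gene z-scores kept for audit."""

    at_insc: pd.Series
    gene_z: pd.DataFrame


def trex_normalize(m: ExpressionMatrix) -> pd.DataFrame:
    """Normalize counts to percent of each subject's total aligned reads."""
    m.validate()
    return 100.0 * m.counts.div(m.totals, axis=0)


def zscore_genes(
    normalized: pd.DataFrame, population: pd.Index | None = None
) -> pd.DataFrame:
    """Z-transform each gene column within the scoring population.

    Means and sample standard deviations (n-1 denominator) come from
    ``population`` rows (default: all rows) and are applied to all rows, so a
    held-out subject can be scored on the population scale.
    """
    pop = normalized.loc[population] if population is not None else normalized
    if len(pop) < 3:
        raise ScoreError(f"scoring population has {len(pop)} subjects; need >= 3")
    mean, sd = pop.mean(axis=0), pop.std(axis=0, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ScoreError(f"zero-variance gene(s) {flat}; cannot Z-transform")
    return (normalized - mean) / sd


def combine_score(gene_z: pd.DataFrame, genes: list[str]) -> InflammationScore:
    """Average the per-gene z-scores of ``genes`` into the composite score."""
    if not genes:
        raise ScoreError("gene subset is empty")
    missing = [g for g in genes if g not in gene_z.columns]
    if missing:
        raise ScoreError(f"genes missing from the z table: {missing}")
    sub = gene_z[list(genes)]
    return InflammationScore(at_insc=sub.mean(axis=1), gene_z=sub)


def expression_from_cohort(cohort: pd.DataFrame, genes: list[str]) -> ExpressionMatrix:
    """Pull the gene-count block of a tidy cohort table into an ExpressionMatrix.

    Rows are indexed by (subject_id, timepoint); total aligned reads come from
    the reserved total-reads variable.
    """
    gc = cohort[cohort["family"] == "gene_count"]
    wide = gc.pivot_table(
        index=["subject_id", "timepoint"], columns="variable", values="value"
    )
    if TOTAL_READS_VARIABLE not in wide.columns:
        raise ScoreError(f"cohort lacks the {TOTAL_READS_VARIABLE!r} variable")
    missing = [g for g in genes if g not in wide.columns]
    if missing:
        raise ScoreError(f"cohort lacks gene counts for {missing}")
    return ExpressionMatrix(
        counts=wide[list(genes)], totals=wide[TOTAL_READS_VARIABLE]
    )


def score_cohort(
    cohort: pd.DataFrame, genes: list[str], per_timepoint: bool = False
) -> pd.DataFrame:
    """End-to-end scoring of a tidy cohort table.

    Normalizes counts, Z-transforms per gene, and averages into the composite
    score.  By default the Z-transform pools all timepoints so week-to-week
    score changes live on a common scale; ``per_timepoint=True`` standardizes
    within each timepoint instead.

    Returns a DataFrame with columns (subject_id, genotype, timepoint, at_insc).
    """
    m = expression_from_cohort(cohort, genes)
    normalized = trex_normalize(m)
    if per_timepoint:
        parts = []
        for tp, block in normalized.groupby(level="timepoint"):
            parts.append(zscore_genes(block))
        gene_z = pd.concat(parts).sort_index()
    else:
        gene_z = zscore_genes(normalized)
    score = combine_score(gene_z, genes)
    out = score.at_insc.rename("at_insc").reset_index()
    geno = (
        cohort[["subject_id", "genotype"]]
        .drop_duplicates()
        .set_index("subject_id")["genotype"]
    )
    out["genotype"] = out["subject_id"].map(geno)
    return out[["subject_id", "genotype", "timepoint", "at_insc"]]
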