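"""Synthetic cohort generator for genotype-stratified diet-intervention studies.

Emulates the data structure of a two-arm (FADS1 TT/CC), two-timepoint dietary
intervention with plasma fatty-acid proportions, LA-/AA-derived eicosanoid
panels, and targeted adipose-tissue gene-expression counts, plus a
cross-sectional obese-cohort variant with a single-gene IL1B readout.

The generative model is a Gaussian latent inflammation factor per
(subject, timepoint) with monotone links to the observed scales:

* eicosanoid concentrations: ``rho * latent + sqrt(1 - rho^2) * noise`` on the
  standardized scale, then an exponential link to a positive concentration
  scale.  Because the downstream analysis is rank-based, the Spearman
  correlation between a generated analyte and the latent factor follows the
  Gaussian-copula identity ``rho_S = (6 / pi) * arcsin(rho / 2)``.
* gene counts: Poisson draws with a log-linear rate in the latent factor
  (``rate = base * exp(loading * latent)``), giving realistic discreteness for
  percent-of-total normalization and Z-scoring downstream.
* fatty-acid proportions: genotype-by-timepoint means plus Gaussian noise
  (optionally latent-coupled), clipped at zero and rescaled so the per-fraction
  sum never exceeds 100 %.

Identical inputs and seed yield byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PRECURSORS = ("LA", "AA")
PATHWAYS = ("COX", "LOX", "CYP450_sEH", "OTHER")
FAMILIES = ("clinical", "fa_proportion", "eicosanoid", "gene_count")

COHORT_COLUMNS = ("subject_id", "genotype", "timepoint", "variable", "family", "value")

#: variable name under which per-subject total aligned reads are stored
TOTAL_READS_VARIABLE = "total_aligned_reads"


class CohortError(ValueError):
    """Invalid design, panel, or effect specification."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Arms, timepoints and per-arm age distributions of a cohort.

    Defaults reproduce the intervention design: TT n=25 and CC n=28,
    ages 55.1 +/- 2.2 and 58.8 +/- 3.1 years, two timepoints.
    """

    arms: tuple[tuple[str, int], ...] = (("TT", 25), ("CC", 28))
    timepoints: tuple[str, ...] = ("week0", "week4")
    age_by_arm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TT": (55.1, 2.2), "CC": (58.8, 3.1)}
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise CohortError("design.arms: at least one arm is required")
        labels = [g for g, _ in self.arms]
        if len(set(labels)) != len(labels):
            raise CohortError("design.arms: duplicate genotype labels")
        for g, n in self.arms:
            if n < 3:
                raise CohortError(
                    f"design.arms: arm {g!r} has n={n}; at least 3 subjects per arm"
                )
        if not self.timepoints:
            raise CohortError("design.timepoints: must be non-empty")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise CohortError("design.timepoints: labels must be unique")
        for g in labels:
            if g not in self.age_by_arm:
                raise CohortError(f"design.age_by_arm: missing arm {g!r}")
            mean, sd = self.age_by_arm[g]
            if sd <= 0:
                raise CohortError(f"design.age_by_arm[{g!r}]: sd must be > 0")


@dataclass(frozen=True)
class EicosanoidPanelSpec:
    """Analyte list with precursor (LA/AA) and biosynthetic-pathway labels."""

    analytes: tuple[tuple[str, str, str], ...]

    def validate(self) -> None:
        names = [a for a, _, _ in self.analytes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise CohortError(f"panel: duplicate analyte names {dup}")
        for name, prec, path in self.analytes:
            if prec not in PRECURSORS:
                raise CohortError(f"panel: analyte {name!r} has unknown precursor {prec!r}")
            if path not in PATHWAYS:
                raise CohortError(f"panel: analyte {name!r} has unknown pathway {path!r}")

    def names(self) -> list[str]:
        return [a for a, _, _ in self.analytes]

    def subset(self, precursor: str | None = None, pathway: str | None = None) -> list[str]:
        return [
            a
            for a, p, w in self.analytes
            if (precursor is None or p == precursor) and (pathway is None or w == pathway)
        ]


@dataclass
class EffectSpec:
    """Parameters of the generative model.

    ``rho`` maps (genotype, timepoint, precursor, pathway) to the latent-scale
    Pearson correlation injected into every analyte of that cell.  ``fa_shift``
    maps (genotype, timepoint) to per-analyte mean shifts of fatty-acid
    proportions; ``fa_rho`` couples a fatty-acid proportion to the latent
    factor the same way eicosanoids are coupled.  ``latent_shift`` moves the
    latent mean of a (genotype, timepoint) cell, which is what produces a
    diet-genotype interaction in the composite inflammation score.
    """

    latent_sd: float = 1.0
    latent_autocorr: float = 0.5
    rho: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    latent_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    fa_shift: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    fa_rho: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    gene_loadings: dict[str, float] = field(default_factory=dict)
    gene_base_mean: float = 200.0
    offpanel_reads_mean: float = 5000.0
    eicosanoid_log_sd: float = 0.4
    fa_noise_sd: float = 1.0
    clinical_noise_sd: float = 1.0

    def validate(self) -> None:
        if self.latent_sd <= 0:
            raise CohortError("effects.latent_sd: must be > 0")
        if not -1.0 <= self.latent_autocorr <= 1.0:
            raise CohortError("effects.latent_autocorr: must be in [-1, 1]")
        for key, r in self.rho.items():
            if not abs(r) < 1.0:
                raise CohortError(f"effects.rho[{key}]: |rho| must be < 1, got {r}")
        for cell, rmap in self.fa_rho.items():
            for name, r in rmap.items():
                if not abs(r) < 1.0:
                    raise CohortError(
                        f"effects.fa_rho[{cell}][{name!r}]: |rho| must be < 1, got {r}"
                    )
        for g, lam in self.gene_loadings.items():
            if not math.isfinite(lam):
                raise CohortError(f"effects.gene_loadings[{g!r}]: must be finite")
        for nm, v in (
            ("gene_base_mean", self.gene_base_mean),
            ("eicosanoid_log_sd", self.eicosanoid_log_sd),
            ("fa_noise_sd", self.fa_noise_sd),
            ("clinical_noise_sd", self.clinical_noise_sd),
        ):
            if v <= 0:
                raise CohortError(f"effects.{nm}: must be > 0")


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def spearman_from_pearson(rho: float) -> float:
    """Spearman correlation of a bivariate Gaussian with Pearson ``rho``."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


def pearson_from_spearman(rs: float) -> float:
    """Latent Pearson correlation producing Spearman ``rs`` under the copula."""
    return 2.0 * math.sin(math.pi * rs / 6.0)


def default_la_panel() -> EicosanoidPanelSpec:
    """11 LA-derived oxylipins: LOX n=4, CYP450/sEH n=4, 3 non-enzymatic."""
    return EicosanoidPanelSpec(
        analytes=(
            ("9-HODE", "LA", "LOX"),
            ("13-HODE", "LA", "LOX"),
            ("9-oxoODE", "LA", "LOX"),
            ("13-oxoODE", "LA", "LOX"),
            ("9(10)-EpOME", "LA", "CYP450_sEH"),
            ("12(13)-EpOME", "LA", "CYP450_sEH"),
            ("9,10-DiHOME", "LA", "CYP450_sEH"),
            ("12,13-DiHOME", "LA", "CYP450_sEH"),
            ("9,10,13-TriHOME", "LA", "OTHER"),
            ("9,12,13-TriHOME", "LA", "OTHER"),
            ("EKODE", "LA", "OTHER"),
        )
    )


def default_aa_panel() -> EicosanoidPanelSpec:
    """21 AA-derived eicosanoids: COX n=4, LOX n=6, CYP450/sEH n=7, 4 other."""
    return EicosanoidPanelSpec(
        analytes=(
            ("PGE2", "AA", "COX"),
            ("PGD2", "AA", "COX"),
            ("TXB2", "AA", "COX"),
            ("6-keto-PGF1a", "AA", "COX"),
            ("5-HETE", "AA", "LOX"),
            ("8-HETE", "AA", "LOX"),
            ("9-HETE", "AA", "LOX"),
            ("11-HETE", "AA", "LOX"),
            ("12-HETE", "AA", "LOX"),
            ("15-HETE", "AA", "LOX"),
            ("8,9-EET", "AA", "CYP450_sEH"),
            ("11,12-EET", "AA", "CYP450_sEH"),
            ("14,15-EET", "AA", "CYP450_sEH"),
            ("5,6-DiHETrE", "AA", "CYP450_sEH"),
            ("8,9-DiHETrE", "AA", "CYP450_sEH"),
            ("11,12-DiHETrE", "AA", "CYP450_sEH"),
            ("14,15-DiHETrE", "AA", "CYP450_sEH"),
            ("20-HETE", "AA", "OTHER"),
            ("8-iso-PGF2a", "AA", "OTHER"),
            ("5-iPF2a-VI", "AA", "OTHER"),
            ("16-HETE", "AA", "OTHER"),
        )
    )


def default_panel() -> EicosanoidPanelSpec:
    """Combined 32-analyte panel (11 LA- plus 21 AA-derived)."""
    la, aa = default_la_panel(), default_aa_panel()
    return EicosanoidPanelSpec(analytes=la.analytes + aa.analytes)


#: inflammatory genes elevated in obese adipose tissue; IL1B always present
DEFAULT_GENES = (
    "IL1B", "TNF", "IL6", "CCL2", "CCL3", "CD68", "ITGAX", "TLR4", "NLRP3", "IL18",
)

#: baseline phospholipid-fraction composition, % of total fatty acids
DEFAULT_PL_COMPOSITION: dict[str, float] = {
    "16:0": 27.0,
    "18:0": 13.5,
    "18:1n-9": 10.5,
    "18:2n-6": 20.5,   # linoleic acid
    "18:3n-6": 0.12,
    "20:3n-6": 1.6,
    "20:4n-6": 9.0,    # arachidonic acid
    "18:3n-3": 0.25,
    "20:5n-3": 1.5,
    "22:6n-3": 3.8,
}

N6_MEMBERS = ("18:2n-6", "18:3n-6", "20:3n-6", "20:4n-6")
N3_MEMBERS = ("18:3n-3", "20:5n-3", "22:6n-3")

#: clinical variables generated besides age: (name, mean by arm, sd)
DEFAULT_CLINICAL: dict[str, dict[str, tuple[float, float]]] = {
    "weight_kg": {"TT": (80.9, 10.5), "CC": (78.7, 9.2)},
    "bmi_kg_m2": {"TT": (25.6, 2.4), "CC": (24.6, 2.3)},
    "glucose_mmol_l": {"TT": (5.6, 0.4), "CC": (5.7, 0.3)},
}


def default_effects(genes: tuple[str, ...] = DEFAULT_GENES) -> EffectSpec:
    """Study conditions for the showcase intervention cohort.

    Pathway-cell Spearman targets mirror the direction and size of the
    genotype- and timepoint-specific pooled correlations the analysis is built
    to detect (positive CYP450/sEH coupling in TT after the diet, negative
    LOX coupling in CC, a COX sign flip in CC), mapped to the latent Pearson
    scale.  The latent mean falls in CC and rises slightly in TT at week 4,
    which is the diet-genotype interaction in the composite score.
    """
    sp = pearson_from_spearman
    rho = {
        ("TT", "week4", "LA", "CYP450_sEH"): sp(0.257),
        ("CC", "week4", "LA", "LOX"): sp(-0.197),
        ("TT", "week4", "AA", "CYP450_sEH"): sp(0.168),
        ("TT", "week0", "AA", "LOX"): sp(-0.214),
        ("TT", "week4", "AA", "LOX"): sp(0.081),
        ("CC", "week0", "AA", "LOX"): sp(0.164),
        ("TT", "week4", "AA", "COX"): sp(0.099),
        ("CC", "week0", "AA", "COX"): sp(0.284),
        ("CC", "week4", "AA", "COX"): sp(-0.377),
    }
    return EffectSpec(
        rho=rho,
        latent_shift={("TT", "week4"): 0.25, ("CC", "week4"): -0.45},
        fa_shift={
            ("TT", "week4"): {"18:2n-6": 2.5, "20:4n-6": 0.8},
            ("CC", "week4"): {"18:2n-6": 2.5, "20:4n-6": -0.3},
        },
        fa_rho={("TT", "week4"): {"18:2n-6": sp(0.544)}},
        gene_loadings={g: 0.5 for g in genes},
    )


def null_effects(genes: tuple[str, ...] = DEFAULT_GENES) -> EffectSpec:
    """All correlations zero, no shifts: the global null, analytes independent."""
    return EffectSpec(gene_loadings={g: 0.5 for g in genes})


# --------------------------------------------------------------------------
# validation of the tidy table contract
# --------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> None:
    """Check the tidy cohort-table invariants; raise CohortError on violation."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"cohort table missing columns {missing}")
    bad_family = set(table["family"]) - set(FAMILIES)
    if bad_family:
        raise CohortError(f"unknown variable family {sorted(bad_family)}")
    dup = table.duplicated(subset=["subject_id", "timepoint", "variable"])
    if dup.any():
        rows = table.index[dup][:5].tolist()
        raise CohortError(f"duplicate (subject, timepoint, variable) at rows {rows}")
    fa = table[table["family"] == "fa_proportion"]
    if (fa["value"] < 0).any():
        rows = fa.index[fa["value"] < 0][:5].tolist()
        raise CohortError(f"negative fa_proportion at rows {rows}")
    if not fa.empty:
        frac = fa["variable"].str.split("_", n=1).str[0]
        sums = fa.groupby([fa["subject_id"], fa["timepoint"], frac])["value"].sum()
        if (sums > 100.0 + 1e-6).any():
            key = sums.index[sums > 100.0 + 1e-6][0]
            raise CohortError(f"fa_proportion sum exceeds 100 for {key}")
    gc = table[table["family"] == "gene_count"]
    if not gc.empty:
        vals = gc["value"].to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise CohortError("gene_count values must be non-negative integers")
    # every subject present at every timepoint it was designed for
    tps = table["timepoint"].unique()
    per_subj = table.groupby("subject_id")["timepoint"].nunique()
    if (per_subj != len(tps)).any():
        bad = per_subj.index[per_subj != len(tps)][:5].tolist()
        raise CohortError(f"subjects missing timepoints: {bad}")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _long_rows(out: list, sids, genos, timepoint, variable, family, values) -> None:
    out.append(
        pd.DataFrame(
            {
                "subject_id": sids,
                "genotype": genos,
                "timepoint": timepoint,
                "variable": variable,
                "family": family,
                "value": values,
            }
        )
    )


def simulate_cohort(
    design: CohortDesign,
    panel: EicosanoidPanelSpec | None = None,
    genes: tuple[str, ...] = DEFAULT_GENES,
    effects: EffectSpec | None = None,
    return_latent: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genotype-stratified multi-timepoint cohort as a tidy table.

    Returns a DataFrame with columns (subject_id, genotype, timepoint,
    variable, family, value), satisfying the cohort-table invariants.
    With ``return_latent`` the per-(subject, timepoint) latent inflammation
    factor is returned alongside (for calibration and recovery studies).
    """
    panel = panel if panel is not None else default_panel()
    effects = effects if effects is not None else default_effects(genes)
    design.validate()
    panel.validate()
    effects.validate()
    if len(set(genes)) != len(genes):
        raise CohortError("genes: duplicate gene names")

    rng = np.random.default_rng(design.seed)
    sids = np.concatenate(
        [np.array([f"{g}{i + 1:03d}" for i in range(n)]) for g, n in design.arms]
    )
    genos = np.concatenate([np.repeat(g, n) for g, n in design.arms])
    n_sub = len(sids)
    sd = effects.latent_sd
    a = effects.latent_autocorr

    # latent inflammation factor, AR(1) across timepoints (zero-mean part)
    lat = np.empty((n_sub, len(design.timepoints)))
    lat[:, 0] = rng.normal(0.0, sd, n_sub)
    for j in range(1, len(design.timepoints)):
        lat[:, j] = a * lat[:, j - 1] + math.sqrt(max(0.0, 1 - a * a)) * rng.normal(
            0.0, sd, n_sub
        )

    # deterministic per-analyte concentration scales (one stream, fixed order)
    scales = np.exp(rng.normal(0.0, 0.5, len(panel.analytes)))

    rows: list[pd.DataFrame] = []

    # clinical: age constant across timepoints, others per timepoint
    ages = np.concatenate(
        [rng.normal(*design.age_by_arm[g], n) for g, n in design.arms]
    ).round(1)
    for j, tp in enumerate(design.timepoints):
        _long_rows(rows, sids, genos, tp, "age_years", "clinical", ages)
        for var, by_arm in DEFAULT_CLINICAL.items():
            vals = np.empty(n_sub)
            for g, _ in design.arms:
                m = genos == g
                mean, s = by_arm.get(g, (1.0, 0.1))
                vals[m] = rng.normal(mean, s * effects.clinical_noise_sd, m.sum())
            _long_rows(rows, sids, genos, tp, var, "clinical", vals.round(3))

    # fatty-acid proportions (PL fraction)
    for j, tp in enumerate(design.timepoints):
        shift = {}
        frho = {}
        for g, _ in design.arms:
            shift[g] = effects.fa_shift.get((g, tp), {})
            frho[g] = effects.fa_rho.get((g, tp), {})
        lat_std = (lat[:, j] - lat[:, j].mean()) / sd
        raw = np.empty((n_sub, len(DEFAULT_PL_COMPOSITION)))
        names = list(DEFAULT_PL_COMPOSITION)
        for k, name in enumerate(names):
            base = DEFAULT_PL_COMPOSITION[name]
            eps = rng.normal(0.0, 1.0, n_sub)
            vals = np.empty(n_sub)
            for g, _ in design.arms:
                m = genos == g
                r = frho[g].get(name, 0.0)
                std = r * lat_std[m] + math.sqrt(1 - r * r) * eps[m]
                noise = effects.fa_noise_sd * max(base * 0.06, 0.02)
                vals[m] = base + shift[g].get(name, 0.0) + noise * std
            raw[:, k] = np.clip(vals, 0.0, None)
        totals = raw.sum(axis=1)
        over = totals > 99.9
        if over.any():  # keep room for unlisted FAs; proportions sum <= 100
            raw[over] *= (99.9 / totals[over])[:, None]
        for k, name in enumerate(names):
            _long_rows(rows, sids, genos, tp, f"PL_{name}", "fa_proportion", raw[:, k].round(4))

    # eicosanoid concentrations
    for j, tp in enumerate(design.timepoints):
        lat_std = lat[:, j] / sd
        for k, (name, prec, path) in enumerate(panel.analytes):
            eps = rng.normal(0.0, 1.0, n_sub)
            std = np.empty(n_sub)
            for g, _ in design.arms:
                m = genos == g
                r = effects.rho.get((g, tp, prec, path), 0.0)
                std[m] = r * lat_std[m] + math.sqrt(1 - r * r) * eps[m]
            conc = scales[k] * np.exp(effects.eicosanoid_log_sd * std)
            _long_rows(rows, sids, genos, tp, name, "eicosanoid", conc.round(6))

    # gene counts on the shifted latent scale, plus per-subject total reads
    for j, tp in enumerate(design.timepoints):
        shift = np.zeros(n_sub)
        for g, _ in design.arms:
            shift[genos == g] = effects.latent_shift.get((g, tp), 0.0)
        lat_eff = lat[:, j] / sd + shift
        panel_sum = np.zeros(n_sub)
        for gname in genes:
            lam = effects.gene_loadings.get(gname, 0.0)
            rate = effects.gene_base_mean * np.exp(lam * lat_eff - lam * lam / 2.0)
            counts = rng.poisson(rate).astype(float)
            panel_sum += counts
            _long_rows(rows, sids, genos, tp, gname, "gene_count", counts)
        total = panel_sum + rng.poisson(effects.offpanel_reads_mean, n_sub)
        _long_rows(rows, sids, genos, tp, TOTAL_READS_VARIABLE, "gene_count", total)

    table = pd.concat(rows, ignore_index=True)
    validate_cohort(table)
    if return_latent:
        latent = pd.DataFrame(lat, index=pd.Index(sids, name="subject_id"),
                              columns=list(design.timepoints))
        return table, latent
    return table


def simulate_cross_sectional(
    design: CohortDesign,
    genes: tuple[str, ...] = ("IL1B",),
    la_effect: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a single-timepoint cohort with a tertile-wise LA -> IL1B effect.

    ``la_effect`` maps genotype to the log-scale mean increment of gene counts
    per step up the within-genotype PL-LA tertile ladder (0 = no effect).
    Default design should carry arms TT n=42 and CC n=28 at one timepoint.
    """
    design.validate()
    if len(design.timepoints) != 1:
        raise CohortError(
            f"cross-sectional design requires exactly 1 timepoint, got {len(design.timepoints)}"
        )
    la_effect = la_effect or {}
    tp = design.timepoints[0]
    rng = np.random.default_rng(design.seed)
    sids = np.concatenate(
        [np.array([f"{g}{i + 1:03d}" for i in range(n)]) for g, n in design.arms]
    )
    genos = np.concatenate([np.repeat(g, n) for g, n in design.arms])
    n_sub = len(sids)

    rows: list[pd.DataFrame] = []
    ages = np.concatenate(
        [rng.normal(*design.age_by_arm[g], n) for g, n in design.arms]
    ).round(1)
    _long_rows(rows, sids, genos, tp, "age_years", "clinical", ages)

    # continuous PL-LA so tertiles are well defined almost surely
    la = rng.normal(DEFAULT_PL_COMPOSITION["18:2n-6"], 2.5, n_sub)
    la = np.clip(la, 0.1, None)
    _long_rows(rows, sids, genos, tp, "PL_18:2n-6", "fa_proportion", la.round(4))

    # gene counts with a per-tertile log-mean step within each genotype
    base = 200.0
    log_shift = np.zeros(n_sub)
    for g, _ in design.arms:
        m = genos == g
        eff = la_effect.get(g, 0.0)
        if eff != 0.0:
            v = la[m]
            cuts = np.percentile(v, [100 / 3, 200 / 3])
            tert = np.where(v <= cuts[0], 0, np.where(v <= cuts[1], 1, 2))
            log_shift[m] = eff * tert
    panel_sum = np.zeros(n_sub)
    for gname in genes:
        noise = rng.normal(0.0, 0.3, n_sub)  # subject-level overdispersion
        counts = rng.poisson(base * np.exp(log_shift + noise)).astype(float)
        panel_sum += counts
        _long_rows(rows, sids, genos, tp, gname, "gene_count", counts)
    total = panel_sum + rng.poisson(5000.0, n_sub)
    _long_rows(rows, sids, genos, tp, TOTAL_READS_VARIABLE, "gene_count", total)

    table = pd.concat(rows, ignore_index=True)
    validate_cohort(table)
    return table


def with_seed(design: CohortDesign, seed: int) -> CohortDesign:
    """A copy of ``design`` with a different seed."""
    return replace(design, seed=seed)
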