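"""Derived fatty-acid quantities.

Desaturase-activity indices (product-to-precursor ratios), n-6/n-3 PUFA
totals, tertile stratification of a continuous measure, and the
normality-routing rule that decides whether a variable enters parametric
analyses on the natural-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05

#: analytes required for the desaturase indices
_D5D_NUM, _D5D_DEN = "20:4n-6", "20:3n-6"
_D6D_NUM, _D6D_DEN = "18:3n-6", "18:2n-6"


class FattyAcidError(ValueError):
    pass


@dataclass(frozen=True)
class FAProfile:
    """Fatty-acid proportions (% of total FA) in one plasma lipid fraction."""

    fraction: str  # PL, CE or TG
    proportions: dict[str, float]

    def validate(self) -> None:
        if self.fraction not in ("PL", "CE", "TG"):
            raise FattyAcidError(f"unknown lipid fraction {self.fraction!r}")
        neg = [k for k, v in self.proportions.items() if v < 0]
        if neg:
            raise FattyAcidError(f"negative proportions for {neg}")
        total = sum(self.proportions.values())
        if total > 100.0 + 1e-6:
            raise FattyAcidError(f"proportions sum to {total} > 100")


@dataclass(frozen=True)
class DesaturaseIndices:
    """Delta-5 and delta-6 desaturase activity estimates.

    d5d = 20:4n-6 / 20:3n-6 and d6d = 18:3n-6 / 18:2n-6; an index whose
    denominator proportion is zero is flagged undefined (NaN value).
    """

    d5d: float
    d6d: float
    fraction: str
    d5d_defined: bool = True
    d6d_defined: bool = True


@dataclass(frozen=True)
class TertileAssignment:
    labels: pd.Series  # per-subject "T1" | "T2" | "T3"
    cutpoints: tuple[float, float]


@dataclass(frozen=True)
class NormalityRoute:
    use_log: bool
    values: np.ndarray
    shapiro_p: float


def desaturase_indices(profile: FAProfile) -> DesaturaseIndices:
    """Estimate D5D and D6D activity as product-to-precursor ratios."""
    profile.validate()
    p = profile.proportions
    for analyte in (_D5D_NUM, _D5D_DEN, _D6D_NUM, _D6D_DEN):
        if analyte not in p:
            raise FattyAcidError(f"profile missing analyte {analyte!r}")
    d5_ok, d6_ok = p[_D5D_DEN] > 0, p[_D6D_DEN] > 0
    return DesaturaseIndices(
        d5d=p[_D5D_NUM] / p[_D5D_DEN] if d5_ok else math.nan,
        d6d=p[_D6D_NUM] / p[_D6D_DEN] if d6_ok else math.nan,
        fraction=profile.fraction,
        d5d_defined=d5_ok,
        d6d_defined=d6_ok,
    )


def pufa_totals(
    profile: FAProfile, n6_members: list[str], n3_members: list[str]
) -> tuple[float, float]:
    """Total n-6 and n-3 PUFA as plain sums of member proportions."""
    profile.validate()
    for member in list(n6_members) + list(n3_members):
        if member not in profile.proportions:
            raise FattyAcidError(f"unknown member analyte {member!r}")
    return (
        sum(profile.proportions[m] for m in n6_members),
        sum(profile.proportions[m] for m in n3_members),
    )


def assign_tertiles(values: pd.Series) -> TertileAssignment:
    """Split subjects into tertiles at the 33.33rd/66.67th percentiles.

    Cut-points use linear interpolation between order statistics; values tied
    with a cut-point go to the lower tertile, so the assignment is
    deterministic and invariant under strictly increasing transforms.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 3:
        raise FattyAcidError(f"need >= 3 subjects for tertiles, got {len(values)}")
    if not np.isfinite(values.to_numpy()).all():
        raise FattyAcidError("non-finite values in tertile input")
    c1, c2 = np.percentile(values.to_numpy(), [100.0 / 3.0, 200.0 / 3.0])
    if c1 == c2 and values.nunique() == 1:
        raise FattyAcidError("degenerate distribution: all values equal, no cut-points")
    labels = pd.Series(
        np.where(values <= c1, "T1", np.where(values <= c2, "T2", "T3")),
        index=values.index,
    )
    return TertileAssignment(labels=labels, cutpoints=(float(c1), float(c2)))


def normality_route(values: np.ndarray | pd.Series) -> NormalityRoute:
    """Route a variable through a natural-log transform when non-normal.

    A Shapiro-Wilk test at alpha=0.05 decides: p < 0.05 with all-positive
    values returns the log-transformed variable with ``use_log`` set;
    otherwise the identity.  A non-normal variable containing non-positive
    values is an error (an explicit offset policy must be chosen upstream;
    nothing is silently shifted).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise FattyAcidError(f"need n >= 3 for the normality route, got {arr.size}")
    if not np.isfinite(arr).all():
        raise FattyAcidError("non-finite values")
    p = float(stats.shapiro(arr).pvalue)
    if p >= SHAPIRO_ALPHA:
        return NormalityRoute(use_log=False, values=arr, shapiro_p=p)
    if (arr <= 0).any():
        raise FattyAcidError(
            "variable is non-normal (Shapiro-Wilk p = %.3g) but contains "
            "non-positive values; apply an explicit offset policy before routing" % p
        )
    return NormalityRoute(use_log=True, values=np.log(arr), shapiro_p=p)
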