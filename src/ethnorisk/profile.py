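"""Area-based risk indices from per-group relative-risk profiles.

Plotting one group's RR values against its SNPs (panel order, unit spacing)
gives one polyline per ethnicity.  The area under that polyline — trapezoid
rule by default — summarizes the group-wide susceptibility of the ethnicity.
Dividing each ethnicity's area by the group minimum yields the *group risk
index*: the minimum-risk ethnicity scores exactly 1 and every other index is
the fold increase over it.  Averaging the three group indices with equal
weights gives the *cumulative index*, a single per-ethnicity susceptibility
summary.

Indices are ratios of areas, so they are invariant under a uniform rescaling
of a group's RRs, and for constant profiles they are independent of the SNP
ordering and of the integration rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, DegenerateProfileError
from .risk import RelativeRiskMatrix

logger = logging.getLogger(__name__)

AREA_RULES = ("trapezoid", "sum")


@dataclass(frozen=True)
class GroupRiskProfile:
    """One ethnicity's ordered RR values over one group's SNPs."""

    group: str
    ethnicity: str
    rr_values: tuple[float, ...]
    snp_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rr_values) != len(self.snp_order):
            raise ConfigError("rr_values and snp_order lengths differ")


@dataclass(frozen=True)
class GroupRiskIndex:
    """Per-group areas and min-normalized indices across ethnicities."""

    group: str
    areas: dict[str, float]
    indices: dict[str, float]
    reference_ethnicity: str
    area_rule: str = "trapezoid"
    tied_reference: bool = False


@dataclass(frozen=True)
class CumulativeIndex:
    """Equal-weight average of the three group indices per ethnicity."""

    per_group: dict[str, dict[str, float]]
    average: dict[str, float]


def profile_area(profile: GroupRiskProfile | Sequence[float], rule: str = "trapezoid") -> float:
    """Area under a risk profile with unit spacing between consecutive SNPs.

    ``trapezoid`` integrates the polyline: sum_i (rr[i] + rr[i+1]) / 2.
    ``sum`` is the plain rectangle rule (sum of RRs).  A constant profile of
    value c over G SNPs has trapezoid area c*(G-1) and sum area c*G; the
    min-normalized indices downstream agree between the rules for constant
    profiles.
    """
    values = profile.rr_values if isinstance(profile, GroupRiskProfile) else profile
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateProfileError(
            f"profile needs at least 2 points, got {arr.size}"
        )
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise DegenerateProfileError("profile values must be finite and nonnegative")
    if rule == "trapezoid":
        return float(np.trapezoid(arr))
    if rule == "sum":
        return float(arr.sum())
    raise ConfigError(f"unknown area rule {rule!r}; choose from {AREA_RULES}")


def group_indices(
    matrix: RelativeRiskMatrix, group: str, area_rule: str = "trapezoid"
) -> GroupRiskIndex:
    """Profile areas and min-normalized indices for one gene group.

    The reference ethnicity is the arg-min of the areas; exact ties resolve to
    the first ethnicity in matrix order, with a logged notice.  The reference
    index is exactly 1 and all indices are >= 1.
    """
    sub = matrix.group_values(group)
    if sub.shape[1] < 2:
        raise DegenerateProfileError(
            f"group {group!r} has {sub.shape[1]} retained SNP(s); need at least 2"
        )
    areas = {eth: profile_area(sub.loc[eth].to_numpy(), rule=area_rule) for eth in sub.index}
    min_area = min(areas.values())
    ref = next(eth for eth in sub.index if areas[eth] == min_area)
    tied = sum(1 for a in areas.values() if a == min_area) > 1
    if tied:
        logger.warning(
            "group %s: tie for minimum area; reference set to first ethnicity %s", group, ref
        )
    if min_area <= 0:
        raise DegenerateProfileError(f"group {group!r}: minimum area is zero")
    indices = {eth: areas[eth] / min_area for eth in areas}
    return GroupRiskIndex(
        group=group, areas=areas, indices=indices,
        reference_ethnicity=ref, area_rule=area_rule, tied_reference=tied,
    )


def cumulative_index(indices: Sequence[GroupRiskIndex]) -> CumulativeIndex:
    """Equal-weight arithmetic mean of exactly three group indices per ethnicity."""
    if len(indices) != 3:
        raise ConfigError(f"cumulative index needs exactly 3 groups, got {len(indices)}")
    eth_sets = [tuple(gi.indices) for gi in indices]
    if any(set(e) != set(eth_sets[0]) for e in eth_sets[1:]):
        raise ConfigError(f"group indices cover different ethnicity sets: {eth_sets}")
    per_group = {gi.group: dict(gi.indices) for gi in indices}
    if len(per_group) != 3:
        raise ConfigError("duplicate group among the three indices")
    ethnicities = eth_sets[0]
    average = {
        eth: sum(gi.indices[eth] for gi in indices) / 3.0 for eth in ethnicities
    }
    return CumulativeIndex(per_group=per_group, average=average)


def format_index(value: float) -> str:
    """Display rounding for index tables: one decimal, trailing ``.0`` dropped
    (5.033 -> "5", 11.667 -> "11.7")."""
    r = round(float(value), 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


def indices_frame(cumulative: CumulativeIndex, group_order: Sequence[str]) -> pd.DataFrame:
    """Ethnicity-per-row table of per-group indices plus the average column."""
    ethnicities = list(cumulative.average)
    data = {g: [cumulative.per_group[g][e] for e in ethnicities] for g in group_order}
    data["average"] = [cumulative.average[e] for e in ethnicities]
    return pd.DataFrame(data, index=pd.Index(ethnicities, name="ethnicity"))


class RiskProfileIndexer(BaseEstimator):
    """Estimator-style wrapper: fit a RelativeRiskMatrix, expose areas/indices.

    Fitted attributes: ``group_indices_`` (group -> GroupRiskIndex),
    ``cumulative_`` (CumulativeIndex, present when exactly three groups),
    ``indices_`` (ethnicity-per-row DataFrame in the standard report layout).
    """

    def __init__(self, area_rule: str = "trapezoid") -> None:
        self.area_rule = area_rule

    def fit(self, X: RelativeRiskMatrix, y=None) -> "RiskProfileIndexer":
        groups = X.groups
        self.group_indices_ = {
            g: group_indices(X, g, area_rule=self.area_rule) for g in groups
        }
        if len(groups) == 3:
            self.cumulative_ = cumulative_index(list(self.group_indices_.values()))
            self.indices_ = indices_frame(self.cumulative_, groups)
        else:
            self.cumulative_ = None
            self.indices_ = pd.DataFrame(
                {g: gi.indices for g, gi in self.group_indices_.items()}
            )
        return self
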