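"""Lung-RADS 1.1 baseline categorization of screening CT nodules.

Implements the baseline (first screening exam) rule table: category 1 for a
negative exam, 2/3/4A/4B by nodule size and density, and the 4X modifier for
category >= 3 nodules carrying additional suspicious features (here,
spiculated margins).  Size boundaries are half-open intervals [lo, hi) on
the mean diameter.  Growth-based categories for follow-up exams are out of
scope; so is the v2022 revision.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable

from .cohort import Density, NoduleObservation

__all__ = ["LungRads", "nodule_category", "classify_lungrads", "LUNGRADS_STRATA"]


class LungRads(Enum):
    """Ordered Lung-RADS 1.1 categories: 1 < 2 < 3 < 4A < 4B < 4X."""

    CAT_1 = "1"
    CAT_2 = "2"
    CAT_3 = "3"
    CAT_4A = "4A"
    CAT_4B = "4B"
    CAT_4X = "4X"

    @property
    def rank(self) -> int:
        return _RANK[self]

    def __lt__(self, other: "LungRads") -> bool:
        return self.rank < other.rank

    @property
    def value_str(self) -> str:
        return self.value


_RANK = {
    LungRads.CAT_1: 1,
    LungRads.CAT_2: 2,
    LungRads.CAT_3: 3,
    LungRads.CAT_4A: 4,
    LungRads.CAT_4B: 5,
    LungRads.CAT_4X: 6,
}

# Table 3 of the stratified predictive-value analysis merges categories.
LUNGRADS_STRATA = ("1/2", "3", "4A", "4B/4X")


def _base_category(nodule: NoduleObservation) -> LungRads:
    """Baseline category of a single nodule before the 4X modifier."""
    d = nodule.mean_diameter_mm
    if nodule.density is Density.SOLID:
        if d < 6:
            return LungRads.CAT_2
        if d < 8:
            return LungRads.CAT_3
        if d < 15:
            return LungRads.CAT_4A
        return LungRads.CAT_4B
    if nodule.density is Density.PART_SOLID:
        sc = nodule.solid_component_mm
        if d < 6:
            return LungRads.CAT_2
        if sc < 6:
            return LungRads.CAT_3
        if sc < 8:
            return LungRads.CAT_4A
        return LungRads.CAT_4B
    # non-solid (ground glass): category 3 only from 30 mm at baseline
    if d < 30:
        return LungRads.CAT_2
    return LungRads.CAT_3


def nodule_category(nodule: NoduleObservation, subject_id: str = "?") -> LungRads:
    """Per-nodule baseline category, including the 4X promotion for
    spiculated nodules whose base category is 3 or higher."""
    nodule.validate(subject_id)
    base = _base_category(nodule)
    if nodule.spiculated and base.rank >= LungRads.CAT_3.rank:
        return LungRads.CAT_4X
    return base


def classify_lungrads(nodules: Iterable[NoduleObservation], subject_id: str = "?") -> LungRads:
    """Subject-level baseline category: the maximum per-nodule category.

    An empty nodule list (negative exam) is category 1.  The result is
    invariant to nodule order, and adding a nodule can never lower it.
    """
    best = LungRads.CAT_1
    for nodule in nodules:
        cat = nodule_category(nodule, subject_id)
        if cat.rank > best.rank:
            best = cat
    return best


def lungrads_stratum(category: LungRads) -> str:
    """Merged stratum used in predictive-value tables: 1/2, 3, 4A, 4B/4X."""
    if category.rank <= LungRads.CAT_2.rank:
        return "1/2"
    if category is LungRads.CAT_3:
        return "3"
    if category is LungRads.CAT_4A:
        return "4A"
    return "4B/4X"
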