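"""Brock (PanCan) nodule malignancy probability model.

The full logistic model with spiculation: the linear predictor combines age
(centered at 62 years), female sex, family history of lung cancer,
emphysema, a nonlinear mean-diameter transform ``(d/10)^-0.5`` centered so
that a 4 mm nodule contributes zero, nodule density (part-solid positive,
non-solid negative relative to solid), upper-lobe location, nodule count
(centered at 4) and spiculated margins.  Coefficients are transcribed in a
versioned JSON constants file with their source citation
(``data/brock_coefficients.json``).

The conventional screening decision threshold is a 5% probability,
compared closed on the left (score >= threshold is flagged).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .cohort import Density, Sex, SubjectRecord, main_nodule

__all__ = [
    "BrockInputs",
    "brock_coefficients",
    "brock_score",
    "brock_flag",
    "brock_stratum",
    "brock_inputs_for_subject",
    "BROCK_STRATA",
]

BROCK_STRATA = ("<1%", "[1-5)%", "[5-10)%", ">=10%")


@dataclass(frozen=True)
class BrockInputs:
    """Covariates of the full-with-spiculation Brock model."""

    age_years: float
    sex: Sex
    family_history_lc: bool
    emphysema: bool
    mean_diameter_mm: float
    density: Density
    upper_lobe: bool
    nodule_count: int
    spiculated: bool

    def validate(self) -> None:
        if not self.mean_diameter_mm > 0:
            raise ValueError("mean_diameter_mm must be positive")
        if self.nodule_count < 1:
            raise ValueError("nodule_count must be >= 1")


@lru_cache(maxsize=1)
def brock_coefficients() -> dict:
    """Published model coefficients, loaded from the packaged JSON file."""
    with resources.files("cfscreen.data").joinpath("brock_coefficients.json").open("r") as fh:
        return json.load(fh)


def brock_score(inputs: BrockInputs) -> float:
    """Malignancy probability in (0, 1) under the full Brock model."""
    inputs.validate()
    c = brock_coefficients()
    x = c["intercept"]
    x += c["age_per_year_centered_62"] * (inputs.age_years - 62.0)
    if inputs.sex is Sex.FEMALE:
        x += c["sex_female"]
    if inputs.family_history_lc:
        x += c["family_history_lc"]
    if inputs.emphysema:
        x += c["emphysema"]
    x += c["size_coefficient"] * ((inputs.mean_diameter_mm / 10.0) ** -0.5 - c["size_center"])
    if inputs.density is Density.PART_SOLID:
        x += c["density_part_solid"]
    elif inputs.density is Density.NON_SOLID:
        x += c["density_non_solid"]
    if inputs.upper_lobe:
        x += c["upper_lobe"]
    x += c["nodule_count_per_nodule_centered_4"] * (inputs.nodule_count - 4.0)
    if inputs.spiculated:
        x += c["spiculated"]
    return 1.0 / (1.0 + math.exp(-x))


def brock_flag(score: float, threshold: float = 0.05) -> bool:
    """True when the malignancy probability meets the decision threshold
    (closed on the left: score >= threshold)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return score >= threshold


def brock_stratum(score: float) -> str:
    """Half-open probability stratum: <1%, [1-5)%, [5-10)%, >=10%."""
    if score < 0.01:
        return BROCK_STRATA[0]
    if score < 0.05:
        return BROCK_STRATA[1]
    if score < 0.10:
        return BROCK_STRATA[2]
    return BROCK_STRATA[3]


def brock_inputs_for_subject(record: SubjectRecord) -> BrockInputs | None:
    """Model inputs for a subject's main baseline nodule.

    Returns None for a nodule-free baseline exam (no score is defined; the
    pipeline treats such subjects as probability 0 for ranking purposes).
    """
    nodule = main_nodule(record)
    if nodule is None:
        return None
    return BrockInputs(
        age_years=record.age_years,
        sex=record.sex,
        family_history_lc=record.family_history_lc,
        emphysema=record.emphysema,
        mean_diameter_mm=nodule.mean_diameter_mm,
        density=nodule.density,
        upper_lobe=nodule.upper_lobe,
        nodule_count=max(1, len(record.baseline_nodules())),
        spiculated=nodule.spiculated,
    )


def brock_score_for_subject(record: SubjectRecord) -> float:
    """Main-nodule Brock score, with 0.0 for a nodule-free baseline exam."""
    inputs = brock_inputs_for_subject(record)
    if inputs is None:
        return 0.0
    return brock_score(inputs)
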