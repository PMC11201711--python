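"""Subject-level cohorts reconstructed from published marginal count tables.

The underlying trial's subject-level data are not deposited, but its
descriptive and stratified tables print exact counts.  The builders here
synthesize minimal subject rows that reproduce those counts, so threshold
performance, group positivity fractions and stratified predictive values
can be recomputed from real (published) numbers without any download.

Each builder reproduces exactly one published marginal/joint table; the
full joint distribution across stratifiers was never published, so the
cohorts are *synthetic reconstructions* and only the counts each one
encodes are meaningful.
"""

from __future__ import annotations

from .cohort import (
    Density,
    NoduleObservation,
    OutcomeClass,
    OutcomeLabel,
    Sex,
    SmokingStatus,
    SubjectRecord,
)

__all__ = [
    "CFDNA_CATEGORY_COUNTS",
    "TABLE_STRATA_COUNTS",
    "cfdna_category_cohort",
    "strata_cohort",
]

# Published cfDNA category counts (<3.15, [3.15-5), >=5 ng/mL) per outcome
# group: benign n=108, prevalent LC n=17, incident LC n=12.
CFDNA_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "benign": (71, 21, 16),
    "prevalent_lc": (3, 2, 12),
    "incident_lc": (3, 5, 4),
}

# Representative concentrations, one per category; 3.15 and 5.0 sit exactly
# on the half-open category boundaries so threshold scans recover them.
CFDNA_CATEGORY_VALUES = (2.0, 3.15, 5.0)

# Published stratified counts at the 3.15 ng/mL cutoff:
# stratum -> (benign_below, cancer_below, benign_above, cancer_above)
TABLE_STRATA_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "size_class": {
        "<6": (41, 1, 19, 5),
        "6-<8": (11, 0, 11, 3),
        "8-<15": (15, 3, 6, 5),
        ">=15": (4, 2, 1, 10),
    },
    "lungrads_class": {
        "1/2": (45, 2, 25, 8),
        "3": (10, 0, 7, 2),
        "4A": (12, 2, 4, 2),
        "4B/4X": (4, 2, 1, 11),
    },
    "brock_class": {
        "<1%": (38, 1, 20, 5),
        "[1-5)%": (20, 1, 10, 2),
        "[5-10)%": (4, 1, 6, 1),
        ">=10%": (9, 3, 1, 15),
    },
}

# Nodule blueprints whose derived stratum lands in the intended class.
# size_class / lungrads_class: solid nodules of the stated diameter
# (5 mm -> Lung-RADS 2, 7 mm -> 3, 10 mm -> 4A, 16 mm -> 4B; spiculation
# promotes >= 3 to 4X).  brock_class: with the default covariates below
# (62 y male, no family history, no emphysema, lower lobe, single nodule,
# no spiculation) the stated diameters give Brock scores of about 0.3%,
# 3.2%, 8.1% and 13.8%.
_STRATUM_NODULES: dict[str, dict[str, dict]] = {
    "size_class": {
        "<6": {"d": 5.0},
        "6-<8": {"d": 7.0},
        "8-<15": {"d": 10.0},
        ">=15": {"d": 16.0},
    },
    "lungrads_class": {
        "1/2": {"d": 5.0},
        "3": {"d": 7.0},
        "4A": {"d": 10.0},
        "4B/4X": {"d": 16.0, "spiculated": True},
    },
    "brock_class": {
        "<1%": {"d": 4.6},
        "[1-5)%": {"d": 10.0},
        "[5-10)%": {"d": 15.0},
        ">=10%": {"d": 20.0},
    },
}


def _subject(
    sid: str,
    cfdna: float,
    outcome: OutcomeLabel,
    nodules: tuple[NoduleObservation, ...] = (),
) -> SubjectRecord:
    rec = SubjectRecord(
        subject_id=sid,
        age_years=62.0,
        sex=Sex.MALE,
        pack_years=40.0,
        smoking_status=SmokingStatus.CURRENT,
        family_history_lc=False,
        emphysema=False,
        cfdna_ng_ml=cfdna,
        outcome=outcome,
        nodules=nodules,
    )
    rec.validate()
    return rec


def _outcome(group: str) -> OutcomeLabel:
    cls = OutcomeClass(group)
    if cls is OutcomeClass.BENIGN:
        return OutcomeLabel(cls)
    if cls is OutcomeClass.PREVALENT_LC:
        return OutcomeLabel(cls, 1)
    return OutcomeLabel(cls, 3)


def cfdna_category_cohort() -> list:
    """137 subjects reproducing the published cfDNA category counts per
    outcome group (no nodule data; cfDNA and outcome only)."""
    records = []
    i = 0
    for group, counts in CFDNA_CATEGORY_COUNTS.items():
        for value, n in zip(CFDNA_CATEGORY_VALUES, counts):
            for _ in range(n):
                i += 1
                records.append(_subject(f"r{i:03d}", value, _outcome(group)))
    return records


def strata_cohort(stratifier: str) -> list:
    """137 subjects reproducing the published below/above-cutoff counts for
    one stratification (size class, merged Lung-RADS class, or Brock score
    class) at the 3.15 ng/mL cfDNA cutoff.

    cfDNA is 2.0 ng/mL below the cutoff and 4.0 at/above it; cancers are
    labelled prevalent (the table does not split them by round).
    """
    if stratifier not in TABLE_STRATA_COUNTS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    records = []
    i = 0
    for stratum, (bb, cb, ba, ca) in TABLE_STRATA_COUNTS[stratifier].items():
        spec_nod = _STRATUM_NODULES[stratifier][stratum]
        nodule = NoduleObservation(
            nodule_id="n1",
            mean_diameter_mm=spec_nod["d"],
            density=Density.SOLID,
            spiculated=spec_nod.get("spiculated", False),
        )
        for cfdna, cancer, n in (
            (2.0, False, bb),
            (2.0, True, cb),
            (4.0, False, ba),
            (4.0, True, ca),
        ):
            outcome = _outcome("prevalent_lc" if cancer else "benign")
            for _ in range(n):
                i += 1
                records.append(_subject(f"s{i:03d}", cfdna, outcome, (nodule,)))
    return records
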