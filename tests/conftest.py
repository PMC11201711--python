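import pytest

from cfscreen.cohort import (
    Density,
    NoduleObservation,
    OutcomeClass,
    OutcomeLabel,
    Sex,
    SmokingStatus,
    SubjectRecord,
)
from cfscreen.simulate import generate_cohort


def make_subject(
    sid="s1",
    cfdna=2.5,
    outcome=OutcomeClass.BENIGN,
    diagnosis_round=None,
    nodules=(),
    **kw,
):
    defaults = dict(
        age_years=62.0,
        sex=Sex.MALE,
        pack_years=40.0,
        smoking_status=SmokingStatus.CURRENT,
        family_history_lc=False,
        emphysema=False,
    )
    defaults.update(kw)
    return SubjectRecord(
        subject_id=sid,
        cfdna_ng_ml=cfdna,
        outcome=OutcomeLabel(outcome, diagnosis_round),
        nodules=tuple(nodules),
        **defaults,
    )


def solid_nodule(d, nid="n1", spiculated=False, upper=False, exam_day=0):
    return NoduleObservation(
        nodule_id=nid,
        mean_diameter_mm=d,
        exam_day=exam_day,
        density=Density.SOLID,
        spiculated=spiculated,
        upper_lobe=upper,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (108 benign / 17 prevalent / 12 incident)."""
    return generate_cohort(seed=42)


@pytest.fixture
def three_class_cohort():
    return [
        make_subject("a", 2.0, OutcomeClass.BENIGN, nodules=[solid_nodule(5.0)]),
        make_subject("b", 9.0, OutcomeClass.PREVALENT_LC, 1, nodules=[solid_nodule(20.0, spiculated=True)]),
        make_subject("c", 4.0, OutcomeClass.INCIDENT_LC, 3),
    ]
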