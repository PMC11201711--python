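"""Lung-RADS 1.1 rule engine and the Brock malignancy model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfscreen.brock import (
    BrockInputs,
    brock_flag,
    brock_score,
    brock_score_for_subject,
    brock_stratum,
)
from cfscreen.cohort import Density, NoduleObservation, Sex, percent_round
from cfscreen.lungrads import LungRads, classify_lungrads, lungrads_stratum

def nodule(d, density=Density.SOLID, solid_comp=0.0, spiculated=False):
    return NoduleObservation(
        nodule_id="n",
        mean_diameter_mm=d,
        density=density,
        solid_component_mm=solid_comp,
        spiculated=spiculated,
    )


class TestLungRads:
    def test_negative_exam_is_category_1(self):
        assert classify_lungrads([]) is LungRads.CAT_1

    @pytest.mark.parametrize(
        "d,expected",
        [(4.0, "2"), (5.9, "2"), (6.0, "3"), (7.0, "3"), (7.9, "3"), (8.0, "4A"), (14.9, "4A"), (15.0, "4B")],
    )
    def test_solid_size_boundaries_half_open(self, d, expected):
        assert classify_lungrads([nodule(d)]).value == expected

    def test_spiculated_large_nodule_promoted_to_4x(self):
        assert classify_lungrads([nodule(23.0, spiculated=True)]) is LungRads.CAT_4X

    def test_spiculation_does_not_promote_category_2(self):
        assert classify_lungrads([nodule(5.0, spiculated=True)]) is LungRads.CAT_2

    @pytest.mark.parametrize(
        "d,sc,expected",
        [(5.0, 2.0, "2"), (8.0, 4.0, "3"), (10.0, 6.0, "4A"), (12.0, 8.0, "4B")],
    )
    def test_part_solid_rules(self, d, sc, expected):
        n = nodule(d, Density.PART_SOLID, solid_comp=sc)
        assert classify_lungrads([n]).value == expected

    @pytest.mark.parametrize("d,expected", [(12.0, "2"), (29.9, "2"), (30.0, "3")])
    def test_non_solid_rules(self, d, expected):
        assert classify_lungrads([nodule(d, Density.NON_SOLID)]).value == expected

    def test_inconsistent_solid_component_rejected(self):
        bad = nodule(8.0, Density.SOLID, solid_comp=4.0)
        with pytest.raises(Exception):
            classify_lungrads([bad])

    @given(
        diam=st.lists(st.floats(min_value=3.0, max_value=30.0), min_size=1, max_size=5),
        extra=st.floats(min_value=3.0, max_value=30.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adding_a_nodule_never_lowers_category(self, diam, extra):
        base = [nodule(d) for d in diam]
        assert classify_lungrads(base + [nodule(extra)]).rank >= classify_lungrads(base).rank

    @given(diam=st.lists(st.floats(min_value=3.0, max_value=30.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_invariance(self, diam):
        nods = [nodule(d) for d in diam]
        assert classify_lungrads(nods) is classify_lungrads(nods[::-1])

    def test_strata_merge(self):
        assert lungrads_stratum(LungRads.CAT_1) == "1/2"
        assert lungrads_stratum(LungRads.CAT_4X) == "4B/4X"


def brock_inputs(**kw):
    defaults = dict(
        age_years=62.0,
        sex=Sex.MALE,
        family_history_lc=False,
        emphysema=False,
        mean_diameter_mm=8.0,
        density=Density.SOLID,
        upper_lobe=False,
        nodule_count=1,
        spiculated=False,
    )
    defaults.update(kw)
    return BrockInputs(**defaults)


class TestBrockScore:
    def test_monotone_in_diameter(self):
        assert brock_score(brock_inputs(mean_diameter_mm=8.0)) > brock_score(
            brock_inputs(mean_diameter_mm=4.0)
        )

    @pytest.mark.parametrize(
        "kw",
        [
            dict(spiculated=True),
            dict(sex=Sex.FEMALE),
            dict(family_history_lc=True),
            dict(emphysema=True),
            dict(upper_lobe=True),
        ],
    )
    def test_positive_risk_factors_increase_score(self, kw):
        assert brock_score(brock_inputs(**kw)) > brock_score(brock_inputs())

    def test_more_nodules_lower_score(self):
        assert brock_score(brock_inputs(nodule_count=5)) < brock_score(brock_inputs(nodule_count=1))

    def test_matches_independent_formula_evaluation(self):
        # independent hand evaluation of the published linear predictor
        inputs = brock_inputs(
            age_years=66.0,
            sex=Sex.FEMALE,
            family_history_lc=True,
            emphysema=True,
            mean_diameter_mm=9.2,
            upper_lobe=True,
            nodule_count=2,
            spiculated=True,
        )
        x = (
            -6.7892
            + 0.0287 * (66.0 - 62.0)
            + 0.6011
            + 0.2961
            + 0.2953
            - 5.3854 * ((9.2 / 10.0) ** -0.5 - 1.58113883)
            + 0.6581
            - 0.0824 * (2 - 4)
            + 0.7729
        )
        expected = 1.0 / (1.0 + math.exp(-x))
        assert brock_score(inputs) == pytest.approx(expected, abs=1e-6)

    def test_probability_bounds(self):
        assert 0.0 < brock_score(brock_inputs(mean_diameter_mm=1.0)) < 1.0
        assert 0.0 < brock_score(brock_inputs(mean_diameter_mm=30.0, spiculated=True)) < 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            brock_score(brock_inputs(mean_diameter_mm=0.0))
        with pytest.raises(ValueError):
            brock_score(brock_inputs(nodule_count=0))


class TestBrockFlag:
    def test_threshold_closed_on_left(self):
        assert not brock_flag(0.049)
        assert brock_flag(0.05)
        assert brock_flag(0.51)

    def test_category_fraction_reporting(self):
        # 16 of 17 high-risk subjects at/above the 5% threshold prints as 94%
        scores = [0.30] * 16 + [0.01]
        frac = sum(brock_flag(s) for s in scores) / len(scores)
        assert percent_round(frac) == 94

    def test_strata(self):
        assert brock_stratum(0.005) == "<1%"
        assert brock_stratum(0.01) == "[1-5)%"
        assert brock_stratum(0.05) == "[5-10)%"
        assert brock_stratum(0.10) == ">=10%"


def test_subject_without_nodules_scores_zero():
    from conftest import make_subject

    assert brock_score_for_subject(make_subject()) == 0.0
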