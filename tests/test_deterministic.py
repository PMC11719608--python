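"""Deterministic exposure and risk indices against independent arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chocrisk.deterministic import (
    classify,
    cr,
    daily_from_weekly,
    evaluate_samples,
    ewi,
    group_summary,
    hq,
    pct_ptwi,
)
from chocrisk.domain import ChocolateSample, PopulationGroup, ToxicologyConstants
from chocrisk.errors import DomainError

CONSTS = ToxicologyConstants()

pos = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestWeeklyIntake:
    @pytest.mark.parametrize(
        "c_ug,rate,expected",
        [
            (290.0, 0.00525, 1.5225),   # max dark Cd x toddler dark rate
            (0.0, 0.004, 0.0),
            (10.0, 0.00179, 0.0179),    # min Cd x elderly milk rate
        ],
    )
    def test_hand_multiplication(self, c_ug, rate, expected):
        assert ewi(c_ug, rate) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "ewi_val,expected",
        [(1.5225, 60.9), (0.0179, 0.716), (2.5, 100.0)],
    )
    def test_pct_ptwi(self, ewi_val, expected):
        assert pct_ptwi(ewi_val, 2.5) == pytest.approx(expected, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            ewi(-1.0, 0.001)
        with pytest.raises(DomainError):
            pct_ptwi(1.0, 0.0)

    @given(pos, st.floats(min_value=0.0, max_value=0.1, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_cross_check(self, c_ug, rate):
        """%PTWI of the weekly intake at PTWI 2.5 equals 40*c*rate."""
        assert pct_ptwi(ewi(c_ug, rate), 2.5) == pytest.approx(40.0 * c_ug * rate)


class TestDailyFromWeekly:
    @pytest.mark.parametrize(
        "weekly,daily",
        [(0.00703, 0.00703 / 7 * 1000), (0.0, 0.0), (0.007, 1.0)],
    )
    def test_conversion(self, weekly, daily):
        assert daily_from_weekly(weekly) == pytest.approx(daily, rel=1e-12)


class TestHazardQuotient:
    def test_hand_evaluation(self):
        # (350/365) * 0.29 * 0.75 * 1e-3 / 1e-3, evaluated independently
        expected = (350.0 / 365.0) * 0.29 * 0.75 * 1e-3 / 1e-3
        assert hq(0.29, 0.75, CONSTS, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration(self):
        assert hq(0.0, 1.0, CONSTS, 5.0) == 0.0

    def test_ef_365_collapses_factor(self):
        consts = ToxicologyConstants(ef=365.0)
        assert hq(0.1, 0.5, consts, 7.0) == pytest.approx(
            0.1 * 0.5 * consts.cf / consts.rfd, rel=1e-12
        )

    @given(pos, pos, st.floats(min_value=0.1, max_value=80.0))
    @settings(max_examples=200, deadline=None)
    def test_exposure_duration_cancels(self, c, ingr, ed):
        """HQ is invariant to ED because AT_nc = 365*ED."""
        assert hq(c, ingr, CONSTS, ed) == pytest.approx(
            hq(c, ingr, CONSTS, 2.0), rel=1e-12, abs=1e-300
        )


class TestCancerRisk:
    def test_hand_evaluation(self):
        expected = (350.0 * 30.0 / 25550.0) * 0.29 * 0.75 * 1e-3 * 6.1
        assert cr(0.29, 0.75, CONSTS, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration(self):
        assert cr(0.0, 5.0, CONSTS, 30.0) == 0.0

    @given(pos, pos, st.floats(min_value=0.1, max_value=40.0))
    @settings(max_examples=200, deadline=None)
    def test_linear_in_exposure_duration(self, c, ingr, ed):
        assert cr(c, ingr, CONSTS, 2 * ed) == pytest.approx(
            2 * cr(c, ingr, CONSTS, ed), rel=1e-12, abs=1e-300
        )


@given(
    st.floats(min_value=1e-4, max_value=10.0),
    st.floats(min_value=1e-4, max_value=10.0),
    st.floats(min_value=1.1, max_value=10.0),
)
@settings(max_examples=100, deadline=None)
def test_indices_homogeneous_in_concentration(c, ingr, k):
    """Scaling every concentration by k scales all four indices by k."""
    assert ewi(k * c, ingr) == pytest.approx(k * ewi(c, ingr), rel=1e-12)
    assert hq(k * c, ingr, CONSTS, 5.0) == pytest.approx(
        k * hq(c, ingr, CONSTS, 5.0), rel=1e-12
    )
    assert cr(k * c, ingr, CONSTS, 5.0) == pytest.approx(
        k * cr(c, ingr, CONSTS, 5.0), rel=1e-12
    )


def test_brute_force_oracle_equivalence():
    """1000 random inputs agree with an independent re-evaluation to 1e-12."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        c, ingr, ed = rng.uniform(1e-4, 1.0), rng.uniform(1e-4, 5.0), rng.uniform(1, 70)
        rate_w = rng.uniform(0, 0.01)
        # independent one-line oracles (no shared code with the module)
        assert ewi(c * 1000, rate_w) == pytest.approx(c * 1000 * rate_w, rel=1e-12)
        assert pct_ptwi(c, 2.5) == pytest.approx(c * 100 / 2.5, rel=1e-12)
        assert hq(c, ingr, CONSTS, ed) == pytest.approx(
            (350 * ed * c * ingr * 1e-3) / (365 * ed * 1e-3), rel=1e-12
        )
        assert cr(c, ingr, CONSTS, ed) == pytest.approx(
            (350 * ed * c * ingr * 1e-3 * 6.1) / 25550, rel=1e-12
        )


class TestClassification:
    @pytest.mark.parametrize(
        "hq_v,cr_v,hq_cls,cr_cls",
        [
            (0.165, 2e-5, "safe", "moderate"),
            (1.0, 1e-6, "safe", "negligible"),     # boundary inclusion
            (2.0, 2e-4, "adverse", "unacceptable"),
            (0.5, 5e-5, "safe", "moderate"),
        ],
    )
    def test_thresholds(self, hq_v, cr_v, hq_cls, cr_cls):
        rc = classify(hq_v, cr_v)
        assert rc.hq_class.value == hq_cls
        assert rc.cr_class.value == cr_cls


class TestGroupSummary:
    TODDLERS = PopulationGroup("toddlers", 0.00703, 0.00525, 2.0, 12.0)

    def test_identical_samples_collapse(self):
        samples = [ChocolateSample(f"S{i}", "dark", 70.0, 0.05) for i in range(5)]
        out = group_summary(samples, self.TODDLERS, CONSTS)
        for gs in out.values():
            assert gs.minimum == gs.mean == gs.maximum

    def test_empty_collection_rejected(self):
        with pytest.raises(DomainError):
            group_summary([], self.TODDLERS, CONSTS)

    def test_type_matched_rates_and_fractions(self, study):
        out = group_summary(study.samples, self.TODDLERS, CONSTS)
        assert out["hq"].maximum < 1.0
        fracs = out["cr"].cr_class_fractions
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_by_type_split(self, study):
        out = group_summary(study.samples, self.TODDLERS, CONSTS, by_type=True)
        assert ("milk", "hq") in out and ("dark", "hq") in out

    def test_long_table_shape(self, study):
        table = evaluate_samples(study.samples, study.population, CONSTS)
        assert len(table) == 150 * 7
        assert set(table["group"]) == {g.name for g in study.population}
        # pct_ptwi column is consistent with the ewi column
        np.testing.assert_allclose(
            table["pct_ptwi"], table["ewi"] * 100 / CONSTS.ptwi, rtol=1e-12
        )
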