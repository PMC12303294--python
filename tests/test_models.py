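"""Unit and property tests for the core model equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multistage import (
    CurvedParams,
    DomainError,
    LinearParams,
    MultistageRates,
    ScaleTransform,
    aggregate_k,
    curved_log_incidence,
    linear_log_incidence,
    map_curved_to_mechanistic,
    ordered_event_probability,
    rescale_time,
    unordered_event_probability,
)

positive_rate = st.floats(1e-6, 1.0)


class TestLinearLogIncidence:
    @pytest.mark.parametrize(
        "t, r, k, expected",
        [
            (1.0, 3.64, 0.29, math.log(0.29)),  # worked bladder example
            (7.3, 1.0, 1.0, 0.0),  # zero slope, zero intercept
            (math.e, 3.0, 2.0, 2.0 + math.log(2.0)),
        ],
    )
    def test_values(self, t, r, k, expected):
        assert linear_log_incidence(t, LinearParams(r, k)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_nonpositive_age(self):
        with pytest.raises(DomainError):
            linear_log_incidence(0.0, LinearParams(3.0, 1.0))

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            LinearParams(3.0, 0.0)


class TestCurvedLogIncidence:
    def test_convex_nasopharynx_value(self):
        p = CurvedParams(-0.54, 2.797, 0.73, 0.14, "convex")
        assert curved_log_incidence(1.0, p) == pytest.approx(
            -0.54 + math.log(0.27), abs=1e-12
        )

    def test_concave_hodgkin_value(self):
        p = CurvedParams(-0.036, 0.1405, 0.007, 2.1, "concave")
        expected = -0.036 + 0.1405 * math.log(2) + math.log(1 + 0.007 * 2 ** 2.1)
        assert expected == pytest.approx(0.09095535674686356, abs=1e-12)  # 30-digit arithmetic
        assert curved_log_incidence(2.0, p) == pytest.approx(expected, abs=1e-12)

    @given(
        a0=st.floats(-3, 3),
        a1=st.floats(-2, 3),
        t=st.floats(0.5, 10),
        curvature=st.sampled_from(["convex", "concave"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_zero_curvature_reduces_to_linear(self, a0, a1, t, curvature):
        p = CurvedParams(a0, a1, 0.0, 1.0, curvature)
        lin = LinearParams.from_slope_intercept(a1, a0)
        assert curved_log_incidence(t, p) == pytest.approx(
            linear_log_incidence(t, lin), rel=1e-12, abs=1e-12
        )

    def test_convex_domain_violation_names_age(self):
        p = CurvedParams(0.0, 2.0, 0.5, 1.0, "convex")  # a2*t >= 1 at t >= 2
        with pytest.raises(DomainError, match="t="):
            curved_log_incidence(np.array([1.0, 4.0]), p)

    def test_negative_a2_rejected(self):
        with pytest.raises(ValueError):
            CurvedParams(0.0, 1.0, -0.1, 1.0, "convex")


class TestEventProbabilities:
    def test_unordered_two_prior_events(self):
        rates = MultistageRates([0.1, 0.1, 0.5])
        assert unordered_event_probability(rates, 2.0) == pytest.approx(0.04)

    def test_zero_time(self):
        assert unordered_event_probability(MultistageRates([0.1, 0.2]), 0.0) == 0.0

    def test_single_event_empty_product(self):
        assert unordered_event_probability(MultistageRates([0.3]), 5.0) == 1.0

    def test_ordered_divides_by_permutations(self):
        rates = MultistageRates([0.1, 0.1, 0.5])
        assert ordered_event_probability(rates, 2.0) == pytest.approx(0.02)
        rates4 = MultistageRates([0.1, 0.1, 0.1, 0.9])
        assert ordered_event_probability(rates4, 1.0) == pytest.approx(0.001 / 6)

    @given(st.lists(positive_rate, min_size=1, max_size=6), st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_ordered_unordered_factorial_identity(self, rates, t):
        mr = MultistageRates(rates)
        assert ordered_event_probability(mr, t) * math.factorial(
            mr.r - 1
        ) == pytest.approx(unordered_event_probability(mr, t), rel=1e-12, abs=0)


class TestAggregateK:
    @pytest.mark.parametrize(
        "rates, expected",
        [((1.0, 1.0, 1.0), 0.5), ((0.3,), 0.3), ((0.01, 0.01, 0.01), 5e-7)],
    )
    def test_values(self, rates, expected):
        assert aggregate_k(MultistageRates(rates)) == pytest.approx(expected)

    @given(st.lists(positive_rate, min_size=2, max_size=6), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_of_prior_events(self, rates, rnd):
        mr = MultistageRates(rates)
        head = list(rates[:-1])
        rnd.shuffle(head)
        assert aggregate_k(MultistageRates(head + [rates[-1]])) == pytest.approx(
            aggregate_k(mr), rel=1e-12
        )

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            MultistageRates([])

    def test_rare_event_warning(self):
        with pytest.warns(UserWarning, match="rare-event"):
            MultistageRates([0.5, 0.001]).check_rare(t_max=3.0)


class TestRescaleTime:
    def test_identity_at_unit_scale(self):
        p = LinearParams(3.0, 0.7)
        q = rescale_time(p, ScaleTransform(1.0))
        assert (q.r, q.k) == pytest.approx((p.r, p.k))

    def test_intercept_shift(self):
        q = rescale_time(LinearParams(3.0, 1.0), ScaleTransform(2.0))
        assert q.intercept == pytest.approx(-2 * math.log(2))
        assert q.slope == pytest.approx(2.0)

    @given(st.floats(1.1, 4.5), st.floats(0.01, 5.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, r, k, w):
        p = LinearParams(r, k)
        q = rescale_time(rescale_time(p, ScaleTransform(w)), ScaleTransform(1 / w))
        assert q.r == pytest.approx(p.r, rel=1e-9)
        assert q.k == pytest.approx(p.k, rel=1e-9)

    @given(
        st.floats(1.0, 4.5), st.floats(0.01, 5.0), st.floats(0.1, 10.0),
        st.floats(0.5, 40.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_predictions_invariant(self, r, k, w, t):
        """Evaluating rescaled parameters at w*t (the rescaled axis)
        reproduces ln I(t)."""
        p = LinearParams(r, k)
        q = rescale_time(p, ScaleTransform(w))
        assert linear_log_incidence(w * t, q) == pytest.approx(
            linear_log_incidence(t, p), rel=1e-9, abs=1e-9
        )

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(DomainError):
            ScaleTransform(0.0)


class TestMechanisticMap:
    def test_nasopharynx_male_subgroup_probabilities(self):
        p = CurvedParams(-0.54, 2.797, 0.73, 0.14, "convex")
        m = map_curved_to_mechanistic(p, "heterogeneity", p=0.0)
        assert m.k_p == pytest.approx(0.583, abs=5e-4)
        assert m.k_q == pytest.approx(0.425, abs=5e-4)
        assert m.r == pytest.approx(3.797)
        assert m.q == pytest.approx(0.14)

    def test_leukemia_male_subgroup_probabilities(self):
        p = CurvedParams(1.15, -0.8291, 0.09, 2.75, "concave")
        m = map_curved_to_mechanistic(p, "heterogeneity", r=1.0)
        assert m.k_p == pytest.approx(3.158, abs=5e-4)
        assert m.k_q == pytest.approx(0.284, abs=5e-4)

    def test_zero_a2_degenerates_to_single_subgroup(self):
        p = CurvedParams(0.5, 2.0, 0.0, 1.0, "concave")
        m = map_curved_to_mechanistic(p, "heterogeneity", p=0.0)
        assert m.k_q == 0.0

    def test_requires_exactly_one_of_p_r(self):
        p = CurvedParams(0.0, 2.0, 0.1, 1.0, "convex")
        with pytest.raises(ValueError):
            map_curved_to_mechanistic(p, "heterogeneity")
        with pytest.raises(ValueError):
            map_curved_to_mechanistic(p, "heterogeneity", p=0.0, r=3.0)

    def test_age_effect_reads_r_from_slope(self):
        p = CurvedParams(-0.54, 2.797, 0.73, 0.14, "convex")
        m = map_curved_to_mechanistic(p, "age_effect")
        assert m.r == pytest.approx(3.797)
        assert m.k_mod == pytest.approx(0.73 * math.exp(-0.54))
        assert m.exp_mod == pytest.approx(0.14 + 3.797 - 1.0)

    @given(
        a0=st.floats(-2, 2),
        a1=st.floats(-2, 3),
        a2=st.floats(0.001, 0.9),
        a3=st.floats(-1, 3),
        p=st.floats(-1, 1),
        curvature=st.sampled_from(["convex", "concave"]),
        mode=st.sampled_from(["heterogeneity", "age_effect"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, a0, a1, a2, a3, p, curvature, mode):
        """Mapping to mechanistic quantities and re-assembling the
        coefficients is the identity."""
        params = CurvedParams(a0, a1, a2, a3, curvature)
        kwargs = {"p": p} if mode == "heterogeneity" else {}
        mech = map_curved_to_mechanistic(params, mode, **kwargs)
        back = mech.to_curved()
        assert back.a0 == pytest.approx(a0, rel=1e-9, abs=1e-9)
        assert back.a1 == pytest.approx(a1, rel=1e-9, abs=1e-9)
        assert back.a2 == pytest.approx(a2, rel=1e-9, abs=1e-9)
        assert back.a3 == pytest.approx(a3, rel=1e-9, abs=1e-9)
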