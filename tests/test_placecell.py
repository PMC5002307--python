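import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpcsim import (
    FiringParams,
    PerceivedLandmark,
    PlaceCell,
    PlaceCode,
    Population,
    evaluate_population,
    firing_rate,
    landmark_weights,
    match_landmarks,
    maybe_recruit,
    wrap_angle_deg,
)


def code(*entries, step=0):
    return PlaceCode(tuple(PerceivedLandmark(*e) for e in entries), step)


def brute_force_rate(stored, current, sigma_d2, sigma_theta2, w_d, w_theta):
    """Independent term-by-term transcription of the similarity measure.

    ``stored``/``current`` are lists of (id, saliency, bearing, distance)
    tuples. Weights are saliency fractions over the whole current percept;
    the sum runs over landmarks whose id appears in both lists; bearing
    differences are reduced to the minimal circular difference.
    """
    total_sal = sum(s for (_, s, _, _) in current)
    stored_by_id = {i: (th, d) for (i, _, th, d) in stored}
    f = 0.0
    for (i, s, th, d) in current:
        if i not in stored_by_id:
            continue
        th_k, d_k = stored_by_id[i]
        dth = abs(th - th_k) % 360.0
        dth = min(dth, 360.0 - dth)
        exponent = w_d * (d - d_k) ** 2 / sigma_d2 + w_theta * dth**2 / sigma_theta2
        f += (s / total_sal) * math.exp(-exponent)
    return f


class TestWeights:
    def test_equal_saliency_splits_evenly(self):
        c = code((0, 1, 0, 12), (1, 1, 90, 11), (2, 1, 180, 13), (3, 1, 270, 14))
        assert landmark_weights(c) == pytest.approx({0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25})

    def test_saliency_proportional_weights(self):
        c = code((0, 1.0, 0, 12), (1, 3.0, 90, 11))
        w = landmark_weights(c)
        assert w[0] == pytest.approx(0.25)
        assert w[1] == pytest.approx(0.75)

    def test_single_landmark_weight_one(self):
        assert landmark_weights(code((5, 2.0, 10, 12)))[5] == pytest.approx(1.0)

    def test_empty_code_empty_map(self):
        assert landmark_weights(code()) == {}

    def test_weights_sum_to_one(self, rng):
        entries = [(i, rng.uniform(0.1, 5), 0, 12) for i in range(17)]
        assert sum(landmark_weights(code(*entries)).values()) == pytest.approx(1.0, abs=1e-12)


class TestMatching:
    def test_intersection_of_ids(self):
        cell = PlaceCell(0, code((1, 1, 0, 12), (2, 1, 0, 12), (3, 1, 0, 12)), 0)
        cur = code((2, 1, 0, 12), (3, 1, 0, 12), (4, 1, 0, 12))
        assert match_landmarks(cell, cur) == {2, 3}

    def test_disjoint_codes_empty(self):
        cell = PlaceCell(0, code((1, 1, 0, 12)), 0)
        assert match_landmarks(cell, code((9, 1, 0, 12))) == frozenset()

    def test_identical_codes_full_match(self):
        entries = [(i, 1, i * 10.0, 10 + i * 0.5) for i in range(7)]
        cell = PlaceCell(0, code(*entries), 0)
        assert len(match_landmarks(cell, code(*entries))) == 7


class TestFiringRate:
    def test_self_recall_is_one(self, baseline_params):
        entries = [(i, 1, i * 40.0, 10 + i * 0.7) for i in range(6)]
        cell = PlaceCell(0, code(*entries), 0)
        assert firing_rate(cell, code(*entries), baseline_params) == pytest.approx(1.0, abs=1e-12)

    def test_five_metre_distance_mismatch(self, baseline_params):
        # single matched landmark, delta_d = 5 m at sigma_d2 = 25 -> e^-1
        cell = PlaceCell(0, code((0, 1, 0, 10.0)), 0)
        rate = firing_rate(cell, code((0, 1, 0, 15.0)), baseline_params)
        assert rate == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_bearing_difference_wraps_across_north(self, baseline_params):
        # 350 deg vs 10 deg is a 20 deg mismatch, not 340 -> e^-4
        cell = PlaceCell(0, code((0, 1, 350.0, 12.0)), 0)
        rate = firing_rate(cell, code((0, 1, 10.0, 12.0)), baseline_params)
        assert rate == pytest.approx(math.exp(-4.0), abs=1e-12)

    def test_indicators_disable_both_terms(self):
        params = FiringParams(25.0, 100.0, w_d=0, w_theta=0, frt=0.2)
        entries = [(i, 1, i * 30.0, 10 + i) for i in range(4)]
        moved = [(i, 1, i * 30.0 + 90.0, 14 - i) for i in range(4)]
        cell = PlaceCell(0, code(*entries), 0)
        assert firing_rate(cell, code(*moved), params) == pytest.approx(1.0, abs=1e-12)

    def test_no_match_fires_zero(self, baseline_params):
        cell = PlaceCell(0, code((0, 1, 0, 12)), 0)
        assert firing_rate(cell, code((1, 1, 0, 12)), baseline_params) == 0.0
        assert firing_rate(cell, code(), baseline_params) == 0.0

    def test_unmatched_current_landmarks_dilute_weights(self, baseline_params):
        cell = PlaceCell(0, code((0, 1, 0.0, 12.0)), 0)
        cur = code((0, 1, 0.0, 12.0), (1, 1, 90.0, 11.0))
        assert firing_rate(cell, cur, baseline_params) == pytest.approx(0.5, abs=1e-12)
        assert firing_rate(
            cell, cur, baseline_params, weight_normalization="matched"
        ) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=150)
    @given(
        dd=st.floats(0, 30, allow_nan=False),
        dth=st.floats(0, 180, allow_nan=False),
    )
    def test_monotone_decay_in_each_mismatch(self, dd, dth, baseline_params):
        cell = PlaceCell(0, code((0, 1, 0.0, 20.0)), 0)
        base = firing_rate(cell, code((0, 1, dth, 20.0 + dd)), baseline_params)
        worse_d = firing_rate(cell, code((0, 1, dth, 20.0 + dd + 1.0)), baseline_params)
        assert worse_d <= base + 1e-15
        if dth <= 178.0:
            worse_th = firing_rate(cell, code((0, 1, dth + 1.0, 20.0 + dd)), baseline_params)
            assert worse_th <= base + 1e-15

    @settings(derandomize=True, max_examples=100)
    @given(scale=st.floats(1.0, 16.0))
    def test_wider_adjustment_factors_raise_rates(self, scale):
        cell = PlaceCell(0, code((0, 1, 15.0, 12.0)), 0)
        cur = code((0, 1, 30.0, 14.0))
        narrow = firing_rate(cell, cur, FiringParams(25.0, 100.0))
        wide = firing_rate(cell, cur, FiringParams(25.0 * scale, 100.0 * scale))
        assert wide >= narrow - 1e-15

    def test_rate_bounded_in_unit_interval(self, rng, baseline_params):
        for _ in range(200):
            stored = [(i, rng.uniform(0.1, 3), rng.uniform(0, 360), rng.uniform(5, 20))
                      for i in rng.choice(10, size=rng.integers(1, 6), replace=False)]
            current = [(i, rng.uniform(0.1, 3), rng.uniform(0, 360), rng.uniform(5, 20))
                       for i in rng.choice(10, size=rng.integers(1, 6), replace=False)]
            cell = PlaceCell(0, code(*stored), 0)
            rate = firing_rate(cell, code(*current), baseline_params)
            assert 0.0 <= rate <= 1.0 + 1e-12

    def test_agrees_with_brute_force_oracle(self, rng):
        # 1000 random small instances, term-by-term oracle, 1e-12 agreement
        for _ in range(1000):
            n_s = int(rng.integers(1, 6))
            n_c = int(rng.integers(1, 6))
            stored = [
                (int(i), float(rng.uniform(0.1, 4)), float(rng.uniform(0, 360)),
                 float(rng.uniform(1, 25)))
                for i in rng.choice(8, size=n_s, replace=False)
            ]
            current = [
                (int(i), float(rng.uniform(0.1, 4)), float(rng.uniform(0, 360)),
                 float(rng.uniform(1, 25)))
                for i in rng.choice(8, size=n_c, replace=False)
            ]
            params = FiringParams(
                float(rng.uniform(1, 100)),
                float(rng.uniform(1, 1000)),
                int(rng.integers(0, 2)),
                int(rng.integers(0, 2)),
                0.2,
            )
            cell = PlaceCell(0, code(*stored), 0)
            expected = brute_force_rate(
                stored, current, params.sigma_d2, params.sigma_theta2, params.w_d, params.w_theta
            )
            assert firing_rate(cell, code(*current), params) == pytest.approx(expected, abs=1e-12)


class TestWrap:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0, 0), (180, -180), (-180, -180), (340, -20), (-340, 20), (539, 179), (360, 0)],
    )
    def test_wraps_into_half_open_interval(self, delta, expected):
        assert wrap_angle_deg(delta) == pytest.approx(expected)
        assert -180.0 <= wrap_angle_deg(delta) <= 180.0


class TestRecruitment:
    def test_empty_population_has_no_winner(self, baseline_params):
        rates, winner = evaluate_population(Population(baseline_params), code((0, 1, 0, 12)))
        assert rates.size == 0 and winner is None

    def test_self_recall_winner(self, baseline_params):
        pop = Population(baseline_params)
        c = code((0, 1, 0, 12), (1, 1, 90, 13))
        pop.recruit(c, 0)
        rates, winner = evaluate_population(pop, c)
        assert winner == 0 and rates[0] == pytest.approx(1.0, abs=1e-12)

    def test_winner_is_argmax_with_low_id_tiebreak(self, baseline_params):
        pop = Population(baseline_params)
        pop.recruit(code((0, 1, 0.0, 12.0)), 0)
        pop.recruit(code((0, 1, 0.0, 17.0)), 1)  # 5 m off the probe -> e^-1
        rates, winner = evaluate_population(pop, code((0, 1, 0.0, 12.0)))
        assert winner == 0 and rates[1] == pytest.approx(math.exp(-1.0), abs=1e-12)
        # exact tie: identical stored codes -> lowest cell id wins
        pop2 = Population(baseline_params)
        pop2.recruit(code((0, 1, 0.0, 12.0)), 0)
        pop2.recruit(code((0, 1, 0.0, 12.0)), 1)
        _, winner2 = evaluate_population(pop2, code((0, 1, 0.0, 12.0)))
        assert winner2 == 0

    def test_bootstrap_recruitment(self, baseline_params):
        pop = Population(baseline_params)
        recruited, rate = maybe_recruit(pop, code((0, 1, 0, 12)))
        assert recruited and rate == 0.0
        assert len(pop) == 1 and pop.cells[0].cell_id == 0

    def test_empty_percept_never_recruits(self, baseline_params):
        pop = Population(baseline_params)
        recruited, _ = maybe_recruit(pop, code())
        assert not recruited and len(pop) == 0

    def test_threshold_is_strict(self):
        # winner rate exactly at FRT must not recruit
        params = FiringParams(25.0, 100.0, 1, 1, frt=math.exp(-1.0))
        pop = Population(params)
        pop.recruit(code((0, 1, 0.0, 12.0)), 0)
        recruited, rate = maybe_recruit(pop, code((0, 1, 0.0, 17.0)))
        assert rate == pytest.approx(math.exp(-1.0), abs=1e-12)
        assert not recruited

    def test_above_threshold_no_recruit_below_recruits(self, baseline_params):
        pop = Population(baseline_params)
        pop.recruit(code((0, 1, 0.0, 12.0)), 0)
        ok, rate = maybe_recruit(pop, code((0, 1, 0.0, 14.0)))  # e^{-4/25} ~ 0.85
        assert not ok and rate > 0.2
        ok, rate = maybe_recruit(pop, code((0, 1, 0.0, 24.0)))  # e^{-144/25} ~ 0.003
        assert ok and rate < 0.2
        assert [c.cell_id for c in pop.cells] == [0, 1]

    def test_memorized_code_is_the_recruitment_percept(self, baseline_params):
        pop = Population(baseline_params)
        c = code((3, 1, 45.0, 11.0), step=42)
        maybe_recruit(pop, c)
        cell = pop.cells[0]
        assert cell.recruited_at == 42
        assert cell.code is c
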