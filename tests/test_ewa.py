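"""EWA core dynamics: updates, components, windows, likelihood, simulator."""

import math

import numpy as np
import pandas as pd
import pytest

from flocklearn.datatypes import UNMARKED, ChoiceEvent, Individual
from flocklearn.ewa import (
    SocialWindowTally,
    category_social_probs,
    choice_probability,
    cue_bias_social_probs,
    ewa_loglik,
    frequency_social_probs,
    individual_probs,
    simulate_choices,
    tally_social_window,
    update_attraction,
)


class TestAttractionUpdate:
    def test_phi_zero_never_updates(self):
        assert update_attraction(0.4, 1.0, 0.0) == 0.4

    def test_phi_one_no_memory(self):
        assert update_attraction(0.4, 1.0, 1.0) == 1.0

    def test_arithmetic(self):
        assert update_attraction(0.4, 1.0, 0.25) == pytest.approx(0.55)

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            update_attraction(0.4, 1.0, 1.5)

    def test_stays_in_unit_interval(self, rng):
        a = 0.0
        for _ in range(200):
            a = update_attraction(a, float(rng.integers(0, 2)),
                                  float(rng.uniform(0, 1)))
            assert 0.0 <= a <= 1.0


class TestIndividualProbs:
    def test_lambda_zero_uniform(self):
        assert np.allclose(individual_probs([0.9, 0.1], 0.0), [0.5, 0.5])

    def test_worked_example(self):
        p = individual_probs([1.0, 0.0], 1.0)
        e = math.e
        assert np.allclose(p, [e / (1 + e), 1 / (1 + e)])

    def test_equal_attractions_symmetric(self):
        for lam in (0.0, 1.0, 7.3):
            assert np.allclose(individual_probs([0.4, 0.4], lam), [0.5, 0.5])

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            individual_probs([1, 0], -0.1)


class TestSocialComponents:
    def test_frequency_unbiased(self):
        assert np.allclose(frequency_social_probs([9, 1], 1.0), [0.9, 0.1])

    def test_frequency_conformist(self):
        assert np.allclose(frequency_social_probs([3, 1], 2.0), [0.9, 0.1])

    def test_frequency_anticonformist(self):
        assert np.allclose(frequency_social_probs([4, 1], 0.5),
                           [2 / 3, 1 / 3])

    def test_frequency_empty_sentinel(self):
        assert frequency_social_probs([0, 0], 1.3) is None

    def test_cue_bias_reduces_to_frequency_at_zero(self, rng):
        for _ in range(20):
            same = rng.integers(0, 5, 2).astype(float)
            other = rng.integers(0, 5, 2).astype(float)
            tally = SocialWindowTally(total=same + other, same_roost=same,
                                      other_roost=other)
            if tally.empty:
                continue
            assert np.allclose(cue_bias_social_probs(tally, 0.0),
                               frequency_social_probs(same + other, 1.0))

    def test_cue_bias_worked_example(self):
        """1 same-roost red vs 1 other-roost blue at beta=log 3 -> 3:1."""
        tally = SocialWindowTally(total=np.array([1.0, 1.0]),
                                  same_roost=np.array([1.0, 0.0]),
                                  other_roost=np.array([0.0, 1.0]))
        assert np.allclose(cue_bias_social_probs(tally, math.log(3)),
                           [0.75, 0.25])

    def test_cue_bias_limit(self):
        tally = SocialWindowTally(total=np.array([1.0, 3.0]),
                                  same_roost=np.array([1.0, 0.0]),
                                  other_roost=np.array([0.0, 3.0]))
        assert np.allclose(cue_bias_social_probs(tally, 50.0), [1.0, 0.0],
                           atol=1e-12)

    def test_category_counts_only(self):
        tally = SocialWindowTally(total=np.array([2.0, 5.0]),
                                  male=np.array([2.0, 0.0]))
        assert np.allclose(category_social_probs(tally, "male"), [1.0, 0.0])

    def test_category_sentinel_falls_back(self):
        tally = SocialWindowTally(total=np.array([0.0, 5.0]),
                                  male=np.array([0.0, 0.0]))
        assert category_social_probs(tally, "male") is None
        # the sentinel makes the choice purely individual
        assert np.allclose(
            choice_probability(np.array([0.7, 0.3]), None, 0.4), [0.7, 0.3])

    def test_category_all_equals_frequency(self):
        tally = SocialWindowTally(total=np.array([4.0, 2.0]))
        assert np.allclose(category_social_probs(tally, "all"),
                           frequency_social_probs([4, 2], 1.0))


class TestChoiceProbability:
    def test_gamma_extremes(self):
        i = np.array([0.8, 0.2])
        s = np.array([0.9, 0.1])
        assert np.allclose(choice_probability(i, s, 0.0), i)
        assert np.allclose(choice_probability(i, s, 1.0), s)

    def test_convex_combination(self):
        out = choice_probability(np.array([0.5, 0.5]), np.array([1.0, 0.0]),
                                 0.2)
        assert np.allclose(out, [0.6, 0.4])

    def test_always_normalized(self, rng):
        for _ in range(50):
            i = rng.dirichlet([1, 1])
            s = rng.dirichlet([1, 1])
            g = rng.uniform(0, 1)
            assert choice_probability(i, s, g).sum() == pytest.approx(
                1.0, abs=1e-12)


class TestWindowTally:
    def _events(self, rows):
        return [ChoiceEvent(i, t, s, o, p) for i, t, s, o, p in rows]

    def test_empty_window(self):
        tally = tally_social_window([], "f", 100.0, "R1")
        assert tally.empty

    def test_self_exclusion(self):
        ev = self._events([("f", 90.0, "R1", "red", 1)])
        assert tally_social_window(ev, "f", 100.0, "R1").empty

    def test_half_open_boundary(self):
        """Demos at t-59..t-1 count; one at exactly t-61 does not."""
        ev = self._events([("x", 39.0, "R1", "red", 1),
                           ("x", 41.0, "R1", "red", 1),
                           ("x", 70.0, "R1", "red", 1),
                           ("x", 99.0, "R1", "red", 1)])
        tally = tally_social_window(ev, "f", 100.0, "R1")
        assert tally.total[0] == 3

    def test_other_site_excluded(self):
        ev = self._events([("x", 90.0, "R2", "red", 1)])
        assert tally_social_window(ev, "f", 100.0, "R1").empty

    def test_unmarked_counts_toward_totals(self, small_roster):
        ev = self._events([(UNMARKED, 90.0, "R1", "blue", 0)])
        tally = tally_social_window(ev, "f", 100.0, "R1",
                                    attributes=small_roster)
        assert tally.total[1] == 1
        assert tally.male[1] == 0

    def test_successful_only_filter(self):
        ev = self._events([("x", 90.0, "R1", "red", 0),
                           ("y", 95.0, "R1", "red", 1)])
        tally = tally_social_window(ev, "f", 100.0, "R1",
                                    demos="successful-only")
        assert tally.total[0] == 1

    def test_roost_categories(self, small_roster):
        ev = self._events([("a1", 90.0, "R1", "red", 1),   # same roost as a2
                           ("j1", 95.0, "R1", "blue", 1)])  # other roost
        tally = tally_social_window(ev, "a2", 100.0, "R1",
                                    attributes=small_roster)
        assert tally.same_roost[0] == 1
        assert tally.other_roost[1] == 1
        assert tally.male[0] == 1 and tally.adult[0] == 1

    def test_unsorted_rejected(self):
        ev = self._events([("x", 90.0, "R1", "red", 1),
                           ("y", 80.0, "R1", "red", 1)])
        with pytest.raises(ValueError, match="sorted"):
            tally_social_window(ev, "f", 100.0, "R1")


class TestLoglik:
    def test_two_step_hand_computation(self, two_choice_events,
                                       uniform_param_table):
        """First naive choice is 1/2; after one rewarded red, A=(0.3,0) and
        lambda=2 gives p(red) = e^0.6/(e^0.6+1)."""
        ll = ewa_loglik(two_choice_events, uniform_param_table, "individual")
        expect = math.log(0.5) + math.log(
            math.exp(0.6) / (math.exp(0.6) + 1))
        assert ll == pytest.approx(expect, abs=1e-10)
        assert ll == pytest.approx(-1.1306, abs=1e-4)

    def test_gamma_zero_equals_individual(self, rng):
        roster = {f"b{k}": Individual(f"b{k}", "adult", "male", roost="R1")
                  for k in range(4)}
        params = pd.DataFrame(
            {"lambda": 2.0, "phi": 0.3, "gamma": 0.0, "f": 1.7,
             "beta": 0.4},
            index=list(roster))
        schedule = [(f"b{k % 4}", 10.0 * t, "R1") for t, k in
                    enumerate(range(40))]
        events = simulate_choices(roster, schedule, params, "frequency",
                                  rng=rng)
        ll_freq = ewa_loglik(events, params, "frequency", attributes=roster)
        ll_ind = ewa_loglik(events, params, "individual", attributes=roster)
        assert ll_freq == pytest.approx(ll_ind, abs=1e-10)

    def test_frequency_f1_equals_cue_beta0(self, rng):
        """Unbiased frequency copying and a zero-strength roost cue are the
        same model."""
        roster = {f"b{k}": Individual(f"b{k}", "adult", "male", roost="R1"
                                      if k % 2 else "R2")
                  for k in range(6)}
        params = pd.DataFrame(
            {"lambda": 1.5, "phi": 0.25, "gamma": 0.3, "f": 1.0,
             "beta": 0.0},
            index=list(roster))
        schedule = [(f"b{k % 6}", 8.0 * k, "R1") for k in range(60)]
        events = simulate_choices(roster, schedule, params, "frequency",
                                  rng=rng)
        ll_freq = ewa_loglik(events, params, "frequency", attributes=roster)
        ll_cue = ewa_loglik(events, params, "roost_bias", attributes=roster)
        assert ll_freq == pytest.approx(ll_cue, abs=1e-10)

    def test_unmarked_contributes_no_terms(self, uniform_param_table):
        events = [ChoiceEvent(UNMARKED, 0.0, "R1", "red", 1),
                  ChoiceEvent("solo", 10.0, "R1", "red", 1)]
        ll = ewa_loglik(events, uniform_param_table, "individual")
        pointwise = ewa_loglik(events, uniform_param_table, "individual",
                               pointwise=True)
        assert len(pointwise) == 1
        assert ll == pytest.approx(math.log(0.5))


class TestSimulator:
    def test_tutored_limit(self):
        roster = {"t": Individual("t", "adult", "male", roost="R1",
                                  tutored_option="red")}
        params = pd.DataFrame({"lambda": 50.0, "phi": 0.2, "gamma": 0.0,
                               "f": 1.0, "beta": 0.0}, index=["t"])
        events = simulate_choices(roster, [("t", 0.0, "R1")], params,
                                  "individual", rng=0)
        assert events[0].option == "red"

    def test_first_choice_frequencies_match_softmax(self):
        """10,000 isolated first choices follow the softmax probability
        within binomial error."""
        roster = {"t": Individual("t", "adult", "male", roost="R1",
                                  tutored_option="red")}
        params = pd.DataFrame({"lambda": 1.0, "phi": 0.2, "gamma": 0.0,
                               "f": 1.0, "beta": 0.0}, index=["t"])
        rng = np.random.default_rng(3)
        n = 10_000
        reds = 0
        for _ in range(n):
            ev = simulate_choices(roster, [("t", 0.0, "R1")], params,
                                  "individual", rng=rng)
            reds += ev[0].option == "red"
        p = math.exp(1.0) / (math.exp(1.0) + 1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(reds / n - p) < 4 * se

    def test_fixed_seed_identical(self, small_roster):
        params = pd.DataFrame(
            {"lambda": 2.0, "phi": 0.3, "gamma": 0.2, "f": 1.0,
             "beta": 0.0}, index=list(small_roster))
        schedule = [(i, 5.0 * k, "R1")
                    for k, i in enumerate(list(small_roster) * 5)]
        e1 = simulate_choices(small_roster, schedule, params, "frequency",
                              rng=11)
        e2 = simulate_choices(small_roster, schedule, params, "frequency",
                              rng=11)
        assert e1 == e2
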