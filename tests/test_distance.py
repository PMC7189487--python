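import itertools

import numpy as np
import pytest

from owlsync import distance as di
from owlsync.trials import TrialSet


def brute_force_vp(a, b, q):
    """Independent oracle: enumerate all spike matchings.

    Every injective pairing between subsets of a and b is scored as
    shift costs for matched spikes plus 1 per unmatched spike; the VP
    distance is the minimum over all pairings.
    """
    a, b = list(a), list(b)
    best = len(a) + len(b)
    for k in range(1, min(len(a), len(b)) + 1):
        for sub_a in itertools.combinations(range(len(a)), k):
            for sub_b in itertools.permutations(range(len(b)), k):
                cost = (len(a) - k) + (len(b) - k)
                for i, j in zip(sub_a, sub_b):
                    cost += q * abs(a[i] - b[j])
                best = min(best, cost)
    return best


GRID = np.linspace(0.0, 0.08, 5)
ALL_TRAINS = [np.array(c) for n in range(4) for c in itertools.combinations(GRID, n)]


class TestVPDistance:
    def test_identical_trains_zero(self):
        t = np.array([0.01, 0.02, 0.05])
        assert di.vp_distance(t, t) == 0.0

    @pytest.mark.parametrize("a,b,expected", [
        ([0.010], [0.015], 0.5),   # shift (cost 0.5) beats delete+insert
        ([0.010], [0.040], 2.0),   # shift cost 3 > 2 -> delete+insert
    ])
    def test_single_spike_examples(self, a, b, expected):
        assert di.vp_distance(a, b, 100.0) == pytest.approx(expected)

    def test_empty_train_costs_other_length(self):
        assert di.vp_distance([], [0.1, 0.2]) == 2.0
        assert di.vp_distance([0.1], []) == 1.0

    def test_matches_brute_force_on_all_small_trains(self):
        q = 100.0
        for a in ALL_TRAINS:
            for b in ALL_TRAINS:
                assert di.vp_distance(a, b, q) == pytest.approx(
                    brute_force_vp(a, b, q)), (a, b)

    def test_metric_axioms_on_small_trains(self):
        q = 100.0
        sample = ALL_TRAINS[::2]
        d = {(i, j): di.vp_distance(a, b, q)
             for i, a in enumerate(sample) for j, b in enumerate(sample)}
        n = len(sample)
        for i in range(n):
            assert d[i, i] == 0.0
            for j in range(n):
                assert d[i, j] == pytest.approx(d[j, i])
                if i != j:
                    assert d[i, j] > 0
                for k in range(n):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_bounded_by_total_spike_count(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(0, 0.1, rng.integers(0, 8)))
            b = np.sort(rng.uniform(0, 0.1, rng.integers(0, 8)))
            assert di.vp_distance(a, b, 100.0) <= a.size + b.size + 1e-12

    def test_q_limits(self, rng):
        a = np.sort(rng.uniform(0, 0.1, 5))
        b = np.sort(rng.uniform(0, 0.1, 8))
        # q -> 0: only count difference matters
        assert di.vp_distance(a, b, 1e-9) == pytest.approx(3.0, abs=1e-6)
        # q -> inf: no affordable shifts, except exact coincidences
        c = np.concatenate([a[:2], [0.099]])
        expected = (a.size + c.size) - 2 * 2
        assert di.vp_distance(a, np.sort(c), 1e9) == pytest.approx(expected)


class TestMeanPairwise:
    def test_identical_trials_zero(self):
        ts = TrialSet("u", [np.array([0.1, 0.2])] * 4, 1.0, analysis_start=0.0)
        assert di.mean_pairwise_distance(ts) == 0.0

    def test_empty_trials_omitted(self):
        ts = TrialSet("u", [np.array([0.010]), np.empty(0), np.array([0.011])],
                      1.0, analysis_start=0.0)
        # only the one surviving non-empty pair contributes: shift 0.1
        assert di.mean_pairwise_distance(ts) == pytest.approx(0.1)

    def test_single_nonempty_trial_is_error(self):
        ts = TrialSet("u", [np.array([0.1]), np.empty(0)], 1.0,
                      analysis_start=0.0)
        with pytest.raises(ValueError):
            di.mean_pairwise_distance(ts)


class TestChanceModel:
    def test_printed_model_evaluation(self):
        m = di.chance_model(0.100)
        assert m.expected_distance(0.0) == 0.0
        assert m.expected_distance(10.0) == pytest.approx(9.981)

    def test_corrected_distance(self):
        m = di.chance_model(0.100)
        assert di.corrected_distance(9.981, 10.0, m) == pytest.approx(0.0, abs=1e-9)
        # identical patterned trains at gm 10 are far more similar than chance
        assert di.corrected_distance(0.0, 10.0, m) == pytest.approx(-9.981)
        assert di.corrected_distance(3.0, 0.0, m) == 3.0

    def test_fit_zero_intercept_and_monotone(self):
        m = di.fit_chance_model(0.1, n_sims=3000, seed=0)
        assert m.expected_distance(0.0) == 0.0
        x = np.linspace(1, 50, 100)
        assert np.all(np.diff(m.expected_distance(x)) > 0)

    def test_fit_requires_enough_sims(self):
        with pytest.raises(ValueError):
            di.fit_chance_model(0.1, n_sims=10)
        with pytest.raises(ValueError):
            di.fit_chance_model(0.1, max_count=0)

    def test_trends_insensitive_to_q(self, rng):
        # corrected-distance-vs-rate orderings agree across the tested q
        # values on a synthetic tuned unit (more spikes & patterning at the
        # preferred condition)
        durations = 0.1
        raw = {}
        for q in (33.0, 64.0, 100.0, 250.0):
            dists = []
            for n, jitter in ((4, 5e-3), (10, 2e-3), (25, 5e-4)):
                base = np.sort(rng.uniform(0, durations, n))
                trialset = TrialSet("u", [np.sort(np.clip(
                    base + rng.normal(0, jitter, n), 0, durations))
                    for _ in range(8)], durations, analysis_start=0.0)
                dists.append(di.mean_pairwise_distance(trialset, di.VPConfig(q)))
            m = di.fit_chance_model(0.1, n_sims=2000, seed=1, q=q)
            corrected = [d - m.expected_distance(x) for d, x in zip(dists, (4, 10, 25))]
            raw[q] = corrected
        # corrected distance decreases with rate+patterning for every q
        for q, vals in raw.items():
            assert vals[0] > vals[1] > vals[2], q
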