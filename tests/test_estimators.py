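"""Estimator algebra, enumeration oracles, and replication checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbgnsum import (
    ConfigurationError,
    DegenerateInputError,
    InestimableVisibilityError,
    VenueSample,
    basic_nsum,
    draw_sample,
    generate_population,
    gnsum_known_probs,
    ht_total,
    relprob_mean,
    relprob_outreport_total,
    true_inclusion_probs,
    vb_gnsum,
)


def _toy() -> VenueSample:
    """Two key respondents (v=[2,4], c=[1,2]) and two non-key (y=[1,3], c=[1,1])."""
    return VenueSample(
        person_id=np.arange(4),
        is_key=np.array([True, True, False, False]),
        c=np.array([1.0, 2.0, 1.0, 1.0]),
        y=np.array([0, 0, 1, 3], dtype=np.int64),
        v=np.array([2.0, 4.0, np.nan, np.nan]),
    )


class TestFormulas:
    @pytest.mark.parametrize("y,d,n,expected", [
        ([1, 1], [10, 10], 100, 10.0),
        ([0, 0, 0], [5, 5, 5], 1000, 0.0),
        ([2, 3, 5], [20, 30, 50], 1000, 100.0),
    ])
    def test_basic_nsum(self, y, d, n, expected):
        assert basic_nsum(y, d, n) == pytest.approx(expected)

    def test_basic_nsum_zero_degree_raises(self):
        with pytest.raises(DegenerateInputError):
            basic_nsum([1, 2], [0, 0], 100)

    @pytest.mark.parametrize("x,pi,expected", [
        ([3], [1.0], 3.0),
        ([1, 1], [0.5, 0.5], 4.0),
    ])
    def test_ht_total(self, x, pi, expected):
        assert ht_total(x, pi) == pytest.approx(expected)

    def test_ht_rejects_invalid_probabilities(self):
        with pytest.raises(ConfigurationError):
            ht_total([1], [0.0])
        with pytest.raises(ConfigurationError):
            ht_total([1], [1.5])

    @pytest.mark.parametrize("v,c,expected", [
        ([2, 4], [1, 1], 3.0),
        ([2, 4], [1, 2], 8.0 / 3.0),
        ([2, 4], [10, 20], 8.0 / 3.0),  # scale invariance, explicit case
    ])
    def test_relprob_mean(self, v, c, expected):
        assert relprob_mean(v, c) == pytest.approx(expected, rel=1e-12)

    def test_relprob_mean_rejects_empty_or_nonpositive(self):
        with pytest.raises(ConfigurationError):
            relprob_mean([], [])
        with pytest.raises(ConfigurationError):
            relprob_mean([1], [0.0])

    @pytest.mark.parametrize("y,c,n,expected", [
        ([1, 3], [1, 1], 10, 20.0),
        ([1, 3], [2, 2], 10, 20.0),
    ])
    def test_relprob_outreport_total(self, y, c, n, expected):
        assert relprob_outreport_total(y, c, n) == pytest.approx(expected)

    def test_vb_gnsum_worked_example(self, toy_sample):
        r = vb_gnsum(toy_sample, 10)
        assert r.numerator_total == pytest.approx(20.0)
        assert r.denominator_mean == pytest.approx(8.0 / 3.0)
        assert r.n_hat == pytest.approx(7.5)

    def test_zero_visibility_raises_not_zero(self, toy_sample):
        s = VenueSample(
            person_id=toy_sample.person_id, is_key=toy_sample.is_key,
            c=toy_sample.c, y=toy_sample.y,
            v=np.where(toy_sample.is_key, 0.0, np.nan),
        )
        with pytest.raises(InestimableVisibilityError):
            vb_gnsum(s, 10)


class TestExactProperties:
    @settings(derandomize=True, max_examples=60)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 40), st.floats(0.05, 50.0)),
            min_size=1, max_size=25,
        ),
        alpha=st.floats(0.01, 100.0),
    )
    def test_relprob_mean_scale_invariance(self, data, alpha):
        v = [d[0] for d in data]
        c = np.array([d[1] for d in data])
        assert relprob_mean(v, c) == pytest.approx(relprob_mean(v, alpha * c), rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(eps=st.floats(-0.9, 4.0), n=st.floats(1.0, 1e6))
    def test_linearity_in_frame_count(self, eps, n):
        toy_sample = _toy()
        base = vb_gnsum(toy_sample, n)
        inflated = vb_gnsum(toy_sample, n * (1 + eps))
        assert inflated.n_hat == pytest.approx(base.n_hat * (1 + eps), rel=1e-12)
        assert base.rescale_frame(n * (1 + eps)).n_hat == pytest.approx(
            inflated.n_hat, rel=1e-12
        )

    def test_scale_invariance_of_full_estimator(self, toy_sample):
        scaled = VenueSample(
            person_id=toy_sample.person_id, is_key=toy_sample.is_key,
            c=toy_sample.c * 123.4, y=toy_sample.y, v=toy_sample.v,
        )
        assert vb_gnsum(scaled, 10).n_hat == pytest.approx(7.5, rel=1e-12)

    def test_census_identity(self, small_population):
        pop = small_population
        full = draw_sample(pop, pop.n_key, pop.n_nonkey, seed=0)
        r = vb_gnsum(full, pop.n_nonkey)
        assert r.n_hat == pytest.approx(pop.n_key, abs=1e-9)

    def test_result_decomposition_identity(self, toy_sample):
        r = vb_gnsum(toy_sample, 10)
        assert r.n_hat == pytest.approx(r.numerator_total / r.denominator_mean)


class TestEnumerationOracles:
    def test_ht_design_unbiased_equal_probability(self):
        # population {2,4,6}, all samples of size 2, pi = 2/3 each:
        # the mean of HT totals over the 3 samples equals the true total 12
        pop = [2, 4, 6]
        totals = [ht_total(s, [2 / 3] * 2) for s in itertools.combinations(pop, 2)]
        assert np.mean(totals) == pytest.approx(sum(pop))

    @pytest.mark.parametrize("pop,k", [
        ([1, 2, 3, 4, 5], 2), ([3, 1, 4, 1, 5, 9, 2, 6], 3), ([7, 7, 7, 7], 2),
    ])
    def test_ht_design_unbiased_srs_enumeration(self, pop, k):
        pi = k / len(pop)
        totals = [ht_total(s, [pi] * k) for s in itertools.combinations(pop, k)]
        assert np.mean(totals) == pytest.approx(sum(pop))

    def test_known_probs_equals_relative_on_equal_probability_design(self):
        # with common pi, the HT numerator equals the relative-probability
        # numerator evaluated at N_{F\K} = (stratum size)/pi
        pop = generate_population(300, 30, 3.0, seed=11)
        s = draw_sample(pop, 10, 90, seed=12)
        pi = 90 / 270
        oracle = gnsum_known_probs(s, [pi] * 90)
        relative = vb_gnsum(s, 90 / pi)
        assert oracle.n_hat == pytest.approx(relative.n_hat, rel=1e-12)


class TestReplicationOracles:
    def test_vb_gnsum_mean_near_truth_small_population(self):
        # 20,000 replicate samples from one small error-free population.
        # The ratio form carries an O(1/n) bias at these tiny stratum sizes,
        # so the replicate mean is checked to 2% of N_K rather than to pure
        # Monte-Carlo error.
        pop = generate_population(30, 5, mean_degree_to_key=2.0, seed=21)
        est = np.empty(20_000)
        root = np.random.SeedSequence(22)
        for i, ss in enumerate(root.spawn(20_000)):
            s = draw_sample(pop, 4, 15, seed=ss)
            est[i] = vb_gnsum(s, 25).n_hat
        assert abs(est.mean() - 5) / 5 < 0.02

    def test_known_and_relative_estimators_agree_under_skewed_design(self):
        # Skewed attendance: both estimators' replicate means stay near N_K.
        from vbgnsum import assign_attendance

        pop = generate_population(400, 40, 3.0, seed=31)
        pop = assign_attendance(pop, "S2", "S2", seed=32)
        probs = true_inclusion_probs(pop, 10, 100, 4000, seed=33)
        est_rel, est_known = [], []
        root = np.random.SeedSequence(34)
        for ss in root.spawn(4000):
            s = draw_sample(pop, 10, 100, seed=ss)
            est_rel.append(vb_gnsum(s, 360).n_hat)
            nonkey = s.person_id[~s.is_key]
            est_known.append(gnsum_known_probs(s, probs[nonkey]).n_hat)
        for est in (est_rel, est_known):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(est.size)
            assert abs(est.mean() - 40) < max(3 * se, 0.03 * 40)
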