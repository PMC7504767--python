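import math

import numpy as np
import pytest
from scipy.spatial.distance import cosine as scipy_cosine
from scipy.stats import entropy as scipy_entropy

from alsim import kl_divergence, relative_entropy, cosine_distance, compare_all
from alsim.datatypes import CellDistribution

# frozen 2-bin example, verified by direct summation:
# KLD((.5,.5)||(.25,.75)) = .5 ln 2 + .5 ln(2/3)
KLD_PQ = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)          # 0.14384...
KLD_QP = 0.25 * math.log(0.5) + 0.75 * math.log(1.5)        # 0.13081...


class TestKlDivergence:
    def test_identical_is_zero(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_two_bin_example(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        assert kl_divergence(p, q) == pytest.approx(KLD_PQ, abs=1e-12)
        assert kl_divergence(q, p) == pytest.approx(KLD_QP, abs=1e-12)
        assert kl_divergence(p, q) == pytest.approx(0.14384, abs=5e-6)
        assert kl_divergence(q, p) == pytest.approx(0.13081, abs=5e-6)
        assert kl_divergence(p, q) != kl_divergence(q, p)

    def test_agrees_with_scipy(self, random_distribution_pairs):
        for p, q in random_distribution_pairs[:25]:
            assert kl_divergence(p, q) == pytest.approx(
                scipy_entropy(p, q), abs=1e-12)

    def test_base_two(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        assert kl_divergence(p, q, base="2") == pytest.approx(
            KLD_PQ / math.log(2), abs=1e-12)

    def test_zero_entry_instructs_smoothing(self):
        with pytest.raises(ValueError, match="smoothed"):
            kl_divergence([0.5, 0.5, 0.0], [0.25, 0.5, 0.25])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kl_divergence([0.5, 0.5], [0.25, 0.5, 0.25])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            kl_divergence([0.5, 0.6], [0.5, 0.5])


class TestRelativeEntropy:
    def test_two_bin_average(self):
        re = relative_entropy([0.5, 0.5], [0.25, 0.75])
        assert re == pytest.approx((KLD_PQ + KLD_QP) / 2, abs=1e-12)
        assert re == pytest.approx(0.13733, abs=5e-6)

    def test_symmetric_and_nonnegative(self, random_distribution_pairs):
        for p, q in random_distribution_pairs:
            re_pq = relative_entropy(p, q)
            assert re_pq == pytest.approx(relative_entropy(q, p), abs=1e-14)
            assert re_pq >= 0.0

    def test_zero_iff_equal(self, random_distribution_pairs):
        for p, q in random_distribution_pairs[:20]:
            assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-14)
            if not np.allclose(p, q):
                assert relative_entropy(p, q) > 0.0


class TestCosineDistance:
    def test_identical_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(x, x) == pytest.approx(0.0, abs=1e-15)

    def test_orthogonal_is_one(self):
        assert cosine_distance([1, 0, 0], [0, 1, 0]) == pytest.approx(1.0)

    def test_closed_form_example(self):
        assert cosine_distance([1, 0], [1, 1]) == pytest.approx(
            1 - 1 / math.sqrt(2), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        for _ in range(25):
            x = rng.integers(0, 100, 8).astype(float) + 1
            y = rng.integers(0, 100, 8).astype(float) + 1
            assert cosine_distance(x, y) == pytest.approx(
                scipy_cosine(x, y), abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.integers(1, 100, 8).astype(float)
        for c in (0.5, 3.0, 1000.0):
            assert cosine_distance(x, c * x) == pytest.approx(0.0, abs=1e-12)

    def test_in_unit_interval_for_nonnegative_vectors(self, rng):
        for _ in range(50):
            x = rng.integers(0, 50, 8).astype(float) + 0.01
            y = rng.integers(0, 50, 8).astype(float) + 0.01
            assert 0.0 - 1e-12 <= cosine_distance(x, y) <= 1.0 + 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0, 0], [1, 1])


def make_dist(rng):
    return CellDistribution(counts=rng.multinomial(3360, rng.dirichlet(np.ones(8))))


class TestCompareAll:
    def test_identical_pair(self, rng):
        d = make_dist(rng)
        (res,) = compare_all([("a", d), ("b", d)])
        assert res.re == pytest.approx(0.0, abs=1e-14)
        assert res.cd == pytest.approx(0.0, abs=1e-12)

    def test_pair_count(self, rng):
        feats = [(f"d{i}", make_dist(rng)) for i in range(5)]
        assert len(compare_all(feats)) == 5 * 4 // 2

    def test_order_invariance(self, rng):
        feats = [(f"d{i}", make_dist(rng)) for i in range(4)]
        a = compare_all(feats)
        b = compare_all(feats[::-1])
        assert a == b

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            compare_all([("a", make_dist(rng)), ("a", make_dist(rng))])

    def test_rank_direction_agreement(self, rng):
        # a small perturbation must score closer than a large one, by both measures
        base = np.array([400, 420, 430, 410, 440, 420, 410, 430])
        small = base + np.array([20, -20, 0, 0, 0, 0, 0, 0])
        large = np.array([1200, 1100, 500, 200, 100, 100, 100, 60])
        p = CellDistribution(base)
        q = CellDistribution(small)
        r = CellDistribution(large)
        assert relative_entropy(p.probabilities, q.probabilities) < \
            relative_entropy(p.probabilities, r.probabilities)
        assert cosine_distance(p.counts, q.counts) < cosine_distance(p.counts, r.counts)
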