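import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastbaps.model import (
    DirichletPrior,
    combine_nodes,
    log1mexp,
    log_dpm_partition_prior,
    log_marginal_h1,
    log_posterior_merge,
    make_leaf,
    make_prior,
)

from oracles import log_dirichlet_multinomial, set_partitions


def flat_prior(betas_per_locus):
    """DirichletPrior from explicit per-locus beta lists."""
    offsets = np.cumsum([0] + [len(b) for b in betas_per_locus])
    beta = np.concatenate([np.asarray(b, float) for b in betas_per_locus])
    return DirichletPrior(kind="symmetric", beta=beta, offsets=offsets)


class TestMarginalH1:
    def test_empty_counts_give_probability_one(self):
        prior = flat_prior([[1.0, 1.0], [0.5, 0.5, 0.5]])
        assert log_marginal_h1(np.zeros(5), prior) == pytest.approx(0.0, abs=1e-14)

    def test_single_symmetric_draw_is_half(self):
        prior = flat_prior([[1.0, 1.0]])
        assert log_marginal_h1(np.array([1.0, 0.0]), prior) == pytest.approx(
            math.log(0.5), abs=1e-12
        )

    def test_matches_exact_rational_oracle(self):
        prior = flat_prior([[1.0, 1.0]])
        got = log_marginal_h1(np.array([2.0, 1.0]), prior)
        want = log_dirichlet_multinomial([[2, 1]], [[Fraction(1), Fraction(1)]])
        assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_loci = rng.integers(1, 5)
        counts, betas = [], []
        for _ in range(n_loci):
            n_alleles = int(rng.integers(2, 5))
            counts.append(list(rng.integers(0, 8, size=n_alleles)))
            betas.append(
                [Fraction(int(rng.integers(1, 5)), int(rng.integers(1, 4)))
                 for _ in range(n_alleles)]
            )
        prior = flat_prior([[float(b) for b in bl] for bl in betas])
        got = log_marginal_h1(
            np.concatenate([np.asarray(c, float) for c in counts]), prior
        )
        assert got == pytest.approx(
            log_dirichlet_multinomial(counts, betas), rel=1e-10, abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        prior = flat_prior([[1.0, 1.0]])
        with pytest.raises(ValueError):
            log_marginal_h1(np.zeros(3), prior)

    def test_exchangeable_in_sample_order(self, tiny_matrix):
        prior = make_prior(tiny_matrix, "baps")
        a = log_marginal_h1(tiny_matrix.cluster_counts([0, 1, 2]), prior)
        b = log_marginal_h1(tiny_matrix.cluster_counts([2, 0, 1]), prior)
        assert a == b

    def test_concentration_limit_on_monomorphic_cluster(self):
        # all 5 samples carry the same allele: the marginal rises
        # monotonically as the scale shrinks toward the concentration
        # limit, where it approaches 1/2 (the chance the first draw
        # fixed this allele)
        counts = np.array([5.0, 0.0])
        values = []
        for scale in [1e-4, 0.1, 1.0, 10.0, 100.0]:
            prior = flat_prior([[0.5 * scale, 0.5 * scale]])
            values.append(log_marginal_h1(counts, prior))
        assert values == sorted(values, reverse=True)
        assert values[0] == pytest.approx(math.log(0.5), abs=1e-2)


class TestPartitionPrior:
    def test_single_item(self):
        assert log_dpm_partition_prior([1], alpha=1.0) == pytest.approx(0.0)

    def test_two_items_both_partitions_half(self):
        assert log_dpm_partition_prior([2], 1.0) == pytest.approx(math.log(0.5))
        assert log_dpm_partition_prior([1, 1], 1.0) == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("n,alpha", [(3, 1.0), (5, 1.0), (6, 1.0),
                                         (5, 0.3), (7, 2.5), (8, 1.0)])
    def test_normalizes_over_all_set_partitions(self, n, alpha):
        total = sum(
            math.exp(log_dpm_partition_prior([len(b) for b in p], alpha))
            for p in set_partitions(range(n))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        sizes=st.lists(st.integers(1, 6), min_size=1, max_size=6),
        alpha=st.floats(0.05, 20.0),
    )
    def test_prior_is_finite_and_exchangeable_in_cluster_order(self, sizes, alpha):
        value = log_dpm_partition_prior(sizes, alpha)
        assert math.isfinite(value) and value <= 0.0
        assert value == pytest.approx(
            log_dpm_partition_prior(sorted(sizes, reverse=True), alpha)
        )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            log_dpm_partition_prior([1, 1], alpha=0.0)


class TestMergeRecursion:
    def setup_method(self):
        self.prior = flat_prior([[1.0, 1.0]])

    def leaf(self, i, counts):
        return make_leaf([i], np.asarray(counts, float), self.prior)

    def test_two_singletons_give_pi_half(self):
        node = combine_nodes(self.leaf(0, [1, 0]), self.leaf(1, [1, 0]), self.prior)
        # d = alpha*Gamma(2) + 1*1 = 2, pi = 1/2
        assert math.exp(node.log_d) == pytest.approx(2.0)
        assert math.exp(node.log_pi) == pytest.approx(0.5)

    def test_three_singletons_d_recursion(self):
        pair = combine_nodes(self.leaf(0, [1, 0]), self.leaf(1, [1, 0]), self.prior)
        trio = combine_nodes(pair, self.leaf(2, [1, 0]), self.prior)
        # d = Gamma(3) + 2*1 = 4, pi = 2/4
        assert math.exp(trio.log_d) == pytest.approx(4.0)
        assert math.exp(trio.log_pi) == pytest.approx(0.5)

    def test_pi_and_one_minus_pi_are_consistent(self):
        pair = combine_nodes(self.leaf(0, [1, 0]), self.leaf(1, [0, 1]), self.prior)
        assert math.exp(pair.log_pi) + math.exp(pair.log_1mpi) == pytest.approx(1.0)

    def test_factorial_dominance_pi_increases_along_chain(self):
        node = self.leaf(0, [1, 0])
        pis = []
        for i in range(1, 20):
            node = combine_nodes(node, self.leaf(i, [1, 0]), self.prior)
            pis.append(node.log_pi)
        # pi climbs toward 1 as the factorial term dominates
        assert all(b >= a for a, b in zip(pis[3:], pis[4:]))
        assert math.exp(pis[-1]) > 0.9

    def test_mixture_identity_holds_exactly(self):
        left = combine_nodes(self.leaf(0, [1, 0]), self.leaf(1, [0, 1]), self.prior)
        node = combine_nodes(left, self.leaf(2, [1, 0]), self.prior)
        direct = np.logaddexp(
            node.log_pi + node.log_p_h1,
            node.log_1mpi + left.log_p_tree + node.children[1].log_p_tree,
        )
        assert node.log_p_tree == pytest.approx(direct, rel=1e-10)
        lower = max(
            node.log_pi + node.log_p_h1,
            node.log_1mpi + left.log_p_tree + node.children[1].log_p_tree,
        )
        assert node.log_p_tree >= lower

    def test_overlapping_members_rejected(self):
        with pytest.raises(ValueError):
            combine_nodes(self.leaf(0, [1, 0]), self.leaf(0, [1, 0]), self.prior)

    @pytest.mark.parametrize("seed", range(10))
    def test_posterior_matches_direct_bayes_ratio(self, seed):
        rng = np.random.default_rng(seed)
        prior = flat_prior([[1.0, 1.0], [0.5, 1.5]])
        a = make_leaf([0], rng.integers(0, 4, 4).astype(float), prior)
        b = make_leaf([1], rng.integers(0, 4, 4).astype(float), prior)
        node = combine_nodes(a, b, prior)
        pi = math.exp(node.log_pi)
        num = pi * math.exp(node.log_p_h1)
        den = num + (1 - pi) * math.exp(a.log_p_tree) * math.exp(b.log_p_tree)
        assert math.exp(node.log_r) == pytest.approx(num / den, rel=1e-10)


class TestLeafConvention:
    def test_leaf_tree_probability_equals_h1(self, tiny_matrix):
        prior = make_prior(tiny_matrix, "baps")
        for members in ([0], [0, 1, 2]):
            leaf = make_leaf(
                members, tiny_matrix.cluster_counts(members), prior, alpha=1.0
            )
            assert leaf.log_p_tree == leaf.log_p_h1
            assert leaf.log_pi == 0.0
            assert leaf.log_d == pytest.approx(0.0)  # log alpha at alpha=1

    def test_r_undefined_on_leaf(self, tiny_matrix):
        prior = make_prior(tiny_matrix, "baps")
        leaf = make_leaf([0], tiny_matrix.cluster_counts([0]), prior)
        with pytest.raises(ValueError):
            log_posterior_merge(leaf)
        with pytest.raises(ValueError):
            leaf.log_r

    def test_empty_members_rejected(self, tiny_matrix):
        prior = make_prior(tiny_matrix, "baps")
        with pytest.raises(ValueError):
            make_leaf([], np.zeros(tiny_matrix.n_columns), prior)


class TestPriorKinds:
    def test_baps_prior_is_inverse_allele_count(self):
        from fastbaps import Alignment, build_snp_matrix

        aln = Alignment(["a", "b", "c", "d"], ["AA", "AA", "AC", "AG"])
        m = build_snp_matrix(aln)  # one locus with three alleles
        prior = make_prior(m, "baps")
        assert np.allclose(prior.beta, 1.0 / 3.0)

    def test_symmetric_prior_is_ones(self, tiny_matrix):
        assert np.allclose(make_prior(tiny_matrix, "symmetric").beta, 1.0)

    def test_counts_prior_tracks_global_frequencies(self, tiny_matrix):
        prior = make_prior(tiny_matrix, "bhc_counts")
        # locus has counts A:2, T:1 -> beta proportional to (2/3, 1/3) * 2
        assert np.allclose(prior.beta, [4.0 / 3.0, 2.0 / 3.0])

    def test_unknown_kind_and_bad_scale_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            make_prior(tiny_matrix, "flat")
        with pytest.raises(ValueError):
            make_prior(tiny_matrix, "baps", scale=-1.0)


def test_log1mexp_against_direct_evaluation():
    for x in [-0.1, -0.5, -math.log(2), -5.0, -50.0]:
        assert log1mexp(x) == pytest.approx(math.log(1 - math.exp(x)), rel=1e-9)
    # near x = 0 the naive form loses precision; log(1-e^x) ~ log(-x)
    assert log1mexp(-1e-12) == pytest.approx(math.log(1e-12), rel=1e-6)
    assert log1mexp(0.0) == -math.inf
    with pytest.raises(ValueError):
        log1mexp(0.5)
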