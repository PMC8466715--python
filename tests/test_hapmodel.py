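import numpy as np
import pytest

from haplarch.hapmodel import (
    build_cluster_model,
    diploid_forward_backward,
    diploid_node_marginals,
    node_marginal,
    pair_prior,
)

from _oracles import brute_force_diploid, enumerate_haplotype_paths


class TestConstruction:
    def test_identical_haplotypes_collapse_to_a_chain(self):
        haps = np.tile([1, 0, 1], (4, 1)).astype(np.int8)
        m = build_cluster_model(haps, edge_floor=0.0)
        assert m.n_nodes == [1, 1, 1, 1]
        for d, a in enumerate([1, 0, 1]):
            assert m.prob[d][0, a] == 1.0

    def test_identical_continuations_merge(self):
        # all four 2-SNP haplotypes equally: both level-1 nodes continue
        # with P(allele 1) = 0.5, TV distance 0 -> merged
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5, dtype=np.int8)
        m = build_cluster_model(haps, merge_tolerance=0.15)
        assert m.n_nodes[1] == 1

    def test_divergent_continuations_stay_distinct(self):
        haps = np.array([[0, 0]] * 9 + [[1, 1]] * 9, dtype=np.int8)
        m = build_cluster_model(haps, merge_tolerance=0.15)
        assert m.n_nodes[1] == 2

    def test_edge_floor_gives_unseen_alleles_positive_probability(self):
        haps = np.array([[0, 0]] * 10, dtype=np.int8)
        m = build_cluster_model(haps)  # default floor 0.5/N
        floor = 0.5 / 10
        assert m.prob[0][0, 1] == pytest.approx(floor / (1 + floor))
        assert np.allclose(m.prob[0].sum(axis=1), 1.0)

    def test_merging_is_monotone_in_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            haps = rng.integers(0, 2, (30, 6)).astype(np.int8)
            strict = build_cluster_model(haps, merge_tolerance=0.0)
            loose = build_cluster_model(haps, merge_tolerance=0.3)
            assert sum(strict.n_nodes) >= sum(loose.n_nodes)

    def test_model_reproduces_training_frequencies_without_flooring(self):
        # tolerance 0 merges only exactly-identical continuation
        # distributions, so path probabilities telescope to empirical
        # haplotype frequencies (window short enough for the full suffix
        # to be inside the merge horizon)
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, (24, 4)).astype(np.int8)
        m = build_cluster_model(haps, merge_tolerance=0.0, edge_floor=0.0)
        uniq, counts = np.unique(haps, axis=0, return_counts=True)
        for h, c in zip(uniq, counts):
            assert m.haplotype_path_probability(h) == pytest.approx(c / 24)

    def test_missing_alleles_rejected(self):
        haps = np.array([[0, 1], [1, 0]], dtype=np.int8)
        haps[0, 0] = -1
        with pytest.raises(ValueError):
            build_cluster_model(haps)


class TestDiploidForwardBackward:
    def test_likelihood_on_single_chain(self, chain_model):
        # both haplotypes forced through the 0.5/0.5 chain
        post = diploid_forward_backward(chain_model, np.array([2, 2]))
        assert post.likelihood == pytest.approx(0.0625)

    def test_missing_site_marginalises_to_one(self, chain_model):
        post = diploid_forward_backward(chain_model, np.array([1, -1]))
        assert post.likelihood == pytest.approx(0.5)

    def test_posterior_tables_normalised(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            haps = rng.integers(0, 2, (15, 5)).astype(np.int8)
            m = build_cluster_model(haps)
            g = rng.integers(0, 3, 5)
            post = diploid_forward_backward(m, g)
            for t in post.tables:
                assert t.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            haps = rng.integers(0, 2, (rng.integers(4, 20), rng.integers(2, 5))).astype(np.int8)
            m = build_cluster_model(haps, merge_tolerance=rng.uniform(0, 0.3))
            g = rng.integers(-1, 3, m.n_snps)
            total, joint = brute_force_diploid(m, g)
            post = diploid_forward_backward(m, g)
            assert post.likelihood == pytest.approx(total, rel=1e-12)
            for d in range(m.n_snps):
                expect = np.zeros_like(post.tables[d])
                for (u, v), w in joint[d].items():
                    expect[u, v] = w / total
                np.testing.assert_allclose(post.tables[d], expect, atol=1e-12)

    def test_batched_marginals_agree_with_single(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, (20, 6)).astype(np.int8)
        m = build_cluster_model(haps)
        genos = rng.integers(-1, 3, (7, 6))
        loglik, marg = diploid_node_marginals(m, genos)
        for i in range(7):
            post = diploid_forward_backward(m, genos[i])
            assert loglik[i] == pytest.approx(post.log_likelihood)
            single = node_marginal(post)
            for d in range(m.n_snps):
                np.testing.assert_allclose(marg[d][i], single[d], atol=1e-12)


class TestMarginalsAndPriors:
    def test_heterozygous_node_pair_splits_half_half(self, split_model):
        # genotype 0+1 at SNP 1 forces the ordered pairs (u00,u11)/(u11,u00)
        post = diploid_forward_backward(split_model, np.array([1, 1]))
        marg = node_marginal(post)[1]
        assert marg[0] == pytest.approx(0.5, abs=0.01)
        assert marg[1] == pytest.approx(0.5, abs=0.01)

    def test_homozygous_path_concentrates(self, chain_model):
        post = diploid_forward_backward(chain_model, np.array([0, 0]))
        marg = node_marginal(post)
        for v in marg:
            assert v.sum() == pytest.approx(1.0)
            assert v.max() == pytest.approx(1.0)  # single-node levels

    def test_priors_conserve_mass_and_balanced_split(self, split_model):
        priors = split_model.node_priors()
        assert priors[0][0] == pytest.approx(1.0)
        np.testing.assert_allclose(priors[1], [0.5, 0.5], atol=1e-9)
        pp = pair_prior(split_model)
        assert pp[1][0, 1] == pytest.approx(0.25, abs=1e-9)
        for d, p in enumerate(priors):
            assert p.sum() == pytest.approx(1.0, abs=1e-12), d

    def test_prior_matches_path_enumeration(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, (12, 4)).astype(np.int8)
        m = build_cluster_model(haps, merge_tolerance=0.1)
        priors = m.node_priors()
        paths = enumerate_haplotype_paths(m)
        for d in range(m.n_snps + 1):
            expect = np.zeros(len(priors[d]))
            for _, nodes, p in paths:
                expect[nodes[d]] += p
            np.testing.assert_allclose(priors[d], expect, atol=1e-12)
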