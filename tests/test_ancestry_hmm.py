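import numpy as np
import pytest

from haplarch.ancestry_hmm import (
    AncestryHMMParams,
    accessible_matrix,
    baum_welch_fit,
    forward_backward_genome,
    sample_paths,
    transition_matrix,
    transition_probability,
    viterbi_path,
)
from haplarch.emission import unordered_pairs

from _oracles import enumerate_hmm_paths, marginals_from_paths


def uniform_params(K, tau=0.06):
    S = len(unordered_pairs(K))
    return AncestryHMMParams([f"p{i}" for i in range(K)], np.full(S, 1 / S), tau)


def random_params(rng, K, tau=None):
    S = len(unordered_pairs(K))
    pi = rng.dirichlet(np.ones(S)) + 1e-6
    pi /= pi.sum()
    return AncestryHMMParams([f"p{i}" for i in range(K)],
                             pi, tau or float(rng.uniform(0.01, 0.4)))


class TestTransitions:
    def test_single_slot_switch_probability(self):
        # K=3, uniform pi, tau=0.06, from (p,p): two accessible pairs
        params = uniform_params(3, tau=0.06)
        got = transition_probability(params, (0, 0), (0, 1))
        assert got == pytest.approx(0.06 * (1 / 6) / (2 / 6))

    def test_self_transition_is_one_minus_tau(self):
        rng = np.random.default_rng(0)
        params = random_params(rng, 4)
        for pair in params.pairs:
            assert transition_probability(params, pair, pair) == pytest.approx(
                1 - params.tau)

    def test_k2_homozygous_state_z_cancels(self):
        rng = np.random.default_rng(1)
        params = random_params(rng, 2, tau=0.13)
        assert transition_probability(params, (0, 0), (0, 1)) == pytest.approx(0.13)

    def test_double_switches_forbidden(self):
        params = uniform_params(3)
        assert transition_probability(params, (0, 0), (1, 1)) == 0.0
        assert transition_probability(params, (0, 1), (2, 2)) == 0.0

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_rows_sum_to_one(self, K):
        rng = np.random.default_rng(K)
        for _ in range(5):
            T = transition_matrix(random_params(rng, K))
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_accessible_set_excludes_self(self):
        for K in (2, 3, 4):
            acc = accessible_matrix(K)
            assert not np.diag(acc).any()


class TestForwardBackward:
    def test_single_flat_group_posterior_is_pi(self):
        rng = np.random.default_rng(2)
        params = random_params(rng, 3)
        dec = forward_backward_genome([np.zeros((1, 6))], params)
        np.testing.assert_allclose(dec.gammas[0][0], params.pi, atol=1e-12)

    def test_flat_emissions_small_tau_keep_pi_and_no_switches(self):
        rng = np.random.default_rng(3)
        params = AncestryHMMParams(["a", "b"], rng.dirichlet(np.ones(3)), 1e-9)
        dec = forward_backward_genome([np.zeros((2, 3))], params)
        for g in dec.gammas[0]:
            np.testing.assert_allclose(g, params.pi, atol=1e-6)
        assert dec.expected_switches < 1e-6

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            K = int(rng.integers(2, 4))
            S = len(unordered_pairs(K))
            ems = [rng.normal(0, 2, (3, S))]
            params = random_params(rng, K)
            ll, post = enumerate_hmm_paths(ems, params)
            dec = forward_backward_genome(ems, params)
            assert dec.log_likelihood == pytest.approx(ll, abs=1e-10)
            np.testing.assert_allclose(
                dec.gammas[0], marginals_from_paths(post[0], 3, S), atol=1e-10)

    def test_chromosomes_are_independent(self):
        rng = np.random.default_rng(5)
        params = random_params(rng, 2)
        e1, e2 = rng.normal(0, 1, (2, 3)), rng.normal(0, 1, (4, 3))
        both = forward_backward_genome([e1, e2], params)
        solo = [forward_backward_genome([e], params) for e in (e1, e2)]
        assert both.log_likelihood == pytest.approx(
            solo[0].log_likelihood + solo[1].log_likelihood)
        np.testing.assert_allclose(both.gammas[0], solo[0].gammas[0], atol=1e-12)
        np.testing.assert_allclose(both.gammas[1], solo[1].gammas[0], atol=1e-12)


class TestBaumWelch:
    def test_single_group_one_iteration_gives_posterior(self):
        # one group: pi becomes the flat-prior posterior of that group
        e = np.array([[0.0, -1.0, -2.0]])
        params = baum_welch_fit([e], populations=["a", "b"], iterations=1,
                                pi_floor=1e-12)
        flat = np.exp(e[0]) / np.exp(e[0]).sum()
        np.testing.assert_allclose(params.pi, flat, atol=1e-9)
        assert params.tau == 0.01  # no adjacencies: untouched

    def test_flat_emissions_fixed_point(self):
        params = baum_welch_fit([np.zeros((4, 6)), np.zeros((3, 6))],
                                populations=["a", "b", "c"], iterations=10)
        np.testing.assert_allclose(params.pi, 1 / 6, atol=1e-9)

    def test_loglik_nondecreasing_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            K = int(rng.integers(2, 4))
            S = len(unordered_pairs(K))
            ems = [rng.normal(0, 2, (int(rng.integers(2, 10)), S))
                   for _ in range(int(rng.integers(1, 3)))]
            pops = [f"p{i}" for i in range(K)]
            _, history = baum_welch_fit(ems, populations=pops, iterations=10,
                                        return_history=True)
            assert (np.diff(history) >= -1e-9).all()

    def test_label_exchangeability(self):
        rng = np.random.default_rng(7)
        S = len(unordered_pairs(3))
        ems = [rng.normal(0, 1.5, (5, S))]
        pairs = unordered_pairs(3)
        perm = {0: 2, 1: 0, 2: 1}
        col = [pairs.index(tuple(sorted((perm[p], perm[q])))) for p, q in pairs]
        ems_perm = [ems[0][:, col].copy()]
        # permuting labels permutes the fitted pi and the Viterbi path
        f1 = baum_welch_fit(ems, populations=list("abc"))
        f2 = baum_welch_fit(ems_perm, populations=list("abc"))
        np.testing.assert_allclose(f2.pi, f1.pi[np.array(col)], atol=1e-9)
        v1 = viterbi_path(ems, f1)
        v2 = viterbi_path(ems_perm, f2)
        assert [col[s] for s in v2] == list(v1)


class TestViterbi:
    def test_dominant_emission_gives_constant_path(self):
        S = len(unordered_pairs(2))
        e = np.full((6, S), -50.0)
        e[:, 0] = 0.0
        params = uniform_params(2, tau=0.01)
        assert (viterbi_path([e], params) == 0).all()

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            K = int(rng.integers(2, 4))
            S = len(unordered_pairs(K))
            ems = [rng.normal(0, 2, (3, S))]
            params = random_params(rng, K)
            _, post = enumerate_hmm_paths(ems, params)
            best = max(post[0], key=post[0].get)
            assert tuple(viterbi_path(ems, params)) == best

    def test_exact_tie_takes_smallest_pair(self):
        params = uniform_params(2, tau=0.1)
        path = viterbi_path([np.zeros((1, 3))], params)
        assert path[0] == 0


class TestSampling:
    def test_tiny_tau_gives_constant_paths(self):
        rng = np.random.default_rng(9)
        S = len(unordered_pairs(2))
        params = AncestryHMMParams(["a", "b"], np.full(S, 1 / S), 1e-9)
        samples = sample_paths([rng.normal(0, 0.5, (6, S))], params,
                               n_samples=50, rng=0)
        assert (samples == samples[:, :1]).all()

    def test_frequencies_match_enumerated_posterior(self):
        rng = np.random.default_rng(10)
        S = len(unordered_pairs(2))
        ems = [rng.normal(0, 1, (2, S))]
        params = random_params(rng, 2)
        _, post = enumerate_hmm_paths(ems, params)
        n = 20_000
        samples = sample_paths(ems, params, n_samples=n, rng=1)
        counts = {}
        for row in samples:
            counts[tuple(row)] = counts.get(tuple(row), 0) + 1
        for path, p in post[0].items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(path, 0) / n - p) <= 3 * se + 1e-12

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(11)
        S = len(unordered_pairs(3))
        ems = [rng.normal(0, 1, (4, S))]
        params = uniform_params(3)
        a = sample_paths(ems, params, n_samples=20, rng=42)
        b = sample_paths(ems, params, n_samples=20, rng=42)
        np.testing.assert_array_equal(a, b)
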