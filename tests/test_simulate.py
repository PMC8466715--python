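import numpy as np
import pytest

from haplarch.simulate import (
    BenchmarkConfig,
    PedigreeSpec,
    _meiosis,
    hudson_fst,
    make_benchmark,
    sample_individuals,
    simulate_pedigree,
    simulate_populations,
)
from haplarch.windows import build_windows, group_windows

from conftest import make_snp_map


class TestPopulations:
    def test_zero_fst_copies_ancestral(self):
        _, pm = simulate_populations(3, 100, 0.0, rng=0)
        for k in range(3):
            np.testing.assert_allclose(pm.frequencies[k], pm.ancestral)

    def test_single_population(self):
        snp_map, pm = simulate_populations(1, 100, 0.2, rng=0)
        assert pm.frequencies.shape == (1, 100)
        assert snp_map.n_snps == 100

    def test_frequencies_clamped(self):
        _, pm = simulate_populations(4, 5000, 0.5, rng=1)
        assert pm.frequencies.min() >= 0.01
        assert pm.frequencies.max() <= 0.99

    def test_realized_fst_near_target(self):
        _, pm = simulate_populations(2, 10_000, 0.2, rng=2)
        a = sample_individuals(pm, "pop0", 50, rng=3).alleles
        b = sample_individuals(pm, "pop1", 50, rng=4).alleles
        fst = hudson_fst(a, b)
        assert abs(fst - 0.2) / 0.2 < 0.2

    def test_chromosome_split(self):
        snp_map, _ = simulate_populations(2, 101, 0.1, rng=0, n_chromosomes=2)
        assert snp_map.chroms == ["1", "2"]
        lo, hi = snp_map.chrom_range("1")
        assert hi - lo == 51


class TestSampling:
    def test_fixed_frequency_fixes_alleles(self):
        _, pm = simulate_populations(1, 10, 0.0, rng=0)
        pm.frequencies[:] = 0.99
        haps = sample_individuals(pm, "pop0", 200, rng=1)
        assert haps.alleles.mean() == pytest.approx(0.99, abs=0.01)

    def test_sample_frequency_within_three_se(self):
        rng = np.random.default_rng(5)
        _, pm = simulate_populations(1, 50, 0.0, rng=rng)
        haps = sample_individuals(pm, "pop0", 500, rng=rng)
        n = 1000
        se = np.sqrt(pm.frequencies[0] * (1 - pm.frequencies[0]) / n)
        dev = np.abs(haps.alleles.mean(axis=0) - pm.frequencies[0])
        assert (dev <= 3 * se + 1e-9).mean() > 0.95

    def test_unphased_returns_dosages(self):
        _, pm = simulate_populations(2, 20, 0.1, rng=0)
        g = sample_individuals(pm, "pop1", 5, phased=False, rng=1)
        assert g.dosages.shape == (5, 20)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}


class TestPedigree:
    def _founders(self, pm, pops, rng):
        from haplarch.containers import HaplotypeSet

        rows, labels = [], []
        for p in pops:
            h = sample_individuals(pm, p, 1, rng=rng)
            rows.append(h.alleles)
            labels += [p, p]
        return HaplotypeSet(np.concatenate(rows), [f"f{i}" for i in range(len(pops))],
                            populations=labels)

    def test_one_generation_is_obligate_heterozygous(self):
        snp_map, pm = simulate_populations(2, 200, 0.2, rng=0,
                                           population_names=["A", "B"])
        groups = group_windows(build_windows(snp_map, 40, 5), 2)
        rng = np.random.default_rng(1)
        founders = self._founders(pm, ["A", "B"], rng)
        _, truth = simulate_pedigree(PedigreeSpec(1, ["A", "B"]), founders,
                                     snp_map, groups, rng)
        assert all(pair == ("A", "B") for pair in truth.group_pairs)
        assert truth.proportions == {"A": 0.5, "B": 0.5}

    def test_two_generation_minority_expectation(self):
        # one B great-grandparent among 4 founders: expected minority 0.25
        snp_map, pm = simulate_populations(2, 300, 0.2, rng=2,
                                           snp_spacing_cm=0.2,
                                           population_names=["A", "B"])
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(300):
            founders = self._founders(pm, ["B", "A", "A", "A"], rng)
            _, truth = simulate_pedigree(PedigreeSpec(2, ["B", "A", "A", "A"]),
                                         founders, snp_map, None, rng)
            fracs.append(truth.proportions.get("B", 0.0))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.25) <= 3 * se

    def test_zero_length_chromosome_never_recombines(self):
        snp_map = make_snp_map(5, spacing_cm=0.0)
        rng = np.random.default_rng(4)
        hap = np.array([[0] * 5, [1] * 5], dtype=np.int8)
        lab = np.array([[0] * 5, [1] * 5], dtype=np.int16)
        for _ in range(50):
            g, l = _meiosis(hap, lab, snp_map, rng)
            assert len(set(l.tolist())) == 1  # whole gamete from one parent

    def test_truth_proportions_sum_to_one(self):
        snp_map, pm = simulate_populations(3, 200, 0.2, rng=5,
                                           population_names=list("ABC"))
        rng = np.random.default_rng(6)
        pops = ["A", "B", "C", "A"]
        founders = self._founders(pm, pops, rng)
        _, truth = simulate_pedigree(PedigreeSpec(2, pops), founders,
                                     snp_map, None, rng)
        assert sum(truth.proportions.values()) == pytest.approx(1.0)

    def test_segments_shorten_with_generations(self):
        snp_map, pm = simulate_populations(2, 400, 0.2, rng=7,
                                           snp_spacing_cm=0.25,
                                           population_names=["A", "B"])
        rng = np.random.default_rng(8)
        cm = snp_map.cm

        def mean_segment_cm(G, reps=100):
            lengths = []
            for _ in range(reps):
                pops = (["A", "B"] * (2 ** G))[: 2 ** G]
                founders = self._founders(pm, pops, rng)
                _, truth = simulate_pedigree(PedigreeSpec(G, pops), founders,
                                             snp_map, None, rng)
                for hap in truth.haplotype_labels:
                    breaks = np.flatnonzero(np.diff(hap) != 0)
                    edges = np.concatenate([[0], breaks + 1, [len(hap)]])
                    for a, b in zip(edges[:-1], edges[1:]):
                        lengths.append(cm[b - 1] - cm[a])
            return float(np.mean(lengths))

        assert mean_segment_cm(3) < mean_segment_cm(1)


class TestBenchmark:
    def test_single_origin_truth(self):
        cfg = BenchmarkConfig(n_snps=400, n_background_haplotypes=20,
                              n_panel_per_pop=5, n_test=4, seed=0,
                              window_size=40, window_overlap=5, group_size=2)
        b = make_benchmark(cfg)
        for t in b.truths:
            pairs = set(t.group_pairs)
            assert len(pairs) == 1
            (p, q), = pairs
            assert p == q
            assert t.proportions == {p: 1.0}

    def test_paired_design_founder_split(self):
        cfg = BenchmarkConfig(design="paired", generations=4, n_snps=400,
                              n_background_haplotypes=20, n_panel_per_pop=5,
                              n_test=2, seed=1, window_size=40, group_size=2)
        from haplarch.simulate import _founder_assignment
        pops = ["pop0", "pop1"]
        a = _founder_assignment(cfg, pops, 0)
        assert a.count("pop0") == 1 and a.count("pop1") == 15
        b = _founder_assignment(cfg, pops, 1)
        assert b.count("pop1") == 1 and b.count("pop0") == 15

    def test_three_way_weights_round_to_founder_counts(self):
        cfg = BenchmarkConfig(design="three_way", generations=4, K=3,
                              weights={"pop0": 0.45, "pop1": 0.50, "pop2": 0.05})
        from haplarch.simulate import _founder_assignment
        a = _founder_assignment(cfg, ["pop0", "pop1", "pop2"], 0)
        assert len(a) == 16
        assert a.count("pop0") == 7 and a.count("pop1") == 8 and a.count("pop2") == 1

    def test_benchmark_is_seed_reproducible(self):
        cfg = BenchmarkConfig(n_snps=300, n_background_haplotypes=10,
                              n_panel_per_pop=4, n_test=2, seed=9,
                              window_size=40, group_size=2)
        a, b = make_benchmark(cfg), make_benchmark(cfg)
        np.testing.assert_array_equal(a.test.dosages, b.test.dosages)
        np.testing.assert_array_equal(a.background.alleles, b.background.alleles)
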