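"""Global ancestry estimates, credible intervals, and evaluation metrics.

The Viterbi path through the pair-ancestry HMM gives each window group a
diploid assignment; global proportions are the genetic-length-weighted
share of haplotype slots assigned to each population.  Credible
intervals are empirical quantiles of the same proportion computed over
paths sampled from the HMM posterior (conditioned on the fitted
parameters, so they reflect path uncertainty only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ancestry_hmm
from .ancestry_hmm import AncestryHMMParams
from .containers import MISSING, GenotypeSet
from .emission import GenomeEmissions, unordered_pairs, window_emission_batch, group_emission
from .windows import WindowGroup


@dataclass
class AdmixtureTruth:
    """Known ancestry of one simulated individual.

    ``group_pairs`` holds the unordered population-name pair of each
    window group (sorted tuples); ``proportions`` the cM-weighted global
    diploid ancestry fractions.  Simulators may attach the full per-SNP
    haplotype labels (2, n_snps population indices into ``label_names``).
    """

    group_pairs: list[tuple[str, str]]
    proportions: dict[str, float]
    haplotype_labels: np.ndarray | None = None
    label_names: list[str] | None = None


@dataclass
class AncestryEstimate:
    """Inferred ancestry of one test individual."""

    individual: str
    populations: list[str]
    proportions: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    path: np.ndarray                      # Viterbi state index per window group
    params: AncestryHMMParams
    sampled_proportions: np.ndarray       # (n_samples, K)
    low_confidence: bool = False

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return unordered_pairs(len(self.populations))

    def path_pairs(self) -> list[tuple[str, str]]:
        """Viterbi assignment per group as sorted population-name pairs."""
        pairs = self.pairs
        return [
            tuple(sorted((self.populations[pairs[s][0]], self.populations[pairs[s][1]])))
            for s in self.path
        ]

    def to_dict(self) -> dict:
        return {
            "individual": self.individual,
            "proportions": {
                p: {
                    "point": self.proportions[p],
                    "ci_lower": self.intervals[p][0],
                    "ci_upper": self.intervals[p][1],
                }
                for p in self.populations
            },
            "tau": self.params.tau,
            "low_confidence": self.low_confidence,
        }


def group_weights(groups: list[WindowGroup]) -> np.ndarray:
    """Genetic lengths (cM) used to weight window groups."""
    w = np.array([g.cm_length for g in groups], dtype=float)
    if w.sum() <= 0:
        raise ValueError("window groups have zero total genetic length")
    return w


def path_to_proportions(
    path: np.ndarray,
    groups: list[WindowGroup],
    n_populations: int,
) -> np.ndarray:
    """cM-weighted population proportions of one state path.

    Each group contributes half its weight per haplotype slot: a group
    assigned (p,q) gives w/2 to p and w/2 to q.
    """
    path = np.asarray(path)
    if len(path) != len(groups):
        raise ValueError("path length must equal group count")
    w = group_weights(groups)
    pairs = unordered_pairs(n_populations)
    out = np.zeros(n_populations)
    for s, wt in zip(path, w):
        p, q = pairs[s]
        out[p] += 0.5 * wt
        out[q] += 0.5 * wt
    return out / w.sum()


def credible_intervals(
    sampled_paths: np.ndarray,
    groups: list[WindowGroup],
    n_populations: int,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-population equal-tailed quantile interval of sampled-path proportions.

    Returns ``(intervals (K, 2), sampled_proportions (n_samples, K))``.
    """
    sampled_paths = np.atleast_2d(sampled_paths)
    if len(sampled_paths) < 2:
        raise ValueError("need at least 2 sampled paths")
    props = np.stack([
        path_to_proportions(p, groups, n_populations) for p in sampled_paths
    ])
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(props, alpha, axis=0)
    hi = np.quantile(props, 1.0 - alpha, axis=0)
    return np.stack([lo, hi], axis=1), props


def global_concordance(true_props: dict[str, float], est_props: dict[str, float]) -> float:
    """Σ_p min(true_p, est_p): intersection of two ancestry distributions."""
    for props in (true_props, est_props):
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")
    pops = set(true_props) | set(est_props)
    return float(sum(min(true_props.get(p, 0.0), est_props.get(p, 0.0)) for p in pops))


def local_concordance(
    truth: AdmixtureTruth | list[tuple[str, str]],
    est_pairs: list[tuple[str, str]],
) -> float:
    """Mean per-group diploid assignment score, phase-free.

    Full credit for a matching unordered pair, half credit when exactly
    one slot matches under the best pairing, zero otherwise.
    """
    true_pairs = truth.group_pairs if isinstance(truth, AdmixtureTruth) else truth
    if len(true_pairs) != len(est_pairs):
        raise ValueError("truth and estimate must cover the same groups")
    total = 0.0
    for t, e in zip(true_pairs, est_pairs):
        remaining = list(e)
        match = 0
        for x in t:
            if x in remaining:
                remaining.remove(x)
                match += 1
        total += match / 2.0
    return total / len(true_pairs)


def precision_recall(
    truths: list[dict[str, float]],
    estimates: list[dict[str, float]],
    population: str,
) -> tuple[float | None, float | None]:
    """Test-set precision/recall of estimated ancestry amounts for one population.

    The correctly identified amount is Σ over individuals of
    min(true_p, est_p); precision divides by the total estimated amount,
    recall by the total true amount.  A zero denominator yields ``None``.
    """
    if len(truths) != len(estimates):
        raise ValueError("need one estimate per truth")
    correct = sum(min(t.get(population, 0.0), e.get(population, 0.0))
                  for t, e in zip(truths, estimates))
    est_total = sum(e.get(population, 0.0) for e in estimates)
    true_total = sum(t.get(population, 0.0) for t in truths)
    precision = correct / est_total if est_total > 0 else None
    recall = correct / true_total if true_total > 0 else None
    return precision, recall


def align_test_genotypes(bundle, test: GenotypeSet) -> np.ndarray:
    """Project test dosages onto the bundle's SNP grid.

    SNPs are matched by id and position; bundle SNPs absent from the
    test set become missing.  Fails when fewer than half the bundle's
    SNPs are covered.
    """
    if test.snp_map is None:
        if test.n_snps != bundle.snp_map.n_snps:
            raise ValueError("test set has no SNP map and does not match the bundle grid")
        return test.dosages
    key_of = {
        (c, s, b): i
        for i, (c, s, b) in enumerate(
            zip(bundle.snp_map.table["chrom"], bundle.snp_map.table["snp_id"],
                bundle.snp_map.table["bp"])
        )
    }
    aligned = np.full((test.n_individuals, bundle.snp_map.n_snps), MISSING, dtype=np.int8)
    hit = 0
    for j, (c, s, b) in enumerate(
        zip(test.snp_map.table["chrom"], test.snp_map.table["snp_id"], test.snp_map.table["bp"])
    ):
        i = key_of.get((c, s, b))
        if i is not None:
            aligned[:, i] = test.dosages[:, j]
            hit += 1
    if hit < 0.5 * bundle.snp_map.n_snps:
        raise ValueError(
            f"only {hit}/{bundle.snp_map.n_snps} bundle SNPs found in the test set "
            "(< 50% overlap)"
        )
    return aligned


def compute_emissions(bundle, dosages: np.ndarray) -> list[GenomeEmissions]:
    """Per-individual window-group emissions, batched per window over individuals."""
    dosages = np.atleast_2d(dosages)
    n_ind = dosages.shape[0]
    window_logs: list[np.ndarray] = []
    for w, model, ann in zip(bundle.windows, bundle.models, bundle.annotations):
        t = dosages[:, w.start:w.end]
        window_logs.append(window_emission_batch(model, ann, t, bundle.populations))
    chrom_order = list(dict.fromkeys(g.chrom for g in bundle.groups))
    out = []
    for i in range(n_ind):
        by_chrom = {c: [] for c in chrom_order}
        for g in bundle.groups:
            by_chrom[g.chrom].append(
                group_emission([window_logs[wi][i] for wi in g.window_indices])
            )
        out.append(GenomeEmissions(
            populations=bundle.populations,
            by_chrom=[np.stack(by_chrom[c]) for c in chrom_order],
        ))
    return out


def infer_ancestry(
    bundle,
    test: GenotypeSet,
    em_iterations: int = 10,
    init_tau: float = 0.01,
    pi_floor: float = 1e-6,
    n_samples: int = 100,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> list[AncestryEstimate]:
    """End-to-end diploid ancestry inference for a set of test individuals.

    Per individual: window emissions → fixed-iteration EM fit of (π, τ)
    → Viterbi decoding → cM-weighted proportions → posterior path
    sampling for credible intervals.  Individuals are independent; each
    gets its own RNG stream derived from ``seed`` and its index, so
    results do not depend on processing order.
    """
    dosages = align_test_genotypes(bundle, test)
    emissions = compute_emissions(bundle, dosages)
    K = len(bundle.populations)
    estimates = []
    for i, em in enumerate(emissions):
        params = ancestry_hmm.baum_welch_fit(
            em, init_tau=init_tau, iterations=em_iterations, pi_floor=pi_floor
        )
        path = ancestry_hmm.viterbi_path(em, params)
        props = path_to_proportions(path, bundle.groups, K)
        rng = np.random.default_rng(None if seed is None else [seed, i])
        samples = ancestry_hmm.sample_paths(em, params, n_samples=n_samples, rng=rng)
        ivals, sampled_props = credible_intervals(samples, bundle.groups, K, ci_level)
        pops = bundle.populations
        estimates.append(AncestryEstimate(
            individual=test.individuals[i],
            populations=pops,
            proportions={p: float(props[k]) for k, p in enumerate(pops)},
            intervals={p: (float(ivals[k, 0]), float(ivals[k, 1])) for k, p in enumerate(pops)},
            path=path,
            params=params,
            sampled_proportions=sampled_props,
            low_confidence=bool(np.all(dosages[i] == MISSING)),
        ))
    return estimates
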