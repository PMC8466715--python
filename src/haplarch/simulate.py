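"""Synthetic founder populations and pedigree admixture with truth tracking.

Founder populations are differentiated with the Balding-Nichols model:
each SNP's population frequency is a Beta draw around a shared ancestral
frequency with spread set by Fst.  Haplotypes are sampled in linkage
equilibrium within populations, so cluster models derive their signal
purely from allele-frequency differentiation.  Admixed test individuals
descend from a pedigree of labeled founders through simulated meioses
(Poisson crossovers on the cM scale, no interference), with per-SNP
ancestry labels carried along so the true local and global ancestry of
the descendant is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeSet, HaplotypeSet, SnpMap
from .estimate import AdmixtureTruth
from .windows import WindowGroup, Window, build_windows, group_windows

CM_PER_MORGAN = 100.0
BP_PER_CM = 1_000_000  # 1 cM/Mb convention for synthetic maps


@dataclass
class PopulationModel:
    """Allele frequencies of K differentiated populations."""

    populations: list[str]
    ancestral: np.ndarray        # (n_snps,)
    frequencies: np.ndarray      # (K, n_snps), clamped to [0.01, 0.99]
    fst: float

    @property
    def n_snps(self) -> int:
        return self.ancestral.shape[0]

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)


@dataclass
class PedigreeSpec:
    """A 2^G-founder pedigree with one descendant after G generations."""

    generations: int
    founder_populations: list[str]

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if len(self.founder_populations) != 2 ** self.generations:
            raise ValueError(
                f"{self.generations}-generation pedigree needs "
                f"{2 ** self.generations} founders"
            )


def simulate_populations(
    K: int,
    n_snps: int,
    fst: float,
    snp_spacing_cm: float = 0.05,
    rng: np.random.Generator | int | None = None,
    n_chromosomes: int = 1,
    population_names: list[str] | None = None,
) -> tuple[SnpMap, PopulationModel]:
    """Draw a synthetic SNP grid and Balding-Nichols population frequencies.

    Ancestral frequencies are uniform on (0.05, 0.95); each population's
    frequency at a SNP is Beta(p(1−F)/F, (1−p)(1−F)/F) (F = Fst), or the
    ancestral frequency exactly when F = 0.  SNPs are uniformly spaced
    ``snp_spacing_cm`` apart, split evenly over ``n_chromosomes``.
    """
    if K < 1 or n_snps < 2:
        raise ValueError("need K >= 1 and n_snps >= 2")
    if not 0.0 <= fst <= 0.5:
        raise ValueError("Fst must be in [0, 0.5]")
    rng = np.random.default_rng(rng)
    names = population_names or [f"pop{k}" for k in range(K)]
    anc = rng.uniform(0.05, 0.95, size=n_snps)
    if fst == 0.0:
        freqs = np.tile(anc, (K, 1))
    else:
        a = anc * (1.0 - fst) / fst
        b = (1.0 - anc) * (1.0 - fst) / fst
        freqs = rng.beta(a, b, size=(K, n_snps))
    freqs = np.clip(freqs, 0.01, 0.99)

    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    rows = []
    i = 0
    for c, n in enumerate(per_chrom, start=1):
        for j in range(n):
            rows.append((str(c), f"snp{i}", int(round(j * snp_spacing_cm * BP_PER_CM)) + 1,
                         j * snp_spacing_cm))
            i += 1
    snp_map = SnpMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "bp", "cm"]))
    return snp_map, PopulationModel(names, anc, freqs, fst)


def sample_individuals(
    model: PopulationModel,
    population: str,
    n: int,
    phased: bool = True,
    rng: np.random.Generator | int | None = None,
    snp_map: SnpMap | None = None,
    id_prefix: str = "ind",
) -> HaplotypeSet | GenotypeSet:
    """Sample n individuals from one population (LE within populations)."""
    rng = np.random.default_rng(rng)
    f = model.frequencies[model.pop_index(population)]
    alleles = (rng.random((2 * n, model.n_snps)) < f).astype(np.int8)
    ids = [f"{id_prefix}{i}" for i in range(n)]
    haps = HaplotypeSet(alleles, ids, populations=[population] * 2 * n, snp_map=snp_map)
    return haps if phased else haps.to_genotypes()


def sample_background(
    model: PopulationModel,
    n_haplotypes: int,
    rng: np.random.Generator | int | None = None,
    snp_map: SnpMap | None = None,
) -> HaplotypeSet:
    """Unlabeled background haplotypes drawn evenly across populations."""
    rng = np.random.default_rng(rng)
    K = len(model.populations)
    n_ind = n_haplotypes // 2
    pops = [model.populations[i % K] for i in range(n_ind)]
    rows = []
    for p in pops:
        f = model.frequencies[model.pop_index(p)]
        rows.append((rng.random((2, model.n_snps)) < f).astype(np.int8))
    return HaplotypeSet(np.concatenate(rows, axis=0),
                        [f"bg{i}" for i in range(n_ind)], snp_map=snp_map)


def hudson_fst(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Hudson's Fst between two haplotype samples (ratio-of-averages form).

    Per-SNP numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
    denominator p₁(1−p₂) + p₂(1−p₁), averaged before the ratio.
    """
    hap_a, hap_b = np.asarray(hap_a, float), np.asarray(hap_b, float)
    n1, n2 = hap_a.shape[0], hap_b.shape[0]
    p1, p2 = hap_a.mean(axis=0), hap_b.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].mean() / den[keep].mean())


def _meiosis(hap_pair: np.ndarray, lab_pair: np.ndarray, snp_map: SnpMap,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Poisson(L/100) crossovers per chromosome, uniform on cM."""
    gam = np.empty(hap_pair.shape[1], dtype=hap_pair.dtype)
    lab = np.empty(lab_pair.shape[1], dtype=lab_pair.dtype)
    cm = snp_map.cm
    for chrom in snp_map.chroms:
        lo, hi = snp_map.chrom_range(chrom)
        c = cm[lo:hi]
        length = c[-1] - c[0]
        n_x = rng.poisson(length / CM_PER_MORGAN) if length > 0 else 0
        cuts = np.sort(rng.uniform(c[0], c[-1], size=n_x))
        start = rng.integers(2)
        which = (start + np.searchsorted(cuts, c, side="right")) % 2
        idx = np.arange(lo, hi)
        gam[lo:hi] = np.where(which == 0, hap_pair[0, idx], hap_pair[1, idx])
        lab[lo:hi] = np.where(which == 0, lab_pair[0, idx], lab_pair[1, idx])
    return gam, lab


def simulate_pedigree(
    spec: PedigreeSpec,
    founders: HaplotypeSet,
    snp_map: SnpMap,
    groups: list[WindowGroup] | None = None,
    rng: np.random.Generator | int | None = None,
    individual_id: str = "desc0",
) -> tuple[GenotypeSet, AdmixtureTruth]:
    """Descend one individual from 2^G labeled founders and record truth.

    Founder order fills a complete binary pedigree left to right.  The
    per-group true assignment is the unordered pair of founder-population
    labels at the group's midpoint SNP; global truth proportions weight
    each SNP by its local cM share.
    """
    rng = np.random.default_rng(rng)
    G = spec.generations
    if founders.n_haplotypes != 2 ** (G + 1):
        raise ValueError("founder count does not match pedigree spec")
    if founders.populations is None:
        raise ValueError("founders must carry population labels")
    pop_names = sorted(set(spec.founder_populations))
    pop_idx = {p: i for i, p in enumerate(pop_names)}
    lab_rows = np.array([pop_idx[p] for p in founders.populations], dtype=np.int16)

    def descend(slot_lo: int, gen: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (2, n_snps) haplotypes and labels of the individual."""
        if gen == 0:
            haps = founders.alleles[2 * slot_lo : 2 * slot_lo + 2]
            labs = np.repeat(lab_rows[2 * slot_lo : 2 * slot_lo + 2, None],
                             founders.n_snps, axis=1)
            return haps.copy(), labs
        half = 2 ** (gen - 1)
        h_a, l_a = descend(slot_lo, gen - 1)
        h_b, l_b = descend(slot_lo + half, gen - 1)
        g0, lg0 = _meiosis(h_a, l_a, snp_map, rng)
        g1, lg1 = _meiosis(h_b, l_b, snp_map, rng)
        return np.stack([g0, g1]), np.stack([lg0, lg1])

    haps, labs = descend(0, G)
    genotypes = GenotypeSet((haps[0] + haps[1]).astype(np.int8)[None, :],
                            [individual_id], snp_map=snp_map)

    w = _snp_cm_weights(snp_map)
    props = {}
    for p, i in pop_idx.items():
        props[p] = float(((labs == i) * w[None, :]).sum() / (2.0 * w.sum()))
    group_pairs = []
    if groups is not None:
        for g in groups:
            mid = g.midpoint_snp
            pair = sorted((pop_names[labs[0, mid]], pop_names[labs[1, mid]]))
            group_pairs.append(tuple(pair))
    return genotypes, AdmixtureTruth(group_pairs=group_pairs, proportions=props,
                                     haplotype_labels=labs, label_names=pop_names)


def _snp_cm_weights(snp_map: SnpMap) -> np.ndarray:
    """Per-SNP genetic-length share (half-interval rule, per chromosome)."""
    w = np.zeros(snp_map.n_snps)
    cm = snp_map.cm
    for chrom in snp_map.chroms:
        lo, hi = snp_map.chrom_range(chrom)
        c = cm[lo:hi]
        if hi - lo == 1 or c[-1] == c[0]:
            w[lo:hi] = 1.0  # degenerate chromosome: uniform weight
            continue
        mids = (c[1:] + c[:-1]) / 2.0
        edges = np.concatenate([[c[0]], mids, [c[-1]]])
        w[lo:hi] = np.diff(edges)
    return w


@dataclass
class BenchmarkConfig:
    """Study design for a fully synthetic end-to-end benchmark."""

    K: int = 2
    fst: float = 0.2
    n_snps: int = 8000
    n_chromosomes: int = 2
    snp_spacing_cm: float = 0.05
    n_background_haplotypes: int = 200
    n_panel_per_pop: int = 50
    design: str = "single_origin"        # single_origin | paired | three_way
    generations: int = 1                 # pedigree depth for admixed designs
    n_test: int = 20
    weights: dict[str, float] | None = None   # three_way founder weights
    window_size: int = 80
    window_overlap: int = 5
    group_size: int = 4
    seed: int | None = None


@dataclass
class BenchmarkData:
    """Everything an end-to-end run needs, plus the truth."""

    snp_map: SnpMap
    population_model: PopulationModel
    windows: list[Window]
    groups: list[WindowGroup]
    background: HaplotypeSet
    panel: GenotypeSet
    test: GenotypeSet
    truths: list[AdmixtureTruth]


def _founder_assignment(cfg: BenchmarkConfig, pops: list[str], which: int) -> list[str]:
    n_founders = 2 ** cfg.generations
    if cfg.design == "paired":
        minority = pops[which % 2]
        majority = pops[(which + 1) % 2]
        return [minority] + [majority] * (n_founders - 1)
    if cfg.design == "three_way":
        if not cfg.weights:
            raise ValueError("three_way design requires founder weights")
        # largest-remainder rounding of weight * 2^G founder slots
        items = sorted(cfg.weights.items())
        raw = {p: w * n_founders for p, w in items}
        counts = {p: int(np.floor(r)) for p, r in raw.items()}
        short = n_founders - sum(counts.values())
        for p, _ in sorted(items, key=lambda kv: -(raw[kv[0]] - np.floor(raw[kv[0]])))[:short]:
            counts[p] += 1
        out: list[str] = []
        for p, _ in items:
            out.extend([p] * counts[p])
        return out
    raise ValueError(f"unknown design {cfg.design!r}")


def make_benchmark(config: BenchmarkConfig) -> BenchmarkData:
    """Generate background, panel, test genotypes and truth for one design.

    ``single_origin`` test individuals are straight population samples
    (truth (p,p) everywhere); ``paired`` descends each test individual
    from a pedigree with one minority founder (expected minority fraction
    1/2^G, alternating which population is the minority); ``three_way``
    fills founder slots proportionally to the given weights.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    snp_map, pop_model = simulate_populations(
        cfg.K, cfg.n_snps, cfg.fst, cfg.snp_spacing_cm,
        rng=rng, n_chromosomes=cfg.n_chromosomes,
    )
    windows = build_windows(snp_map, cfg.window_size, cfg.window_overlap)
    groups = group_windows(windows, cfg.group_size)
    pops = pop_model.populations

    background = sample_background(pop_model, cfg.n_background_haplotypes, rng, snp_map)
    panel_parts, panel_labels, panel_ids = [], [], []
    for p in pops:
        g = sample_individuals(pop_model, p, cfg.n_panel_per_pop, phased=False,
                               rng=rng, id_prefix=f"panel_{p}_")
        panel_parts.append(g.dosages)
        panel_labels += [p] * cfg.n_panel_per_pop
        panel_ids += g.individuals
    panel = GenotypeSet(np.concatenate(panel_parts, axis=0), panel_ids,
                        labels=panel_labels, snp_map=snp_map)

    test_rows, test_ids, truths = [], [], []
    for i in range(cfg.n_test):
        if cfg.design == "single_origin":
            p = pops[i % cfg.K]
            g = sample_individuals(pop_model, p, 1, phased=False, rng=rng,
                                   id_prefix=f"test{i}_")
            test_rows.append(g.dosages[0])
            truths.append(AdmixtureTruth(
                group_pairs=[(p, p)] * len(groups), proportions={p: 1.0}))
        else:
            fpops = _founder_assignment(cfg, pops, i)
            spec = PedigreeSpec(cfg.generations, fpops)
            frows, fl = [], []
            for p in fpops:
                h = sample_individuals(pop_model, p, 1, phased=True, rng=rng)
                frows.append(h.alleles)
                fl += [p, p]
            founders = HaplotypeSet(np.concatenate(frows, axis=0),
                                    [f"f{j}" for j in range(len(fpops))],
                                    populations=fl)
            g, truth = simulate_pedigree(spec, founders, snp_map, groups, rng)
            test_rows.append(g.dosages[0])
            truths.append(truth)
        test_ids.append(f"test{i}")
    test = GenotypeSet(np.stack(test_rows), test_ids, snp_map=snp_map)
    return BenchmarkData(snp_map, pop_model, windows, groups, background,
                         panel, test, truths)
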