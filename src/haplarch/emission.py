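"""Ancestry emission likelihoods: P(test genotype | unordered population pair).

For a test genotype t_w in a window, the chain is

    P_d(t_w|u,v)   = P_d(t_w,u,v) / P_d(u,v)        (pair-node likelihood ratio)
    P_d(u,v|p,q)   = ½(P_d(u|p)P_d(v|q) + P_d(u|q)P_d(v|p))
    P_d(t_w|p,q)   = Σ_{u,v} P_d(t_w|u,v) · P_d(u,v|p,q)
    P(t_w|p,q)     = (1/D) Σ_d P_d(t_w|p,q)

i.e. every SNP of the window votes with the population profile of the
clusters the genotype plausibly occupies around it, and the window
averages those votes.  Window-group emissions multiply member-window
likelihoods (one shared ancestry state per group) and are max-normalised
in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotate import Annotation
from .containers import MISSING
from .hapmodel import (
    PRIOR_TINY,
    ClusterModel,
    DiploidPosterior,
    _backward_sweep,
    diploid_forward,
    pair_prior,
)

logger = logging.getLogger(__name__)

LOG_TINY = -745.0  # log of smallest positive normal double, a safe floor


def unordered_pairs(n_populations: int) -> list[tuple[int, int]]:
    """All unordered population pairs (p, q), p <= q, in lexicographic order."""
    return [(p, q) for p in range(n_populations) for q in range(p, n_populations)]


def emission_given_nodes(
    model: ClusterModel, posterior: DiploidPosterior
) -> list[np.ndarray]:
    """P_d(t_w|u,v) tables: posterior-to-prior ratio scaled by P(t_w).

    Node pairs whose prior is numerically zero are excluded (entry 0).
    """
    priors = pair_prior(model)
    lik = np.exp(posterior.log_likelihood)
    out = []
    for post, prior in zip(posterior.tables, priors):
        table = np.where(prior > PRIOR_TINY, lik * post / np.maximum(prior, PRIOR_TINY), 0.0)
        out.append(table)
    return out


def pair_population_prob(
    annotation: Annotation, d: int, u: int, v: int, p: int, q: int
) -> float:
    """P_d(u,v|p,q): phase-symmetric product of per-population occupancies."""
    A = annotation.tables[d]
    return 0.5 * (A[u, p] * A[v, q] + A[u, q] * A[v, p])


def window_emission_batch(
    model: ClusterModel,
    annotation: Annotation,
    dosages: np.ndarray,
    populations: list[str] | None = None,
) -> np.ndarray:
    """log P(t_w|p,q) over unordered pairs, batched over genotypes.

    Per level the population-pair value is A_dᵀ M_d A_d with
    M_d = posterior/prior (the P_d(t|u,v) table divided by P(t)); the
    level values are averaged and rescaled by log P(t_w).  Returns a
    (B, S) array, S = K(K+1)/2, pairs ordered as :func:`unordered_pairs`.
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    if np.all(dosages == MISSING):
        logger.info("window emission on all-missing genotypes is uninformative")
    tables = annotation.matrix(populations)
    K = tables[0].shape[1]
    priors = pair_prior(model)
    F, log_lik = diploid_forward(model, dosages)
    B = dosages.shape[0]
    acc = np.zeros((B, K, K))

    def reduce_fn(d, post):
        prior = priors[d]
        M = np.where(prior > PRIOR_TINY, post / np.maximum(prior, PRIOR_TINY), 0.0)
        A = tables[d]
        acc[:] += A.T @ M @ A

    _backward_sweep(model, dosages, F, reduce_fn)
    mean_levels = acc / model.n_snps
    pairs = unordered_pairs(K)
    vals = np.stack([0.5 * (mean_levels[:, p, q] + mean_levels[:, q, p]) for p, q in pairs], axis=1)
    return log_lik[:, None] + np.log(np.maximum(vals, np.exp(LOG_TINY)))


def window_emission(
    model: ClusterModel,
    annotation: Annotation,
    t_w: np.ndarray,
    populations: list[str] | None = None,
) -> np.ndarray:
    """log P(t_w|p,q) for one genotype; see :func:`window_emission_batch`."""
    return window_emission_batch(model, annotation, np.asarray(t_w)[None, :], populations)[0]


def group_emission(window_log_emissions: list[np.ndarray]) -> np.ndarray:
    """Combine member windows of a group: sum of logs, max-normalised.

    A window group carries a single diploid ancestry state, so member
    windows are conditionally independent given the pair and their
    likelihoods multiply; subtracting the max is a per-group constant
    that leaves HMM posteriors and Viterbi paths unchanged.
    """
    if not window_log_emissions:
        raise ValueError("a window group needs at least one member window")
    total = np.sum(window_log_emissions, axis=0)
    return total - total.max(axis=-1, keepdims=True)


@dataclass
class GenomeEmissions:
    """Per-group log emission matrices, split by chromosome.

    ``by_chrom[c]`` is an (n_groups_c, S) matrix of max-normalised
    log P(t_g|p,q); pair column order follows :func:`unordered_pairs`
    over ``populations``.
    """

    populations: list[str]
    by_chrom: list[np.ndarray]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return unordered_pairs(len(self.populations))

    @property
    def n_groups(self) -> int:
        return sum(len(m) for m in self.by_chrom)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.by_chrom, axis=0)
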