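"""Genome-wide HMM over unordered ancestry pairs: EM, Viterbi, path sampling.

Hidden states are the K(K+1)/2 unordered population pairs (p,q) carried
by each window group.  Between adjacent groups of one chromosome, with
probability 1−τ nothing changes; with probability τ exactly *one* of the
two haplotypes' ancestries switches, the new pair drawn proportionally
to the individual's global pair distribution π restricted to the pairs
reachable by a single-slot change.  Chromosome starts redraw the pair
independently from π.  π and τ are learned per test individual with a
fixed number of Baum-Welch-style updates (no convergence stop, guarding
against the overfitting tendency of a free τ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission import GenomeEmissions, unordered_pairs

TAU_MIN, TAU_MAX = 1e-6, 0.5


@dataclass
class AncestryHMMParams:
    """HMM parameters for one test individual.

    ``pi`` is the distribution over unordered pairs in the order of
    :func:`haplarch.emission.unordered_pairs`; ``tau`` the per-adjacency
    single-haplotype switch probability.
    """

    populations: list[str]
    pi: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        S = len(unordered_pairs(len(self.populations)))
        if self.pi.shape != (S,):
            raise ValueError(f"pi must have {S} entries for K={len(self.populations)}")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi < 0).any():
            raise ValueError("pi must be a probability distribution")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly inside (0, 1)")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return unordered_pairs(len(self.populations))

    def population_marginal(self) -> np.ndarray:
        """π_p = Σ_q π_{p,q}·(share of the pair), a diagnostic proportion."""
        K = len(self.populations)
        out = np.zeros(K)
        for s, (p, q) in enumerate(self.pairs):
            out[p] += 0.5 * self.pi[s]
            out[q] += 0.5 * self.pi[s]
        return out


def accessible_matrix(n_populations: int) -> np.ndarray:
    """Boolean (S, S): pairs reachable by changing exactly one slot.

    Two unordered pairs are adjacent iff their multiset intersection has
    size exactly one, which rules out both the self pair and double
    switches such as (p,p) → (q,q).
    """
    pairs = unordered_pairs(n_populations)
    S = len(pairs)
    acc = np.zeros((S, S), dtype=bool)
    for i, (p, q) in enumerate(pairs):
        for j, (r, s) in enumerate(pairs):
            if i == j:
                continue
            a, b = sorted((p, q)), sorted((r, s))
            inter = 0
            bb = list(b)
            for x in a:
                if x in bb:
                    bb.remove(x)
                    inter += 1
            if inter == 1:
                acc[i, j] = True
    return acc


def transition_matrix(params: AncestryHMMParams) -> np.ndarray:
    """Row-stochastic (S, S) transition kernel between adjacent groups."""
    acc = accessible_matrix(len(params.populations))
    if acc.shape == (1, 1):  # single population: no switch is possible
        return np.ones((1, 1))
    Z = acc @ params.pi
    if np.any(Z <= 0):
        raise ValueError("pi has no mass on an accessible set; floor pi first")
    T = np.where(acc, params.tau * params.pi[None, :] / Z[:, None], 0.0)
    np.fill_diagonal(T, 1.0 - params.tau)
    return T


def transition_probability(params: AncestryHMMParams, from_pair: tuple[int, int],
                           to_pair: tuple[int, int]) -> float:
    """Single transition entry for unordered pairs given as (p, q) tuples."""
    pairs = params.pairs
    i = pairs.index(tuple(sorted(from_pair)))
    j = pairs.index(tuple(sorted(to_pair)))
    return float(transition_matrix(params)[i, j])


@dataclass
class PosteriorDecoding:
    """Smoothed per-group posteriors plus EM sufficient statistics."""

    gammas: list[np.ndarray]          # per chromosome, (G_c, S)
    log_likelihood: float
    xi_sum: np.ndarray                # (S, S) expected transition counts
    start_expect: np.ndarray          # (S,) summed chromosome-start posteriors
    n_adjacent: int                   # within-chromosome adjacent group pairs

    @property
    def expected_switches(self) -> float:
        return float(self.xi_sum.sum() - np.trace(self.xi_sum))

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.gammas, axis=0)


def _chrom_emissions(emissions) -> list[np.ndarray]:
    if isinstance(emissions, GenomeEmissions):
        return emissions.by_chrom
    return [np.atleast_2d(e) for e in emissions]


def forward_backward_genome(emissions, params: AncestryHMMParams) -> PosteriorDecoding:
    """Scaled forward-backward over all chromosomes (independent given params)."""
    T = transition_matrix(params)
    S = len(params.pi)
    gammas, loglik = [], 0.0
    xi_sum = np.zeros((S, S))
    start_expect = np.zeros(S)
    n_adjacent = 0
    for log_e in _chrom_emissions(emissions):
        e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
        G = len(e)
        f = np.empty((G, S))
        scales = np.empty(G)
        v = params.pi * e[0]
        scales[0] = v.sum()
        f[0] = v / scales[0]
        for t in range(1, G):
            v = (f[t - 1] @ T) * e[t]
            scales[t] = v.sum()
            f[t] = v / scales[t]
        loglik += float(np.log(scales).sum() + (log_e.max(axis=1)).sum())

        b = np.empty((G, S))
        b[G - 1] = 1.0
        for t in range(G - 2, -1, -1):
            b[t] = T @ (e[t + 1] * b[t + 1]) / scales[t + 1]
            xi = (f[t][:, None] * T * (e[t + 1] * b[t + 1])[None, :]) / scales[t + 1]
            xi_sum += xi
        g = f * b
        g /= g.sum(axis=1, keepdims=True)
        gammas.append(g)
        start_expect += g[0]
        n_adjacent += G - 1
    return PosteriorDecoding(gammas=gammas, log_likelihood=loglik, xi_sum=xi_sum,
                             start_expect=start_expect, n_adjacent=n_adjacent)


def _maximize_pi(
    c: np.ndarray,
    m: np.ndarray,
    acc: np.ndarray,
    pi_start: np.ndarray,
    floor: float,
    inner_iterations: int = 30,
) -> np.ndarray:
    """Maximize Q(π) = Σ_s c_s log π_s − Σ_s m_s log Z_s(π) on the floored simplex.

    ``c`` are chromosome-start plus switch-target expectations, ``m``
    expected switch counts out of each state, and Z_s sums π over the
    accessible set of s.  Each MM step replaces log Z_s by its tangent
    bound at the current π, giving the separable surrogate
    Σ c_s log π_s − Σ d_s π_s with d = accᵀ (m / Z); its constrained
    maximizer is π_s = max(floor, c_s/(λ + d_s)) with λ solving Σπ = 1.
    Starting each bound at the current iterate makes every step, and
    hence the whole EM iteration, non-decreasing in likelihood.
    """
    if len(pi_start) == 1:
        return np.ones(1)
    pi = pi_start.copy()
    for _ in range(inner_iterations):
        Z = acc @ pi
        d = acc.T @ (m / Z)

        def total(lam: float) -> float:
            return float(np.maximum(floor, c / (lam + d)).sum())

        # bracket λ: total() is decreasing in λ
        lo_bound = -float(d[c > 0].min()) if np.any(c > 0) else 0.0
        hi = max(float(c.sum()) - float(d.min()), lo_bound + 1.0)
        while total(hi) > 1.0:
            hi = lo_bound + 2.0 * (hi - lo_bound)
        lo = hi
        step = max(hi - lo_bound, 1.0)
        while total(lo) < 1.0:
            step /= 2.0
            lo = lo_bound + step
            if step < 1e-300:
                break
        for _ in range(200):  # bisection to float precision
            mid = 0.5 * (lo + hi)
            if mid == lo or mid == hi:
                break
            if total(mid) > 1.0:
                lo = mid
            else:
                hi = mid
        new_pi = np.maximum(floor, c / (0.5 * (lo + hi) + d))
        new_pi /= new_pi.sum()
        if np.abs(new_pi - pi).max() < 1e-14:
            pi = new_pi
            break
        pi = new_pi
    return pi


def baum_welch_fit(
    emissions,
    populations: list[str] | None = None,
    init_tau: float = 0.01,
    iterations: int = 10,
    pi_floor: float = 1e-6,
    return_history: bool = False,
):
    """Fit (π, τ) with a fixed number of Baum-Welch updates.

    π starts uniform over pairs and τ at ``init_tau``.  Each iteration
    runs forward-backward, then applies exact M-steps for the kernel's
    parameterisation: τ becomes the expected fraction of adjacencies
    with a single-slot switch (clamped to [1e−6, 0.5]), and π maximizes
    the expected complete-data log-likelihood — in which it appears both
    as the chromosome-start distribution and as the switch-target weight
    π_{p',q'}/Z_{p,q} — by an MM inner loop on the π-floored simplex
    (:func:`_maximize_pi`).  Both steps are constrained maximizations
    from the current parameters, so the data log-likelihood is
    non-decreasing across iterations.  Exactly ``iterations`` updates
    run — no convergence stopping, which guards against overfitting τ.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if populations is None:
        if not isinstance(emissions, GenomeEmissions):
            raise ValueError("populations required when emissions is a bare list")
        populations = emissions.populations
    K = len(populations)
    S = len(unordered_pairs(K))
    acc = accessible_matrix(K)
    params = AncestryHMMParams(populations, np.full(S, 1.0 / S), init_tau)
    history = []
    for _ in range(iterations):
        dec = forward_backward_genome(emissions, params)
        history.append(dec.log_likelihood)
        off = dec.xi_sum.copy()
        np.fill_diagonal(off, 0.0)
        if dec.n_adjacent > 0:
            tau = float(np.clip(off.sum() / dec.n_adjacent, TAU_MIN, TAU_MAX))
        else:
            tau = params.tau
        c = dec.start_expect + off.sum(axis=0)   # start + switch-target counts
        m = off.sum(axis=1)                      # switches out of each state
        pi = _maximize_pi(c, m, acc, params.pi, pi_floor)
        params = AncestryHMMParams(populations, pi, tau)
    if return_history:
        # per-iteration data log-likelihoods (E-step values, pre-update)
        history.append(forward_backward_genome(emissions, params).log_likelihood)
        return params, np.asarray(history)
    return params


def viterbi_path(emissions, params: AncestryHMMParams) -> np.ndarray:
    """Maximum-probability state path, concatenated over chromosomes.

    Ties resolve toward the lexicographically smallest pair (the state
    order of :func:`haplarch.emission.unordered_pairs` makes the first
    argmax index the smallest pair).
    """
    with np.errstate(divide="ignore"):
        logT = np.log(transition_matrix(params))
        log_pi = np.log(params.pi)
    paths = []
    for log_e in _chrom_emissions(emissions):
        G, S = log_e.shape
        delta = log_pi + log_e[0]
        back = np.zeros((G, S), dtype=np.int32)
        for t in range(1, G):
            cand = delta[:, None] + logT
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(S)] + log_e[t]
        path = np.empty(G, dtype=np.int32)
        path[G - 1] = int(np.argmax(delta))
        for t in range(G - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        paths.append(path)
    return np.concatenate(paths)


def sample_paths(
    emissions,
    params: AncestryHMMParams,
    n_samples: int = 100,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw state paths from the posterior (forward filter, backward sample).

    Returns an (n_samples, n_groups) int array, groups concatenated over
    chromosomes; fully reproducible given ``rng``.
    """
    rng = np.random.default_rng(rng)
    T = transition_matrix(params)
    S = len(params.pi)
    per_chrom = []
    for log_e in _chrom_emissions(emissions):
        e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
        G = len(e)
        f = np.empty((G, S))
        v = params.pi * e[0]
        f[0] = v / v.sum()
        for t in range(1, G):
            v = (f[t - 1] @ T) * e[t]
            f[t] = v / v.sum()
        samples = np.empty((n_samples, G), dtype=np.int32)
        samples[:, G - 1] = rng.choice(S, size=n_samples, p=f[G - 1])
        for t in range(G - 2, -1, -1):
            w = f[t][None, :] * T[:, samples[:, t + 1]].T
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(n_samples)
            samples[:, t] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        per_chrom.append(samples)
    return np.concatenate(per_chrom, axis=1)
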