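"""Localized haplotype-cluster models (leveled DAG) and diploid inference.

A cluster model for a window of D SNPs is a leveled directed acyclic
graph in the style of BEAGLE's localized haplotype clustering: level ``d``
(0..D) holds the states a haplotype can occupy just before emitting the
allele of the window's d-th SNP (level D is terminal), and each node
carries allele-labeled probabilistic edges to the next level.  A haplotype
is a root-to-terminal path; the graph is read as a Markov chain over
nodes, which makes unphased-genotype inference a forward-backward pass
over *ordered node pairs* (one node per haplotype).

Construction follows split-then-merge: each level's nodes are split by
the observed allele at the next SNP and re-merged whenever two nodes'
empirical continuation distributions (over the next few SNPs) are close
in total-variation distance.  Unobserved alleles receive a small floored
edge probability so that haplotypes absent from training retain positive
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING

PRIOR_TINY = 1e-300


@dataclass
class ClusterModel:
    """Leveled haplotype-cluster DAG for one window.

    Attributes
    ----------
    child : list of (n_d, 2) int arrays
        For levels 0..D-1: node index at the next level reached by
        emitting allele 0 or 1.
    prob : list of (n_d, 2) float arrays
        Edge probabilities, rows sum to 1 (after flooring).
    node_counts : list of (n_d,) int arrays
        Training haplotype count clustered by each node, levels 0..D.
    n_haplotypes : int
        Training haplotype count N (flooring uses 0.5/N).
    """

    child: list[np.ndarray]
    prob: list[np.ndarray]
    node_counts: list[np.ndarray]
    n_haplotypes: int

    @property
    def n_snps(self) -> int:
        return len(self.child)

    @property
    def n_nodes(self) -> list[int]:
        return [len(c) for c in self.node_counts]

    def node_priors(self) -> list[np.ndarray]:
        """P_d(u): prior node occupancy by forward propagation from the root."""
        priors = [np.ones(1)]
        for d in range(self.n_snps):
            nxt = np.zeros(len(self.node_counts[d + 1]))
            for a in (0, 1):
                np.add.at(nxt, self.child[d][:, a], priors[d] * self.prob[d][:, a])
            priors.append(nxt)
        return priors

    def transfer_matrices(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per level, dense (n_d, n_{d+1}) single-allele transition matrices."""
        cached = getattr(self, "_transfer_cache", None)
        if cached is not None:
            return cached
        out = []
        for d in range(self.n_snps):
            n, m = len(self.node_counts[d]), len(self.node_counts[d + 1])
            mats = []
            for a in (0, 1):
                T = np.zeros((n, m))
                T[np.arange(n), self.child[d][:, a]] = self.prob[d][:, a]
                mats.append(T)
            out.append((mats[0], mats[1]))
        self._transfer_cache = out
        return out

    def haplotype_path_probability(self, alleles: np.ndarray) -> float:
        """Probability of the (unique) path spelling a given haplotype."""
        alleles = np.asarray(alleles)
        u, p = 0, 1.0
        for d, a in enumerate(alleles):
            p *= self.prob[d][u, a]
            u = self.child[d][u, a]
        return float(p)

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for d in range(self.n_snps):
            h.update(self.child[d].astype(np.int64).tobytes())
            h.update(self.prob[d].tobytes())
        return h.hexdigest()


def _suffix_distribution(hap_window: np.ndarray, members: np.ndarray, d: int, horizon: int) -> np.ndarray:
    """Empirical distribution of the next ``horizon`` alleles for a node's members."""
    if horizon == 0:
        return np.ones(1)
    suffix = hap_window[members, d : d + horizon]
    codes = suffix @ (1 << np.arange(horizon - 1, -1, -1))
    dist = np.bincount(codes, minlength=1 << horizon).astype(float)
    return dist / dist.sum()


def build_cluster_model(
    hap_window: np.ndarray,
    merge_horizon: int = 3,
    merge_tolerance: float = 0.15,
    edge_floor: float | None = None,
) -> ClusterModel:
    """Build the cluster DAG for one window from phased 0/1 haplotypes.

    Parameters
    ----------
    hap_window : (N, D) array of 0/1
        Background haplotypes restricted to the window's SNPs.
    merge_horizon : int
        Number of downstream SNPs over which continuation distributions
        are compared when deciding to merge two nodes.
    merge_tolerance : float
        Maximum total-variation distance between continuation
        distributions for a merge; 0 merges only identical continuations.
    edge_floor : float, optional
        Probability floor placed on each node's unobserved allele before
        renormalisation; defaults to ``0.5 / N``.
    """
    hap_window = np.asarray(hap_window)
    n_hap, n_snps = hap_window.shape
    if n_hap < 2 or n_snps < 2:
        raise ValueError("need >= 2 haplotypes and >= 2 SNPs per window")
    if not np.isin(hap_window, (0, 1)).all():
        raise ValueError("phased haplotypes cannot contain missing alleles")
    if edge_floor is None:
        edge_floor = 0.5 / n_hap

    # members[u] = training haplotype rows clustered by node u at this level
    members: list[np.ndarray] = [np.arange(n_hap)]
    child_l: list[np.ndarray] = []
    prob_l: list[np.ndarray] = []
    counts_l: list[np.ndarray] = [np.array([n_hap])]

    for d in range(n_snps):
        # split each node by the allele at SNP d
        prov_members: list[np.ndarray] = []
        edges: list[tuple[int, int, int, int]] = []  # (parent, allele, prov_child, count)
        for u, mem in enumerate(members):
            al = hap_window[mem, d]
            for a in (0, 1):
                sub = mem[al == a]
                if sub.size:
                    edges.append((u, a, len(prov_members), sub.size))
                    prov_members.append(sub)

        # merge provisional children with close continuation distributions
        horizon = min(merge_horizon, n_snps - (d + 1))
        clusters: list[list[int]] = [[i] for i in range(len(prov_members))]
        mem_of = {i: prov_members[i] for i in range(len(prov_members))}

        def cluster_members(c: list[int]) -> np.ndarray:
            return np.concatenate([mem_of[i] for i in c])

        merged = True
        while merged and len(clusters) > 1:
            merged = False
            dists = [
                _suffix_distribution(hap_window, cluster_members(c), d + 1, horizon)
                for c in clusters
            ]
            sizes = [sum(mem_of[i].size for i in c) for c in clusters]
            order = sorted(range(len(clusters)), key=lambda i: (-sizes[i], min(clusters[i])))
            for ii in range(len(order)):
                for jj in range(ii + 1, len(order)):
                    i, j = order[ii], order[jj]
                    tv = 0.5 * np.abs(dists[i] - dists[j]).sum()
                    if tv <= merge_tolerance + 1e-12:
                        clusters[i] = clusters[i] + clusters[j]
                        del clusters[j]
                        merged = True
                        break
                if merged:
                    break

        # deterministic node order: by smallest provisional id in the cluster
        clusters.sort(key=min)
        final_of_prov = {}
        for k, c in enumerate(clusters):
            for i in c:
                final_of_prov[i] = k

        child = np.zeros((len(members), 2), dtype=np.int32)
        prob = np.zeros((len(members), 2))
        for parent, allele, prov, count in edges:
            child[parent, allele] = final_of_prov[prov]
            prob[parent, allele] = count / members[parent].size
        child_l.append(child)
        prob_l.append(prob)

        members = [cluster_members(c) for c in clusters]
        counts_l.append(np.array([m.size for m in members]))

    _apply_edge_floor(child_l, prob_l, counts_l, edge_floor)
    return ClusterModel(child=child_l, prob=prob_l, node_counts=counts_l, n_haplotypes=n_hap)


def _apply_edge_floor(child_l, prob_l, counts_l, floor: float) -> None:
    """Give every node's unobserved allele a floored edge, then renormalise.

    The floored edge needs a destination: it points at the most-populated
    node of the next level that any node reaches with that allele, or, if
    the training column is monomorphic, back to the node's own child so
    the path rejoins the graph.
    """
    if floor <= 0:
        return
    for d, (child, prob) in enumerate(zip(child_l, prob_l)):
        counts_next = counts_l[d + 1]
        fallback = {}
        for a in (0, 1):
            seen = child[prob[:, a] > 0, a]
            if seen.size:
                fallback[a] = int(seen[np.argmax(counts_next[seen])])
        for u in range(len(child)):
            for a in (0, 1):
                if prob[u, a] == 0:
                    child[u, a] = fallback.get(a, child[u, 1 - a])
                    prob[u, a] = floor
            prob[u] /= prob[u].sum()


@dataclass
class DiploidPosterior:
    """Smoothed ordered-node-pair posteriors for one genotype in one window.

    ``tables[d][u, v]`` is P_d(u, v | x_w), the posterior that the two
    haplotypes occupy nodes u and v just before SNP d, given the whole
    window; ``log_likelihood`` is log P(x_w).
    """

    tables: list[np.ndarray]
    log_likelihood: float

    @property
    def likelihood(self) -> float:
        return float(np.exp(self.log_likelihood))


_ALLELE_PAIRS = {0: ((0, 0),), 1: ((0, 1), (1, 0)), 2: ((1, 1),), MISSING: ((0, 0), (0, 1), (1, 0), (1, 1))}


def _combine(V: dict[tuple[int, int], np.ndarray], dosages_d: np.ndarray) -> np.ndarray:
    """Select, per batch row, the dosage-allowed sum of the four allele-pair terms."""
    out = np.zeros_like(V[(0, 0)])
    for g, pairs in _ALLELE_PAIRS.items():
        rows = dosages_d == g
        if rows.any():
            acc = sum(V[ab][rows] for ab in pairs)
            out[rows] = acc
    return out


def diploid_forward(model: ClusterModel, dosages: np.ndarray):
    """Scaled pair-state forward pass, batched over genotypes.

    Parameters
    ----------
    dosages : (B, D) int array with entries 0/1/2/−1.

    Returns
    -------
    F : list of (B, n_d, n_d) scaled forward tables, levels 0..D
    log_lik : (B,) log P(x_w)
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    B, D = dosages.shape
    if D != model.n_snps:
        raise ValueError("genotype length does not match window size")
    transfer = model.transfer_matrices()
    F = [np.ones((B, 1, 1))]
    log_lik = np.zeros(B)
    for d in range(D):
        T0, T1 = transfer[d]
        U0 = T0.T @ F[d]
        U1 = T1.T @ F[d]
        V = {
            (0, 0): U0 @ T0, (0, 1): U0 @ T1,
            (1, 0): U1 @ T0, (1, 1): U1 @ T1,
        }
        nxt = _combine(V, dosages[:, d])
        scale = nxt.sum(axis=(1, 2))
        if np.any(scale <= 0):
            raise FloatingPointError("zero diploid likelihood; is the edge floor disabled?")
        F.append(nxt / scale[:, None, None])
        log_lik += np.log(scale)
    return F, log_lik


def _backward_sweep(model: ClusterModel, dosages: np.ndarray, F: list[np.ndarray], reduce_fn) -> None:
    """Backward pass calling ``reduce_fn(d, posterior)`` for levels D-1..0.

    ``posterior`` is the (B, n_d, n_d) normalised ordered-pair posterior.
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    B, D = dosages.shape
    transfer = model.transfer_matrices()
    Bk = np.ones((B,) + F[D].shape[1:])
    for d in range(D - 1, -1, -1):
        T0, T1 = transfer[d]
        X0 = T0 @ Bk
        X1 = T1 @ Bk
        V = {
            (0, 0): X0 @ T0.T, (0, 1): X0 @ T1.T,
            (1, 0): X1 @ T0.T, (1, 1): X1 @ T1.T,
        }
        Bk = _combine(V, dosages[:, d])
        # keep magnitudes bounded; posteriors renormalise anyway
        Bk = Bk / Bk.sum(axis=(1, 2), keepdims=True)
        post = F[d] * Bk
        post /= post.sum(axis=(1, 2), keepdims=True)
        reduce_fn(d, post)


def diploid_forward_backward(model: ClusterModel, genotype_window: np.ndarray) -> DiploidPosterior:
    """Full smoothed pair posteriors P_d(u,v|x_w) for one genotype.

    The hidden state at level d is the *ordered* pair of nodes occupied by
    the two haplotypes; allele pairs are constrained to sum to the dosage
    at each SNP (all four pairs are allowed where the dosage is missing).
    """
    genotype_window = np.asarray(genotype_window)
    F, log_lik = diploid_forward(model, genotype_window[None, :])
    tables: list[np.ndarray | None] = [None] * model.n_snps

    def keep(d, post):
        tables[d] = post[0]

    _backward_sweep(model, genotype_window[None, :], F, keep)
    return DiploidPosterior(tables=tables, log_likelihood=float(log_lik[0]))


def node_marginal(posterior: DiploidPosterior) -> list[np.ndarray]:
    """P_d(u|x_w): marginalise the ordered-pair posterior over the partner node."""
    return [t.sum(axis=1) for t in posterior.tables]


def diploid_node_marginals(model: ClusterModel, dosages: np.ndarray):
    """Batched P_d(u|x) node marginals (used by panel annotation).

    Returns ``(log_lik (B,), marginals)`` where ``marginals[d]`` is
    (B, n_d).
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    F, log_lik = diploid_forward(model, dosages)
    marg: list[np.ndarray | None] = [None] * model.n_snps

    def keep(d, post):
        marg[d] = post.sum(axis=2)

    _backward_sweep(model, dosages, F, keep)
    return log_lik, marg


def pair_prior(model: ClusterModel) -> list[np.ndarray]:
    """P_d(u,v) = P_d(u)·P_d(v): independent-haplotype pair prior per level."""
    priors = model.node_priors()
    return [np.outer(p, p) for p in priors]
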