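"""Independent brute-force oracles used to validate dynamic-programming code.

Everything here enumerates explicitly (path pairs through a cluster DAG,
state paths through the ancestry HMM) and is intentionally unrelated to
the package's forward-backward implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

from haplarch.ancestry_hmm import AncestryHMMParams, transition_matrix


def enumerate_haplotype_paths(model):
    """All root-to-terminal paths: (allele tuple, node-per-level tuple, prob)."""
    D = model.n_snps
    out = []

    def rec(d, u, alleles, nodes, p):
        nodes = nodes + [u]
        if d == D:
            out.append((tuple(alleles), tuple(nodes), p))
            return
        for a in (0, 1):
            pr = model.prob[d][u, a]
            if pr > 0:
                rec(d + 1, model.child[d][u, a], alleles + [a], nodes, p * pr)

    rec(0, 0, [], [], 1.0)
    return out


def brute_force_diploid(model, genotype):
    """(P(x_w), per-level dict {(u,v): P_d(x_w,u,v)}) by path-pair enumeration."""
    paths = enumerate_haplotype_paths(model)
    D = model.n_snps
    total = 0.0
    joint = [dict() for _ in range(D)]
    for a1, n1, p1 in paths:
        for a2, n2, p2 in paths:
            if any(g >= 0 and a1[d] + a2[d] != g for d, g in enumerate(genotype)):
                continue
            w = p1 * p2
            total += w
            for d in range(D):
                key = (n1[d], n2[d])
                joint[d][key] = joint[d].get(key, 0.0) + w
    return total, joint


def enumerate_hmm_paths(log_emissions_per_chrom, params: AncestryHMMParams):
    """All state paths with exact posterior probabilities, per chromosome.

    Returns (total log-likelihood, list per chromosome of
    {path tuple: posterior probability}).
    """
    T = transition_matrix(params)
    total_ll = 0.0
    per_chrom = []
    for log_e in log_emissions_per_chrom:
        e = np.exp(log_e)
        G, S = e.shape
        probs = {}
        for path in itertools.product(range(S), repeat=G):
            p = params.pi[path[0]] * e[0, path[0]]
            for t in range(1, G):
                p *= T[path[t - 1], path[t]] * e[t, path[t]]
            probs[path] = p
        z = sum(probs.values())
        total_ll += np.log(z)
        per_chrom.append({k: v / z for k, v in probs.items()})
    return total_ll, per_chrom


def marginals_from_paths(path_posterior, G, S):
    """Per-group state marginals from an enumerated path posterior."""
    gamma = np.zeros((G, S))
    for path, p in path_posterior.items():
        for t, s in enumerate(path):
            gamma[t, s] += p
    return gamma
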