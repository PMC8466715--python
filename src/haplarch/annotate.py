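"""Population annotation of cluster-model nodes from a labeled reference panel.

Each node ``u`` at level ``d`` of a window's cluster model is annotated
with P_d(u|p): the probability that a haplotype drawn from population
``p`` occupies that node, estimated as the average of the diploid node
marginals P_d(u|x) over the panel genotypes of ``p``.  Panel genotypes
are pushed through the model several times with a random fraction of
sites masked to missing ("downsampling"), so the annotation also credits
nodes representing haplotypes *similar* to — not identical with — the
panel's, which matters when a population has few representatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING
from .hapmodel import ClusterModel, diploid_node_marginals

_BATCH_ROWS = 256


@dataclass
class Annotation:
    """Per-window node-population occupancy table.

    ``tables[d]`` is an (n_d, K) matrix whose column ``p`` is P_d(u|p)
    and sums to 1 over nodes; ``counts[p]`` is the effective number of
    (downsampled) genotype examples averaged for population ``p``.
    """

    populations: list[str]
    tables: list[np.ndarray]
    counts: dict[str, float]
    model_digest: str

    @property
    def n_levels(self) -> int:
        return len(self.tables)

    def matrix(self, populations: list[str] | None = None) -> list[np.ndarray]:
        """Tables with columns reordered to ``populations`` (default: own order)."""
        if populations is None or populations == self.populations:
            return self.tables
        idx = [self.populations.index(p) for p in populations]
        return [t[:, idx] for t in self.tables]


def annotate_window(
    model: ClusterModel,
    panel_dosages: np.ndarray,
    labels: list[str],
    downsample_reps: int = 100,
    missing_rate: float = 0.2,
    rng: np.random.Generator | int | None = None,
    populations: list[str] | None = None,
) -> Annotation:
    """Annotate one window's model from labeled unphased panel genotypes.

    Every panel genotype is replicated ``downsample_reps`` times, each
    replicate masking every SNP to missing independently with probability
    ``missing_rate``; missing sites are marginalised inside the diploid
    forward-backward.  P_d(u|p) is the average node marginal over all
    replicates of all individuals of ``p`` (n_p counts replicates).
    """
    rng = np.random.default_rng(rng)
    panel_dosages = np.asarray(panel_dosages, dtype=np.int8)
    if panel_dosages.shape[0] != len(labels):
        raise ValueError("one label per panel individual required")
    if downsample_reps < 1:
        raise ValueError("downsample_reps must be >= 1")
    pops = populations if populations is not None else sorted(set(labels))
    if not pops:
        raise ValueError("annotation needs a non-empty labeled panel")
    label_arr = np.asarray(labels) if labels else np.empty(0, dtype=str)
    empty = [p for p in pops if not (label_arr == p).any()]
    if empty:
        raise ValueError(f"populations with no panel members: {empty}")

    reps = np.repeat(panel_dosages, downsample_reps, axis=0)
    if missing_rate > 0:
        mask = rng.random(reps.shape) < missing_rate
        reps = np.where(mask, np.int8(MISSING), reps)
    rep_labels = np.repeat(label_arr, downsample_reps)

    D = model.n_snps
    n_nodes = model.n_nodes
    sums = [np.zeros((len(n_nodes) and n_nodes[d], len(pops))) for d in range(D)]
    n_per_pop = np.zeros(len(pops))
    pop_index = {p: k for k, p in enumerate(pops)}
    rep_cols = np.array([pop_index[p] for p in rep_labels])

    for lo in range(0, reps.shape[0], _BATCH_ROWS):
        chunk = reps[lo : lo + _BATCH_ROWS]
        cols = rep_cols[lo : lo + _BATCH_ROWS]
        _, marg = diploid_node_marginals(model, chunk)
        onehot = np.zeros((len(cols), len(pops)))
        onehot[np.arange(len(cols)), cols] = 1.0
        for d in range(D):
            sums[d] += marg[d].T @ onehot
        n_per_pop += onehot.sum(axis=0)

    tables = [s / n_per_pop[None, :] for s in sums]
    counts = {p: float(n_per_pop[pop_index[p]]) for p in pops}
    return Annotation(populations=pops, tables=tables, counts=counts,
                      model_digest=model.digest())


def merge_annotations(a: Annotation, b: Annotation) -> Annotation:
    """Count-weighted merge of two annotations of the same window model.

    Shared populations are averaged with weights n_a/(n_a+n_b) and
    n_b/(n_a+n_b); populations present in only one annotation are carried
    over unchanged, so a panel extension can introduce new populations
    without retraining.
    """
    if a.model_digest != b.model_digest:
        raise ValueError("annotations come from different window models")
    pops = sorted(set(a.populations) | set(b.populations))
    tables = []
    for d in range(a.n_levels):
        ta, tb = a.tables[d], b.tables[d]
        out = np.zeros((ta.shape[0], len(pops)))
        for k, p in enumerate(pops):
            na = a.counts.get(p, 0.0)
            nb = b.counts.get(p, 0.0)
            col = np.zeros(ta.shape[0])
            if na:
                col += na * ta[:, a.populations.index(p)]
            if nb:
                col += nb * tb[:, b.populations.index(p)]
            out[:, k] = col / (na + nb)
        tables.append(out)
    counts = {p: a.counts.get(p, 0.0) + b.counts.get(p, 0.0) for p in pops}
    return Annotation(populations=pops, tables=tables, counts=counts,
                      model_digest=a.model_digest)
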