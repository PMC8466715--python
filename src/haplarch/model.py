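"""Scikit-learn-style estimator wrapping the full train/annotate/infer pipeline.

``fit`` consumes the labeled reference panel (X = dosage matrix, y =
population labels) together with the unlabeled background haplotypes and
the SNP map; ``predict`` assigns each test individual a diploid ancestry
pair per window group, and ``predict_proportions`` returns global
ancestry fractions with credible intervals.  The fitted state is exactly
a :class:`~haplarch.io.ModelBundle`, so estimators round-trip through
``save``/``load`` and inference needs no access to the training data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import estimate as _estimate
from .annotate import annotate_window
from .containers import GenotypeSet, HaplotypeSet, SnpMap
from .hapmodel import build_cluster_model
from .io import ModelBundle, load_model_bundle, save_model_bundle
from .windows import build_windows, group_windows


class ArchesAncestryModel(BaseEstimator):
    """Diploid local/global ancestry inference from unphased genotypes.

    Parameters mirror the method's tunables: genome partition (window
    size/overlap, group size), cluster-model construction (merge horizon
    and tolerance, edge floor), panel annotation (downsampling replicates
    and missing rate), and the genome-wide pair HMM (EM iterations,
    initial switch rate τ, π floor, number of sampled paths).

    Examples
    --------
    >>> model = ArchesAncestryModel(downsample_reps=4, random_state=0)
    >>> model.fit(panel.dosages, panel.labels,
    ...           haplotypes=background, snp_map=snp_map)   # doctest: +SKIP
    >>> model.predict_proportions(test.dosages)             # doctest: +SKIP
    """

    def __init__(
        self,
        window_size: int = 80,
        window_overlap: int = 5,
        group_size: int = 4,
        target_groups: int | None = None,
        merge_horizon: int = 3,
        merge_tolerance: float = 0.15,
        edge_floor: float | None = None,
        downsample_reps: int = 100,
        missing_rate: float = 0.2,
        em_iterations: int = 10,
        init_tau: float = 0.01,
        pi_floor: float = 1e-6,
        n_path_samples: int = 100,
        ci_level: float = 0.95,
        random_state: int | None = None,
    ):
        self.window_size = window_size
        self.window_overlap = window_overlap
        self.group_size = group_size
        self.target_groups = target_groups
        self.merge_horizon = merge_horizon
        self.merge_tolerance = merge_tolerance
        self.edge_floor = edge_floor
        self.downsample_reps = downsample_reps
        self.missing_rate = missing_rate
        self.em_iterations = em_iterations
        self.init_tau = init_tau
        self.pi_floor = pi_floor
        self.n_path_samples = n_path_samples
        self.ci_level = ci_level
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None, *, haplotypes, snp_map: SnpMap | None = None):
        """Build, then annotate, one cluster model per window.

        Parameters
        ----------
        X : (n_panel, n_snps) dosage array or GenotypeSet
            Labeled reference panel (unphased).
        y : sequence of str, optional
            Panel population labels; may be omitted when X is a
            GenotypeSet that carries labels.
        haplotypes : (n_hap, n_snps) 0/1 array or HaplotypeSet
            Phased background cohort the cluster models are built from.
        snp_map : SnpMap
            SNP grid with genetic positions; may be omitted when the
            containers carry one.
        """
        if isinstance(X, GenotypeSet):
            snp_map = snp_map or X.snp_map
            y = y if y is not None else X.require_labels()
            X = X.dosages
        if isinstance(haplotypes, HaplotypeSet):
            snp_map = snp_map or haplotypes.snp_map
            haplotypes = haplotypes.alleles
        if snp_map is None:
            raise ValueError("a SnpMap is required (argument or container attribute)")
        X = np.asarray(X)
        haplotypes = np.asarray(haplotypes)
        if y is None or len(y) != X.shape[0]:
            raise ValueError("panel labels y must match the panel row count")
        if X.shape[1] != snp_map.n_snps or haplotypes.shape[1] != snp_map.n_snps:
            raise ValueError("panel/haplotype SNP count must match the SNP map")

        windows = build_windows(snp_map, self.window_size, self.window_overlap)
        groups = group_windows(windows, self.group_size, self.target_groups)
        seeds = np.random.SeedSequence(self.random_state).spawn(len(windows))
        models, annotations = [], []
        for w, seed in zip(windows, seeds):
            model = build_cluster_model(
                haplotypes[:, w.start:w.end],
                merge_horizon=self.merge_horizon,
                merge_tolerance=self.merge_tolerance,
                edge_floor=self.edge_floor,
            )
            annotations.append(annotate_window(
                model, X[:, w.start:w.end], list(y),
                downsample_reps=self.downsample_reps,
                missing_rate=self.missing_rate,
                rng=np.random.default_rng(seed),
            ))
            models.append(model)
        self.populations_ = annotations[0].populations
        self.windows_ = windows
        self.groups_ = groups
        self.bundle_ = ModelBundle(snp_map, windows, groups, models,
                                   annotations, self.populations_)
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> ModelBundle:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("estimator is not fitted; call fit() or load()")
        return self.bundle_

    def infer(self, X) -> list[_estimate.AncestryEstimate]:
        """Full per-individual estimates (path, proportions, intervals)."""
        bundle = self._check_fitted()
        if not isinstance(X, GenotypeSet):
            X = GenotypeSet(np.atleast_2d(np.asarray(X, dtype=np.int8)),
                            [f"sample{i}" for i in range(np.atleast_2d(X).shape[0])])
        return _estimate.infer_ancestry(
            bundle, X,
            em_iterations=self.em_iterations,
            init_tau=self.init_tau,
            pi_floor=self.pi_floor,
            n_samples=self.n_path_samples,
            ci_level=self.ci_level,
            seed=self.random_state,
        )

    def predict(self, X) -> np.ndarray:
        """Diploid assignment per window group.

        Returns an (n_individuals, n_groups, 2) integer array of
        population indices (into ``populations_``), unordered pairs
        stored sorted.
        """
        ests = self.infer(X)
        pairs = ests[0].pairs
        out = np.array([[pairs[s] for s in e.path] for e in ests], dtype=np.int32)
        return out

    def predict_proportions(self, X) -> pd.DataFrame:
        """Global ancestry point estimates and credible bounds per individual."""
        ests = self.infer(X)
        rows = []
        for e in ests:
            row: dict[str, float] = {}
            for p in e.populations:
                row[p] = e.proportions[p]
                row[f"{p}_ci_lower"], row[f"{p}_ci_upper"] = e.intervals[p]
            rows.append(row)
        return pd.DataFrame(rows, index=[e.individual for e in ests])

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_model_bundle(self._check_fitted(), path)

    @classmethod
    def load(cls, path, **params) -> "ArchesAncestryModel":
        est = cls(**params)
        est.bundle_ = load_model_bundle(path)
        est.populations_ = est.bundle_.populations
        est.windows_ = est.bundle_.windows
        est.groups_ = est.bundle_.groups
        return est
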