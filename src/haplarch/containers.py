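"""Core in-memory containers: SNP maps, haplotype and genotype matrices.

All genotype data is held as plain integer numpy matrices over biallelic
SNPs coded 0/1 (haplotypes) or 0/1/2 dosages (genotypes), with ``-1``
marking a missing genotype.  SNP coordinates are 0-based indices into a
:class:`SnpMap`; all ranges are half-open ``[start, end)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class SnpMap:
    """Ordered biallelic SNPs with physical (bp) and genetic (cM) positions.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``chrom`` (str), ``snp_id`` (str), ``bp`` (int), ``cm``
        (float, centimorgans).  Rows are ordered by chromosome then
        position; bp and cM must be non-decreasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "snp_id", "bp", "cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SnpMap table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(bp) < 0):
                raise ValueError(f"bp positions decrease on chromosome {chrom}")
            if np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"cM positions decrease on chromosome {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in file order."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global SNP index range of one chromosome."""
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return int(idx[0]), int(idx[-1]) + 1

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(dtype=float)

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy(dtype=np.int64)

    def digest(self) -> str:
        """SHA-256 over chromosome/id/bp content, for bundle compatibility checks."""
        h = hashlib.sha256()
        for col in ("chrom", "snp_id"):
            h.update("\x00".join(map(str, self.table[col])).encode())
        h.update(self.table["bp"].to_numpy(dtype=np.int64).tobytes())
        return h.hexdigest()


@dataclass
class HaplotypeSet:
    """Phased haplotypes: a (2·n_individuals, n_snps) 0/1 matrix.

    Rows come in pairs: rows ``2i`` and ``2i+1`` are the two haplotypes of
    individual ``i``.  ``populations`` optionally labels each *haplotype row*
    (used by the simulator for pedigree founders).
    """

    alleles: np.ndarray
    individuals: list[str]
    populations: list[str] | None = None
    snp_map: "SnpMap | None" = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.individuals):
            raise ValueError("expected two haplotype rows per individual")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if self.populations is not None and len(self.populations) != self.alleles.shape[0]:
            raise ValueError("one population label per haplotype row required")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def to_genotypes(self) -> "GenotypeSet":
        """Collapse phase: dosage matrix with one row per individual."""
        dosages = self.alleles[0::2].astype(np.int8) + self.alleles[1::2]
        return GenotypeSet(dosages=dosages, individuals=list(self.individuals),
                           snp_map=self.snp_map)


@dataclass
class GenotypeSet:
    """Unphased genotypes: an (n_individuals, n_snps) dosage matrix.

    Entries are allele dosages 0/1/2 or :data:`MISSING` (−1).  ``labels``
    optionally assigns a population to each individual (reference panels).
    """

    dosages: np.ndarray
    individuals: list[str]
    labels: list[str] | None = None
    snp_map: "SnpMap | None" = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if self.dosages.shape[0] != len(self.individuals):
            raise ValueError("one dosage row per individual required")
        if not np.isin(self.dosages, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")
        if self.labels is not None and len(self.labels) != len(self.individuals):
            raise ValueError("one label per individual required")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def require_labels(self) -> list[str]:
        if self.labels is None:
            raise ValueError("population labels are required but absent")
        unlabeled = [s for s, l in zip(self.individuals, self.labels) if l is None]
        if unlabeled:
            raise ValueError(f"samples without a population label: {unlabeled[:5]}")
        return self.labels
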