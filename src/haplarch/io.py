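"""Readers and writers: VCF genotypes, genetic maps, labels, model bundles.

The model bundle is the train/infer separation boundary: everything the
inference phase needs (SNP grid, window/group definitions, one cluster
model and one annotation per window, the population list) is serialised
into a single ``.npz`` archive with a JSON metadata header and 64-bit
binary arrays, and round-trips bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .annotate import Annotation
from .containers import MISSING, GenotypeSet, HaplotypeSet, SnpMap
from .hapmodel import ClusterModel
from .windows import Window, WindowGroup

logger = logging.getLogger(__name__)

BUNDLE_VERSION = "haplarch-bundle-1"


# ---------------------------------------------------------------------------
# VCF reading

def _parse_region(region: str) -> tuple[str, int, int]:
    if ":" in region:
        chrom, span = region.split(":", 1)
        lo, hi = span.split("-")
        return chrom, int(lo), int(hi)
    return region, 0, 2**63 - 1


def _snp_records(vcf_path: str, region_filter: str | None):
    """Yield biallelic SNP records, counting skipped multi-allelic/non-SNP ones."""
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    skipped = 0
    region = _parse_region(region_filter) if region_filter else None
    for v in vcf:
        if region is not None:
            chrom, lo, hi = region
            if v.CHROM != chrom or not (lo <= v.POS <= hi):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        yield samples, v
    if skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", skipped)


def read_phased_vcf(path: str | Path, region_filter: str | None = None
                    ) -> tuple[SnpMap, HaplotypeSet]:
    """Read phased biallelic genotypes: two 0/1 haplotype rows per sample.

    Every GT must be phased (``|``-separated); cM positions are set to 0
    pending :func:`read_genetic_map`.
    """
    rows, meta, samples = [], [], None
    for samples, v in _snp_records(path, region_filter):
        gts = v.genotypes
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], g[-1]
            if not phased or a0 < 0 or a1 < 0:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS} ({v.ID or '.'})"
                )
            col[2 * i], col[2 * i + 1] = a0, a1
        rows.append(col)
        meta.append((v.CHROM, v.ID or f"{v.CHROM}:{v.POS}", v.POS, 0.0))
    if not rows:
        raise ValueError("no biallelic SNP records matched" +
                         (f" region {region_filter}" if region_filter else ""))
    snp_map = SnpMap(pd.DataFrame(meta, columns=["chrom", "snp_id", "bp", "cm"]))
    haps = HaplotypeSet(np.stack(rows, axis=1), samples, snp_map=snp_map)
    return snp_map, haps


def read_genotype_vcf(path: str | Path, labels_path: str | Path | None = None,
                      region_filter: str | None = None) -> GenotypeSet:
    """Read unphased dosages (0/1/2, ``./.`` → missing), with optional labels.

    The label TSV maps ``sample_id<TAB>population``; labelled samples
    missing from the VCF draw a warning, VCF samples without a label are
    stored as ``None`` and rejected later wherever labels are required.
    """
    rows, meta, samples = [], [], None
    for samples, v in _snp_records(path, region_filter):
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a0, a1 = g[0], g[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        rows.append(col)
        meta.append((v.CHROM, v.ID or f"{v.CHROM}:{v.POS}", v.POS, 0.0))
    if not rows:
        raise ValueError("no biallelic SNP records matched" +
                         (f" region {region_filter}" if region_filter else ""))
    snp_map = SnpMap(pd.DataFrame(meta, columns=["chrom", "snp_id", "bp", "cm"]))
    labels = None
    if labels_path is not None:
        mapping = read_labels(labels_path)
        extra = set(mapping) - set(samples)
        if extra:
            logger.warning("labels file has %d samples absent from VCF: %s",
                           len(extra), sorted(extra)[:5])
        labels = [mapping.get(s) for s in samples]
    return GenotypeSet(np.stack(rows, axis=1), samples, labels=labels, snp_map=snp_map)


def read_labels(path: str | Path) -> dict[str, str]:
    """sample_id → population from a two-column TSV (no header)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed labels line: {line!r}")
        out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Genetic map

def read_genetic_map(path: str | Path, snp_map: SnpMap) -> SnpMap:
    """Fill cM positions by linear interpolation from a recombination map.

    Accepts the HapMap text layout: a header line then
    ``position  rate(cM/Mb)  cumulative_cM`` columns, either with a
    leading chromosome column or single-chromosome (3 columns, in which
    case the SNP map must also be single-chromosome).  SNPs beyond the
    map's ends take the boundary cM value.
    """
    raw = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    if raw.shape[1] >= 4:
        chroms = raw.iloc[:, 0].astype(str)
        bp = raw.iloc[:, 1].astype(np.int64)
        cm = raw.iloc[:, 3].astype(float)
    elif raw.shape[1] == 3:
        if len(snp_map.chroms) != 1:
            raise ValueError("3-column map given but SNP map has several chromosomes")
        chroms = pd.Series([snp_map.chroms[0]] * len(raw))
        bp = raw.iloc[:, 0].astype(np.int64)
        cm = raw.iloc[:, 2].astype(float)
    else:
        raise ValueError("genetic map needs 3 or 4 whitespace-separated columns")

    new_cm = np.empty(snp_map.n_snps)
    table = snp_map.table
    for chrom in snp_map.chroms:
        sel = (chroms == chrom).to_numpy()
        if not sel.any():
            raise ValueError(f"chromosome {chrom} missing from genetic map")
        mb = bp[sel].to_numpy()
        mc = cm[sel].to_numpy()
        order = np.argsort(mb, kind="stable")
        mb, mc = mb[order], mc[order]
        if np.any(np.diff(mc) < 0):
            raise ValueError(f"genetic map cM decreases on chromosome {chrom}")
        lo, hi = snp_map.chrom_range(chrom)
        new_cm[lo:hi] = np.interp(table["bp"].to_numpy()[lo:hi], mb, mc)
    out = table.copy()
    out["cm"] = new_cm
    return SnpMap(out)


# ---------------------------------------------------------------------------
# Writers (synthetic data export)

def write_vcf(path: str | Path, snp_map: SnpMap,
              data: HaplotypeSet | GenotypeSet) -> None:
    """Write a minimal uncompressed VCF 4.2 (REF=A, ALT=G placeholders)."""
    phased = isinstance(data, HaplotypeSet)
    ids = data.individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in snp_map.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        t = snp_map.table
        for j in range(snp_map.n_snps):
            if phased:
                gts = [f"{data.alleles[2*i, j]}|{data.alleles[2*i+1, j]}"
                       for i in range(len(ids))]
            else:
                conv = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [conv[int(d)] for d in data.dosages[:, j]]
            fh.write(f"{t['chrom'][j]}\t{t['bp'][j]}\t{t['snp_id'][j]}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_genetic_map(path: str | Path, snp_map: SnpMap) -> None:
    """Write the SNP map's own grid as a 4-column recombination map."""
    t = snp_map.table
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate\tcm\n")
        for chrom in snp_map.chroms:
            lo, hi = snp_map.chrom_range(chrom)
            for j in range(lo, hi):
                fh.write(f"{t['chrom'][j]}\t{t['bp'][j]}\t0.0\t{float(t['cm'][j])!r}\n")


def write_labels(path: str | Path, genotypes: GenotypeSet) -> None:
    labels = genotypes.require_labels()
    with open(path, "w") as fh:
        for s, p in zip(genotypes.individuals, labels):
            fh.write(f"{s}\t{p}\n")


def windows_to_bed(windows: list[Window], snp_map: SnpMap) -> pd.DataFrame:
    """Window spans as BED-like records (chrom, bp_start, bp_end, window_id)."""
    bp = snp_map.bp
    return pd.DataFrame(
        [(w.chrom, int(bp[w.start]) - 1, int(bp[w.end - 1]), f"window_{i}")
         for i, w in enumerate(windows)],
        columns=["chrom", "bp_start", "bp_end", "window_id"],
    )


# ---------------------------------------------------------------------------
# Model bundle

class ModelBundle:
    """Trained, annotated window models plus the genome partition.

    A complete bundle suffices for inference: the background haplotypes
    and reference panel are not needed once it is saved.
    """

    def __init__(self, snp_map: SnpMap, windows: list[Window],
                 groups: list[WindowGroup], models: list[ClusterModel],
                 annotations: list[Annotation], populations: list[str],
                 version: str = BUNDLE_VERSION):
        if len(models) != len(windows) or len(annotations) != len(windows):
            raise ValueError("bundle needs one model and one annotation per window")
        for ann in annotations:
            if ann.populations != populations:
                raise ValueError("population list must be identical across windows")
        self.snp_map = snp_map
        self.windows = windows
        self.groups = groups
        self.models = models
        self.annotations = annotations
        self.populations = populations
        self.version = version

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelBundle):
            return NotImplemented
        if (self.version != other.version
                or self.populations != other.populations
                or self.windows != other.windows
                or self.groups != other.groups
                or not self.snp_map.table.equals(other.snp_map.table)):
            return False
        for ma, mb in zip(self.models, other.models):
            if ma.n_haplotypes != mb.n_haplotypes:
                return False
            for d in range(ma.n_snps):
                if not (np.array_equal(ma.child[d], mb.child[d])
                        and np.array_equal(ma.prob[d], mb.prob[d])):
                    return False
            if not all(np.array_equal(a, b)
                       for a, b in zip(ma.node_counts, mb.node_counts)):
                return False
        for aa, ab in zip(self.annotations, other.annotations):
            if aa.counts != ab.counts:
                return False
            if not all(np.array_equal(x, y) for x, y in zip(aa.tables, ab.tables)):
                return False
        return True


def save_model_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialise a bundle to one ``.npz`` archive (JSON header + arrays)."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": bundle.version,
        "snp_digest": bundle.snp_map.digest(),
        "populations": bundle.populations,
        "chroms": list(bundle.snp_map.table["chrom"]),
        "snp_ids": list(bundle.snp_map.table["snp_id"]),
        "windows": [[w.chrom, w.start, w.end] for w in bundle.windows],
        "groups": [[g.chrom, list(g.window_indices), g.start, g.end]
                   for g in bundle.groups],
        "n_haplotypes": [m.n_haplotypes for m in bundle.models],
        "ann_counts": [a.counts for a in bundle.annotations],
    }
    arrays["smap_bp"] = bundle.snp_map.bp
    arrays["smap_cm"] = bundle.snp_map.cm
    arrays["win_cm"] = np.array([[w.cm_start, w.cm_end] for w in bundle.windows])
    arrays["grp_cm"] = np.array([g.cm_length for g in bundle.groups])
    for i, (m, a) in enumerate(zip(bundle.models, bundle.annotations)):
        arrays[f"w{i}_nnodes"] = np.array([len(c) for c in m.node_counts], dtype=np.int64)
        arrays[f"w{i}_child"] = np.concatenate(m.child, axis=0).astype(np.int32)
        arrays[f"w{i}_prob"] = np.concatenate(m.prob, axis=0)
        arrays[f"w{i}_counts"] = np.concatenate(m.node_counts).astype(np.int64)
        arrays[f"w{i}_ann"] = np.concatenate(a.tables, axis=0)
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model_bundle(path: str | Path, snp_map: SnpMap | None = None) -> ModelBundle:
    """Load a bundle; optionally verify it matches a supplied SNP map."""
    try:
        with np.load(path) as z:
            data = {k: z[k] for k in z.files}
    except Exception as exc:  # truncated/invalid archive
        raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
    if "meta" not in data:
        raise ValueError(f"{path} is not a model bundle (no metadata)")
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version {meta.get('version')!r} unsupported "
            f"(expected {BUNDLE_VERSION!r})"
        )
    table = pd.DataFrame({
        "chrom": meta["chroms"],
        "snp_id": meta["snp_ids"],
        "bp": data["smap_bp"],
        "cm": data["smap_cm"],
    })
    loaded_map = SnpMap(table)
    if loaded_map.digest() != meta["snp_digest"]:
        raise ValueError("bundle is internally inconsistent (SNP digest mismatch)")
    if snp_map is not None and snp_map.digest() != meta["snp_digest"]:
        raise ValueError("bundle was built on a different SNP map (digest mismatch)")

    windows = [
        Window(c, int(s), int(e), float(cm0), float(cm1))
        for (c, s, e), (cm0, cm1) in zip(meta["windows"], data["win_cm"])
    ]
    groups = [
        WindowGroup(c, tuple(int(x) for x in wi), int(s), int(e), float(cm))
        for (c, wi, s, e), cm in zip(meta["groups"], data["grp_cm"])
    ]
    populations = list(meta["populations"])
    models, annotations = [], []
    for i in range(len(windows)):
        nnodes = data[f"w{i}_nnodes"]
        off = np.concatenate([[0], np.cumsum(nnodes)])
        child_flat, prob_flat = data[f"w{i}_child"], data[f"w{i}_prob"]
        counts_flat, ann_flat = data[f"w{i}_counts"], data[f"w{i}_ann"]
        D = len(nnodes) - 1
        child = [child_flat[off[d]:off[d + 1]] for d in range(D)]
        prob = [prob_flat[off[d]:off[d + 1]] for d in range(D)]
        node_counts = [counts_flat[off[d]:off[d + 1]] for d in range(D + 1)]
        model = ClusterModel(child=child, prob=prob, node_counts=node_counts,
                             n_haplotypes=int(meta["n_haplotypes"][i]))
        tables = [ann_flat[off[d]:off[d + 1]] for d in range(D)]
        annotations.append(Annotation(
            populations=populations, tables=tables,
            counts={k: float(v) for k, v in meta["ann_counts"][i].items()},
            model_digest=model.digest(),
        ))
        models.append(model)
    return ModelBundle(loaded_map, windows, groups, models, annotations,
                       populations, version=meta["version"])
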