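"""Genome partition into overlapping fixed-size SNP windows and window groups.

Each chromosome is cut into windows of a fixed SNP count (default 80)
overlapping by a fixed number of SNPs (default 5); a haplotype-cluster
model is later built per window.  Consecutive windows are tied into groups
of 3-4 that share a single diploid ancestry state in the genome-wide HMM;
a group's genetic length (cM) is the weight it later carries in global
ancestry proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .containers import SnpMap

DEFAULT_WINDOW_SIZE = 80
DEFAULT_WINDOW_OVERLAP = 5
DEFAULT_GROUP_SIZE = 4


@dataclass(frozen=True)
class Window:
    """Half-open SNP index range [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    cm_start: float  # cM of first SNP
    cm_end: float    # cM of last SNP

    @property
    def n_snps(self) -> int:
        return self.end - self.start

    @property
    def cm_length(self) -> float:
        return self.cm_end - self.cm_start


@dataclass(frozen=True)
class WindowGroup:
    """Consecutive windows of one chromosome sharing one ancestry state."""

    chrom: str
    window_indices: tuple[int, ...]
    start: int  # first SNP of first member window
    end: int    # end of last member window
    cm_length: float  # cM span, first SNP of first window to last SNP of last

    @property
    def n_windows(self) -> int:
        return len(self.window_indices)

    @property
    def midpoint_snp(self) -> int:
        return (self.start + self.end) // 2


def build_windows(
    snp_map: SnpMap,
    size: int = DEFAULT_WINDOW_SIZE,
    overlap: int = DEFAULT_WINDOW_OVERLAP,
) -> list[Window]:
    """Tile every chromosome with windows of ``size`` SNPs overlapping by ``overlap``.

    Windows start at multiples of the stride ``size - overlap``.  If the
    last strided window does not reach the chromosome end, one extra
    window covering the final ``size`` SNPs is appended, so every SNP is
    inside at least one window and all windows have identical SNP counts
    (keeping cluster-model depth constant genome-wide).
    """
    if not 0 <= overlap < size:
        raise ValueError("require 0 <= overlap < size")
    stride = size - overlap
    cm = snp_map.cm
    out: list[Window] = []
    for chrom in snp_map.chroms:
        lo, hi = snp_map.chrom_range(chrom)
        n = hi - lo
        if n < size:
            raise ValueError(
                f"chromosome {chrom} has {n} SNPs < window size {size}; "
                "use a smaller window size"
            )
        starts = list(range(0, n - size + 1, stride))
        if starts[-1] + size < n:
            starts.append(n - size)
        for s in starts:
            a, b = lo + s, lo + s + size
            out.append(Window(chrom, a, b, float(cm[a]), float(cm[b - 1])))
    return out


def group_windows(
    windows: list[Window],
    group_size: int = DEFAULT_GROUP_SIZE,
    target_groups: int | None = None,
) -> list[WindowGroup]:
    """Chunk consecutive same-chromosome windows into groups.

    Groups never span chromosomes; the final group of a chromosome absorbs
    the remainder (it may be shorter).  When ``target_groups`` is given,
    each chromosome's group size is chosen as ``ceil(n_windows / share)``,
    with the chromosome's share of groups proportional to its window
    count, to approach the requested genome-wide total.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    if target_groups is not None:
        total = len(windows)
        sizes = {
            chrom: max(
                1,
                math.ceil(len(idx) / max(1, round(target_groups * len(idx) / total))),
            )
            for chrom, idx in by_chrom.items()
        }
    else:
        sizes = {chrom: group_size for chrom in by_chrom}

    groups: list[WindowGroup] = []
    for chrom, idxs in by_chrom.items():
        gs = sizes[chrom]
        for k in range(0, len(idxs), gs):
            member = tuple(idxs[k : k + gs])
            first, last = windows[member[0]], windows[member[-1]]
            groups.append(
                WindowGroup(chrom, member, first.start, last.end,
                            last.cm_end - first.cm_start)
            )
    return groups


def groups_by_chromosome(groups: list[WindowGroup]) -> list[list[int]]:
    """Indices of ``groups`` partitioned by chromosome, in order."""
    out: list[list[int]] = []
    seen: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        if g.chrom not in seen:
            seen[g.chrom] = []
            out.append(seen[g.chrom])
        seen[g.chrom].append(i)
    return out
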