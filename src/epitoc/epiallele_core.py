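"""Per-bin epiallele extraction and summarization.

The genome is partitioned into fixed, non-overlapping 100-bp bins aligned
to multiples of the bin size; a bin enters the analysis only if it contains
at least ``min_cpgs`` CpGs (default 2 — a single CpG carries no pattern
structure). Within a bin, each read contributes one binary methylation
pattern ("epiallele"); reads missing a call at any bin CpG are dropped and
counted rather than imputed, a deliberately conservative complete-read
policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CpGMap, MethylRead, Region

__all__ = [
    "BinReadMatrix",
    "EpialleleProfile",
    "partition_bins",
    "extract_bin_matrix",
    "classify_pattern",
    "profile_bin",
    "bulk_methylation",
    "group_reads_by_bin",
    "profile_library",
]


@dataclass
class BinReadMatrix:
    """n reads x k CpGs of complete binary calls for one bin."""

    region: Region
    cpg_positions: tuple[int, ...]
    rows: np.ndarray  # shape (n, k), dtype uint8, values in {0,1}
    dropped: int = 0  # reads excluded by the complete-read policy

    @property
    def n_reads(self) -> int:
        return int(self.rows.shape[0])

    @property
    def k(self) -> int:
        return len(self.cpg_positions)


@dataclass
class EpialleleProfile:
    """Pattern counts and proportions for one bin in one library."""

    region: Region
    k: int
    counts: dict[str, int]
    total: int
    dropped: int = 0

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {p: c / self.total for p, c in self.counts.items()}

    def clusters(self, min_cluster_fraction: float = 0.05) -> set[str]:
        """Patterns whose proportion meets the cluster-membership floor."""
        if self.total == 0:
            return set()
        return {
            p for p, c in self.counts.items() if c / self.total >= min_cluster_fraction
        }


def partition_bins(cpg_map: CpGMap, bin_size: int = 100, min_cpgs: int = 2) -> list[Region]:
    """Grid-aligned non-overlapping bins containing >= min_cpgs CpGs."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[Region] = []
    for chrom in cpg_map.chroms:
        pos = cpg_map.positions(chrom)
        if pos.size == 0:
            continue
        starts, counts = np.unique(pos // bin_size, return_counts=True)
        for s, c in zip(starts, counts):
            if c >= min_cpgs:
                bins.append(Region(chrom, int(s) * bin_size, (int(s) + 1) * bin_size))
    return bins


def group_reads_by_bin(reads: list[MethylRead]) -> dict[tuple[str, int], list[MethylRead]]:
    """Index reads by their (chrom, bin_start) assignment."""
    by_bin: dict[tuple[str, int], list[MethylRead]] = {}
    for r in reads:
        by_bin.setdefault((r.chrom, r.bin_start), []).append(r)
    return by_bin


def extract_bin_matrix(
    reads: list[MethylRead], bin_region: Region, cpg_map: CpGMap
) -> BinReadMatrix:
    """Build the bin's read x CpG matrix under the complete-read policy.

    Only reads with a non-missing call at every bin CpG are retained;
    incomplete reads are dropped and tallied. A read referencing a CpG
    outside the bin is an error (mis-assigned input).
    """
    pos = cpg_map.positions(bin_region.chrom)
    lo = int(np.searchsorted(pos, bin_region.start))
    hi = int(np.searchsorted(pos, bin_region.end))
    bin_positions = tuple(int(p) for p in pos[lo:hi])
    k = len(bin_positions)
    pos_index = {p: j for j, p in enumerate(bin_positions)}

    kept: list[np.ndarray] = []
    dropped = 0
    for read in reads:
        for p in read.cpg_positions:
            if p not in pos_index:
                raise ValueError(
                    f"read {read.read_id} references CpG {read.chrom}:{p} "
                    f"outside bin {bin_region.chrom}:{bin_region.start}-{bin_region.end}"
                )
        if not read.is_complete or len(read.cpg_positions) < k:
            dropped += 1
            continue
        row = np.zeros(k, dtype=np.uint8)
        for p, c in zip(read.cpg_positions, read.calls):
            row[pos_index[p]] = 1 if c == "1" else 0
        kept.append(row)
    rows = np.vstack(kept) if kept else np.empty((0, k), dtype=np.uint8)
    return BinReadMatrix(bin_region, bin_positions, rows, dropped)


def classify_pattern(pattern: str) -> float:
    """Methylation-percent class of a pattern: 100 * (#1s)/k to one decimal.

    For 3-CpG bins this yields exactly the classes 0.0, 33.3, 66.7, 100.0.
    """
    if not pattern:
        raise ValueError("empty pattern")
    bad = set(pattern) - {"0", "1"}
    if bad:
        raise ValueError(f"non-binary characters in pattern: {sorted(bad)}")
    return round(100.0 * pattern.count("1") / len(pattern), 1)


def profile_bin(matrix: BinReadMatrix, min_cluster_fraction: float = 0.05) -> EpialleleProfile:
    """Count identical read patterns; conserves reads (sum counts == rows)."""
    counts: dict[str, int] = {}
    for row in matrix.rows:
        pat = "".join("1" if v else "0" for v in row)
        counts[pat] = counts.get(pat, 0) + 1
    return EpialleleProfile(matrix.region, matrix.k, counts, matrix.n_reads, matrix.dropped)


def bulk_methylation(profile: EpialleleProfile) -> tuple[np.ndarray, float]:
    """Read-averaged per-CpG methylation fractions and their bin mean."""
    if profile.total == 0:
        raise ValueError("bulk methylation undefined for an empty profile")
    per_cpg = np.zeros(profile.k)
    for pat, c in profile.counts.items():
        per_cpg += c * np.array([ch == "1" for ch in pat], dtype=float)
    per_cpg /= profile.total
    return per_cpg, float(per_cpg.mean())


def profile_library(
    reads: list[MethylRead],
    cpg_map: CpGMap,
    bin_size: int = 100,
    min_cpgs: int = 2,
) -> dict[tuple[str, int], EpialleleProfile]:
    """Profile every qualifying bin of one library, keyed by (chrom, bin_start)."""
    bins = partition_bins(cpg_map, bin_size, min_cpgs)
    by_bin = group_reads_by_bin(reads)
    profiles: dict[tuple[str, int], EpialleleProfile] = {}
    for b in bins:
        matrix = extract_bin_matrix(by_bin.get((b.chrom, b.start), []), b, cpg_map)
        profiles[(b.chrom, b.start)] = profile_bin(matrix)
    return profiles
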