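"""Readers and writers for the epiread TSV dialect, BED regions, truth
tables, and run configuration.

Coordinate convention: everything is 0-based, half-open (BED-compatible).

The epiread dialect is a flat, alignment-free carrier for read-level
methylation calls: one tab-separated row per read per bin with columns

    chrom  bin_start  read_id  cpg_positions(comma-sep)  call_string

where the call string is over ``{0,1,?}`` (unmethylated / methylated /
missing) and is positionally aligned with ``cpg_positions``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CpGMap",
    "MethylRead",
    "Region",
    "RegionSet",
    "RunConfig",
    "FormatError",
    "read_epiread",
    "write_epiread",
    "read_bed",
    "write_bed",
    "read_truth",
    "write_truth",
    "load_config",
    "read_chrom_sizes",
]

VALID_CALLS = frozenset("01?")


class FormatError(ValueError):
    """A file violated the epiread/BED/config contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class CpGMap:
    """Universe of CpG cytosine coordinates per chromosome.

    Positions are stored as sorted, unique, non-negative int64 arrays; every
    coordinate referenced by any read must exist here.
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
            if arr.size and arr[0] < 0:
                raise ValueError(f"negative CpG coordinate on {chrom}")
            self._pos[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        arr = self.positions(chrom)
        i = int(np.searchsorted(arr, pos))
        return i < arr.size and arr[i] == pos

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of CpGs in [start, end) — order-independent by construction."""
        arr = self.positions(chrom)
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CpGMap):
            return NotImplemented
        return self._pos.keys() == other._pos.keys() and all(
            np.array_equal(self._pos[c], other._pos[c]) for c in self._pos
        )


@dataclass(frozen=True)
class MethylRead:
    """One sequencing read's binary methylation calls within one bin."""

    read_id: str
    chrom: str
    bin_start: int
    cpg_positions: tuple[int, ...]
    calls: str  # over {0,1,?}, aligned with cpg_positions

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != len(self.calls):
            raise ValueError(
                f"read {self.read_id}: {len(self.cpg_positions)} positions "
                f"vs {len(self.calls)} calls"
            )
        if any(b >= a for a, b in zip(self.cpg_positions[1:], self.cpg_positions)):
            raise ValueError(f"read {self.read_id}: positions not strictly increasing")
        bad = set(self.calls) - VALID_CALLS
        if bad:
            raise ValueError(f"read {self.read_id}: invalid calls {sorted(bad)}")

    @property
    def is_complete(self) -> bool:
        return "?" not in self.calls


@dataclass(frozen=True)
class Region:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    label: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class RegionSet:
    """Ordered collection of Regions with identity-set semantics.

    Membership and set operations use the (chrom, start, end) key; labels
    ride along from the left operand.
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self.regions: list[Region] = list(regions)
        self._keys = {r.key() for r in self.regions}

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region: Region) -> bool:
        return region.key() in self._keys

    def keys(self) -> set[tuple[str, int, int]]:
        return set(self._keys)

    def difference(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(r for r in self.regions if r.key() not in other._keys)

    def intersection(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(r for r in self.regions if r.key() in other._keys)

    def union(self, other: "RegionSet") -> "RegionSet":
        out = list(self.regions)
        seen = set(self._keys)
        for r in other.regions:
            if r.key() not in seen:
                out.append(r)
                seen.add(r.key())
        return RegionSet(out)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis parameters.

    Defaults mirror the published protocol: 100-bp bins, 100 resampling
    draws per bin, per-draw two-sided Fisher at alpha 0.05, a call requires
    significance in a consistent direction on more than 95% of draws, and a
    CpG needs >=5 reads in each library to enter the stand-in DMR test.
    """

    bin_size: int = 100
    n_draws: int = 100
    alpha: float = 0.05
    consistency: float = 0.95
    min_reads: int = 10
    min_cpgs: int = 2
    min_cluster_fraction: float = 0.05
    seed: int = 0
    # region_stats parameters
    n_controls: int = 100
    density_tol: float = 0.10
    max_attempts: int = 10_000
    pad_to: int = 2000
    min_cpg_reads: int = 5
    fdr_alpha: float = 0.05
    min_dmr_delta: float = 0.05
    min_dmr_cpgs: int = 3
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 <= self.consistency <= 1.0):
            raise ValueError("consistency must be in [0,1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not (0.0 <= self.min_cluster_fraction <= 1.0):
            raise ValueError("min_cluster_fraction must be in [0,1]")
        if not (0.0 < self.density_tol < 1.0):
            raise ValueError("density_tol must be in (0,1)")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must be in (0,1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML config, fill defaults, reject unknown keys."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse config: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Epiread TSV
# ---------------------------------------------------------------------------


def read_epiread(path: str | Path, cpg_map: CpGMap) -> list[MethylRead]:
    """Parse an epiread TSV; every referenced position must be in cpg_map.

    Malformed rows raise FormatError naming the offending line number.
    """
    reads: list[MethylRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, bin_start_s, read_id, pos_s, calls = parts
            try:
                bin_start = int(bin_start_s)
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(positions) != len(calls):
                raise FormatError(
                    f"{path}:{lineno}: {len(positions)} positions vs "
                    f"{len(calls)}-character call string"
                )
            for p in positions:
                if (chrom, p) not in cpg_map:
                    raise FormatError(f"{path}:{lineno}: position {chrom}:{p} not in CpG map")
            try:
                reads.append(MethylRead(read_id, chrom, bin_start, positions, calls))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_epiread(reads: Iterable[MethylRead], path: str | Path) -> None:
    """Write reads in input order; output is byte-deterministic."""
    with open(path, "w") as fh:
        for r in reads:
            pos = ",".join(str(p) for p in r.cpg_positions)
            fh.write(f"{r.chrom}\t{r.bin_start}\t{r.read_id}\t{pos}\t{r.calls}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3+ file (0-based half-open); column 4, if present, is the label."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            label = parts[3] if len(parts) > 3 else "."
            try:
                regions.append(Region(parts[0], start, end, label))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(regions)


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Simulation truth table (BED+)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRow:
    region: Region
    event_type: str  # toc | dmr | none
    subpop_fraction: float
    source_pattern: str
    target_pattern: str


def write_truth(rows: Iterable[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in rows:
            r = t.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{t.event_type}\t"
                f"{t.subpop_fraction:g}\t{t.source_pattern}\t{t.target_pattern}\n"
            )


def read_truth(path: str | Path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            chrom, start, end, event, frac, src, tgt = parts
            if event not in ("toc", "dmr", "none"):
                raise FormatError(f"{path}:{lineno}: bad event_type {event!r}")
            rows.append(
                TruthRow(Region(chrom, int(start), int(end)), event, float(frac), src, tgt)
            )
    return rows


def write_cpg_map(cpg_map: CpGMap, path: str | Path) -> None:
    """Write a CpG map as two-column TSV (chrom, 0-based position)."""
    with open(path, "w") as fh:
        for chrom in cpg_map.chroms:
            for p in cpg_map.positions(chrom):
                fh.write(f"{chrom}\t{p}\n")


def read_cpg_map(path: str | Path) -> CpGMap:
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            by_chrom.setdefault(parts[0], []).append(int(parts[1]))
    return CpGMap(by_chrom)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes
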