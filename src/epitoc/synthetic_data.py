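"""Synthetic read-level WGBS libraries with known ground truth.

The generator emulates the structure the downstream analysis is built to
detect: each 100-bp bin carries a mixture of cell-subtype epialleles
(binary methylation patterns), and between an earlier and a later
developmental age two kinds of events can occur:

* ``toc`` — "topping off": a subpopulation of cells (default 30%, matching
  the observation that most such events involve fewer than 40% of reads)
  moves from a pattern one CpG short of full methylation to the fully
  methylated pattern. Bulk methylation changes by subpop_fraction at the
  single topped-off CpG and nowhere else, so the bin-mean shift is
  subpop_fraction / cpgs_per_bin — the reason such events evade bulk
  DMR callers.
* ``dmr`` — a whole-population shift: every CpG's marginal methylation
  probability rises by dmr_delta (>= 5%), spread across all patterns.

Reads are sampled per bin and library at negative-binomial depth (default
mean 54, matching the reported average of ~54 informative reads per bin),
with optional per-call missingness.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    CpGMap,
    MethylRead,
    Region,
    TruthRow,
    write_cpg_map,
    write_epiread,
    write_truth,
)

__all__ = [
    "SimConfig",
    "StudyData",
    "baseline_mixture",
    "simulate_cpg_map",
    "inject_events",
    "sample_reads",
    "simulate_study",
]

Mixture = dict[str, float]

SIM_CHROM = "chrS"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    depth_dispersion is the negative-binomial size parameter r
    (variance = mean + mean^2 / r); smaller r means more overdispersed
    per-bin depths.
    """

    n_bins: int = 100
    cpgs_per_bin: int = 3
    bin_size: int = 100
    depth_mean: float = 54.0
    depth_dispersion: float = 25.0
    groups: tuple[str, ...] = ("P12", "P35")
    later_groups: tuple[str, ...] | None = None  # default: last group only
    toc_fraction: float = 0.0
    toc_subpop: float = 0.3
    dmr_fraction: float = 0.0
    dmr_delta: float = 0.15
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("toc_fraction", "toc_subpop", "dmr_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.cpgs_per_bin < 2:
            raise ValueError("cpgs_per_bin must be >= 2")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.toc_fraction + self.dmr_fraction > 1.0 + 1e-12:
            raise ValueError("toc_fraction + dmr_fraction must not exceed 1")
        if self.dmr_fraction > 0 and self.dmr_delta < 0.05:
            raise ValueError("dmr_delta below the 5% bulk-shift floor")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def resolved_later_groups(self) -> tuple[str, ...]:
        later = self.later_groups if self.later_groups is not None else (self.groups[-1],)
        unknown = set(later) - set(self.groups)
        if unknown:
            raise ValueError(f"later_groups not in groups: {sorted(unknown)}")
        return tuple(later)


def baseline_mixture(k: int) -> Mixture:
    """Default per-bin epiallele mixture shared by all groups at baseline.

    50% fully unmethylated cells, 30% one-CpG-short-of-full (the future
    topping-off source), 20% fully methylated.
    """
    return {"0" * k: 0.5, "1" * (k - 1) + "0": 0.3, "1" * k: 0.2}


def _check_mixture(mixture: Mixture) -> None:
    if not mixture:
        raise ValueError("empty mixture")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# Genome scaffold
# ---------------------------------------------------------------------------


def simulate_cpg_map(config: SimConfig) -> tuple[CpGMap, list[Region]]:
    """Lay out n_bins disjoint, grid-aligned bins with exactly cpgs_per_bin
    CpGs placed uniformly within each.

    Bins occupy every other grid slot so adjacent bins never touch.
    Deterministic under a fixed config seed.
    """
    if config.cpgs_per_bin > config.bin_size / 2:
        raise ValueError("cpgs_per_bin exceeds bin_size/2; cannot place distinct CpGs")
    rng = np.random.default_rng([config.seed, 1])
    positions: list[int] = []
    bins: list[Region] = []
    for i in range(config.n_bins):
        start = 2 * i * config.bin_size
        offs = np.sort(rng.choice(config.bin_size, size=config.cpgs_per_bin, replace=False))
        positions.extend(int(start + o) for o in offs)
        bins.append(Region(SIM_CHROM, start, start + config.bin_size, f"bin{i}"))
    return CpGMap({SIM_CHROM: positions}), bins


# ---------------------------------------------------------------------------
# Event injection
# ---------------------------------------------------------------------------


def _apply_toc(mixture: Mixture, source: str, subpop: float) -> Mixture:
    """Move an absolute mass of `subpop` cells from `source` to all-ones."""
    full = "1" * len(source)
    if mixture.get(source, 0.0) + 1e-9 < subpop:
        raise ValueError(
            f"source pattern {source} has mass {mixture.get(source, 0.0)}, "
            f"cannot move {subpop}"
        )
    out = dict(mixture)
    out[source] = out[source] - subpop
    out[full] = out.get(full, 0.0) + subpop
    if out[source] <= 1e-12:
        del out[source]
    return out


def _percpg_methylation(mixture: Mixture, k: int) -> np.ndarray:
    m = np.zeros(k)
    for pat, w in mixture.items():
        m += w * np.array([c == "1" for c in pat], dtype=float)
    return m


def _apply_dmr(mixture: Mixture, k: int, delta: float) -> Mixture:
    """Raise every CpG's marginal methylation by `delta`.

    Each unmethylated call in each pattern flips to methylated independently
    with per-CpG probability delta / (1 - m_j), which lifts CpG j's marginal
    from m_j to m_j + delta exactly. The resulting pattern mixture is
    computed in closed form by enumerating flip subsets.
    """
    m = _percpg_methylation(mixture, k)
    if np.any(m + delta > 1.0 + 1e-9):
        raise ValueError("dmr_delta pushes a CpG's methylation above 1")
    q = delta / (1.0 - m)  # flip-up probability per CpG
    out: dict[str, float] = {}
    for pat, w in mixture.items():
        zeros = [j for j, c in enumerate(pat) if c == "0"]
        for flips in itertools.chain.from_iterable(
            itertools.combinations(zeros, r) for r in range(len(zeros) + 1)
        ):
            prob = w
            for j in zeros:
                prob *= q[j] if j in flips else (1.0 - q[j])
            new = "".join(
                "1" if (c == "1" or j in flips) else "0" for j, c in enumerate(pat)
            )
            out[new] = out.get(new, 0.0) + prob
    return {p: w for p, w in out.items() if w > 1e-15}


def inject_events(
    config: SimConfig, bins: list[Region], rng: np.random.Generator
) -> tuple[dict[str, list[Mixture]], list[TruthRow]]:
    """Assign toc/dmr/none events to bins and build per-group mixtures.

    Event counts are deterministic (round(fraction * n_bins)); which bins
    carry them is drawn from `rng`. Earlier groups always see the baseline
    mixture; groups in `later_groups` see the event-modified mixture.
    """
    n = len(bins)
    k = config.cpgs_per_bin
    n_toc = int(round(config.toc_fraction * n))
    n_dmr = int(round(config.dmr_fraction * n))
    if n_toc + n_dmr > n:
        raise ValueError("toc_fraction + dmr_fraction allocate more bins than exist")
    perm = rng.permutation(n)
    toc_idx = set(int(i) for i in perm[:n_toc])
    dmr_idx = set(int(i) for i in perm[n_toc : n_toc + n_dmr])

    base = baseline_mixture(k)
    source = "1" * (k - 1) + "0"
    full = "1" * k
    later = set(config.resolved_later_groups)

    early_mixes: list[Mixture] = []
    late_mixes: list[Mixture] = []
    truth: list[TruthRow] = []
    for i, region in enumerate(bins):
        early_mixes.append(dict(base))
        if i in toc_idx:
            late_mixes.append(_apply_toc(base, source, config.toc_subpop))
            truth.append(TruthRow(region, "toc", config.toc_subpop, source, full))
        elif i in dmr_idx:
            late_mixes.append(_apply_dmr(base, k, config.dmr_delta))
            truth.append(TruthRow(region, "dmr", 1.0, ".", "."))
        else:
            late_mixes.append(dict(base))
            truth.append(TruthRow(region, "none", 0.0, ".", "."))

    mixtures = {
        g: (late_mixes if g in later else early_mixes) for g in config.groups
    }
    for mixes in mixtures.values():
        for mix in mixes:
            _check_mixture(mix)
    return mixtures, truth


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------


def sample_reads(
    mixture: Mixture,
    cpg_positions: tuple[int, ...],
    chrom: str,
    bin_start: int,
    depth_mean: float,
    depth_dispersion: float,
    missing_rate: float,
    rng: np.random.Generator,
    read_prefix: str = "r",
    depth_factor: float | None = None,
) -> list[MethylRead]:
    """Sample one bin's reads: NB depth, i.i.d. patterns, i.i.d. missingness.

    The negative binomial is realized hierarchically as a Gamma-mixed
    Poisson. When ``depth_factor`` (the bin's relative accessibility, mean
    1) is supplied the Gamma stage has already been drawn by the caller and
    the count is Poisson(depth_mean * depth_factor); `simulate_study` uses
    this to share one accessibility factor per bin across libraries, the
    way mappability and GC bias affect all libraries of a study alike.
    Standalone calls leave it None and draw the full NB here.
    """
    _check_mixture(mixture)
    r = depth_dispersion
    if depth_factor is None:
        depth_factor = rng.gamma(shape=r, scale=1.0 / r)
    n = int(rng.poisson(depth_mean * depth_factor))
    patterns = list(mixture)
    probs = np.array([mixture[p] for p in patterns])
    probs = probs / probs.sum()
    idx = rng.choice(len(patterns), size=n, p=probs)
    reads: list[MethylRead] = []
    k = len(cpg_positions)
    for i, j in enumerate(idx):
        calls = patterns[j]
        if missing_rate > 0:
            mask = rng.random(k) < missing_rate
            if mask.any():
                calls = "".join("?" if m else c for c, m in zip(calls, mask))
        reads.append(
            MethylRead(f"{read_prefix}{i}", chrom, bin_start, tuple(cpg_positions), calls)
        )
    return reads


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    config: SimConfig
    cpg_map: CpGMap
    bins: list[Region]
    mixtures: dict[str, list[Mixture]]
    reads: dict[str, list[MethylRead]]  # group -> all reads
    truth: list[TruthRow]


def simulate_study(config: SimConfig, outdir: str | Path | None = None) -> StudyData:
    """Generate the full study: map, events, per-group libraries, truth.

    With `outdir`, writes one epiread TSV per group plus truth.bed,
    cpg_map.tsv, chrom_sizes.tsv and a config echo JSON; outputs are
    byte-identical under a fixed seed.
    """
    cpg_map, bins = simulate_cpg_map(config)
    rng_events = np.random.default_rng([config.seed, 2])
    mixtures, truth = inject_events(config, bins, rng_events)

    bin_positions = [
        tuple(int(p) for p in cpg_map.positions(SIM_CHROM)[
            np.searchsorted(cpg_map.positions(SIM_CHROM), b.start):
            np.searchsorted(cpg_map.positions(SIM_CHROM), b.end)
        ])
        for b in bins
    ]
    # One accessibility factor per bin, shared across libraries: bin-level
    # depth biases (mappability, GC) are common to all libraries of a study.
    rng_depth = np.random.default_rng([config.seed, 4])
    r = config.depth_dispersion
    depth_factors = rng_depth.gamma(shape=r, scale=1.0 / r, size=len(bins))

    reads: dict[str, list[MethylRead]] = {}
    for gi, group in enumerate(config.groups):
        group_reads: list[MethylRead] = []
        for bi, region in enumerate(bins):
            rng = np.random.default_rng([config.seed, 3, gi, bi])
            group_reads.extend(
                sample_reads(
                    mixtures[group][bi],
                    bin_positions[bi],
                    region.chrom,
                    region.start,
                    config.depth_mean,
                    config.depth_dispersion,
                    config.missing_rate,
                    rng,
                    read_prefix=f"{group}_b{bi}_",
                    depth_factor=float(depth_factors[bi]),
                )
            )
        reads[group] = group_reads

    study = StudyData(config, cpg_map, bins, mixtures, reads, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for group in config.groups:
            write_epiread(reads[group], outdir / f"reads_{group}.tsv")
        write_truth(truth, outdir / "truth.bed")
        write_cpg_map(cpg_map, outdir / "cpg_map.tsv")
        last_end = bins[-1].end
        (outdir / "chrom_sizes.tsv").write_text(f"{SIM_CHROM}\t{last_end}\n")
        echo = dataclasses.asdict(config)
        (outdir / "sim_config.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    return study
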