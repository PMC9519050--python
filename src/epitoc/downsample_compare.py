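"""Depth-normalized, resampled per-epiallele enrichment comparison.

Two merged libraries rarely share read depth, and epiallele proportions
estimated at unequal depths are not comparable. The framework therefore,
for every qualifying bin:

1. sets the bin's target depth to the shallower library's read count;
2. draws `n_draws` (default 100) paired resamples of both libraries at the
   target depth, WITHOUT replacement (multivariate hypergeometric over
   patterns) — the shallower library's draw is therefore its full read set
   on every draw, by construction;
3. tests each candidate pattern per draw with a two-sided Fisher exact test
   on the 2x2 table (pattern vs all other reads, library A vs B) at
   ``alpha`` (default 0.05);
4. calls a pattern enriched only if it is significant *in the same
   direction* on strictly more than ``consistency`` (default 0.95) of the
   draws.

No multiple-testing correction is applied across bins or patterns; the
draw-consistency rule is the guard against unstable calls. Resampling
streams are keyed per bin and per library content, so results are
independent of bin processing order and swapping the two libraries flips
every call's direction and changes nothing else.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .epiallele_core import EpialleleProfile, classify_pattern, profile_library
from .io_formats import CpGMap, MethylRead, Region, RunConfig

__all__ = [
    "EnrichmentCall",
    "ComparisonResult",
    "target_depth",
    "draw_resample",
    "fisher_exact_two_sided",
    "compare_bin",
    "run_comparison",
]

A_OVER_B = "A_over_B"
B_OVER_A = "B_over_A"


@dataclass(frozen=True)
class EnrichmentCall:
    """Per-bin, per-pattern verdict of the down-sampling comparison."""

    region: Region
    pattern: str
    direction: str  # A_over_B | B_over_A
    n_significant_draws: int
    n_draws: int
    enriched: bool
    median_p: float
    delta_proportion: float  # full-profile prop(A) - prop(B), signed
    total_a: int
    total_b: int
    target: int


@dataclass
class SkippedBin:
    region: Region
    reason: str
    total_a: int
    total_b: int


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    skipped: list[SkippedBin]
    mean_reads_a: float
    mean_reads_b: float
    n_bins_tested: int


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def target_depth(profile_a: EpialleleProfile, profile_b: EpialleleProfile) -> int:
    """The shallower merged library's depth is the bin's resampling target."""
    return min(profile_a.total, profile_b.total)


def draw_resample(
    profile: EpialleleProfile, target: int, rng: np.random.Generator
) -> dict[str, int]:
    """Draw `target` reads without replacement; counts sum to target."""
    if target > profile.total:
        raise ValueError(f"target {target} exceeds library depth {profile.total}")
    patterns = sorted(profile.counts)
    colors = np.array([profile.counts[p] for p in patterns], dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(colors, target)
    return {p: int(c) for p, c in zip(patterns, drawn)}


@lru_cache(maxsize=1_000_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    num = 0
    for k in range(kmin, kmax + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= w_obs:
            num += w
    return num / comb(n, c1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for [[a, b], [c, d]].

    Sums the conditional hypergeometric probabilities of every table (same
    margins) no more probable than the observed one. Probabilities are
    compared as exact integer weights, so ties are exact rather than
    float-tolerant.
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"table entries must be non-negative integers, got {v!r}")
    return _fisher_cached(int(a), int(b), int(c), int(d))


# ---------------------------------------------------------------------------
# Per-bin comparison
# ---------------------------------------------------------------------------


def _content_stream(seed: int, region: Region, profile: EpialleleProfile) -> np.random.Generator:
    # Keyed by bin coordinates and library content (not argument position),
    # so compare_bin(A, B) and compare_bin(B, A) resample identically.
    content = ";".join(f"{p}:{c}" for p, c in sorted(profile.counts.items()))
    h = zlib.crc32(content.encode()) & 0x7FFFFFFF
    chrom_h = zlib.crc32(region.chrom.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed, chrom_h, region.start, h])


def compare_bin(
    profile_a: EpialleleProfile,
    profile_b: EpialleleProfile,
    config: RunConfig,
    seed: int | None = None,
) -> list[EnrichmentCall]:
    """Run the paired resampling comparison for one bin.

    Candidate patterns are those meeting the cluster floor
    (``min_cluster_fraction``; set to 0 to test every observed pattern) in
    at least one full library. Returns one call per candidate pattern with
    its draw-consistency statistics; ``enriched`` requires significance in
    one consistent direction on > consistency of draws.
    """
    if seed is None:
        seed = config.seed
    region = profile_a.region
    target = target_depth(profile_a, profile_b)
    candidates = sorted(
        profile_a.clusters(config.min_cluster_fraction)
        | profile_b.clusters(config.min_cluster_fraction)
    )
    if not candidates or target == 0:
        return []

    patterns = sorted(set(profile_a.counts) | set(profile_b.counts))
    idx = {p: j for j, p in enumerate(patterns)}
    colors_a = np.array([profile_a.counts.get(p, 0) for p in patterns], dtype=np.int64)
    colors_b = np.array([profile_b.counts.get(p, 0) for p in patterns], dtype=np.int64)

    rng_a = _content_stream(seed, region, profile_a)
    rng_b = _content_stream(seed, region, profile_b)
    draws_a = rng_a.multivariate_hypergeometric(colors_a, target, size=config.n_draws)
    draws_b = rng_b.multivariate_hypergeometric(colors_b, target, size=config.n_draws)

    props_a = profile_a.proportions
    props_b = profile_b.proportions
    calls: list[EnrichmentCall] = []
    for pat in candidates:
        j = idx[pat]
        ca = draws_a[:, j]
        cb = draws_b[:, j]
        pvals = np.array(
            [
                _fisher_cached(int(a), int(target - a), int(b), int(target - b))
                for a, b in zip(ca, cb)
            ]
        )
        sig = pvals < config.alpha
        n_sig_a = int(np.sum(sig & (ca > cb)))
        n_sig_b = int(np.sum(sig & (cb > ca)))
        n_sig, direction = max(
            (n_sig_a, A_OVER_B), (n_sig_b, B_OVER_A), key=lambda t: t[0]
        )
        delta = props_a.get(pat, 0.0) - props_b.get(pat, 0.0)
        if n_sig_a == n_sig_b == 0:
            direction = A_OVER_B if delta >= 0 else B_OVER_A
        enriched = n_sig / config.n_draws > config.consistency
        calls.append(
            EnrichmentCall(
                region=region,
                pattern=pat,
                direction=direction,
                n_significant_draws=n_sig,
                n_draws=config.n_draws,
                enriched=enriched,
                median_p=float(np.median(pvals)),
                delta_proportion=delta,
                total_a=profile_a.total,
                total_b=profile_b.total,
                target=target,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Genome-wide driver
# ---------------------------------------------------------------------------


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "pattern": c.pattern,
            "class_percent": classify_pattern(c.pattern),
            "direction": c.direction,
            "n_significant_draws": c.n_significant_draws,
            "n_draws": c.n_draws,
            "enriched": c.enriched,
            "median_p": c.median_p,
            "delta_proportion": c.delta_proportion,
            "total_a": c.total_a,
            "total_b": c.total_b,
            "target": c.target,
        }
        for c in calls
    ]
    columns = [
        "chrom", "start", "end", "pattern", "class_percent", "direction",
        "n_significant_draws", "n_draws", "enriched", "median_p",
        "delta_proportion", "total_a", "total_b", "target",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_comparison(
    reads_a: list[MethylRead],
    reads_b: list[MethylRead],
    cpg_map: CpGMap,
    config: RunConfig,
) -> ComparisonResult:
    """Apply compare_bin to every bin where both libraries meet min_reads.

    Bins below the depth floor in either library are recorded in the
    skipped-bin ledger, not dropped silently.
    """
    profiles_a = profile_library(reads_a, cpg_map, config.bin_size, config.min_cpgs)
    profiles_b = profile_library(reads_b, cpg_map, config.bin_size, config.min_cpgs)

    calls: list[EnrichmentCall] = []
    skipped: list[SkippedBin] = []
    depths_a: list[int] = []
    depths_b: list[int] = []
    n_tested = 0
    for key in profiles_a:
        pa, pb = profiles_a[key], profiles_b[key]
        if pa.total > 0 or pb.total > 0:
            depths_a.append(pa.total)
            depths_b.append(pb.total)
        if pa.total < config.min_reads or pb.total < config.min_reads:
            if pa.total > 0 or pb.total > 0:
                skipped.append(
                    SkippedBin(pa.region, "below min_reads", pa.total, pb.total)
                )
            continue
        n_tested += 1
        calls.extend(compare_bin(pa, pb, config))

    return ComparisonResult(
        table=calls_to_frame(calls),
        skipped=skipped,
        mean_reads_a=float(np.mean(depths_a)) if depths_a else 0.0,
        mean_reads_b=float(np.mean(depths_b)) if depths_b else 0.0,
        n_bins_tested=n_tested,
    )
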