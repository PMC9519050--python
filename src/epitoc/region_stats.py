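"""Region-level statistics: stand-in DMR calling, CpG-density-matched null
controls, published-region enrichment, and SNP overlap odds ratios.

The DMR caller here is an explicitly labelled stand-in, NOT DSS: it tests
each sufficiently covered CpG with a two-sided Fisher exact test, applies
Benjamini-Hochberg correction, and merges nearby same-sign significant
CpGs, keeping regions at the published thresholds (q < 0.05, at least 3
CpGs, |mean delta| >= 5%, >= 5 reads per library per CpG). It exists so
the contrast between bulk DMR calling and read-level cluster analysis can
be exercised end to end; its merging parameters are its own, not DSS's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .downsample_compare import fisher_exact_two_sided
from .io_formats import CpGMap, MethylRead, Region, RegionSet, RunConfig

__all__ = [
    "DMRRecord",
    "EnrichmentResult",
    "OddsResult",
    "ControlMatchError",
    "percpg_counts",
    "standin_call_dmrs",
    "generate_matched_controls",
    "published_region_enrichment",
    "overlap_odds_ratio",
]

STANDIN_LABEL = "standin_not_DSS"


@dataclass(frozen=True)
class DMRRecord:
    """A stand-in differentially methylated region (labelled, not DSS)."""

    region: Region
    n_cpgs: int
    mean_delta: float  # late - early methylation fraction
    q_value: float  # worst BH-adjusted p among member CpGs
    direction: str  # gain | loss
    label: str = STANDIN_LABEL


@dataclass(frozen=True)
class EnrichmentResult:
    observed_overlap: float
    null_mean: float
    fold: float | None
    z: float
    p: float
    n_controls: int
    n_features: int
    n_unmatched: int


@dataclass(frozen=True)
class OddsResult:
    odds_ratio: float | None  # observed/expected co-occurrence proportion ratio
    p: float
    observed: float | None  # co-occurrence proportion among feature SNPs
    expected: float  # genome-wide co-occurrence proportion
    table: tuple[int, int, int, int]  # (in_both, in_notboth, out_both, out_notboth)


class ControlMatchError(RuntimeError):
    """No qualifying matched placement found within the attempt budget."""


# ---------------------------------------------------------------------------
# Stand-in DMR caller
# ---------------------------------------------------------------------------


def percpg_counts(reads: list[MethylRead]) -> pd.DataFrame:
    """Tally (methylated, total) non-missing calls per CpG from reads."""
    meth: dict[tuple[str, int], int] = {}
    total: dict[tuple[str, int], int] = {}
    for r in reads:
        for p, c in zip(r.cpg_positions, r.calls):
            if c == "?":
                continue
            key = (r.chrom, p)
            total[key] = total.get(key, 0) + 1
            if c == "1":
                meth[key] = meth.get(key, 0) + 1
    rows = [
        {"chrom": k[0], "pos": k[1], "meth": meth.get(k, 0), "total": total[k]}
        for k in sorted(total)
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])


def standin_call_dmrs(
    counts_early: pd.DataFrame,
    counts_late: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[DMRRecord]:
    """Call stand-in DMRs from per-CpG count tables (columns chrom, pos,
    meth, total).

    Only CpGs with at least ``min_cpg_reads`` (default 5) reads in each
    library are tested. Deltas are late minus early.
    """
    if config is None:
        config = RunConfig()
    merged = counts_early.merge(
        counts_late, on=["chrom", "pos"], how="outer", suffixes=("_e", "_l"), indicator=True
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("mismatched CpG universes between the two count tables")
    merged = merged.drop(columns="_merge")
    merged = merged.sort_values(["chrom", "pos"])
    covered = merged[
        (merged["total_e"] >= config.min_cpg_reads)
        & (merged["total_l"] >= config.min_cpg_reads)
    ].reset_index(drop=True)
    if covered.empty:
        return []

    pvals = np.array(
        [
            fisher_exact_two_sided(
                int(r.meth_l), int(r.total_l - r.meth_l), int(r.meth_e), int(r.total_e - r.meth_e)
            )
            for r in covered.itertuples()
        ]
    )
    _, qvals, _, _ = multipletests(pvals, alpha=config.fdr_alpha, method="fdr_bh")
    delta = covered["meth_l"] / covered["total_l"] - covered["meth_e"] / covered["total_e"]
    sig = (qvals < config.fdr_alpha) & (delta != 0)

    records: list[DMRRecord] = []
    run: list[int] = []  # indices of the current same-sign run

    def flush(run_idx: list[int]) -> None:
        if len(run_idx) < config.min_dmr_cpgs:
            return
        sub = covered.iloc[run_idx]
        mean_delta = float(delta.iloc[run_idx].mean())
        if abs(mean_delta) < config.min_dmr_delta:
            return
        region = Region(
            sub["chrom"].iloc[0], int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]) + 1,
            STANDIN_LABEL,
        )
        records.append(
            DMRRecord(
                region=region,
                n_cpgs=len(run_idx),
                mean_delta=mean_delta,
                q_value=float(qvals[run_idx].max()),
                direction="gain" if mean_delta > 0 else "loss",
            )
        )

    for i in range(len(covered)):
        if not sig[i]:
            continue
        if run:
            j = run[-1]
            same_chrom = covered["chrom"].iloc[i] == covered["chrom"].iloc[j]
            close = covered["pos"].iloc[i] - covered["pos"].iloc[j] <= config.merge_gap
            same_sign = (delta.iloc[i] > 0) == (delta.iloc[j] > 0)
            if same_chrom and close and same_sign:
                run.append(i)
                continue
            flush(run)
        run = [i]
    flush(run)
    return records


# ---------------------------------------------------------------------------
# Matched null controls
# ---------------------------------------------------------------------------


def generate_matched_controls(
    region: Region,
    cpg_map: CpGMap,
    chrom_sizes: dict[str, int],
    n: int,
    rng: np.random.Generator,
    density_tol: float = 0.10,
    max_attempts: int = 10_000,
) -> list[Region]:
    """Sample n random regions of identical length whose CpG count is
    within ±density_tol (relative) of the query's.

    Placements are uniform over all chromosomes (length-weighted); controls
    may overlap each other or the query. Raises ControlMatchError when the
    attempt budget is exhausted.
    """
    query_count = cpg_map.count_in(region.chrom, region.start, region.end)
    if query_count < 1:
        raise ControlMatchError(f"query region {region.chrom}:{region.start} has no CpGs")
    length = region.length
    lo = query_count * (1.0 - density_tol) - 1e-9
    hi = query_count * (1.0 + density_tol) + 1e-9
    chroms = [c for c, s in chrom_sizes.items() if s >= length]
    if not chroms:
        raise ControlMatchError("no chromosome long enough for a matched control")
    weights = np.array([chrom_sizes[c] - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()

    controls: list[Region] = []
    for _ in range(max_attempts):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
        count = cpg_map.count_in(chrom, start, start + length)
        if lo <= count <= hi:
            controls.append(Region(chrom, start, start + length, "control"))
            if len(controls) == n:
                return controls
    raise ControlMatchError(
        f"only {len(controls)}/{n} matched controls found for "
        f"{region.chrom}:{region.start}-{region.end} in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Published-region enrichment
# ---------------------------------------------------------------------------


def pad_region(region: Region, min_size: int) -> Region:
    """Expand a region symmetrically about its midpoint to at least min_size."""
    if region.length >= min_size:
        return region
    mid = (region.start + region.end) // 2
    start = max(0, mid - min_size // 2)
    return Region(region.chrom, start, start + min_size, region.label)


def _build_tree(regions: RegionSet | list[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], region: Region) -> bool:
    tree = trees.get(region.chrom)
    return bool(tree is not None and tree.overlap(region.start, region.end))


def published_region_enrichment(
    feature_set: RegionSet,
    published_set: RegionSet,
    cpg_map: CpGMap,
    chrom_sizes: dict[str, int],
    config: RunConfig,
    rng: np.random.Generator,
) -> EnrichmentResult:
    """Overlap of features with a published region set versus matched nulls.

    Published regions are padded to >= ``pad_to`` (default 2 kb) before
    overlap. Each feature contributes one size- and density-matched control
    per control set; ``n_controls`` (default 100) such sets give the null
    overlap distribution. Significance is a one-proportion Z test of the
    observed overlap proportion against the null-set mean (no continuity
    correction); features that cannot be matched are excluded and counted.
    """
    if len(feature_set) == 0:
        raise ValueError("empty feature set")
    trees = _build_tree([pad_region(r, config.pad_to) for r in published_set])

    matched_features: list[Region] = []
    controls_per_feature: list[list[Region]] = []
    n_unmatched = 0
    for feat in feature_set:
        try:
            ctrls = generate_matched_controls(
                feat, cpg_map, chrom_sizes, config.n_controls, rng,
                config.density_tol, config.max_attempts,
            )
        except ControlMatchError:
            n_unmatched += 1
            continue
        matched_features.append(feat)
        controls_per_feature.append(ctrls)
    if not matched_features:
        raise ValueError("no feature region could be density-matched")

    n_feat = len(matched_features)
    observed = sum(_overlaps(trees, f) for f in matched_features) / n_feat
    null_props = np.array(
        [
            sum(_overlaps(trees, ctrls[s]) for ctrls in controls_per_feature) / n_feat
            for s in range(config.n_controls)
        ]
    )
    p0 = float(null_props.mean())

    if 0.0 < p0 < 1.0:
        z = (observed - p0) / np.sqrt(p0 * (1.0 - p0) / n_feat)
    elif observed == p0:
        z = 0.0
    else:
        z = np.inf if observed > p0 else -np.inf
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    fold = observed / p0 if p0 > 0 else None
    return EnrichmentResult(
        observed_overlap=observed,
        null_mean=p0,
        fold=fold,
        z=float(z),
        p=p,
        n_controls=config.n_controls,
        n_features=n_feat,
        n_unmatched=n_unmatched,
    )


# ---------------------------------------------------------------------------
# SNP overlap odds ratio
# ---------------------------------------------------------------------------


def overlap_odds_ratio(
    snps_a: RegionSet,
    snps_b: RegionSet,
    feature_regions: RegionSet,
    universe_snps: RegionSet,
) -> OddsResult:
    """Feature-conditional enrichment of SNPs annotated to both traits.

    Expected is the genome-wide proportion of universe SNPs present in both
    A and B; observed is the same proportion among universe SNPs falling
    inside the features. The odds ratio is observed/expected, and the
    two-sided Fisher exact p comes from the implied 2x2
    (inside/outside features x in-both/not-in-both).
    """
    if len(universe_snps) == 0:
        raise ValueError("empty SNP universe")
    keys_a = snps_a.keys()
    keys_b = snps_b.keys()
    trees = _build_tree(feature_regions)

    in_both = in_notboth = out_both = out_notboth = 0
    for snp in universe_snps:
        both = snp.key() in keys_a and snp.key() in keys_b
        inside = _overlaps(trees, snp)
        if inside and both:
            in_both += 1
        elif inside:
            in_notboth += 1
        elif both:
            out_both += 1
        else:
            out_notboth += 1

    n = len(universe_snps)
    expected = (in_both + out_both) / n
    n_inside = in_both + in_notboth
    observed = in_both / n_inside if n_inside > 0 else None
    if observed is None or expected == 0.0:
        odds = None
    else:
        odds = observed / expected
    p = fisher_exact_two_sided(in_both, in_notboth, out_both, out_notboth)
    return OddsResult(
        odds_ratio=odds,
        p=p,
        observed=observed,
        expected=expected,
        table=(in_both, in_notboth, out_both, out_notboth),
    )
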