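"""Stand-in DMR caller, matched controls, enrichment and odds ratio."""

import numpy as np
import pandas as pd
import pytest

from epitoc import (
    ControlMatchError,
    CpGMap,
    Region,
    RegionSet,
    RunConfig,
    generate_matched_controls,
    overlap_odds_ratio,
    percpg_counts,
    published_region_enrichment,
    standin_call_dmrs,
)
from epitoc.io_formats import MethylRead
from epitoc.region_stats import STANDIN_LABEL, pad_region


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])


# -- stand-in DMR caller -----------------------------------------------------


def test_low_coverage_cpgs_excluded():
    """A CpG with 4 reads in one library never enters the test, however
    extreme its difference."""
    early = counts_frame([("chr1", i, 0, 4) for i in (10, 20, 30)])
    late = counts_frame([("chr1", i, 200, 200) for i in (10, 20, 30)])
    assert standin_call_dmrs(early, late) == []


def test_identical_counts_give_no_dmrs():
    tbl = counts_frame([("chr1", i, 10, 20) for i in range(0, 300, 10)])
    assert standin_call_dmrs(tbl, tbl.copy()) == []


def test_strong_shift_called_and_labelled():
    # 10% -> 60% methylation at 200x over five CpGs within 100 bp
    early = counts_frame([("chr1", 10 + 20 * i, 20, 200) for i in range(5)])
    late = counts_frame([("chr1", 10 + 20 * i, 120, 200) for i in range(5)])
    (dmr,) = standin_call_dmrs(early, late)
    assert dmr.n_cpgs == 5
    assert dmr.direction == "gain"
    assert dmr.mean_delta == pytest.approx(0.5)
    assert dmr.label == STANDIN_LABEL
    assert dmr.q_value < 0.05


def test_merge_respects_gap_and_sign():
    # two strong clusters separated by 500 bp -> two regions, not one
    pos = [0, 20, 40, 600, 620, 640]
    early = counts_frame([("chr1", p, 20, 200) for p in pos])
    late = counts_frame([("chr1", p, 120, 200) for p in pos])
    dmrs = standin_call_dmrs(early, late)
    assert len(dmrs) == 2
    assert all(not (a.region.end > b.region.start and a.region.start < b.region.end)
               for a, b in zip(dmrs, dmrs[1:]))


def test_mismatched_universes_rejected():
    early = counts_frame([("chr1", 10, 5, 10)])
    late = counts_frame([("chr1", 11, 5, 10)])
    with pytest.raises(ValueError):
        standin_call_dmrs(early, late)


def test_percpg_counts_ignores_missing_calls():
    reads = [
        MethylRead("a", "chr1", 0, (10, 20), "1?"),
        MethylRead("b", "chr1", 0, (10, 20), "01"),
    ]
    tbl = percpg_counts(reads)
    assert tbl.loc[tbl.pos == 10, "total"].item() == 2
    assert tbl.loc[tbl.pos == 10, "meth"].item() == 1
    assert tbl.loc[tbl.pos == 20, "total"].item() == 1


# -- matched controls --------------------------------------------------------


def test_controls_match_length_and_density(uniform_genome, rng):
    cpg_map, sizes = uniform_genome
    query = Region("chrU", 10_000, 12_000)  # 2 kb, 40 CpGs
    controls = generate_matched_controls(query, cpg_map, sizes, 100, rng)
    assert len(controls) == 100
    q = cpg_map.count_in("chrU", 10_000, 12_000)
    for c in controls:
        assert c.length == 2000
        count = cpg_map.count_in(c.chrom, c.start, c.end)
        assert q * 0.9 - 1e-9 <= count <= q * 1.1 + 1e-9


def test_control_densities_distribute_around_query(uniform_genome, rng):
    cpg_map, sizes = uniform_genome
    query = Region("chrU", 0, 5000)
    controls = generate_matched_controls(query, cpg_map, sizes, 100, rng)
    q = cpg_map.count_in("chrU", 0, 5000)
    counts = [cpg_map.count_in(c.chrom, c.start, c.end) for c in controls]
    assert np.mean(counts) == pytest.approx(q, rel=0.05)


def test_unmatchable_query_raises():
    sparse = CpGMap({"chrU": [100]})
    with pytest.raises(ControlMatchError):
        generate_matched_controls(
            Region("chrU", 90, 190), sparse, {"chrU": 100_000}, 10,
            np.random.default_rng(0), max_attempts=200,
        )


# -- published-region enrichment ---------------------------------------------


def test_pad_to_two_kb_about_midpoint():
    padded = pad_region(Region("chr1", 10_000, 10_500), 2000)
    assert (padded.start, padded.end) == (9250, 11250)
    untouched = pad_region(Region("chr1", 0, 3000), 2000)
    assert (untouched.start, untouched.end) == (0, 3000)


def test_self_enrichment_is_maximal(uniform_genome):
    cpg_map, sizes = uniform_genome
    rng = np.random.default_rng(42)
    starts = rng.choice(1_990_000 // 1000, size=30, replace=False) * 1000
    features = RegionSet([Region("chrU", int(s), int(s) + 1000) for s in starts])
    cfg = RunConfig(n_controls=50)
    res = published_region_enrichment(features, features, cpg_map, sizes, cfg, rng)
    assert res.observed_overlap == 1.0
    assert res.fold is not None and res.fold > 1
    assert res.p < 0.05
    assert res.z > 0


def test_independent_placement_is_null(uniform_genome):
    cpg_map, sizes = uniform_genome
    rng = np.random.default_rng(7)
    folds = []
    for _ in range(10):
        fs = rng.integers(0, 1_990_000, size=25)
        ps = rng.integers(0, 1_990_000, size=25)
        features = RegionSet([Region("chrU", int(s), int(s) + 1000) for s in fs])
        published = RegionSet([Region("chrU", int(s), int(s) + 1000) for s in ps])
        cfg = RunConfig(n_controls=30)
        res = published_region_enrichment(features, published, cpg_map, sizes, cfg, rng)
        if res.fold is not None:
            folds.append(res.fold)
    mean = np.mean(folds)
    se = np.std(folds, ddof=1) / np.sqrt(len(folds))
    assert abs(mean - 1.0) <= 3 * se + 0.05


def test_empty_feature_set_rejected(uniform_genome, rng):
    cpg_map, sizes = uniform_genome
    with pytest.raises(ValueError):
        published_region_enrichment(
            RegionSet([]), RegionSet([Region("chrU", 0, 2000)]),
            cpg_map, sizes, RunConfig(), rng,
        )


# -- SNP overlap odds ratio --------------------------------------------------


def _snps(positions):
    return RegionSet([Region("chr1", p, p + 1) for p in positions])


def test_disjoint_traits_give_undefined_or():
    universe = _snps(range(0, 1000, 10))
    res = overlap_odds_ratio(
        _snps([0, 10]), _snps([20, 30]), RegionSet([Region("chr1", 0, 100)]), universe
    )
    assert res.odds_ratio is None  # expected co-occurrence is zero


def test_whole_genome_features_give_or_one():
    universe = _snps(range(0, 1000, 10))
    res = overlap_odds_ratio(
        _snps([0, 10, 500]), _snps([0, 10, 700]),
        RegionSet([Region("chr1", 0, 1000)]), universe,
    )
    assert res.odds_ratio == pytest.approx(1.0)


def test_constructed_double_cooccurrence():
    """Universe built so co-occurrence inside features is twice the
    genome-wide rate -> OR recovered near 2 with a significant p."""
    inside = list(range(0, 10_000, 10))  # 1000 SNPs in features
    outside = list(range(20_000, 30_000, 10))  # 1000 SNPs outside
    both_inside = inside[:400]  # 40% co-occur inside
    both_outside = outside[:200]  # 20% outside -> overall expected 30%
    universe = _snps(inside + outside)
    a = _snps(both_inside + both_outside)
    b = _snps(both_inside + both_outside)
    res = overlap_odds_ratio(a, b, RegionSet([Region("chr1", 0, 10_000)]), universe)
    assert res.observed == pytest.approx(0.4)
    assert res.expected == pytest.approx(0.3)
    assert res.odds_ratio == pytest.approx(0.4 / 0.3)
    assert res.p < 0.05


def test_empty_universe_rejected():
    with pytest.raises(ValueError):
        overlap_odds_ratio(_snps([]), _snps([]), RegionSet([]), RegionSet([]))
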