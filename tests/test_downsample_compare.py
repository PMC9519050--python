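"""Down-sampling enrichment framework: exact test, resampling, symmetry."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest
import scipy.stats

from epitoc import (
    RunConfig,
    SimConfig,
    compare_bin,
    draw_resample,
    fisher_exact_two_sided,
    run_comparison,
    simulate_study,
    target_depth,
)


# -- independent oracle for the exact test ---------------------------------


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher via exact rational enumeration of all tables with
    the observed margins, using the factorial form of the hypergeometric
    probability (independent of the implementation's binomial-weight path).
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2

    def table_prob(x):
        # P(table) = r1! r2! c1! c2! / (n! x! (r1-x)! (c1-x)! (r2-c1+x)!)
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2),
            factorial(n)
            * factorial(x)
            * factorial(r1 - x)
            * factorial(c1 - x)
            * factorial(r2 - c1 + x),
        )

    if n == 0 or min(r1, r2, c1, c2) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    return float(sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs))


def test_fisher_no_association_table():
    assert fisher_exact_two_sided(0, 10, 0, 10) == 1.0


def test_fisher_extreme_table_closed_form():
    # [[10,0],[0,10]]: only the two perfectly separated tables are as extreme
    assert fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(
        2 / comb(20, 10), abs=1e-12
    )


@pytest.mark.parametrize("seed", [0, 1])
def test_fisher_matches_enumeration_oracle_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-9
        )


def test_fisher_agrees_with_scipy():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(expected, rel=1e-6)


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(-1, 2, 3, 4)


# -- target depth & resampling ----------------------------------------------


def test_target_depth_is_minimum(profile_factory):
    assert target_depth(profile_factory({"111": 60}), profile_factory({"111": 45})) == 45
    assert target_depth(profile_factory({"111": 45}), profile_factory({"111": 45})) == 45


def test_resample_at_full_depth_is_identity(profile_factory, rng):
    prof = profile_factory({"111": 30, "000": 20})
    assert draw_resample(prof, 50, rng) == prof.counts


def test_resample_single_pattern(profile_factory, rng):
    assert draw_resample(profile_factory({"111": 100}), 30, rng) == {"111": 30}


def test_resample_rejects_oversized_target(profile_factory, rng):
    with pytest.raises(ValueError):
        draw_resample(profile_factory({"111": 10}), 11, rng)


def test_resample_mean_matches_hypergeometric(profile_factory):
    prof = profile_factory({"111": 50, "000": 50})
    rng = np.random.default_rng(123)
    counts = [draw_resample(prof, 20, rng)["111"] for _ in range(10_000)]
    # hypergeometric mean = 20 * 50/100 = 10
    assert np.mean(counts) == pytest.approx(10.0, abs=0.2)


# -- compare_bin -------------------------------------------------------------


def test_identical_profiles_yield_no_enrichment(profile_factory, default_config):
    prof = profile_factory({"111": 20, "000": 80})
    calls = compare_bin(prof, profile_factory({"111": 20, "000": 80}), default_config)
    assert all(not c.enriched for c in calls)


def test_strong_shift_detected_in_correct_direction(profile_factory, default_config):
    # regression expectation verified by simulation: 5% -> 60% at depth 100
    # is far beyond the detection threshold at these settings
    prof_a = profile_factory({"111": 5, "000": 95})
    prof_b = profile_factory({"111": 60, "000": 40})
    calls = {c.pattern: c for c in compare_bin(prof_a, prof_b, default_config)}
    assert calls["111"].enriched and calls["111"].direction == "B_over_A"
    assert calls["111"].n_significant_draws == 100
    assert calls["111"].delta_proportion == pytest.approx(-0.55)


def test_swap_flips_directions_and_nothing_else(profile_factory, default_config):
    prof_a = profile_factory({"111": 10, "110": 30, "000": 60})
    prof_b = profile_factory({"111": 45, "110": 15, "000": 40})
    fwd = compare_bin(prof_a, prof_b, default_config)
    rev = compare_bin(prof_b, prof_a, default_config)
    flip = {"A_over_B": "B_over_A", "B_over_A": "A_over_B"}
    assert len(fwd) == len(rev)
    for f, r in zip(fwd, rev):
        assert f.pattern == r.pattern
        assert f.enriched == r.enriched
        assert f.n_significant_draws == r.n_significant_draws
        assert r.direction == flip[f.direction]
        assert r.delta_proportion == pytest.approx(-f.delta_proportion)


def test_enrichment_requires_strictly_more_than_consistency(profile_factory):
    """A pattern significant on exactly 95 of 100 draws is not enriched."""
    cfg = RunConfig(consistency=0.95, n_draws=100)
    prof_a = profile_factory({"111": 10, "000": 90})
    calls = compare_bin(prof_a, profile_factory({"111": 30, "000": 70}), cfg)
    for c in calls:
        if c.n_significant_draws == 95:
            assert not c.enriched
        if c.enriched:
            assert c.n_significant_draws >= 96


def test_min_cluster_fraction_gates_candidates(profile_factory):
    cfg = RunConfig(min_cluster_fraction=0.5)
    prof_a = profile_factory({"111": 10, "000": 90})
    prof_b = profile_factory({"111": 40, "000": 60})
    pats = {c.pattern for c in compare_bin(prof_a, prof_b, cfg)}
    assert pats == {"000"}  # only 000 reaches 50% in a full library


# -- run_comparison ----------------------------------------------------------


def test_run_comparison_deterministic(small_study, default_config):
    r1 = run_comparison(
        small_study.reads["P12"], small_study.reads["P35"], small_study.cpg_map, default_config
    )
    r2 = run_comparison(
        small_study.reads["P12"], small_study.reads["P35"], small_study.cpg_map, default_config
    )
    assert r1.table.equals(r2.table)


def test_run_comparison_empty_overlap(default_config):
    study = simulate_study(SimConfig(n_bins=3, seed=1))
    res = run_comparison([], [], study.cpg_map, default_config)
    assert res.table.empty
    assert res.n_bins_tested == 0


def test_shallow_bins_recorded_not_tested(profile_factory, default_config):
    study = simulate_study(SimConfig(n_bins=5, depth_mean=4.0, seed=2))
    res = run_comparison(
        study.reads["P12"], study.reads["P35"], study.cpg_map, default_config
    )
    assert res.n_bins_tested + len(res.skipped) == 5
    assert all(s.reason == "below min_reads" for s in res.skipped)


def test_mean_informative_reads_reported(small_study, default_config):
    res = run_comparison(
        small_study.reads["P12"], small_study.reads["P35"], small_study.cpg_map, default_config
    )
    assert 30 < res.mean_reads_a < 90  # depth_mean 54 by construction
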