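"""Topped-off cluster (TOC) calling and gain/loss decomposition.

A TOC is a bin whose fully methylated epiallele cluster is significantly
enriched in the later-age library. The decomposition asks where that gain
came from: for each methylation-percent class below 100%, the proportional
loss between ages is tallied, and ``topoff_fraction`` is the share of total
losses contributed by the class one CpG short of full methylation. True
topping-off events concentrate their losses there (topoff_fraction near 1);
whole-population shifts spread losses across classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .downsample_compare import B_OVER_A
from .epiallele_core import EpialleleProfile, classify_pattern
from .io_formats import Region, RegionSet

__all__ = [
    "TOCRecord",
    "call_tocs",
    "decompose_gains",
    "sex_specific_sets",
    "tocs_to_frame",
]


@dataclass(frozen=True)
class TOCRecord:
    region: Region
    full_pattern: str
    gain_full: float  # prop_late(all-1s) - prop_early(all-1s), > 0
    losses: dict[float, float]  # class percent -> non-negative loss
    topoff_fraction: float | None  # None when no class lost mass
    n_significant_draws: int


def decompose_gains(
    profile_early: EpialleleProfile, profile_late: EpialleleProfile
) -> tuple[float, dict[float, float], float | None]:
    """Gain of the fully methylated class and per-class losses feeding it.

    Returns (gain_full, losses, topoff_fraction) where losses maps each
    methylation class < 100% to max(0, early - late) mass, and
    topoff_fraction is the (k-1)/k class's share of total losses (None when
    nothing was lost).
    """
    if profile_early.k != profile_late.k:
        raise ValueError(
            f"CpG count mismatch: {profile_early.k} vs {profile_late.k}"
        )
    k = profile_early.k
    full = "1" * k
    pe = profile_early.proportions
    pl = profile_late.proportions
    gain_full = pl.get(full, 0.0) - pe.get(full, 0.0)

    class_early: dict[float, float] = {}
    class_late: dict[float, float] = {}
    for pat, prop in pe.items():
        if pat != full:
            c = classify_pattern(pat)
            class_early[c] = class_early.get(c, 0.0) + prop
    for pat, prop in pl.items():
        if pat != full:
            c = classify_pattern(pat)
            class_late[c] = class_late.get(c, 0.0) + prop

    losses = {
        c: max(0.0, class_early.get(c, 0.0) - class_late.get(c, 0.0))
        for c in set(class_early) | set(class_late)
    }
    losses = {c: v for c, v in losses.items() if v > 0.0}
    total_loss = sum(losses.values())
    if total_loss > 0:
        one_short = classify_pattern("1" * (k - 1) + "0")
        topoff = losses.get(one_short, 0.0) / total_loss
    else:
        topoff = None
    return gain_full, losses, topoff


def call_tocs(
    enrichment_table: pd.DataFrame,
    profiles_early: dict[tuple[str, int], EpialleleProfile],
    profiles_late: dict[tuple[str, int], EpialleleProfile],
    later_direction: str = B_OVER_A,
) -> tuple[list[TOCRecord], list[Region]]:
    """Call TOCs from a comparison run with A = earlier, B = later library.

    Returns (tocs, early_enriched): bins whose all-ones pattern is enriched
    in the later library become TOCRecords with decomposition attached;
    bins where the full pattern is enriched in the *earlier* library are
    returned separately — they are not TOCs under the later-relative
    definition.
    """
    tocs: list[TOCRecord] = []
    early_enriched: list[Region] = []
    if enrichment_table.empty:
        return tocs, early_enriched
    full_rows = enrichment_table[
        enrichment_table["enriched"]
        & (enrichment_table["pattern"].str.fullmatch("1+"))
    ]
    for row in full_rows.itertuples():
        key = (row.chrom, row.start)
        region = Region(row.chrom, row.start, row.end)
        if row.direction != later_direction:
            early_enriched.append(region)
            continue
        if key not in profiles_early or key not in profiles_late:
            raise KeyError(f"missing profile for called bin {key}")
        gain_full, losses, topoff = decompose_gains(
            profiles_early[key], profiles_late[key]
        )
        tocs.append(
            TOCRecord(
                region=region,
                full_pattern=row.pattern,
                gain_full=gain_full,
                losses=losses,
                topoff_fraction=topoff,
                n_significant_draws=int(row.n_significant_draws),
            )
        )
    return tocs, early_enriched


def sex_specific_sets(
    toc_bins_male: RegionSet, toc_bins_female: RegionSet, bin_size: int = 100
) -> tuple[RegionSet, RegionSet, RegionSet]:
    """Split two TOC bin sets into (male-specific, female-specific, common).

    Overlap is exact bin identity on the shared fixed grid, so the three
    outputs partition the union. Non-grid regions are rejected.
    """
    for rs in (toc_bins_male, toc_bins_female):
        for r in rs:
            if r.start % bin_size != 0 or r.length != bin_size:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} is not a {bin_size}-bp grid bin"
                )
    male_specific = toc_bins_male.difference(toc_bins_female)
    female_specific = toc_bins_female.difference(toc_bins_male)
    common = toc_bins_male.intersection(toc_bins_female)
    return male_specific, female_specific, common


def tocs_to_frame(tocs: list[TOCRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": t.region.chrom,
            "start": t.region.start,
            "end": t.region.end,
            "gain_full": t.gain_full,
            "topoff_fraction": t.topoff_fraction if t.topoff_fraction is not None else float("nan"),
            "n_significant_draws": t.n_significant_draws,
        }
        for t in tocs
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gain_full", "topoff_fraction", "n_significant_draws"],
    )
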