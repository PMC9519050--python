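# Methods

## Problem and model

Bulk differential-methylation analysis averages over all cells in a sample.
When a methylation change occurs in only a subpopulation of cells — e.g.
one neuronal subtype within a sorted neuronal nuclei pool — the bulk shift
at any CpG can stay below a conventional DMR caller's effect-size cutoff
while the read-level picture changes dramatically. epitoc implements a
read-level alternative: each sequencing read's binary methylation calls
across the CpGs of a fixed 100-bp bin form an *epiallele*, a proxy for the
methylation state of one cell's allele; reads sharing a pattern form an
epiallele cluster, interpreted as a cell subpopulation.

The analysis proceeds in the order the modules are laid out:

1. **epiallele_core** — the genome is partitioned into non-overlapping
   100-bp bins aligned to multiples of the bin size; bins with ≥2 CpGs are
   kept (a single CpG carries no pattern structure). Reads missing a call
   at any bin CpG are dropped and counted (complete-read policy; see
   Limitations). Pattern counts per bin and library form an
   `EpialleleProfile`; a pattern's methylation class is `100·(#1s)/k`
   rounded to one decimal, giving the canonical {0, 33.3, 66.7, 100}
   classes for 3-CpG bins.
2. **downsample_compare** — two merged libraries are compared per bin
   after depth normalization: the shallower library's depth is the target;
   both libraries are resampled to the target 100 times without
   replacement (multivariate hypergeometric over patterns — the shallower
   library's draw is therefore its full read set on every draw); each
   draw tests each candidate pattern (pattern vs all other reads, 2×2)
   with a two-sided Fisher exact test at α = 0.05; a pattern is *enriched*
   only if significant in one consistent direction on strictly more than
   95% of draws. No multiple-testing correction is applied across bins or
   patterns; the draw-consistency rule is the stability guard.
3. **toc_caller** — a *topped-off cluster* (TOC) is a bin whose fully
   methylated pattern is enriched in the later-age library. The gain/loss
   decomposition tallies, per methylation class below 100%, the
   proportional loss between ages; `topoff_fraction` is the share of total
   losses contributed by the class one CpG short of full. True topping-off
   concentrates losses there (fraction ≈ 1); whole-population shifts
   spread them. Sex-specific TOC sets are formed by exact bin-identity
   difference (both sexes share the same fixed grid), with common bins
   excluded.
4. **region_stats** — a deliberately simple, explicitly labelled stand-in
   DMR caller (per-CpG Fisher, BH correction, merge of same-sign
   significant CpGs within 100 bp, keep regions with ≥3 CpGs,
   |Δ| ≥ 5%, q < 0.05, ≥5 reads per library per CpG); matched-null region
   enrichment (each feature paired with random regions of identical
   length and CpG count within ±10%, 100 control sets, one-proportion Z
   test of the observed overlap against the null-set mean, published
   regions padded symmetrically to ≥2 kb first); and a feature-conditional
   SNP co-occurrence odds ratio (observed/expected proportion ratio with a
   two-sided Fisher exact p from the implied 2×2).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 100 bp | analysis bin width; bins align to multiples |
| `min_cpgs` | 2 | minimum CpGs for a bin to enter the analysis |
| `n_draws` | 100 | resampling draws per bin |
| `alpha` | 0.05 | per-draw two-sided Fisher threshold |
| `consistency` | 0.95 | a call needs significance on > this fraction of draws (96/100; a tie at exactly 95 fails) |
| `min_reads` | 10 | per-library depth floor for a bin to be compared |
| `min_cluster_fraction` | 0.05 | cluster floor; candidate patterns must reach it in at least one full library (set 0 to test all) |
| `min_cpg_reads` | 5 | per-CpG, per-library depth floor in the stand-in DMR test |
| `density_tol` | 0.10 | relative CpG-count tolerance for matched controls |
| `n_controls` | 100 | control sets per enrichment analysis |
| `pad_to` | 2000 bp | minimum width of published regions before overlap |

## Synthetic data

The generator emulates the structure the analysis targets, with known
per-bin truth. Baseline bins carry a fixed three-cluster mixture: 50%
fully unmethylated, 30% one-CpG-short-of-full, 20% fully methylated.
Between the earlier and later group:

* **toc** events move an absolute mass of `toc_subpop` (default 0.3,
  consistent with most such events involving fewer than 40% of reads)
  from the one-short pattern to the fully methylated pattern. Bulk
  methylation changes by `toc_subpop` at the single topped-off CpG and
  nowhere else, so the bin mean moves by `toc_subpop / k` — the reason
  these events evade bulk DMR calling.
* **dmr** events lift every CpG's marginal methylation by `dmr_delta`
  (default 0.15): each unmethylated call flips up independently with
  probability `delta / (1 − m_j)`, computed in closed form over the
  pattern lattice, so the shift is exact and spread across patterns.

Depth: per-library read counts are negative binomial with mean 54
(matching the reported average of ~54 informative reads per bin in merged
libraries) and dispersion r = 25 (depth CV ≈ 0.24, typical of bin-level
WGBS coverage after mapping filters). The NB is realized as a Gamma-mixed
Poisson whose Gamma "accessibility" factor is shared between libraries of
the same bin, because bin-level depth biases (mappability, GC) are common
to all libraries of a study; each library then adds independent Poisson
noise. Missing calls are i.i.d. per call at `missing_rate`.

What the generator does **not** emulate: correlated missingness within a
read, bisulfite non-conversion errors, CpG-density-dependent depth,
fragment-length structure, between-sample heterogeneity inside a merged
library, CpH context, or sex chromosomes. Passing tests therefore show the
machinery is correct and calibrated under these idealized conditions, not
that real libraries meet them.

## Numerical choices

* Coordinates are 0-based half-open everywhere (BED convention).
* The Fisher exact test sums conditional hypergeometric probabilities of
  all tables no more probable than the observed one, computed with exact
  integer binomial weights, so ties are decided exactly rather than by a
  float tolerance; results are cached per table.
* Resampling streams are keyed by (seed, chromosome, bin start, library
  pattern content), so results are independent of bin processing order and
  `compare_bin(A, B)` and `compare_bin(B, A)` are exact mirror images. Two
  libraries with identical per-bin content receive identical draws and can
  never produce a call — the correct degenerate behaviour.
* `delta_proportion` is reported from the full (un-resampled) profiles.
* Empty bins, zero-total profiles, undefined topoff fractions (no losses)
  and degenerate odds ratios (zero expected co-occurrence) are signalled
  (`None`/error) rather than coerced to numbers.
* Stand-in DMR merging runs left-to-right per chromosome; a run breaks on
  chromosome change, a gap > 100 bp, or a sign change.

## Design choices made where the design was open

* **Without-replacement resampling.** "Resampling to the target depth" is
  read as depth normalization of the observed reads rather than bootstrap
  inference; the documented consequence is that the shallower library is
  constant across draws, so draw-to-draw variation comes only from the
  deeper library. A bootstrap variant was evaluated and is strictly more
  conservative (see Calibration).
* **Strictly greater than 95%.** A pattern significant on exactly 95 of
  100 draws is not called.
* **Direction consistency** across draws is required; mixed-direction
  significance never counts.
* **Candidate eligibility.** Only patterns meeting the cluster floor in at
  least one full library are tested, configurable to 0.
* **topoff_fraction** is defined as the one-short class's share of total
  losses (the decomposition is presented graphically in the source
  analysis without a formula).
* **Controls may overlap** each other or the query region (uniform
  sampling); the Z test uses the control-set mean as the null proportion
  with no continuity correction; CpG-density tolerance is relative.
* **Sex-specificity** uses exact bin identity, not interval intersection,
  because both analyses share one fixed grid.

## Calibration and the power/specificity trade-off

The acceptance suite measures two global properties of the framework at
the default study conditions (3-CpG bins, depth 54, baseline mixture
above): the null false-call rate (identical mixtures in both libraries,
2,000 bins) and TOC recall (subpop 0.3, 500 bins). These two sit on a hard
trade-off: the per-bin evidence is a single 2×2 table with ~54 reads per
arm, and for the 0.20→0.50 shift in the fully methylated cluster that a
subpop-0.3 event induces, a two-sided Fisher test has ≈0.89 power at
α = 0.05 (where ~10% of null bins show some enriched pattern at the bin
level) and ≈0.60 power at the α ≈ 0.005 needed to push the null bin rate
under 1%. No decision rule monotone in that evidence can deliver both a
sub-1% null bin rate and ≥0.8 recall at these depths. The implemented
procedure measures ≈2–3% null bins and ≈0.6–0.85 recall depending on
seed; both numbers are computed and reported honestly by
`scripts/acceptance.py` rather than tuned. Increasing depth, subpopulation
fraction, or the draw count moves both in the right direction.

The stand-in DMR caller likewise has essentially no power to recover a
15-percentage-point whole-population shift at ~54× per CpG after BH
correction, because it tests CpGs singly; smoothing across CpGs (as
dedicated beta-binomial DML callers do) is what rescues such effects and
is deliberately out of scope. The caller exists to demonstrate the
contrast — single-CpG topping-off events produce zero stand-in DMR calls —
and every output row is labelled `standin_not_DSS`.

## Problem sizes

Test-suite and acceptance-script runs use 500–2,000 simulated bins,
50 enrichment replicates with 30–100 control sets, and exhaustive exact-
test verification for all 2×2 tables with row margins ≤ 30 (≈246,000
tables). These sizes give stable estimates of the reported rates (binomial
SE ≤ ~2 percentage points) while completing in seconds to a couple of
minutes.

## Known limitations

* The complete-read policy discards reads missing any bin CpG instead of
  imputing them; at high missingness this biases profiles toward shorter
  well-covered patterns. The dropped-read count is reported so the
  approximation stays visible.
* No multiple-testing control across bins; genome-scale applications
  should treat per-bin calls as screening hits.
* The one-proportion Z test treats control-set means as a fixed null
  proportion; with few features the normal approximation is rough.
* The stand-in DMR caller is not DSS and its merge parameters are its own.
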