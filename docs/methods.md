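# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order data flows through a screen.

## Coordinates and sequence model

All internal coordinates are 0-based, half-open; GenBank and GFF3 1-based
inclusive coordinates are converted at the file boundary. A gene's anchor
is the genome coordinate of the first base of its start codon (`start` on
the + strand, `end − 1` on the −strand). Windows are always expressed in
transcript orientation relative to that anchor (offset 0 = A of ATG,
negative = upstream), which removes every off-by-one ambiguity from the
tiling arithmetic. Compound (joined) CDS locations are flattened to their
outermost span with a warning: only the translation-initiation region is
targeted, so internal structure is irrelevant here. Genomes default to
linear topology unless the record says circular; windows wrap on circular
genomes and are clipped (with a logged note) at linear sequence ends.

## Guide design

**RBS panel.** Each CDS receives `n_guides` (default 7) spacers of
`spacer_len` (default 31) nt whose target-window centers sit at
`window_center_offset + step·(i − (n−1)/2)`, i.e. −15, −10, … +15 nt from
the start codon with the defaults, so the windows collectively span
−30…+30 nt. This geometry keeps every window inside the empirically
susceptible tract around the RBS and guarantees at least one window
overlapping both the RBS (around −10) and the start codon. The stored
`spacer` is the crRNA spacer (antisense to the mRNA); `target_window` is
the mRNA-sense protospacer; `revcomp(spacer) == target_window` is an
invariant. Guides whose window would cross a linear sequence end are
dropped, not shifted — shifting would silently change the tiling geometry.
For even `n_guides` the center grid shifts half a step upstream (integer
arithmetic on the 5' end), a documented convention.

**Single-nucleotide tiling.** One guide per position of a transcript
region; the region handed to the tiler should already include the
intended extension (the `design_nt_tiling_for_gene` wrapper builds a CDS
±100 nt region via `extract_window`, which clips at linear ends), giving
`len(region) − spacer_len + 1` guides. `sense="sense"` emits
non-targeting sense controls (spacer = window).

**Oligo encoding.** The 100-nt synthesis layout is
`fwd_primer(20) | GGTCTC·N·AAAC(11) | spacer(31) | junction(1) |
TGCT·N·GAGACC(11) | rev_primer(20) | pad(6)`. The 1-nt junction preserves
the first base of the entry-vector terminator (default `A`); the pad and
the arbitrary base inside each BsaI element are drawn from the seed and
re-drawn (bounded) if they would create a spurious recognition site, so
assembly is a pure function of (guides, primers, seed). Simulated BsaI
digestion cuts `GGTCTC N↓NNNN`, releasing a 40-nt insert (AAAC overhang +
spacer + junction + TGCT tract) with 5' overhangs `AAAC` and `AGCA`
(bottom strand of TGCT) — the geometry Golden Gate cloning requires. Note
the element lengths sum to 100 nt while amplicon sizings of such pools are
sometimes quoted slightly shorter; this implementation follows the element
list. Oligos with any site count ≠ 2 are excluded before synthesis.

**Off-targets** are scanned Hamming-only (no indels, no G-U wobble)
against RBS windows (start codon ±35 nt of every gene) at ≤ 2 mismatches,
with same-gene matches suppressed. **Subpool primers** are found by seeded
random search: 20-nt, GC 40–60%, BsaI-free, pairwise Hamming ≥ 8 including
reverse complements; infeasible constraint sets fail after a bounded
number of draws rather than looping.

## Counting

Reads are expected to carry `…GGTTTGAAAC · spacer · ATGCTTGGGC…`. The
upstream anchor is located exactly first, then with ≤ 1 mismatch (the
fallback is optional and tallied separately); the `match_len` (default 30)
bases after it form the candidate; the downstream anchor must occur after
the candidate (≤ 1 mismatch) — *after*, not adjacent, because a 31-nt
library spacer leaves one base between the 30-nt candidate and the anchor.
The Phred floor (default 20) applies per base of the candidate, the
strictest reading of a minimum-quality filter; a mean-quality mode is
available. Assignment compares the candidate to the first `match_len`
bases of every library spacer and returns the unique minimum-Hamming
member within `max_mismatch` (default 2); ties are reported `ambiguous`,
not guessed. Every read ends in exactly one bucket, so
`assigned + Σ rejections = total` per sample. Read pairs are merged by the
longest overlap (≥ 10 nt) whose mismatch fraction is ≤ 0.1, disagreements
resolving to the higher-quality base.

## Fitness

1. **Decile QC.** Guides are ranked by mean count across baseline (MOI-0)
   samples; the bottom and top `floor(0.10·N)` are excluded. Filtering on
   the *unselected* condition only avoids biasing enrichment; an option
   exists to also filter test-condition extrema. Ties resolve by input
   order (stable sort) so reruns are identical. Below 10 guides the filter
   is skipped (a decile would be empty).
2. **Normalization.** Phage mode scales each post-QC sample column to a
   total of 10⁶ pseudocounts (column sums are exactly 10⁶, giving
   comparable fold-change denominators); the growth-assay mode adds 1 to
   every raw count and converts to reads per million.
3. **Guide log₂ fold-changes.** Phage mode divides each selected sample by
   the guide's mean baseline abundance, one log₂ ratio per replicate;
   `crrna_fitness` is the median across replicates and `mean_log2fc` the
   mean. The per-guide p is a two-sided one-sample t-test of the ratios
   against zero (NaN with < 2 replicates). The growth-assay mode averages
   test replicates before dividing by the T = 0 baseline; either the T = 0
   or a crRNA-only library can serve as that baseline.
4. **Gene-level K–S.** Each gene's guide fitness values are compared to
   the pooled values of *all* surviving guides (the gene's own included)
   with the one-sided statistic `D = sup [F_pool − F_gene]`, sensitive to
   right-shift only. `p = exp(−2 D² m n/(m+n))` with m = gene guides and
   n = pooled size; for genes with < 5 guides an exact
   enumeration/permutation p over m-subsets of the pool is available
   (`p_method="auto"`), since the asymptotic form is least accurate there.
   Gene fitness is the mean over replicates of the per-replicate mean of
   the gene's guide log₂ fold-changes — a stated convention, since
   guide→gene aggregation admits several orderings that differ only at
   the third decimal in practice.
5. **Classification.** The threshold T is the minimum fitness among genes
   with `p < α` *and* fitness above the genome median (restricting the
   threshold to the right tail; significant depletion is never
   interpreted, because phage predation at high MOI distorts the left
   tail). Fit ⇔ `fitness ≥ T` and `p < α`; Semi-fit ⇔ `fitness ≥ T` and
   `p ≥ α`; otherwise Not-fit. With no significant gene, all calls are
   Not-fit and T is reported as undefined. Boundary comparisons use
   exactly `≥` / `<` so reruns are bit-stable.

Per-guide effectiveness summaries (within-gene z-scores with population
sd, top-3 rank tallies per panel position, ties broken by position) and
plaque-assay arithmetic (efficiency of plaquing and plaque-size
fold-change as ratios of means, with the lysis-from-without convention of
1 p.f.u. at the most concentrated clearing) round out the module.

## Simulator

The generator emulates the *structure* of a pooled selection screen, not
infection mechanics: baseline guide abundances are log-normal(0, σ = 1)
(oligo synthesis and cloning skew); selection multiplies a guide's
expected share by `2^e` where the true enrichment e is 0 for guides of
non-fit genes and Normal(+4, 1) in log₂ units per guide of a fit gene
(log-normal guide-to-guide variability around the gene effect, the
dominant source of false negatives in such screens); counts are negative
binomial with size k = 10 (variance μ + μ²/10, matching overdispersed
deep-sequenced pools; k = None gives the Poisson limit) at 10⁶ reads per
sample, 3 replicates per MOI condition. Defaults follow the screen design
the package models: 200 genes with 7 guides each and 7.5% truly fit.
Synthetic genomes pack non-overlapping ATG…stop CDSs on both strands with
≥ 60 nt intergenic context so every RBS window exists. Reads are written
as `flank + upstream anchor + spacer + downstream anchor + flank` with
independent per-base substitution errors and Phred strings consistent
with the error rate. Everything is deterministic under the seed
(`numpy.random.default_rng` streams only).

What the simulator deliberately omits — PCR jackpotting, index hopping,
position-dependent guide efficacy, polar effects, phage population
dynamics — bounds what passing tests show: they validate the statistics
and bookkeeping of the pipeline, not its behavior on every artifact of
real libraries.

## Calibration behavior and known limitations

- The one-sided K–S Fit call at α = 0.05 has a measured per-gene type-I
  rate of ≈ 3% on null screens (7 guides/gene, pooled reference). Across
  a couple hundred tested genes this implies a handful of false Fit calls
  per screen near the threshold; the classification is calibrated as a
  per-gene error rate, not a screen-wide zero. No multiple-testing
  correction is applied, mirroring standard practice for this statistic.
- Because the pooled reference contains every gene's guides, strong true
  effects compress the fold-change scale of null genes (normalization is
  zero-sum), which shifts absolute fitness values but not the rank-based
  K–S calls.
- log₂ ratios of noisy counts carry a small negative (Jensen) bias; the
  median-across-replicates guide summary reduces but does not remove it.
- Anchored extraction is substitution-tolerant only; indel-containing
  reads are rejected rather than realigned.
- Problem sizes in the test-suite and acceptance runs (10-gene design
  genomes, 50-guide counting libraries, 100–200-gene screens, 200-seed
  null calibration at 2×10⁵ reads/sample) were chosen as the smallest
  instances at which every measured property is stable; all scale
  linearly if enlarged.
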