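# Methods

`refscaf` re-implements, as a reusable toolkit, a reference-guided assembly
workflow of the kind used to assemble large mammalian genomes from short
SOLiD-era reads by anchoring them to a related species' genome (a water
buffalo sequenced against the cattle reference is the motivating case).
This note records the models, rules, numerical choices, and the open design
decisions the implementation had to settle.

## Pipeline model

1. **Quality trimming.** A read is truncated immediately before the first
   base whose Phred quality drops below a floor (default Q15 ≈ 3% error);
   the offending base and everything after it are removed. Surviving
   prefixes shorter than `min_len` (default 30 bp) are discarded. This is a
   pure 3' suffix cut — no 5' trimming and no sliding window. Mates are
   trimmed independently; when one mate of a pair is discarded the survivor
   is demoted to fragment status so it still contributes to contigs but no
   longer to links. For even-sized runs the median read length is the mean
   of the two central values; a `floor_median` reporting flag reproduces
   tools that print truncated integer medians.

2. **Contig stitching.** Mapped reads arrive as SAM; each primary record
   with `MAPQ >= min_mapq` (default 0) is projected onto reference columns
   through its CIGAR (M/=/X consume read and reference, D emits a gap
   symbol, I is dropped, S/H consume only the read). Two placements are
   chained when their reference intervals share at least `min_overlap`
   bases (default 50 bp); contigs are the connected components of that
   relation, computed by a left-to-right sweep with union-find (the member
   with the greatest end bounds the best achievable overlap, so the sweep
   is exact; it is verified against an O(n²) all-pairs oracle). Per
   covered column the majority projected symbol is called; a majority gap
   deletes the column. Ties break by summed base quality, then the
   reference base when provided, then ASCII order — quality-weighted
   majority being the least surprising rule where no consensus rule is
   otherwise fixed. Insertions relative to the reference are not
   recovered: stitching against a reference locus is a reference-frame
   assembly, and recovering insertions would require a realignment stage
   this toolkit does not include. Unmapped reads are collected verbatim
   for an external de novo assembler.

3. **Mate verification.** Libraries carry an insert model
   (mean, SD, orientation). `ff` (same-strand, long-insert mate-pair
   chemistry) is the default orientation; `fr` (inward paired-end) is
   available. Each mate "points" toward its partner: along its own strand
   in `fr` for both mates and for the first mate in `ff`, against its
   strand for the second mate in `ff`. A pair on one contig is `intra`; a
   pair on two contigs is `spanning` when each mate lies within
   `end_window` of the contig end it points to, else `conflicting`
   (the geometric reading of a link joining contigs in a non-suffix–prefix
   manner). `end_window` defaults to `insert_mean + 3·insert_sd` — beyond
   that the implied gap is statistically implausible. The window must
   cover the insert distribution's actual support: against the synthetic
   generator, whose inserts are truncated at ±4 SD, the pipeline widens it
   to 4 SD (`end_window_sds=4.0`), since a 3 SD window provably
   misclassifies genuine 3–4 SD pairs straddling a junction as
   conflicting. A contig is
   **confirmed** with ≥ 3 intra pairs and zero conflicting links touching
   it; a single conflict demotes it (`--max-conflicts` relaxes this; the
   strict reading of "no conflicting pairs" argues for 0).

4. **Scaffolding.** The implied gap of a spanning pair is
   `insert_mean − d_a − d_b`, where `d_x` is the distance from the mate's
   outer coordinate to the gap-facing contig end; negative values mean
   contig overlap. Links bundle by (contig pair, orientation class):
   weight = link count, gap mean/SD over the bundle (SD of a singleton
   bundle is +∞ — least trusted); when orientation classes disagree for a
   pair only the heaviest class survives. Greedy path-merging then
   processes edges in deterministic order (weight descending, gap SD
   ascending, pair id) and accepts an edge only when both implicated
   contig ends are free termini of two different paths — no interior
   attachments, no cycles, and no flip of a contig already constrained
   relative to its path (whole paths may reverse). `min_weight` defaults
   to 3, mirroring the confirmation threshold, since no separate
   scaffolding threshold is otherwise fixed. Emission clamps gaps at
   `max(round(gap_mean), min_gap)` N characters (default 10); implied
   overlaps are *not* merged — no overlap-merge step is modelled.
   Greedy-by-weight can skip a very short contig flanked by two long ones
   when the long-insert edge across it outweighs the local edges; this is
   inherent to the algorithm family and is visible in the adjacency
   accuracy rather than hidden.

5. **Metrics.** N50/L50 use the minimal descending prefix holding ≥ 50% of
   total length. Ungapped length excludes `N`/`n` only; IUPAC ambiguity
   codes count as sequence. Repeat content is genomic *coverage*: per
   family and reference sequence, intervals are unioned before summing,
   so nested or re-reported hits never double-count. Because published
   repeat percentages are printed inconsistently (round-half-up
   vs truncation), both renderings are exposed.

6. **Synteny.** Whole-genome alignment segments (PAF) shorter than 100 bp
   on the reference are discarded; the rest are grouped per (reference,
   query, strand), midpoint-trimmed to remove reference overlaps
   (chaining requires disjointness; the symmetric split is unbiased), and
   chained while both the reference gap and the query gap stay within
   `max_join_gap` (default 50 kb — no coalescing gap is otherwise fixed,
   so it is exposed as `--max-gap`) and query order stays monotone
   (reverse-monotone on `-`). Strand inversions never join one block. A
   span filter (1 Mb, or 500 kb for fragmented assemblies) selects blocks
   for plotting. Gene-structure verification demands one scaffold, one
   strand, and exon scaffold-order matching transcript order (reversed on
   `-`); failures classify in the order split → strand_mixed → disordered.

## Synthetic data

The generator emulates the study design end to end, hermetically:

* **Genomes.** A uniform-random donor (optionally seeded with dispersed
  500 bp repeat motif copies) and a reference derived from it by
  substitutions at `divergence` (default 0.02, the right scale for
  related bovids) and 1–3 bp indels at `indel_rate` (default 0.001).
  Every edit is recorded; donor↔reference coordinate maps are kept.
* **Hypervariable patches.** Short regions (150–450 bp, ~1 per 20 kb,
  ≥ 5 kb apart, ~25% local divergence) where reads overlapping by ≥ 30%
  of their length are emitted unmapped. This models the one feature of
  real reference-guided assembly that uniform divergence cannot produce:
  mapping dropout. Patches are what break the assembly into contigs,
  create the gaps the mate libraries must bridge, and feed the
  unmapped-read collection.
* **Reads.** 75 bp fragments at 30× plus two `ff` mate libraries
  (1 kb ± 100 and 3 kb ± 300, 60 bp reads, 10× each), uniform starts,
  inserts truncated at ±4 SD, per-base errors at `base_error_rate`
  (default 0.01). Qualities follow a linearly decaying mean (start Q30)
  with Gaussian per-cycle noise (SD 2). The mean profile crosses the Q15
  floor at `quality_cross_frac · read_len`, default 1.6 — i.e. past the
  read end, producing mild 3' tail trimming. The crossing deliberately
  sits beyond the read: under the 50 bp pairwise stitching rule a read
  trimmed below 50 bp can never chain and degenerates into a nested
  single-read contig, so a heavy-trimming default would reduce the whole
  assembly to read-sized fragments. Heavy-trimming regimes (crossing at
  ~0.7·read_len) remain available by configuration for studying the
  trimmer, and the trimming rule itself is exercised exhaustively at unit
  level.
* **Alignments.** SAM is derived from the known truth (trimming-aware,
  CIGARs computed through the edit map, coordinate-sorted), so no
  external mapper is needed and the mapped-reads input boundary is
  reproduced exactly.
* **Determinism.** One integer seed drives a single `numpy` Generator;
  outputs are byte-identical across runs and platforms.

What the generator does **not** emulate: color-space encoding and
machine-specific error profiles, GC/coverage bias, chimeric pairs, and
genome-scale repeat families long enough to defeat unique anchoring.
Passing recovery benchmarks therefore demonstrate the pipeline's logic
(stitching, classification, path-merging, bookkeeping), not robustness to
every artefact of real SOLiD data.

## Truth evaluation

`truth_evaluate` scores an assembly against the simulation: donor coverage
(union of contig anchors lifted through the edit map), consensus identity
(length-weighted edit-distance identity of each contig against its donor
window, via edlib), and adjacency accuracy (fraction of truly neighbouring
contig pairs placed next to each other, correctly oriented, in a scaffold
path). True neighbours are defined over the *backbone* tiling: a contig
whose anchor lies inside another contig's anchor — e.g. a single
over-trimmed read nested mid-contig — has no meaningful left/right
neighbour and is excluded from the adjacency denominator (it still counts
toward coverage and identity).

## Benchmark problem sizes

The canonical recovery run uses a 2 Mb donor with the default read model
(~1.47 M reads): large enough for ~100 contigs and non-trivial
scaffolding statistics, small enough for a single CPU in a few minutes.
Unit and property tests use 10–100 kb genomes. Expected recovery under
the canonical conditions: donor coverage ≈ 98.7% (the unmappable patches
bound it), consensus identity ≈ 99.9% (residual loss is donor bases absent
from the reference frame), adjacency accuracy ≈ 100%, zero conflicting
links.

## Known limitations

* Reference-frame assembly cannot recover donor insertions relative to
  the reference; consensus identity is bounded by the indel rate.
* The greedy path-merger is locally optimal only; the short-contig skip
  described above is the typical failure mode.
* Repeat-aware anchoring is out of scope: with `repeat_fraction` high
  enough to create multi-copy ambiguity, truth-derived alignments place
  reads at their true copy, which a real mapper could not guarantee.
* The AGP writer emits only W and scaffold-gap N lines (linkage
  "paired-ends"); chromosome-level objects are not modelled.
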