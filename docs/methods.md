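# Methods

This note documents the models and procedures behind `genomeaudit`, the
parameter defaults and why they were chosen, the numerical and design
decisions made where several reasonable options existed, and what the
synthetic fixtures do and do not demonstrate about real data.

## Whole-genome comparison

### Anchoring

Two assemblies are first related through *maximal unique exact matches*:
a k-mer (default k = 24) seeds a match only when it occurs exactly once on
the reference forward strand and exactly once across both query strands.
Seeds are found by 2-bit-encoding every k-mer into a 64-bit word (windows
containing ambiguous bases are skipped), intersecting the unique sets of
the two genomes, merging seeds that overlap on one alignment diagonal, and
extending each merged run outward as far as the sequences stay identical.
Extension never crosses an N: ambiguous bases are not matches.

The uniqueness requirement deliberately ignores repeated sequence. Inside
a long exact region interrupted only by a repeat, extension still carries
anchors through the repeat, so unique flanks recover the full match; what
the method does not attempt is repeat-resolved alignment of genuinely
repetitive genomes (see *Limitations*).

The minimum anchor length of 24 keeps the chance of a spurious unique
match between unrelated 2 Mb sequences negligible (≈ L² / 4²⁴ per
diagonal class) while remaining much shorter than any planted or
biologically interesting event.

### Chaining and gap closing

Anchors on one (reference contig, query contig, strand) combination are
chained greedily in reference order when the reference-side and query-side
gaps are both at most `gap_limit` (default 1,000 bp) and roughly balanced
(diagonal offset change ≤ `gap_limit`). Each inter-anchor gap is closed
with an end-to-end edit-distance alignment (edlib, extended CIGAR), whose
identity columns feed the block's match count; small anchor overlaps at
chain joins are trimmed inside the exact runs, where reference and query
advance together and a trim is loss-free. The 1,000 bp default matches
the scale below which short fragments are considered noise throughout the
package (the same cutoff as the short-contig pre-filter).

The chained blocks are then filtered to a **1-to-1 set**: blocks are
accepted in decreasing match order, and a candidate overlapping an
accepted block on either genome is trimmed at its edges (inside its
terminal exact runs) or dropped. The output therefore covers each genome
at most once, which makes aligned-base fractions well defined and keeps
variant calls unambiguous.

### Variant calls

Within each 1-to-1 block the composed alignment is walked column by
column: mismatch columns become SNPs; each maximal gap run becomes one
insertion or deletion call. Indels are left-normalized (shifted left while
the flanking base allows), positions are reference coordinates, 0-based
half-open internally and 1-based in reports and VCF. Calls whose alleles
contain N are suppressed and logged. VCF output anchors indels on the
preceding reference base per convention.

### Structural events

Events are junction-level features of the 1-to-1 block layout, counted
per displaced *run* rather than per junction. For each reference contig:

1. The dominant (query contig, strand) is the one covering the most
   reference bases; among its blocks, the maximum-weight subsequence with
   consistent query order (weighted LIS) forms the *backbone*.
2. Every maximal run of non-backbone blocks yields exactly one event:
   **translocation** when the run maps to a different query contig,
   **inversion** when it maps in the opposite orientation, **relocation**
   otherwise.
3. A junction between reference-adjacent backbone blocks whose diagonal
   offset jumps by more than `gap_limit` is one additional relocation —
   unless the query-side gap between them is occupied by other aligned
   blocks, in which case the jump is the re-insertion site of material
   already counted as its own displaced-run event and is not counted
   twice.

This run-merged counting is a published, tested definition of this
package; alignment-based rearrangement counts are not standardized across
tools, and per-junction counts would systematically double-count a simple
relocation (one junction at the excision site, one at the insertion site).
The raw junction structure remains available from the blocks table.

### Summary statistics

Aligned fraction is the union of block spans divided by genome length,
per side. ANI is `100 x Σmatches / Σcolumns` over the 1-to-1 blocks — an
alignment-identity statistic comparable to, but not parameter-identical
with, other published ANI estimators; self-comparisons yield exactly
100.0. Comparisons run after dropping contigs shorter than 1 kb so short
fragments cannot exaggerate structural counts.

## Variant consequences

Gene models are single- or multi-interval CDS features (GFF3, phase
honored). Coding SNPs are classified by translating the affected codon,
strand-aware, under NCBI translation table 11; a first-codon change that
destroys a valid table-11 start codon is `start_lost`. Coding indels are
`frameshift` when the CDS-overlapping length is not a multiple of three,
`inframe_indel` otherwise — an indel straddling a CDS boundary is judged
by its CDS-overlapping part. Non-coding variants within 1,000 nt of a
gene are `upstream`/`downstream` relative to gene orientation; otherwise
`intergenic`. When a variant touches several genes, the most severe
consequence is reported (severity order: frameshift > stop_gained >
stop_lost > start_lost > missense > inframe_indel > synonymous) and all
per-gene calls are retained on the annotation.

Tallies group all protein-altering classes — missense, frameshift,
start/stop loss, stop gain, and in-frame indels — as *nonsynonymous*;
upstream, downstream and intergenic calls are *other*; synonymous stands
alone, so the three groups always sum to the variant count. In-frame
indels are placed in the nonsynonymous group because they change the
protein; reporting conventions that enumerate example classes rather than
a partition leave this placement open, and count conservation forces a
choice. "Duplicate variants" is reported as the number of exact-duplicate
call records (same contig, position, kind, alleles).

## Metadata audit

A value counts as empty when its trimmed, case-folded form is one of
`"", na, n/a, unknown, missing, not provided, not applicable, none,
other` — a configurable lexicon whose defaults are the placeholder entries
actually observed in public records. A field absent from a record counts
as empty as well, since record dialects simply omit never-filled lines;
audits that should distinguish the two can run on each dialect separately.
Field names are matched case-insensitively with punctuation stripped
because the two NCBI dialects spell the same field differently.

Strain labels are matched with
`(ATCC|NCTC)[\s\-_]*\d{1,6}[A-Za-z]?`, covering the separator variants
seen in the wild without over-matching longer digit strings. NCTC→ATCC
synonymy is always an explicit input table, never inferred: cross-
collection identity is curated knowledge, not derivable from the records.

## Equivalence statistics

* N50 equivalence: `ratio = N50_ours / N50_public`, equivalent-or-superior
  iff `ratio >= 0.95`, boundary inclusive.
* Log ratios are base 2 (stated in output headers), so swapping a pair
  negates the value.
* Extreme outliers: values strictly above `median + 3 x (Q3 - Q1)`;
  quartiles use linear interpolation between order statistics (the common
  default; the choice is pinned by oracle tests). With an all-equal input
  the fence collapses to the median and nothing is flagged.
* Enrichment folds are ratios of group means by default (medians
  available); a zero denominator reports not-computable rather than a
  value. No significance testing is attached to folds.

## Synthetic fixtures

The simulator emulates what the audit pipeline consumes: bacterial-scale
multi-replicon genomes (i.i.d. bases at a controlled GC), public
counterparts derived by a `MutationPlan` of planted events, fragmented
drafts, planted CDS genes (ATG + sense codons + stop, both strands), and
metadata with controlled imperfections. Defaults describe a plausible
strain-vs-deposited-assembly divergence — tens of SNPs, a few short
indels, zero-to-few kb-scale rearrangements per genome, a 40%-missing
"sequencing technology" field — but true divergence between deposited
isolates and authenticated material is unknown and strain-specific, so
these are fixture conditions, not estimates.

Fixture identifiability is engineered, not assumed:

* **Bounded repeats**: `max_repeat` (default 19 in fixtures) rejects and
  resamples any duplicated (max_repeat+1)-mer across strands and
  replicons, so every ≥24 bp anchor is unique and planted-event recovery
  is not confounded by spurious matches.
* **Unambiguous indels**: planted insertion payloads mismatch both flanks
  and deleted runs cannot shift, so the left-normalized call position is
  unique and must equal the planted coordinate.
* **Event spacing**: all events are placed with a clearance margin
  (default 120 bp, ≥ 60 bp in tests) so the planted edit set is also the
  unique optimal alignment; two edits placed a few bases apart can have a
  cheaper joint representation, which is an ambiguity of truth, not an
  alignment error.
* **Relocation distance**: moved blocks travel more than `gap_limit`, the
  scale below which coordinate jumps are treated as alignment noise.

Consequently, passing recovery tests demonstrates correctness of the
alignment, calling, classification and audit logic under identifiable
conditions. They do not demonstrate performance on repeat-rich genomes,
on diverged strains (>>1% distance), on real indel-in-homopolymer
ambiguity, or on the adversarial messiness of real database metadata
beyond the planted imperfection classes.

## Numerical and degenerate-input choices

* N50 ties: when the cumulative sum exactly reaches half the total, that
  contig is the N50 (≥ rule); N90 analogous.
* GC denominator excludes IUPAC-ambiguous bases, keeping GC ≤ 1 on gapped
  scaffolds. Runs of ≥10 N are counted as scaffold gaps but sequences are
  never split, since public assemblies do not reliably distinguish contigs
  from scaffolds.
* "Aberrant depth" in the chaff filter is a fold-from-median parameter
  (default 3); both the length and the depth condition must hold.
* Deterministic tie-breaks everywhere: block selection orders by
  (matches, ref id, ref start), table rows sort by key, and every random
  generator is seeded.
* Empty inputs raise `ValueError` early (empty assemblies, zero-length
  contigs, empty groups, <4 values for the outlier fence) rather than
  propagating NaNs.

## Known limitations

* Anchoring is unique-match based: genuinely repetitive or highly
  rearranged repeat families yield unaligned or fragmented blocks, and
  breakpoint coordinates inside long repeats are not base-precise.
* ANI is computed from 1-to-1 alignment blocks and is not numerically
  identical to k-mer or BLAST-based ANI estimators.
* The consequence classifier handles CDS features only — no regulatory
  motifs, no splice logic, no protein-impact scoring.
* The simulator does not model sequencing error, plasmid copy number, or
  phylogenetically realistic divergence; it provides planted ground truth,
  not realism.
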