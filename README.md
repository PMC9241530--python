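# genomeaudit

Tooling for auditing how well public bacterial genome assemblies and their
database records represent the authenticated biological material they claim
to describe. Given a reference-grade assembly for a strain (e.g. one built
from a biorepository's own material) and any public counterpart, the
package quantifies how the two differ — in contiguity, composition,
sequence, structure, and predicted protein consequences — and audits the
public record's descriptor metadata for completeness, duplicated strain
claims, and contradictory provenance labels.

It is aimed at comparative-genomics and data-curation work where the
question is not "which assembly is newer" but "are these two genomes
equivalent representations of the same strain, and can the public record's
provenance be trusted".

## What it computes

**Assembly metrics** (`genomeaudit.metrics`) — N50/L50/N90, GC content,
length and contig-count summaries. N50 is the length of the contig at
which the cumulative sum of descending-sorted contig lengths first reaches
half the assembly size; L50 is its rank. GC excludes ambiguous bases from
numerator and denominator. Includes the `<1 kb` contig pre-filter and a
chaff filter (short **and** depth-aberrant contigs).

**Metadata audit** (`genomeaudit.metadata`) — parses both NCBI metadata
dialects (tab-delimited `assembly_summary` rows and `key: value` assembly
reports), counts fields that are empty or carry placeholder entries
("na", "unknown", "other", ...), extracts and normalizes ATCC/NCTC strain
labels across their separator variants, selects ATCC-traceable records
(NCTC-only records survive only through a curated synonym table), reports
strain keys claimed by multiple accessions, and flags records labeled as
type material while described as genetically modified.

**Whole-genome comparison** (`genomeaudit.compare`) — anchors the two
assemblies on maximal unique exact matches (both strands), chains
collinear anchors, closes small gaps with end-to-end edit-distance
alignment, reduces the result to a 1-to-1 block set, and derives:

* SNP and run-length-collapsed indel calls (left-normalized, reference
  coordinates, N-overlapping calls suppressed),
* structural events — *relocations* (order-inconsistent or large-offset
  blocks on the same replicon), *inversions* (opposite-orientation runs)
  and *translocations* (blocks mapping to a different replicon), one event
  per displaced run,
* aligned-base fractions of each genome and ANI, computed as
  `100 x matches / alignment columns` over the 1-to-1 blocks.

**Variant consequences** (`genomeaudit.effects`) — classifies calls
against CDS annotations under the bacterial genetic code (translation
table 11): synonymous / missense / stop_gained / stop_lost / start_lost
for coding SNPs, frameshift / inframe_indel for coding indels,
upstream / downstream within 1,000 nt of a gene (strand-aware), intergenic
otherwise. Tallies group every protein-altering class as nonsynonymous.

**Equivalence statistics** (`genomeaudit.stats`) — N50-ratio equivalence
(`ratio >= 0.95` counts as equivalent-or-superior), base-2 log-ratio
tables, signed GC deltas in percentage points, extreme-outlier detection
(values above `median + 3*IQR`), and category enrichment folds
(ratio of group means).

**Synthetic fixtures** (`genomeaudit.simulate`) — seeded multi-replicon
genomes with controlled GC and optionally bounded repeat length, mutated
counterparts with planted SNPs/indels/inversions/relocations/
translocations recorded in a ground-truth `MutationPlan`, fragmented
draft versions, planted CDS gene models, and metadata sets with controlled
missingness, strain-label variants and duplicate groups. Every generator
is a pure function of its arguments including the seed.

## Worked example

Simulate a strain fixture and audit it end to end:

```
$ genomeaudit simulate --outdir demo --seed 7
$ genomeaudit metrics demo/truth.fasta demo/public_draft.fasta
Assembly      Genome assembly size  Total contigs  N50     L50  N90
truth         280000                2              200000  1    80000
public_draft  279986                8              53833   2    13055
```

The fragmented public counterpart has the same genome size but an N50 of
53.8 kb against the truth assembly's 200 kb — an N50 ratio of 0.27, well
below the 0.95 equivalence threshold.

```
$ genomeaudit compare --ref demo/truth.fasta --qry demo/public.fasta -o demo/cmp
{
  "RefAlignedBase%": 99.99892857142856,
  "QueryAlignedBase%": 99.99892851785447,
  "ANI": 99.96678856098049,
  "SNPs": 25,
  "Indels": 8,
  "RefRelocations": 1,
  "RefInversions": 1,
  "RefTranslocations": 1,
  "TotalSVs": 3
}
```

Over 99.99% of each genome aligns and ANI is 99.97%, yet the comparison
still uncovers 25 SNPs, 8 indels and three structural rearrangements —
exactly the edits this fixture planted; high ANI alone does not mean two
assemblies are interchangeable.

```
$ genomeaudit effects --vcf demo/cmp/variants.vcf --gff demo/genes.gff3 \
      --ref demo/truth.fasta -o demo/eff
{
  "TotalVariants": 33,
  "TotalSynonymous": 2,
  "TotalNonsynonymous": 0,
  "TotalOther": 31,
  ...
}
```

Synonymous + nonsynonymous + other always equals the variant count.
`genomeaudit audit-metadata` and `genomeaudit stats` audit the simulated
record set and join per-comparison outputs into the three report tables
(equivalence, alignment, variants).

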