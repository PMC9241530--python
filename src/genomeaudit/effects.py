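"""Variant-consequence classification against bacterial CDS annotations.

SNPs falling in a coding sequence are classified by strand-aware codon
translation under the bacterial genetic code (NCBI table 11):
synonymous, missense, stop_gained, stop_lost, or start_lost (start codons
per table 11).  Coding indels are frameshift when their length is not a
multiple of three, inframe_indel otherwise.  Variants outside any CDS are
upstream/downstream when within 1,000 nt of a gene (strand-aware), else
intergenic.

Counts are grouped the way comparative audits report them: nonsynonymous
collects every protein-altering class (missense, frameshift, start/stop
loss, stop gain, in-frame indels); upstream/downstream/intergenic fall
under "other"; synonymous stands alone.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .assembly import GenomeAssembly, revcomp
from .compare import VariantCall

__all__ = [
    "GeneModel",
    "EffectAnnotation",
    "EffectTally",
    "classify_variant",
    "classify_variants",
    "tally_effects",
    "read_gff3",
    "write_gff3",
]

logger = logging.getLogger(__name__)

PROXIMITY_LIMIT = 1000  # nt; beyond this a non-coding variant is intergenic

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
START_CODONS = frozenset(_TABLE11.start_codons)

#: most to least severe; ties across genes resolve to the earlier entry
SEVERITY_ORDER = (
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense",
    "inframe_indel",
    "synonymous",
    "upstream",
    "downstream",
    "intergenic",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "frameshift", "start_lost", "stop_lost", "stop_gained",
     "inframe_indel"}
)
OTHER_CLASSES = frozenset({"upstream", "downstream", "intergenic"})


@dataclass(frozen=True)
class GeneModel:
    """A (possibly multi-interval) CDS gene model.

    ``cds_intervals`` are 0-based half-open genomic intervals in ascending
    genomic order; for minus-strand genes translation runs through them in
    reverse.  ``phase`` is the number of bases to skip before the first
    complete codon (GFF3 phase of the 5'-most CDS segment).
    """

    gene_id: str
    ref_id: str
    strand: str
    cds_intervals: Tuple[Tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.cds_intervals))
        for (a, b) in ivs:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty CDS interval {(a, b)}")
        for (_, b1), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        object.__setattr__(self, "cds_intervals", ivs)
        if self.phase not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: phase must be 0, 1, or 2")

    @property
    def start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        return self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_intervals)

    def genomic_positions(self) -> List[int]:
        """Genomic positions of CDS bases in translation (5'->3') order."""
        pos = [p for a, b in self.cds_intervals for p in range(a, b)]
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_sequence(self, ref: GenomeAssembly) -> str:
        seq = ref[self.ref_id]
        parts = "".join(seq[a:b] for a, b in self.cds_intervals)
        if self.strand == "-":
            parts = revcomp(parts)
        return parts[self.phase :]


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantCall
    consequence: str
    gene_id: Optional[str] = None
    all_consequences: Tuple[Tuple[str, str], ...] = ()  # (gene_id, consequence)


def _variant_span(v: VariantCall) -> Tuple[int, int]:
    """Genomic footprint: SNP/deletion cover bases; insertion is a point."""
    if v.kind == "snp":
        return v.position, v.position + 1
    if v.kind == "deletion":
        return v.position, v.position + len(v.ref_allele)
    return v.position, v.position  # insertion: between-base point


def _overlaps_cds(v: VariantCall, gene: GeneModel) -> int:
    """Bases of the variant footprint inside the gene's CDS (insertions: 1 if interior)."""
    s, e = _variant_span(v)
    if v.kind == "insertion":
        # an insertion disrupts the CDS only when strictly inside it
        return 1 if any(a < s < b for a, b in gene.cds_intervals) else 0
    return sum(max(0, min(e, b) - max(s, a)) for a, b in gene.cds_intervals)


def _classify_snp_in_cds(v: VariantCall, gene: GeneModel, ref: GenomeAssembly) -> str:
    positions = gene.genomic_positions()[gene.phase :]
    try:
        cds_pos = positions.index(v.position)
    except ValueError:
        # within the phase-trimmed overhang: no complete codon affected
        return "synonymous"
    codon_idx = cds_pos // 3
    codon_positions = positions[3 * codon_idx : 3 * codon_idx + 3]
    if len(codon_positions) < 3:
        return "synonymous"  # trailing partial codon
    seq = ref[gene.ref_id]
    complement = str.maketrans("ACGTN", "TGCAN")

    # codon_positions are already in translation (5'->3') order, so minus-strand
    # codons need per-base complementing without a second reversal
    def build(alt: Optional[str]) -> str:
        out = []
        for p in codon_positions:
            b = seq[p] if (alt is None or p != v.position) else alt
            out.append(b)
        codon = "".join(out)
        if gene.strand == "-":
            codon = codon.translate(complement)
        return codon

    ref_codon = build(None)
    alt_codon = build(v.alt_allele)
    if "N" in ref_codon or "N" in alt_codon:
        return "synonymous"
    if codon_idx == 0 and gene.phase == 0:
        if ref_codon in START_CODONS and alt_codon not in START_CODONS:
            return "start_lost"
    ref_aa = str(Seq(ref_codon).translate(table=11))
    alt_aa = str(Seq(alt_codon).translate(table=11))
    if ref_aa == alt_aa:
        return "synonymous"
    if ref_aa == "*":
        return "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "missense"


def _classify_for_gene(v: VariantCall, gene: GeneModel, ref: GenomeAssembly) -> Optional[str]:
    """Consequence of ``v`` on one gene, or None when the variant is outside its CDS."""
    overlap = _overlaps_cds(v, gene)
    if overlap == 0:
        return None
    if v.kind == "snp":
        return _classify_snp_in_cds(v, gene, ref)
    # indel: judged by the CDS-overlapping part
    if v.kind == "insertion":
        changed = len(v.alt_allele)
    else:
        changed = overlap
    return "frameshift" if changed % 3 != 0 else "inframe_indel"


def _nearest_gene_class(
    v: VariantCall, genes: Sequence[GeneModel], limit: int = PROXIMITY_LIMIT
) -> Tuple[str, Optional[str]]:
    s, e = _variant_span(v)
    best: Tuple[int, str, Optional[str]] = (limit + 1, "intergenic", None)
    for g in genes:
        if g.ref_id != v.ref_id:
            continue
        if e <= g.start:
            dist = g.start - e + 1
            side = "upstream" if g.strand == "+" else "downstream"
        elif s >= g.end:
            dist = s - g.end + 1
            side = "downstream" if g.strand == "+" else "upstream"
        else:
            dist, side = 0, "upstream"  # inside gene span but outside CDS intervals
        if dist < best[0]:
            best = (dist, side, g.gene_id)
    if best[0] <= limit:
        return best[1], best[2]
    return "intergenic", None


def classify_variant(
    v: VariantCall, genes: Sequence[GeneModel], ref: GenomeAssembly
) -> EffectAnnotation:
    """Classify one variant call against a set of gene models.

    When a variant touches several genes the most severe consequence is
    reported (all per-gene calls are kept in ``all_consequences``).
    """
    if v.ref_id not in ref:
        raise ValueError(f"variant contig {v.ref_id!r} not in reference")
    if _variant_span(v)[1] > len(ref[v.ref_id]):
        raise ValueError(f"variant at {v.ref_id}:{v.position} beyond contig end")
    per_gene: List[Tuple[str, str]] = []
    for gene in genes:
        if gene.ref_id != v.ref_id:
            continue
        cons = _classify_for_gene(v, gene, ref)
        if cons is not None:
            per_gene.append((gene.gene_id, cons))
    if per_gene:
        gene_id, consequence = min(
            per_gene, key=lambda gc: _SEVERITY_RANK[gc[1]]
        )
        if len(per_gene) > 1:
            logger.debug("variant %s:%d hits %d genes: %s",
                         v.ref_id, v.position, len(per_gene), per_gene)
        return EffectAnnotation(v, consequence, gene_id, tuple(per_gene))
    consequence, gene_id = _nearest_gene_class(v, genes)
    return EffectAnnotation(v, consequence, gene_id)


def classify_variants(
    variants: Sequence[VariantCall], genes: Sequence[GeneModel], ref: GenomeAssembly
) -> List[EffectAnnotation]:
    return [classify_variant(v, genes, ref) for v in variants]


@dataclass
class EffectTally:
    counts: Dict[str, int] = field(default_factory=dict)
    n_variants: int = 0
    n_duplicate_records: int = 0

    @property
    def synonymous(self) -> int:
        return self.counts.get("synonymous", 0)

    @property
    def nonsynonymous(self) -> int:
        return sum(self.counts.get(c, 0) for c in NONSYNONYMOUS_CLASSES)

    @property
    def other(self) -> int:
        return sum(self.counts.get(c, 0) for c in OTHER_CLASSES)


def tally_effects(
    annotations: Sequence[EffectAnnotation],
) -> EffectTally:
    """Aggregate consequence counts into the standard reporting groups.

    Exact-duplicate variant records (same contig, position, kind, alleles)
    are counted in ``n_duplicate_records`` but every record contributes to
    the class counts, so synonymous + nonsynonymous + other equals the
    number of inputs.
    """
    counts = Counter(a.consequence for a in annotations)
    seen = Counter(
        (a.variant.ref_id, a.variant.position, a.variant.kind,
         a.variant.ref_allele, a.variant.alt_allele)
        for a in annotations
    )
    n_dup = sum(c - 1 for c in seen.values() if c > 1)
    return EffectTally(dict(counts), n_variants=len(annotations), n_duplicate_records=n_dup)


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Read CDS gene models from a GFF3 file (phase column honored).

    CDS features sharing an ID (or Parent) are merged into one model.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: Dict[str, List] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [None])[0]
        gid = parent or cds.attributes.get("ID", [cds.id])[0]
        by_gene.setdefault(gid, []).append(cds)
    models = []
    for gid, parts in by_gene.items():
        parts.sort(key=lambda f: f.start)
        strand = parts[0].strand
        five_prime = parts[0] if strand == "+" else parts[-1]
        phase = int(five_prime.frame) if five_prime.frame in ("0", "1", "2") else 0
        models.append(
            GeneModel(
                gene_id=gid,
                ref_id=parts[0].seqid,
                strand=strand,
                cds_intervals=tuple((f.start - 1, f.end) for f in parts),
                phase=phase,
            )
        )
    models.sort(key=lambda g: (g.ref_id, g.start))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path,
               ref: GenomeAssembly | None = None) -> None:
    """Write gene models as GFF3 (gene + CDS features)."""
    lines = ["##gff-version 3"]
    if ref is not None:
        for name, seq in ref.contigs():
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in sorted(genes, key=lambda g: (g.ref_id, g.start)):
        lines.append(
            "\t".join([g.ref_id, "genomeaudit", "gene", str(g.start + 1),
                       str(g.end), ".", g.strand, ".", f"ID=gene-{g.gene_id}"])
        )
        ivs = list(g.cds_intervals)
        phases = _cds_phases(g)
        for (a, b), ph in zip(ivs, phases):
            lines.append(
                "\t".join([g.ref_id, "genomeaudit", "CDS", str(a + 1), str(b),
                           ".", g.strand, str(ph),
                           f"ID=cds-{g.gene_id};Parent=gene-{g.gene_id}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _cds_phases(g: GeneModel) -> List[int]:
    """Per-interval GFF3 phases walking 5'->3'."""
    ivs = list(g.cds_intervals)
    order = ivs if g.strand == "+" else ivs[::-1]
    phases_in_order = []
    consumed = -g.phase
    for a, b in order:
        phases_in_order.append((-consumed) % 3)
        consumed += b - a
    return phases_in_order if g.strand == "+" else phases_in_order[::-1]


def effect_table(annotations: Sequence[EffectAnnotation]):
    """Per-variant effect annotations as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig": a.variant.ref_id,
                "position": a.variant.position + 1,  # 1-based for reports
                "kind": a.variant.kind,
                "ref": a.variant.ref_allele,
                "alt": a.variant.alt_allele,
                "consequence": a.consequence,
                "gene_id": a.gene_id or "",
            }
            for a in annotations
        ]
    )
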