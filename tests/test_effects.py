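"""Consequence classifier vs a whole-CDS brute-force translation oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from genomeaudit.assembly import GenomeAssembly
from genomeaudit.compare import VariantCall
from genomeaudit.effects import (
    EffectAnnotation,
    GeneModel,
    START_CODONS,
    classify_variant,
    classify_variants,
    read_gff3,
    tally_effects,
    write_gff3,
)
from genomeaudit.simulate import plan_cds_snps


def apply_to_cds(cds: str, v: VariantCall, gene: GeneModel) -> str:
    """Oracle helper: replay a genomic variant on the CDS sequence itself."""
    positions = gene.genomic_positions()
    comp = str.maketrans("ACGTN", "TGCAN")
    if v.kind == "snp":
        i = positions.index(v.position)
        base = v.alt_allele if gene.strand == "+" else v.alt_allele.translate(comp)
        return cds[:i] + base + cds[i + 1 :]
    if v.kind == "deletion":
        idx = sorted(
            positions.index(p)
            for p in range(v.position, v.position + len(v.ref_allele))
            if p in set(positions)
        )
        out = [c for i, c in enumerate(cds) if i not in set(idx)]
        return "".join(out)
    # insertion before genomic position v.position
    if gene.strand == "+":
        i = positions.index(v.position)
        return cds[:i] + v.alt_allele + cds[i:]
    i = positions.index(v.position - 1)
    return cds[:i] + str(Seq(v.alt_allele).reverse_complement()) + cds[i:]


def oracle_class(cds: str, mutated_cds: str) -> str:
    """Brute-force class from full-CDS translation of truth vs mutant."""
    if len(mutated_cds) % 3 != 0:
        return "frameshift"
    p1 = str(Seq(cds).translate(table=11))
    p2 = str(Seq(mutated_cds).translate(table=11))
    if len(cds) != len(mutated_cds):
        return "inframe_indel"
    if p1 == p2:
        if cds[:3] in START_CODONS and mutated_cds[:3] not in START_CODONS:
            return "start_lost"
        return "synonymous"
    if cds[:3] in START_CODONS and mutated_cds[:3] not in START_CODONS:
        return "start_lost"
    diffs = [(a, b) for a, b in zip(p1, p2) if a != b]
    ref_aa, alt_aa = diffs[0]
    if ref_aa == "*":
        return "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "missense"


class TestSnpClassification:
    def test_third_position_synonymous_plus_strand(self):
        # GCA -> GCG: Ala -> Ala at the wobble position
        genome = GenomeAssembly("g", {"c": "ATG" + "GCA" + "TAA" + "ACGT" * 300})
        gene = GeneModel("g1", "c", "+", ((0, 9),))
        v = VariantCall("c", 5, "snp", "A", "G")
        assert classify_variant(v, [gene], genome).consequence == "synonymous"

    def test_missense(self):
        genome = GenomeAssembly("g", {"c": "ATG" + "GCA" + "TAA" + "ACGT" * 300})
        gene = GeneModel("g1", "c", "+", ((0, 9),))
        v = VariantCall("c", 4, "snp", "C", "A")  # GCA -> GAA, Ala -> Glu
        assert classify_variant(v, [gene], genome).consequence == "missense"

    def test_stop_gained_and_lost(self):
        genome = GenomeAssembly("g", {"c": "ATG" + "TGC" + "TAA" + "ACGT" * 300})
        gene = GeneModel("g1", "c", "+", ((0, 9),))
        gained = VariantCall("c", 5, "snp", "C", "A")  # TGC -> TGA
        lost = VariantCall("c", 8, "snp", "A", "C")  # TAA -> TAC (Tyr)
        assert classify_variant(gained, [gene], genome).consequence == "stop_gained"
        assert classify_variant(lost, [gene], genome).consequence == "stop_lost"

    def test_start_lost(self):
        genome = GenomeAssembly("g", {"c": "ATG" + "TGC" + "TAA" + "ACGT" * 300})
        gene = GeneModel("g1", "c", "+", ((0, 9),))
        v = VariantCall("c", 1, "snp", "T", "C")  # ATG -> ACG, not a start
        assert classify_variant(v, [gene], genome).consequence == "start_lost"


class TestIndelClassification:
    def make(self):
        genome = GenomeAssembly("g", {"c": "ATG" + "GCA" * 20 + "TAA" + "A" * 2000})
        gene = GeneModel("g1", "c", "+", ((0, 66),))
        return genome, gene

    def test_one_bp_deletion_is_frameshift(self):
        genome, gene = self.make()
        v = VariantCall("c", 10, "deletion", "C", "")
        assert classify_variant(v, [gene], genome).consequence == "frameshift"

    def test_three_bp_insertion_is_inframe(self):
        genome, gene = self.make()
        v = VariantCall("c", 10, "insertion", "", "TTT")
        assert classify_variant(v, [gene], genome).consequence == "inframe_indel"


class TestNonCoding:
    def make(self):
        genome = GenomeAssembly("g", {"c": "A" * 5000})
        plus = GeneModel("gp", "c", "+", ((2000, 2300),))
        minus = GeneModel("gm", "c", "-", ((4000, 4300),))
        return genome, [plus, minus]

    def test_upstream_downstream_strand_aware(self):
        genome, genes = self.make()
        before_plus = VariantCall("c", 1500, "snp", "A", "G")
        after_plus = VariantCall("c", 2800, "snp", "A", "G")
        assert classify_variant(before_plus, genes, genome).consequence == "upstream"
        a = classify_variant(after_plus, genes, genome)
        assert a.consequence == "downstream" and a.gene_id == "gp"
        after_minus = VariantCall("c", 4500, "snp", "A", "G")
        assert classify_variant(after_minus, genes, genome).consequence == "upstream"

    def test_intergenic_beyond_1kb(self):
        genome, genes = self.make()
        v = VariantCall("c", 200, "snp", "A", "G")  # 1800 nt from nearest gene
        ann = classify_variant(v, genes, genome)
        assert ann.consequence == "intergenic" and ann.gene_id is None

    def test_boundary_at_exactly_1000nt(self):
        genome, genes = self.make()
        v = VariantCall("c", 1000, "snp", "A", "G")  # exactly 1000 nt upstream
        assert classify_variant(v, genes, genome).consequence == "upstream"

    def test_variant_beyond_contig_rejected(self):
        genome, genes = self.make()
        with pytest.raises(ValueError):
            classify_variant(VariantCall("c", 5000, "snp", "A", "G"), genes, genome)


class TestOracleAgreement:
    def test_random_cds_snps_match_bruteforce(self, coding_genome):
        genome, genes = coding_genome
        plan = plan_cds_snps(genome, genes, 300, seed=31)
        variants = [
            VariantCall(e.sequence_id, e.start, "snp",
                        genome[e.sequence_id][e.start], e.payload)
            for e in plan.events
        ]
        annotations = classify_variants(variants, genes, genome)
        for ann in annotations:
            gene = next(g for g in genes if g.gene_id == ann.gene_id)
            cds = gene.cds_sequence(genome)
            mutated = apply_to_cds(cds, ann.variant, gene)
            assert ann.consequence == oracle_class(cds, mutated), ann

    def test_random_cds_indels_match_bruteforce(self, coding_genome):
        genome, genes = coding_genome
        rng = np.random.default_rng(33)
        variants = []
        for _ in range(150):
            gene = genes[int(rng.integers(len(genes)))]
            # interior positions only, away from start/stop codons
            pos = int(rng.integers(gene.start + 6, gene.end - 9))
            size = int(rng.integers(1, 7))
            if rng.random() < 0.5:
                payload = "".join(
                    "ACGT"[i] for i in rng.integers(0, 4, size=size)
                )
                variants.append(VariantCall(gene.ref_id, pos, "insertion", "",
                                            payload))
            else:
                ref_allele = genome[gene.ref_id][pos : pos + size]
                variants.append(VariantCall(gene.ref_id, pos, "deletion",
                                            ref_allele, ""))
        annotations = classify_variants(variants, genes, genome)
        for ann in annotations:
            gene = next(g for g in genes if g.gene_id == ann.gene_id)
            cds = gene.cds_sequence(genome)
            mutated = apply_to_cds(cds, ann.variant, gene)
            assert ann.consequence == oracle_class(cds, mutated), ann

    def test_fourfold_degenerate_plans_all_synonymous(self, coding_genome):
        genome, genes = coding_genome
        plan = plan_cds_snps(genome, genes, 120, seed=35,
                             fourfold_third_position_only=True)
        variants = [
            VariantCall(e.sequence_id, e.start, "snp",
                        genome[e.sequence_id][e.start], e.payload)
            for e in plan.events
        ]
        annotations = classify_variants(variants, genes, genome)
        assert all(a.consequence == "synonymous" for a in annotations)

    def test_strand_symmetry_on_mirrored_fixture(self):
        cds = "ATG" + "GCATTAGGC" * 10 + "TAA"
        pad = "ACGTTGCA" * 50
        fwd_seq = pad + cds + pad
        from genomeaudit.assembly import revcomp

        rev_seq = revcomp(fwd_seq)
        start = len(pad)
        end = start + len(cds)
        g_fwd = GenomeAssembly("f", {"c": fwd_seq})
        g_rev = GenomeAssembly("r", {"c": rev_seq})
        gene_fwd = GeneModel("g1", "c", "+", ((start, end),))
        rstart = len(fwd_seq) - end
        gene_rev = GeneModel("g1", "c", "-", ((rstart, rstart + len(cds)),))
        comp = str.maketrans("ACGT", "TGCA")
        for offset in range(3, len(cds) - 3):
            pos_f = start + offset
            ref_f = fwd_seq[pos_f]
            alt_f = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_f]
            v_f = VariantCall("c", pos_f, "snp", ref_f, alt_f)
            pos_r = len(fwd_seq) - 1 - pos_f
            v_r = VariantCall("c", pos_r, "snp", ref_f.translate(comp),
                              alt_f.translate(comp))
            c_f = classify_variant(v_f, [gene_fwd], g_fwd).consequence
            c_r = classify_variant(v_r, [gene_rev], g_rev).consequence
            assert c_f == c_r, (offset, c_f, c_r)


class TestTally:
    def ann(self, consequence, pos=0, kind="snp"):
        if kind == "snp":
            v = VariantCall("c", pos, "snp", "A", "G")
        else:
            v = VariantCall("c", pos, "deletion", "A", "")
        return EffectAnnotation(v, consequence)

    def test_empty_is_all_zero(self):
        t = tally_effects([])
        assert t.n_variants == t.synonymous == t.nonsynonymous == t.other == 0

    def test_nonsynonymous_grouping(self):
        anns = [self.ann("missense", 1), self.ann("missense", 2),
                self.ann("frameshift", 3, kind="deletion")]
        assert tally_effects(anns).nonsynonymous == 3

    def test_count_conservation(self):
        anns = [self.ann("synonymous", 1), self.ann("intergenic", 2),
                self.ann("upstream", 3), self.ann("stop_gained", 4)]
        t = tally_effects(anns)
        assert t.synonymous + t.nonsynonymous + t.other == t.n_variants == 4

    def test_duplicate_records_counted(self):
        anns = [self.ann("synonymous", 5), self.ann("synonymous", 5)]
        t = tally_effects(anns)
        assert t.n_duplicate_records == 1 and t.n_variants == 2


def test_gff3_round_trip(coding_genome, tmp_path):
    genome, genes = coding_genome
    path = tmp_path / "genes.gff3"
    write_gff3(genes, path, genome)
    restored = read_gff3(path)
    assert sorted((g.ref_id, g.strand, g.cds_intervals, g.phase) for g in genes) == \
        sorted((g.ref_id, g.strand, g.cds_intervals, g.phase) for g in restored)
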