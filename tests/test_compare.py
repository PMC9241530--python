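"""Whole-genome comparator: anchors, chaining, variant calls, SV classes."""

import itertools

import pytest

from genomeaudit.assembly import GenomeAssembly, revcomp
from genomeaudit.compare import (
    VariantCall,
    call_variants,
    chain_and_align,
    classify_events,
    compare_genomes,
    find_anchors,
    summarize,
    write_vcf,
    read_vcf,
)
from genomeaudit.simulate import (
    MutationPlan,
    PlannedEvent,
    apply_mutation_plan,
    generate_genome,
    plan_mutations,
)


def exhaustive_kmer_matches(ref: str, qry: str, k: int):
    """Independent brute-force oracle: all exact k-mer match diagonals."""
    index = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    fwd, rev = set(), set()
    for j in range(len(qry) - k + 1):
        for i in index.get(qry[j : j + k], ()):
            fwd.add((i, j))
        for i in index.get(revcomp(qry[j : j + k]), ()):
            rev.add((i, j))
    return fwd, rev


class TestAnchors:
    def test_identity_single_full_anchor(self):
        g = generate_genome([10_000], 0.5, seed=1, max_repeat=15)
        anchors = find_anchors(g, g, 20)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.ref_start, a.ref_end) == (0, 10_000)
        assert (a.qry_start, a.qry_end) == (0, 10_000)
        assert a.strand == "+" and a.matches == a.block_length == 10_000

    def test_revcomp_single_minus_anchor(self):
        g = generate_genome([10_000], 0.5, seed=2, max_repeat=15)
        anchors = find_anchors(g, g.reverse_complement(), 20)
        assert len(anchors) == 1
        a = anchors[0]
        assert a.strand == "-"
        assert (a.ref_start, a.ref_end) == (0, 10_000)
        assert (a.qry_start, a.qry_end) == (0, 10_000)

    def test_planted_inversion_anchor_layout(self):
        g = generate_genome([30_000], 0.5, seed=3, max_repeat=15)
        name = next(iter(g.sequences))
        plan = MutationPlan(
            [PlannedEvent("inversion", name, 10_000, 12_000)], seed=0,
            truth_genome_id=g.assembly_id,
        )
        mut = apply_mutation_plan(g, plan)
        anchors = find_anchors(g, mut, 24)
        plus = [a for a in anchors if a.strand == "+"]
        minus = [a for a in anchors if a.strand == "-"]
        assert len(minus) == 1
        inv = minus[0]
        # the minus anchor covers the inverted span (up to chance end-extension)
        assert abs(inv.ref_start - 10_000) <= 24
        assert abs(inv.ref_end - 12_000) <= 24
        assert len(plus) == 2

    def test_anchors_agree_with_bruteforce_on_tiny_sequences(self):
        ref = generate_genome([400], 0.5, seed=4, max_repeat=11)
        qry_seqs = dict(ref.sequences)
        name = next(iter(qry_seqs))
        s = qry_seqs[name]
        qry_seqs[name] = s[:200] + revcomp(s[200:300]) + s[300:]
        qry = GenomeAssembly("q", qry_seqs)
        k = 12
        fwd, rev = exhaustive_kmer_matches(ref[name], qry[name], k)
        anchors = find_anchors(ref, qry, k)
        # every anchor must be a true exact match per the oracle
        for a in anchors:
            if a.strand == "+":
                for off in range(a.ref_len - k + 1):
                    assert (a.ref_start + off, a.qry_start + off) in fwd
            else:
                L = a.ref_len
                for off in range(L - k + 1):
                    # minus-strand: ref offset maps to mirrored qry offset
                    assert (a.ref_start + off, a.qry_end - k - off) in rev

    def test_min_len_validation(self):
        g = generate_genome([1000], 0.5, seed=5)
        with pytest.raises(ValueError):
            find_anchors(g, g, 8)
        with pytest.raises(ValueError):
            find_anchors(GenomeAssembly("e", {}), g, 24)


class TestChaining:
    def test_single_anchor_passthrough(self):
        g = generate_genome([5000], 0.5, seed=6, max_repeat=15)
        anchors = find_anchors(g, g, 20)
        blocks = chain_and_align(anchors, g, g)
        assert len(blocks) == 1 and blocks[0].matches == 5000

    def test_snp_gap_closed_into_one_block(self):
        g = generate_genome([5000], 0.5, seed=7, max_repeat=15)
        name = next(iter(g.sequences))
        alt = "A" if g[name][2500] != "A" else "C"
        plan = MutationPlan(
            [PlannedEvent("snp", name, 2500, 2501, alt)], seed=0,
            truth_genome_id=g.assembly_id,
        )
        mut = apply_mutation_plan(g, plan)
        blocks = chain_and_align(find_anchors(g, mut, 20), g, mut)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.block_length == 5000 and b.matches == 4999

    def test_one_to_one_no_overlaps(self):
        g = generate_genome([40_000], 0.5, seed=8, max_repeat=17)
        plan = plan_mutations(g, seed=9, n_snps=10, n_insertions=2,
                              n_deletions=2, n_inversions=1, sv_size=(1500, 2000))
        mut = apply_mutation_plan(g, plan)
        blocks = chain_and_align(find_anchors(g, mut, 24), g, mut)
        for a, b in itertools.combinations(blocks, 2):
            if a.ref_id == b.ref_id:
                assert min(a.ref_end, b.ref_end) <= max(a.ref_start, b.ref_start)
            if a.qry_id == b.qry_id:
                assert min(a.qry_end, b.qry_end) <= max(a.qry_start, b.qry_start)


class TestVariantCalls:
    def test_identical_genomes_no_calls(self, small_genome):
        res = compare_genomes(small_genome, small_genome)
        assert res.variants == []

    def test_planted_snps_exact(self, small_genome):
        plan = plan_mutations(small_genome, seed=10, n_snps=40)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        called = sorted(
            (v.ref_id, v.position, v.ref_allele, v.alt_allele)
            for v in res.variants
        )
        planted = sorted(
            (e.sequence_id, e.start, small_genome[e.sequence_id][e.start],
             e.payload)
            for e in plan.events
        )
        assert called == planted

    def test_planted_deletion_run_length_collapsed(self, small_genome):
        name = next(iter(small_genome.sequences))
        seq = small_genome[name]
        s = next(
            p for p in range(20_000, 30_000)
            if seq[p + 6] != seq[p - 1] and seq[p] != seq[p + 7]
        )
        plan = MutationPlan(
            [PlannedEvent("deletion", name, s, s + 7)], seed=0,
            truth_genome_id=small_genome.assembly_id,
        )
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        assert len(res.variants) == 1
        v = res.variants[0]
        assert v.kind == "deletion" and v.position == s
        assert v.ref_allele == seq[s : s + 7]

    def test_vcf_round_trip(self, small_genome, tmp_path):
        plan = plan_mutations(small_genome, seed=12, n_snps=8, n_insertions=3,
                              n_deletions=3)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        path = tmp_path / "calls.vcf"
        write_vcf(res.variants, small_genome, path)
        assert read_vcf(path, small_genome) == sorted(res.variants)


class TestStructuralEvents:
    @pytest.mark.parametrize("kind, kwargs", [
        ("inversion", dict(n_inversions=1)),
        ("relocation", dict(n_relocations=1)),
        ("translocation", dict(n_translocations=1)),
    ])
    def test_single_planted_event_single_call(self, small_genome, kind, kwargs):
        plan = plan_mutations(small_genome, seed=14, **kwargs)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        assert [e.kind for e in res.events] == [kind]

    def test_inversion_span_covers_planted_interval(self, small_genome):
        plan = plan_mutations(small_genome, seed=15, n_inversions=1)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        (event,) = res.events
        (planted,) = plan.events
        assert event.ref_id == planted.sequence_id
        assert abs(event.ref_span[0] - planted.start) <= 30
        assert abs(event.ref_span[1] - planted.end) <= 30

    def test_collinear_blocks_no_events(self, small_genome):
        plan = plan_mutations(small_genome, seed=16, n_snps=30, n_insertions=3,
                              n_deletions=3)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        assert res.events == []

    def test_mixed_sv_counts(self, small_genome):
        plan = plan_mutations(small_genome, seed=17, n_inversions=1,
                              n_relocations=1)
        mut = apply_mutation_plan(small_genome, plan)
        res = compare_genomes(small_genome, mut)
        kinds = sorted(e.kind for e in res.events)
        assert kinds == ["inversion", "relocation"]
        assert res.summary.total_sv == 2


class TestSummary:
    def test_self_comparison_identity(self, small_genome):
        s = compare_genomes(small_genome, small_genome).summary
        assert s.ref_aligned_fraction == 1.0
        assert s.qry_aligned_fraction == 1.0
        assert s.ani == 100.0
        assert s.total_sv == 0 and s.snp_count == 0 and s.indel_count == 0

    def test_strand_involution(self, small_genome):
        res = compare_genomes(small_genome, small_genome.reverse_complement())
        assert res.summary.ani == 100.0
        assert res.summary.ref_aligned_fraction == 1.0
        assert all(b.strand == "-" for b in res.blocks)
        assert res.variants == [] and res.events == []

    def test_one_percent_snps_ani_near_99(self):
        g = generate_genome([100_000], 0.5, seed=18, max_repeat=19)
        plan = plan_mutations(g, seed=19, n_snps=1000, margin=20)
        mut = apply_mutation_plan(g, plan)
        s = compare_genomes(g, mut).summary
        assert 98.9 <= s.ani <= 99.1
        assert s.snp_count == 1000

    def test_short_contigs_excluded_before_comparison(self, small_genome):
        # a 600 bp contig below the pre-filter cutoff must not contribute
        contigs = dict(small_genome.sequences)
        contigs["chaff"] = "ACGT" * 150
        withchaff = GenomeAssembly("wc", contigs)
        res = compare_genomes(withchaff, small_genome, min_contig=1000)
        assert all(b.ref_id != "chaff" for b in res.blocks)
        assert res.summary.ref_aligned_fraction == 1.0
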