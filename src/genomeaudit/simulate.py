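"""Seeded synthetic fixtures with planted ground truth.

Everything downstream of this module is testable without network access:
multi-replicon genomes with controlled GC, mutated "public" counterparts
carrying planted SNPs/indels/inversions/relocations/translocations,
fragmented draft versions, CDS gene models, and metadata record sets with
controlled field missingness, strain-label variants, and duplicates.

Every generator is a pure function of its arguments including the seed.
Event coordinates are reported in the truth genome's coordinate system,
0-based half-open.  The optional bounded-repeat mode rejects and resamples
duplicated k-mers so that planted-event recovery is never confounded by
spurious alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._kmers import canonical_kmers
from .assembly import GenomeAssembly, revcomp
from .effects import GeneModel
from .metadata import MetadataRecord, normalize_field_name

__all__ = [
    "PlannedEvent",
    "MutationPlan",
    "generate_genome",
    "plan_mutations",
    "apply_mutation_plan",
    "fragment_assembly",
    "plant_genes",
    "plan_cds_snps",
    "generate_metadata",
    "write_metadata_table",
]

_BASES = "ACGT"
EVENT_KINDS = ("snp", "insertion", "deletion", "inversion", "relocation",
               "translocation")
SV_KINDS = ("inversion", "relocation", "translocation")

#: codon boxes that are fourfold degenerate under the bacterial code
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
)


@dataclass(frozen=True)
class PlannedEvent:
    """One planted edit, in truth-genome coordinates (0-based half-open).

    * snp: ``end == start + 1``; payload is the single alternate base.
    * insertion: ``end == start``; payload inserted before base ``start``.
    * deletion: span ``[start, end)`` removed; payload empty.
    * inversion: span reverse-complemented in place.
    * relocation: span excised and re-inserted before truth position
      ``target_position`` on the same sequence.
    * translocation: as relocation, but onto ``target_sequence_id``.
    """

    kind: str
    sequence_id: str
    start: int
    end: int
    payload: str = ""
    target_sequence_id: Optional[str] = None
    target_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "snp":
            if self.end != self.start + 1 or len(self.payload) != 1:
                raise ValueError("snp must span one base with a one-base payload")
        if self.kind == "insertion" and (self.end != self.start or not self.payload):
            raise ValueError("insertion must have end == start and a payload")
        if self.kind in ("deletion", *SV_KINDS) and self.end <= self.start:
            raise ValueError(f"{self.kind} must span at least one base")
        if self.kind in ("relocation", "translocation"):
            if self.target_position is None:
                raise ValueError(f"{self.kind} requires a target_position")

    @property
    def footprint(self) -> Tuple[int, int]:
        """Occupied truth interval used for overlap checks (insertions: 1 base)."""
        return self.start, max(self.end, self.start + 1)


@dataclass
class MutationPlan:
    """Ordered ground-truth edit list linking a truth genome to its mutant."""

    events: List[PlannedEvent]
    seed: int
    truth_genome_id: str
    min_sv_block: int = 1000

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.sequence_id, e.start))

    def validate(self, genome: GenomeAssembly) -> None:
        occupied: Dict[str, List[Tuple[int, int]]] = {}
        for e in self.events:
            if e.sequence_id not in genome:
                raise ValueError(f"event on unknown sequence {e.sequence_id!r}")
            length = len(genome[e.sequence_id])
            lo, hi = e.footprint
            if lo < 0 or hi > length:
                raise ValueError(
                    f"{e.kind} at {e.sequence_id}:{e.start}-{e.end} out of range"
                )
            if e.kind in SV_KINDS and e.end - e.start < self.min_sv_block:
                raise ValueError(
                    f"{e.kind} span shorter than minimum block ({self.min_sv_block})"
                )
            if e.kind == "snp" and genome[e.sequence_id][e.start] == e.payload:
                raise ValueError("snp payload equals the reference base")
            occupied.setdefault(e.sequence_id, []).append((lo, hi))
            if e.kind in ("relocation", "translocation"):
                tgt_seq = e.target_sequence_id or e.sequence_id
                if tgt_seq not in genome:
                    raise ValueError(f"unknown target sequence {tgt_seq!r}")
                if not 0 <= e.target_position <= len(genome[tgt_seq]):
                    raise ValueError("target_position out of range")
                occupied.setdefault(tgt_seq, []).append(
                    (e.target_position, e.target_position + 1)
                )
        for seq_id, ivs in occupied.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping events on {seq_id}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "truth_genome_id": self.truth_genome_id,
                "min_sv_block": self.min_sv_block,
                "events": [asdict(e) for e in self.events],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MutationPlan":
        data = json.loads(text)
        return cls(
            events=[PlannedEvent(**e) for e in data["events"]],
            seed=data["seed"],
            truth_genome_id=data["truth_genome_id"],
            min_sv_block=data.get("min_sv_block", 1000),
        )


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def generate_genome(
    lengths: int | Sequence[int],
    gc_target: float,
    seed: int,
    assembly_id: str = "synthetic",
    replicon_names: Optional[Sequence[str]] = None,
    max_repeat: Optional[int] = None,
) -> GenomeAssembly:
    """Random multi-replicon genome with controlled GC content.

    ``max_repeat`` bounds the longest exact repeat (including across
    reverse complements and replicons): any duplicated (max_repeat+1)-mer
    is rejected and resampled until none remain.
    """
    if isinstance(lengths, int):
        lengths = [lengths]
    lengths = [int(l) for l in lengths]
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("replicon lengths must be positive")
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    if replicon_names is None:
        replicon_names = [f"{assembly_id}_rep{i + 1}" for i in range(len(lengths))]
    if len(replicon_names) != len(lengths):
        raise ValueError("replicon_names and lengths disagree")

    rng = np.random.default_rng(seed)
    reps = [_random_bases(rng, l, gc_target) for l in lengths]

    if max_repeat is not None:
        k = max_repeat + 1
        if not 2 <= k <= 31:
            raise ValueError("max_repeat must be in [1, 30]")
        for iteration in range(80):
            seqs = [_codes_to_str(r) for r in reps]
            all_vals = []
            owners = []
            for i, s in enumerate(seqs):
                vals, ok = canonical_kmers(s, k)
                idx = np.flatnonzero(ok)
                all_vals.append(vals[idx])
                owners.append(np.stack([np.full(len(idx), i), idx], axis=1))
            vals = np.concatenate(all_vals) if all_vals else np.empty(0, np.uint64)
            if len(vals) == 0:
                break
            owner = np.concatenate(owners)
            order = np.argsort(vals, kind="stable")
            sv = vals[order]
            dup = np.zeros(len(sv), dtype=bool)
            same = sv[1:] == sv[:-1]
            dup[1:] |= same
            dup[:-1] |= same
            if not dup.any():
                break
            for rep_i, pos in owner[order[dup]]:
                n = min(k, len(reps[rep_i]) - pos)
                reps[rep_i][pos : pos + n] = _random_bases(rng, n, gc_target)
        else:
            raise RuntimeError("bounded-repeat resampling did not converge")

    return GenomeAssembly(
        assembly_id,
        {name: _codes_to_str(r) for name, r in zip(replicon_names, reps)},
    )


# ---------------------------------------------------------------------------
# mutation planning and application
# ---------------------------------------------------------------------------

def _reserve(
    occupied: Dict[str, List[Tuple[int, int]]], seq_id: str, lo: int, hi: int
) -> bool:
    for s, e in occupied.get(seq_id, ()):
        if lo < e and s < hi:
            return False
    occupied.setdefault(seq_id, []).append((lo, hi))
    return True


def plan_mutations(
    genome: GenomeAssembly,
    seed: int,
    n_snps: int = 0,
    n_insertions: int = 0,
    n_deletions: int = 0,
    n_inversions: int = 0,
    n_relocations: int = 0,
    n_translocations: int = 0,
    indel_size: Tuple[int, int] = (1, 20),
    sv_size: Tuple[int, int] = (1500, 4000),
    min_move: int = 3000,
    margin: int = 120,
) -> MutationPlan:
    """Sample a valid, unambiguous mutation plan on a truth genome.

    Events are placed with ``margin`` bp of clearance so each is flanked by
    anchorable sequence; indel sites are chosen so the edit cannot be
    shifted left or right (unique normalized placement); relocation and
    translocation targets sit at least ``min_move`` bp from their source.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.sequences)
    seqs = genome.sequences
    weights = np.array([len(seqs[n]) for n in names], dtype=float)
    weights /= weights.sum()
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    events: List[PlannedEvent] = []
    min_sv = min(sv_size)

    def pick_sequence() -> str:
        return names[int(rng.choice(len(names), p=weights))]

    def try_place(kind: str) -> Optional[PlannedEvent]:
        seq_id = pick_sequence()
        seq = seqs[seq_id]
        L = len(seq)
        if kind == "snp":
            if L < 2 * margin + 1:
                return None
            p = int(rng.integers(margin, L - margin))
            ref = seq[p]
            if ref not in _BASES:
                return None
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            if not _reserve(occupied, seq_id, p - margin, p + 1 + margin):
                return None
            return PlannedEvent("snp", seq_id, p, p + 1, alt)
        if kind == "insertion":
            size = int(rng.integers(indel_size[0], indel_size[1] + 1))
            p = int(rng.integers(margin, L - margin))
            payload = list(_codes_to_str(_random_bases(rng, size, 0.5)))
            # block left/right shifts: ends must mismatch the flanks
            if payload[-1] == seq[p - 1]:
                payload[-1] = _BASES[(_BASES.index(seq[p - 1]) + 1) % 4]
            if payload[0] == seq[p]:
                payload[0] = _BASES[(_BASES.index(seq[p]) + 1) % 4]
            if size > 1 and payload[0] == payload[-1] == seq[p - 1]:
                return None  # give up, resample elsewhere
            if not _reserve(occupied, seq_id, p - margin, p + 1 + margin):
                return None
            return PlannedEvent("insertion", seq_id, p, p, "".join(payload))
        if kind == "deletion":
            size = int(rng.integers(indel_size[0], indel_size[1] + 1))
            s = int(rng.integers(margin, L - margin - size))
            e = s + size
            # unique placement: deleted run must not be shiftable
            if seq[e - 1] == seq[s - 1] or seq[s] == seq[e]:
                return None
            if not _reserve(occupied, seq_id, s - margin, e + margin):
                return None
            return PlannedEvent("deletion", seq_id, s, e)
        size = int(rng.integers(sv_size[0], sv_size[1] + 1))
        if L < size + 4 * margin:
            return None
        s = int(rng.integers(margin, L - margin - size))
        e = s + size
        if kind == "inversion":
            if not _reserve(occupied, seq_id, s - margin, e + margin):
                return None
            return PlannedEvent("inversion", seq_id, s, e)
        if kind == "relocation":
            for _ in range(20):
                t = int(rng.integers(margin, L - margin))
                if abs(t - s) > min_move + size and not (s - margin <= t <= e + margin):
                    break
            else:
                return None
            if not _reserve(occupied, seq_id, s - margin, e + margin):
                return None
            if not _reserve(occupied, seq_id, t - margin, t + margin):
                return None
            return PlannedEvent("relocation", seq_id, s, e,
                                target_sequence_id=seq_id, target_position=t)
        if kind == "translocation":
            others = [n for n in names if n != seq_id]
            if not others:
                raise ValueError("translocation requires at least two replicons")
            tgt = others[int(rng.integers(len(others)))]
            Lt = len(seqs[tgt])
            if Lt < 2 * margin + 1:
                return None
            t = int(rng.integers(margin, Lt - margin))
            if not _reserve(occupied, seq_id, s - margin, e + margin):
                return None
            if not _reserve(occupied, tgt, t - margin, t + margin):
                return None
            return PlannedEvent("translocation", seq_id, s, e,
                                target_sequence_id=tgt, target_position=t)
        raise ValueError(kind)

    wanted = (
        [("translocation", n_translocations), ("relocation", n_relocations),
         ("inversion", n_inversions), ("deletion", n_deletions),
         ("insertion", n_insertions), ("snp", n_snps)]
    )
    for kind, n in wanted:
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise RuntimeError(
                    f"could not place {n} {kind} events; genome too small or "
                    f"too crowded"
                )
            ev = try_place(kind)
            if ev is not None:
                events.append(ev)
                placed += 1

    plan = MutationPlan(events, seed=seed, truth_genome_id=genome.assembly_id,
                        min_sv_block=min_sv)
    plan.validate(genome)
    return plan


def apply_mutation_plan(
    genome: GenomeAssembly, plan: MutationPlan, assembly_id: Optional[str] = None
) -> GenomeAssembly:
    """Apply a plan to the truth genome, returning the mutated counterpart.

    The input genome is never modified.  The resulting total length equals
    the original plus net insertion payload minus net deletions;
    relocations conserve per-assembly length and translocations move bases
    between sequences.
    """
    plan.validate(genome)
    # moved blocks keyed by (target_sequence, target_position, plan order)
    inserts: Dict[str, List[Tuple[int, int, str]]] = {}
    for order, e in enumerate(plan.events):
        if e.kind in ("relocation", "translocation"):
            content = genome[e.sequence_id][e.start : e.end]
            tgt = e.target_sequence_id or e.sequence_id
            inserts.setdefault(tgt, []).append((e.target_position, order, content))

    out: Dict[str, str] = {}
    for seq_id, seq in genome.contigs():
        ops: List[Tuple[int, int, str, PlannedEvent | str]] = []
        # rank orders same-position ops: block inserts, then splice events
        for e in plan.events:
            if e.sequence_id != seq_id:
                continue
            ops.append((e.start, 1, e.kind, e))
        for pos, order, content in inserts.get(seq_id, ()):
            ops.append((pos, 0, "blockinsert", content))
        ops.sort(key=lambda t: (t[0], t[1]))
        parts: List[str] = []
        cur = 0
        for pos, _, kind, obj in ops:
            parts.append(seq[cur:pos])
            cur = pos
            if kind == "blockinsert":
                parts.append(obj)  # type: ignore[arg-type]
            elif kind == "snp":
                parts.append(obj.payload)
                cur = pos + 1
            elif kind == "insertion":
                parts.append(obj.payload)
            elif kind == "deletion":
                cur = obj.end
            elif kind == "inversion":
                parts.append(revcomp(seq[pos : obj.end]))
                cur = obj.end
            elif kind in ("relocation", "translocation"):
                cur = obj.end  # excised; re-inserted via blockinsert
        parts.append(seq[cur:])
        out[seq_id] = "".join(parts)

    return GenomeAssembly(assembly_id or f"{genome.assembly_id}_mut", out)


def fragment_assembly(
    genome: GenomeAssembly,
    breakpoints_per_replicon: int,
    seed: int,
    assembly_id: Optional[str] = None,
) -> GenomeAssembly:
    """Split each replicon at random breakpoints, emulating a draft assembly.

    Total length is conserved; the contig count equals the replicon count
    plus the total number of breakpoints.
    """
    if breakpoints_per_replicon < 0:
        raise ValueError("breakpoints_per_replicon must be >= 0")
    rng = np.random.default_rng(seed)
    out: Dict[str, str] = {}
    for name, seq in genome.contigs():
        n = breakpoints_per_replicon
        if n >= len(seq):
            raise ValueError(
                f"{name}: {n} breakpoints do not fit a {len(seq)} bp replicon"
            )
        if n == 0:
            out[name] = seq
            continue
        cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n, replace=False))
        bounds = [0, *map(int, cuts), len(seq)]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            out[f"{name}_frag{i}"] = seq[a:b]
    return GenomeAssembly(assembly_id or f"{genome.assembly_id}_frag", out)


# ---------------------------------------------------------------------------
# gene planting (for variant-consequence tests)
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


def plant_genes(
    genome: GenomeAssembly,
    n_genes: int,
    seed: int,
    codon_range: Tuple[int, int] = (100, 400),
    margin: int = 200,
) -> Tuple[GenomeAssembly, List[GeneModel]]:
    """Overwrite non-overlapping regions with valid CDS genes.

    Each gene is ATG + sense codons + stop, pasted onto alternating
    strands.  Returns the modified genome and the gene models.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.sequences)
    seqs = {n: list(s) for n, s in genome.contigs()}
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    genes: List[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * max(n_genes, 1):
            raise RuntimeError("could not place requested genes")
        seq_id = names[int(rng.integers(len(names)))]
        L = len(seqs[seq_id])
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        length = 3 * (n_codons + 2)
        if L < length + 2 * margin:
            continue
        start = int(rng.integers(margin, L - margin - length))
        if not _reserve(occupied, seq_id, start - margin, start + length + margin):
            continue
        body = [_SENSE_CODONS[int(i)] for i in rng.integers(0, len(_SENSE_CODONS),
                                                            size=n_codons)]
        stop = _STOPS[int(rng.integers(3))]
        cds = "ATG" + "".join(body) + stop
        strand = "+" if len(genes) % 2 == 0 else "-"
        paste = cds if strand == "+" else revcomp(cds)
        seqs[seq_id][start : start + length] = list(paste)
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1:04d}",
                ref_id=seq_id,
                strand=strand,
                cds_intervals=((start, start + length),),
            )
        )
    out = GenomeAssembly(genome.assembly_id, {n: "".join(s) for n, s in seqs.items()})
    genes.sort(key=lambda g: (g.ref_id, g.start))
    return out, genes


def plan_cds_snps(
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    n_snps: int,
    seed: int,
    fourfold_third_position_only: bool = False,
) -> MutationPlan:
    """Plant SNPs inside CDS regions.

    With ``fourfold_third_position_only`` every SNP lands on the third
    position of a fourfold-degenerate codon, so all are synonymous by
    construction.
    """
    rng = np.random.default_rng(seed)
    events: List[PlannedEvent] = []
    used: Dict[str, set] = {}
    attempts = 0
    while len(events) < n_snps:
        attempts += 1
        if attempts > 500 * max(n_snps, 1):
            raise RuntimeError("could not place requested CDS SNPs")
        g = genes[int(rng.integers(len(genes)))]
        positions = g.genomic_positions()  # translation order
        n_codons = len(positions) // 3
        codon_idx = int(rng.integers(1, n_codons - 1))  # skip start & stop codons
        codon_pos = positions[3 * codon_idx : 3 * codon_idx + 3]
        seq = genome[g.ref_id]
        complement = str.maketrans("ACGT", "TGCA")
        codon = "".join(
            seq[p] if g.strand == "+" else seq[p].translate(complement)
            for p in codon_pos
        )
        if fourfold_third_position_only:
            if codon[:2] not in FOURFOLD_PREFIXES:
                continue
            genomic_p = codon_pos[2]
        else:
            genomic_p = codon_pos[int(rng.integers(3))]
        if genomic_p in used.setdefault(g.ref_id, set()):
            continue
        ref_base = seq[genomic_p]
        alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        used[g.ref_id].add(genomic_p)
        events.append(PlannedEvent("snp", g.ref_id, genomic_p, genomic_p + 1, alt))
    plan = MutationPlan(events, seed=seed, truth_genome_id=genome.assembly_id)
    plan.validate(genome)
    return plan


# ---------------------------------------------------------------------------
# metadata fixtures
# ---------------------------------------------------------------------------

KNOWN_FIELDS = (
    "assembly_accession",
    "organism_name",
    "infraspecific_name",
    "isolate",
    "assembly_level",
    "refseq_category",
    "assembly type",
    "sequencing technology",
    "assembly method",
    "description",
    "relation to type material",
    "submitter",
)

_SPECIES = (
    "Serratia marcescens", "Escherichia coli", "Bacillus cereus",
    "Pseudomonas aeruginosa", "Staphylococcus aureus",
    "Acinetobacter baumannii", "Klebsiella pneumoniae",
    "Enterococcus faecalis", "Salmonella enterica", "Listeria monocytogenes",
)
_SEQ_TECH = ("Illumina MiSeq", "Oxford Nanopore GridION", "Illumina NextSeq 2000",
             "PacBio RS II")
_ASM_METHOD = ("Unicycler v0.4.8", "SPAdes v3.15.3", "SKESA v2.4.0",
               "Velvet 1.2.10")
_LEVELS = ("Complete Genome", "Chromosome", "Scaffold", "Contig")
_CATEGORIES = ("reference genome", "representative genome", "na", "")
_SEPARATORS = (" ", "", "-", "_")
_TYPE_RELATIONS = ("assembly from type material", "assembly designated as neotype",
                   "assembly from synonym type material")


def generate_metadata(
    n_records: int,
    missingness: Optional[Mapping[str, float]] = None,
    duplicate_strains: int = 0,
    seed: int = 0,
    duplicate_group_size: int = 3,
    type_material_conflicts: int = 0,
    with_truth: bool = False,
):
    """Synthetic public-assembly metadata with planted imperfections.

    Plants ``duplicate_strains`` groups of ``duplicate_group_size`` records
    sharing one strain, a mix of ATCC-only / NCTC-only / dual-labeled
    records (NCTC-only records alternate between having a curated ATCC
    synonym and being orphans), and per-field missingness at the requested
    Bernoulli rates (missing cells become "" or "na").

    With ``with_truth`` returns ``(records, truth)`` where truth holds the
    planted quantities (realized empty counts, duplicate groups, the
    synonym table, expected selection, conflict accessions).
    """
    missingness = dict(missingness or {})
    known_norm = {normalize_field_name(f): f for f in KNOWN_FIELDS}
    for f, p in missingness.items():
        if normalize_field_name(f) not in known_norm:
            raise ValueError(f"unknown metadata field {f!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"missingness fraction for {f!r} outside [0, 1]")
    if duplicate_strains * duplicate_group_size > n_records:
        raise ValueError("duplicate groups exceed the record count")

    rng = np.random.default_rng(seed)
    records: List[MetadataRecord] = []
    synonyms: Dict[str, str] = {}
    duplicate_groups: Dict[str, List[str]] = {}
    expected_selected: List[str] = []
    conflict_accessions: List[str] = []
    label_cycle = ("atcc", "atcc", "atcc", "nctc_syn", "atcc", "nctc_orphan",
                   "dual", "atcc", "plain")
    empty_counts = {f: 0 for f in missingness}

    n_dup_records = duplicate_strains * duplicate_group_size
    for i in range(n_records):
        accession = f"GCF_{900000000 + i}.1"
        species = _SPECIES[i % len(_SPECIES)]
        sep = _SEPARATORS[i % len(_SEPARATORS)]
        if i < n_dup_records:
            group = i // duplicate_group_size
            atcc_num = 13000 + group
            label_type = "atcc"
        else:
            atcc_num = 20000 + i
            label_type = label_cycle[i % len(label_cycle)]
        nctc_num = 90000 + i
        organism = species
        infra = ""
        if label_type == "atcc":
            organism = f"{species} ATCC{sep}{atcc_num}"
            infra = f"strain=ATCC {atcc_num}"
        elif label_type == "dual":
            organism = f"{species} ATCC{sep}{atcc_num}"
            infra = f"strain=NCTC {nctc_num}"
        elif label_type in ("nctc_syn", "nctc_orphan"):
            organism = f"{species} NCTC{sep}{nctc_num}"
            infra = f"strain=NCTC {nctc_num}"
            if label_type == "nctc_syn":
                synonyms[f"NCTC {nctc_num}"] = f"ATCC {atcc_num}"

        fields = {
            "assembly_accession": accession,
            "organism_name": organism,
            "infraspecific_name": infra,
            "isolate": f"isolate-{i:05d}",
            "assembly_level": _LEVELS[i % len(_LEVELS)],
            "refseq_category": _CATEGORIES[i % len(_CATEGORIES)],
            "assembly type": "haploid",
            "sequencing technology": _SEQ_TECH[i % len(_SEQ_TECH)],
            "assembly method": _ASM_METHOD[i % len(_ASM_METHOD)],
            "description": f"{species} whole genome shotgun assembly",
            "relation to type material": (
                _TYPE_RELATIONS[i % len(_TYPE_RELATIONS)] if i % 5 == 0 else ""
            ),
            "submitter": f"Lab {1 + i % 17}",
        }
        is_conflict = len(conflict_accessions) < type_material_conflicts
        if is_conflict:
            fields["relation to type material"] = _TYPE_RELATIONS[0]
            fields["description"] = (
                f"genetically modified derivative of {species}"
            )

        blanked_fields = set()
        for f, p in missingness.items():
            canonical = known_norm[normalize_field_name(f)]
            if rng.random() < p:
                fields[canonical] = "" if rng.random() < 0.5 else "na"
                empty_counts[f] += 1
                blanked_fields.add(canonical)

        record = MetadataRecord(accession, fields, source_dialect="synthetic")
        records.append(record)

        if is_conflict and not (
            {"relation to type material", "description"} & blanked_fields
        ):
            conflict_accessions.append(accession)

        # expected selection depends on which label-carrying fields survived
        both_blanked = {"organism_name", "infraspecific_name"} <= blanked_fields
        if label_type in ("atcc", "nctc_syn") and not both_blanked:
            expected_selected.append(accession)
        elif label_type == "dual" and "organism_name" not in blanked_fields:
            expected_selected.append(accession)  # the ATCC label lives there
        if i < n_dup_records and not both_blanked:
            duplicate_groups.setdefault(f"ATCC {atcc_num}", []).append(accession)

    duplicate_groups = {k: v for k, v in duplicate_groups.items() if len(v) >= 2}
    if not with_truth:
        return records
    truth = {
        "n_records": n_records,
        "missingness_requested": dict(missingness),
        "empty_counts": empty_counts,
        "duplicate_groups": duplicate_groups,
        "synonyms": synonyms,
        "expected_selected": expected_selected,
        "type_material_conflicts": conflict_accessions,
    }
    return records, truth


def write_metadata_table(records: Sequence[MetadataRecord], path: str | Path) -> None:
    """Write records in the tab-delimited assembly_summary dialect."""
    columns = list(KNOWN_FIELDS)
    extra = sorted(
        {k for r in records for k in r.fields if k not in columns}
    )
    columns += extra
    lines = ["#" + "\t".join(columns)]
    for r in records:
        lines.append("\t".join(r.fields.get(c, "") for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def write_synonym_table(synonyms: Mapping[str, str], path: str | Path) -> None:
    lines = ["#nctc_key\tatcc_key"]
    for nctc, atcc in sorted(synonyms.items()):
        lines.append(f"{nctc}\t{atcc}")
    Path(path).write_text("\n".join(lines) + "\n")
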