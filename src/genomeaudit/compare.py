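"""Desk-scale pairwise whole-genome comparison.

The comparator aligns two assemblies by (1) finding maximal unique exact
matches (MUM-like anchors) on both strands via 2-bit k-mer indexing,
(2) chaining collinear anchors and closing the small gaps between them
with end-to-end edit-distance alignment (edlib), (3) filtering the chained
blocks to a 1-to-1 set that covers each genome at most once, then calling
per-base variants (SNPs, run-length-collapsed indels) and classifying
junction-level structural differences (relocations, inversions,
translocations) from the surviving block layout.  The summary reports
aligned-base fractions per genome, alignment-identity ANI over the 1-to-1
blocks, and per-kind structural-event counts.

Coordinates are 0-based half-open on forward strands throughout; reports
convert to 1-based inclusive.  Ambiguous bases (N) never count as matches
and variant calls overlapping N are suppressed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from ._kmers import encode_kmers
from .assembly import GenomeAssembly, revcomp
from .metrics import filter_short_contigs

__all__ = [
    "AlignmentBlock",
    "VariantCall",
    "StructuralEvent",
    "ComparisonSummary",
    "ComparisonResult",
    "find_anchors",
    "chain_and_align",
    "call_variants",
    "classify_events",
    "summarize",
    "compare_genomes",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 24
DEFAULT_GAP_LIMIT = 1000

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One gap-free or gap-closed alignment block.

    ``qry_start``/``qry_end`` are forward-strand query coordinates even for
    minus-strand blocks.  ``cigar`` (extended ops ``=``, ``X``, ``I``, ``D``)
    describes ref vs query-in-block-orientation; for minus-strand blocks the
    query side is the reverse complement of the forward-strand slice.
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    matches: int
    block_length: int
    cigar: str = ""

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise ValueError("empty alignment block")
        if self.matches > self.block_length:
            raise ValueError("matches exceed block length")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start

    def qprime_start(self, qry_seq_len: int) -> int:
        """Query start in block orientation (revcomp coords when strand is '-')."""
        return self.qry_start if self.strand == "+" else qry_seq_len - self.qry_end


@dataclass(frozen=True, order=True)
class VariantCall:
    ref_id: str
    position: int
    kind: str  # snp | insertion | deletion
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp alleles must differ")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have empty ref allele")
        elif self.kind == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have empty alt allele")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass(frozen=True)
class StructuralEvent:
    kind: str  # relocation | inversion | translocation
    ref_id: str
    qry_id: str
    ref_span: Tuple[int, int]
    qry_span: Tuple[int, int]


@dataclass(frozen=True)
class ComparisonSummary:
    ref_aligned_fraction: float
    qry_aligned_fraction: float
    ani: float
    snp_count: int
    indel_count: int
    relocations: int
    inversions: int
    translocations: int

    @property
    def total_sv(self) -> int:
        return self.relocations + self.inversions + self.translocations

    def to_row(self) -> Dict[str, float | int]:
        """One comparison as a supplementary-table-style row."""
        return {
            "RefAlignedBase%": 100.0 * self.ref_aligned_fraction,
            "QueryAlignedBase%": 100.0 * self.qry_aligned_fraction,
            "ANI": self.ani,
            "SNPs": self.snp_count,
            "Indels": self.indel_count,
            "RefRelocations": self.relocations,
            "RefInversions": self.inversions,
            "RefTranslocations": self.translocations,
            "TotalSVs": self.total_sv,
        }


@dataclass
class ComparisonResult:
    blocks: List[AlignmentBlock]
    variants: List[VariantCall]
    events: List[StructuralEvent]
    summary: ComparisonSummary


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _kmer_catalog(assembly: GenomeAssembly, k: int, both_strands: bool):
    """(values, contig_idx, pos, strand_flag) over all valid k-mer windows."""
    vals_parts, contig_parts, pos_parts, strand_parts = [], [], [], []
    for idx, (_, seq) in enumerate(assembly.contigs()):
        variants = [("+", seq)]
        if both_strands:
            variants.append(("-", revcomp(seq)))
        for strand, s in variants:
            vals, ok = encode_kmers(s, k)
            if len(vals) == 0:
                continue
            keep = np.flatnonzero(ok)
            vals_parts.append(vals[keep])
            contig_parts.append(np.full(len(keep), idx, dtype=np.int32))
            pos_parts.append(keep.astype(np.int64))
            strand_parts.append(
                np.full(len(keep), 0 if strand == "+" else 1, dtype=np.int8)
            )
    if not vals_parts:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int8)
    return (
        np.concatenate(vals_parts),
        np.concatenate(contig_parts),
        np.concatenate(pos_parts),
        np.concatenate(strand_parts),
    )


def _unique_entries(vals, *companions):
    """Entries whose k-mer value occurs exactly once in the catalog."""
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    is_first = np.empty(len(sv), dtype=bool)
    if len(sv):
        is_first[0] = True
        is_first[1:] = sv[1:] != sv[:-1]
    is_last = np.empty(len(sv), dtype=bool)
    if len(sv):
        is_last[-1] = True
        is_last[:-1] = sv[1:] != sv[:-1]
    unique_mask = is_first & is_last
    idx = order[unique_mask]
    return vals[idx], tuple(c[idx] for c in companions)


def _max_shared_prefix(a: str, b: str, i: int, j: int, limit: int) -> int:
    """Longest e with a[i:i+e] == b[j:j+e], no N, e <= limit."""

    def ok(m: int) -> bool:
        seg = a[i : i + m]
        return seg == b[j : j + m] and "N" not in seg

    hi = min(limit, len(a) - i, len(b) - j)
    if hi <= 0 or not ok(1):
        return 0
    step = 1
    while step * 2 <= hi and ok(step * 2):
        step *= 2
    lo, up = step, min(step * 2, hi)
    while lo < up:  # invariant: ok(lo), not ok(up+1-ish)
        mid = (lo + up + 1) // 2
        if ok(mid):
            lo = mid
        else:
            up = mid - 1
    return lo


def find_anchors(
    ref: GenomeAssembly, qry: GenomeAssembly, min_len: int = DEFAULT_MIN_ANCHOR
) -> List[AlignmentBlock]:
    """Maximal unique exact matches of length >= ``min_len`` on both strands.

    A k-mer seed participates only when it occurs exactly once on the
    reference forward strand and exactly once across both query strands
    (MUM-style uniqueness).  Seeds on one diagonal are merged and extended
    maximally, yielding gap-free blocks with ``matches == block_length``.
    """
    if len(ref) == 0 or len(qry) == 0:
        raise ValueError("both assemblies must be non-empty")
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    k = min(min_len, 31)

    r_vals, (r_contig, r_pos, _) = _unique_entries(
        *_kmer_catalog(ref, k, both_strands=False)
    )
    q_vals, (q_contig, q_pos, q_strand) = _unique_entries(
        *_kmer_catalog(qry, k, both_strands=True)
    )
    shared, r_idx, q_idx = np.intersect1d(
        r_vals, q_vals, assume_unique=True, return_indices=True
    )
    if len(shared) == 0:
        return []

    rc = r_contig[r_idx]
    rp = r_pos[r_idx]
    qc = q_contig[q_idx]
    qp = q_pos[q_idx]  # position in strand orientation (revcomp coords for '-')
    qs = q_strand[q_idx]
    diag = rp - qp

    order = np.lexsort((rp, diag, qs, qc, rc))
    rc, rp, qc, qp, qs, diag = (a[order] for a in (rc, rp, qc, qp, qs, diag))

    ref_names = list(ref.sequences)
    qry_names = list(qry.sequences)
    ref_seqs = list(ref.sequences.values())
    qry_fwd = list(qry.sequences.values())
    qry_rev = [revcomp(s) for s in qry_fwd]
    # reversed copies for leftward extension (built lazily, once per contig)
    rev_cache: Dict[Tuple[str, int], str] = {}

    def reversed_seq(tag: str, idx: int, s: str) -> str:
        key = (tag, idx)
        if key not in rev_cache:
            rev_cache[key] = s[::-1]
        return rev_cache[key]

    # split into runs of seeds on one diagonal with overlapping/adjacent windows
    new_group = np.ones(len(rp), dtype=bool)
    if len(rp) > 1:
        same = (
            (rc[1:] == rc[:-1])
            & (qc[1:] == qc[:-1])
            & (qs[1:] == qs[:-1])
            & (diag[1:] == diag[:-1])
            & (rp[1:] - rp[:-1] <= k)  # overlapping seeds stay exact when merged
        )
        new_group[1:] = ~same
    starts = np.flatnonzero(new_group)
    ends = np.append(starts[1:], len(rp))

    blocks: List[AlignmentBlock] = []
    seen = set()
    for s_i, e_i in zip(starts, ends):
        i0, i1 = int(s_i), int(e_i) - 1
        ri, qi, strand = int(rc[i0]), int(qc[i0]), int(qs[i0])
        rstart, rend = int(rp[i0]), int(rp[i1]) + k
        qseq = qry_fwd[qi] if strand == 0 else qry_rev[qi]
        rseq = ref_seqs[ri]
        qstart = int(qp[i0])
        # maximal extension of the merged exact run
        left = _max_shared_prefix(
            reversed_seq("r", ri, rseq),
            reversed_seq(f"q{strand}", qi, qseq),
            len(rseq) - rstart, len(qseq) - qstart,
            min(rstart, qstart),
        )
        right = _max_shared_prefix(
            rseq, qseq, rend, qstart + (rend - rstart), len(rseq),
        )
        rstart -= left
        qstart -= left
        rend += right
        length = rend - rstart
        if length < min_len:
            continue
        qlen_total = len(qseq)
        if strand == 0:
            q0, q1 = qstart, qstart + length
            strand_sym = "+"
        else:
            q0, q1 = qlen_total - (qstart + length), qlen_total - qstart
            strand_sym = "-"
        key = (ri, qi, strand, rstart, rend)
        if key in seen:
            continue
        seen.add(key)
        blocks.append(
            AlignmentBlock(
                ref_id=ref_names[ri],
                qry_id=qry_names[qi],
                ref_start=rstart,
                ref_end=rend,
                qry_start=q0,
                qry_end=q1,
                strand=strand_sym,
                matches=length,
                block_length=length,
                cigar=f"{length}=",
            )
        )
    blocks.sort(key=lambda b: (b.ref_id, b.ref_start, b.qry_id, b.qry_start))
    return blocks


# ---------------------------------------------------------------------------
# chaining, gap closing, 1-to-1 filtering
# ---------------------------------------------------------------------------

def _cigar_runs(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _runs_to_cigar(runs: Sequence[Tuple[int, str]]) -> str:
    merged: List[Tuple[int, str]] = []
    for n, op in runs:
        if n <= 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


def _align_gap(ref_seg: str, qry_seg: str) -> Tuple[str, int, int]:
    """(cigar, matches, columns) for an end-to-end gap alignment."""
    if not ref_seg and not qry_seg:
        return "", 0, 0
    if not ref_seg:
        return f"{len(qry_seg)}I", 0, len(qry_seg)
    if not qry_seg:
        return f"{len(ref_seg)}D", 0, len(ref_seg)
    res = edlib.align(qry_seg, ref_seg, mode="NW", task="path")
    cigar = res["cigar"] or ""
    matches = columns = 0
    runs = []
    qpos = rpos = 0
    for n, op in _cigar_runs(cigar):
        if op == "=":
            # edlib treats N==N as equal; demote N-containing columns to X
            seg = ref_seg[rpos : rpos + n]
            if "N" in seg:
                sub = [
                    (1, "X" if c == "N" else "=") for c in seg
                ]
                runs.extend(sub)
                matches += sum(1 for c in seg if c != "N")
            else:
                runs.append((n, "="))
                matches += n
            rpos += n
            qpos += n
        elif op == "X":
            runs.append((n, "X"))
            rpos += n
            qpos += n
        elif op == "I":
            runs.append((n, "I"))
            qpos += n
        elif op == "D":
            runs.append((n, "D"))
            rpos += n
        columns += n
    return _runs_to_cigar(runs), matches, columns


@dataclass
class _Chain:
    ref_id: str
    qry_id: str
    strand: str
    ref_start: int
    ref_end: int
    qp_start: int
    qp_end: int
    matches: int
    columns: int
    runs: List[Tuple[int, str]] = field(default_factory=list)


def chain_and_align(
    anchors: Sequence[AlignmentBlock],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    gap_limit: int = DEFAULT_GAP_LIMIT,
) -> List[AlignmentBlock]:
    """Chain collinear anchors, close their gaps, and keep a 1-to-1 block set.

    Anchors on one (ref contig, qry contig, strand) are greedily chained in
    reference order when the ref-side and query-side gaps are both within
    ``gap_limit`` and roughly balanced; each gap is closed with an
    end-to-end alignment whose identities feed the block's ``matches``.
    The chained blocks are then filtered greedily by match count so that no
    two blocks overlap on the reference or on the query; small edge
    overlaps are trimmed away inside the terminal exact runs.
    """
    qry_rev = {name: revcomp(seq) for name, seq in qry.contigs()}
    qlen = {name: len(seq) for name, seq in qry.contigs()}

    groups: Dict[Tuple[str, str, str], List[AlignmentBlock]] = {}
    for a in anchors:
        groups.setdefault((a.ref_id, a.qry_id, a.strand), []).append(a)

    chains: List[_Chain] = []
    for (ref_id, qry_id, strand), group in groups.items():
        group.sort(key=lambda b: (b.ref_start, b.qry_start))
        rseq = ref[ref_id]
        qseq = qry[qry_id] if strand == "+" else qry_rev[qry_id]
        current: Optional[_Chain] = None
        for a in group:
            a_rs, a_re = a.ref_start, a.ref_end
            a_qs = a.qprime_start(qlen[qry_id])
            a_len = a_re - a_rs
            if current is not None:
                rgap = a_rs - current.ref_end
                qgap = a_qs - current.qp_end
                trim = max(0, -rgap, -qgap)
                joinable = (
                    rgap + trim >= 0
                    and qgap + trim >= 0
                    and rgap <= gap_limit
                    and qgap <= gap_limit
                    and abs(rgap - qgap) <= gap_limit
                    and trim < a_len
                )
                if joinable:
                    if trim:
                        a_rs += trim
                        a_qs += trim
                        a_len -= trim
                        rgap = a_rs - current.ref_end
                        qgap = a_qs - current.qp_end
                    if rgap or qgap:
                        cig, m, cols = _align_gap(
                            rseq[current.ref_end : a_rs],
                            qseq[current.qp_end : a_qs],
                        )
                        current.runs.extend(_cigar_runs(cig))
                        current.matches += m
                        current.columns += cols
                    current.runs.append((a_len, "="))
                    current.matches += a_len
                    current.columns += a_len
                    current.ref_end = a_rs + a_len
                    current.qp_end = a_qs + a_len
                    continue
                chains.append(current)
            current = _Chain(
                ref_id, qry_id, strand,
                a.ref_start, a.ref_end,
                a.qprime_start(qlen[qry_id]),
                a.qprime_start(qlen[qry_id]) + a_len,
                matches=a_len, columns=a_len,
                runs=[(a_len, "=")],
            )
        if current is not None:
            chains.append(current)

    candidates = []
    for c in chains:
        candidates.append(_chain_to_block(c, qlen))
    # greedy 1-to-1 selection by matches (deterministic tie-break)
    candidates.sort(key=lambda b: (-b.matches, b.ref_id, b.ref_start, b.qry_id))
    accepted: List[AlignmentBlock] = []
    for cand in candidates:
        block = _resolve_overlaps(cand, accepted, qlen)
        if block is not None:
            accepted.append(block)
    accepted.sort(key=lambda b: (b.ref_id, b.ref_start))
    return accepted


def _chain_to_block(c: _Chain, qlen: Dict[str, int]) -> AlignmentBlock:
    if c.strand == "+":
        q0, q1 = c.qp_start, c.qp_end
    else:
        q0, q1 = qlen[c.qry_id] - c.qp_end, qlen[c.qry_id] - c.qp_start
    return AlignmentBlock(
        ref_id=c.ref_id, qry_id=c.qry_id,
        ref_start=c.ref_start, ref_end=c.ref_end,
        qry_start=q0, qry_end=q1,
        strand=c.strand, matches=c.matches, block_length=c.columns,
        cigar=_runs_to_cigar(c.runs),
    )


def _edge_exact_lengths(cigar: str) -> Tuple[int, int]:
    runs = _cigar_runs(cigar)
    first = runs[0][0] if runs and runs[0][1] == "=" else 0
    last = runs[-1][0] if runs and runs[-1][1] == "=" else 0
    return first, last


def _trim_block(block: AlignmentBlock, t_start: int, t_end: int,
                qlen: Dict[str, int]) -> Optional[AlignmentBlock]:
    """Trim ``t_start``/``t_end`` alignment columns off the block edges.

    Trims are only legal inside the terminal exact runs, where ref and
    query advance together; otherwise the block is dropped (None).
    """
    if t_start == 0 and t_end == 0:
        return block
    first, last = _edge_exact_lengths(block.cigar)
    if t_start >= first and t_start > 0:
        return None
    if t_end >= last and t_end > 0:
        return None
    if block.ref_len - t_start - t_end <= 0:
        return None
    runs = _cigar_runs(block.cigar)
    runs[0] = (runs[0][0] - t_start, "=")
    runs[-1] = (runs[-1][0] - t_end, "=")
    qp0 = block.qprime_start(qlen[block.qry_id]) + t_start
    ref_start = block.ref_start + t_start
    ref_end = block.ref_end - t_end
    qp_end = (
        (block.qry_end if block.strand == "+" else qlen[block.qry_id] - block.qry_start)
        - t_end
    )
    if block.strand == "+":
        q0, q1 = qp0, qp_end
    else:
        q0, q1 = qlen[block.qry_id] - qp_end, qlen[block.qry_id] - qp0
    return AlignmentBlock(
        ref_id=block.ref_id, qry_id=block.qry_id,
        ref_start=ref_start, ref_end=ref_end,
        qry_start=q0, qry_end=q1,
        strand=block.strand,
        matches=block.matches - t_start - t_end,
        block_length=block.block_length - t_start - t_end,
        cigar=_runs_to_cigar(runs),
    )


def _resolve_overlaps(
    cand: AlignmentBlock,
    accepted: Sequence[AlignmentBlock],
    qlen: Dict[str, int],
) -> Optional[AlignmentBlock]:
    """Trim ``cand`` until it overlaps no accepted block; None when impossible."""
    for _ in range(8):  # a few passes settle multi-block overlaps
        t_ref_start = t_ref_end = 0
        t_qf_start = t_qf_end = 0  # forward-qry coords
        for b in accepted:
            if b.ref_id == cand.ref_id:
                lo = max(cand.ref_start, b.ref_start)
                hi = min(cand.ref_end, b.ref_end)
                if hi > lo:
                    if b.ref_start <= cand.ref_start and b.ref_end >= cand.ref_end:
                        return None  # contained
                    if lo == cand.ref_start:
                        t_ref_start = max(t_ref_start, hi - lo)
                    elif hi == cand.ref_end:
                        t_ref_end = max(t_ref_end, hi - lo)
                    else:
                        return None  # accepted block sits inside candidate
            if b.qry_id == cand.qry_id:
                lo = max(cand.qry_start, b.qry_start)
                hi = min(cand.qry_end, b.qry_end)
                if hi > lo:
                    if b.qry_start <= cand.qry_start and b.qry_end >= cand.qry_end:
                        return None
                    if lo == cand.qry_start:
                        t_qf_start = max(t_qf_start, hi - lo)
                    elif hi == cand.qry_end:
                        t_qf_end = max(t_qf_end, hi - lo)
                    else:
                        return None
        if cand.strand == "+":
            t_start = max(t_ref_start, t_qf_start)
            t_end = max(t_ref_end, t_qf_end)
        else:
            t_start = max(t_ref_start, t_qf_end)
            t_end = max(t_ref_end, t_qf_start)
        if t_start == 0 and t_end == 0:
            return cand
        trimmed = _trim_block(cand, t_start, t_end, qlen)
        if trimmed is None:
            return None
        cand = trimmed
    return None


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _left_normalize_insertion(seq: str, pos: int, payload: str) -> Tuple[int, str]:
    while pos > 0 and payload[-1] == seq[pos - 1]:
        payload = seq[pos - 1] + payload[:-1]
        pos -= 1
    return pos, payload


def _left_normalize_deletion(seq: str, start: int, end: int) -> Tuple[int, int]:
    while start > 0 and seq[end - 1] == seq[start - 1]:
        start -= 1
        end -= 1
    return start, end


def call_variants(
    blocks: Sequence[AlignmentBlock],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
) -> List[VariantCall]:
    """Emit SNP and run-length-collapsed indel calls from 1-to-1 blocks.

    Positions are reference coordinates; indels are left-normalized.
    Calls whose alleles contain N are suppressed (and logged).
    """
    qry_rev = {name: revcomp(seq) for name, seq in qry.contigs()}
    calls: List[VariantCall] = []
    suppressed = 0
    for block in blocks:
        rseq = ref[block.ref_id]
        qseq = qry[block.qry_id] if block.strand == "+" else qry_rev[block.qry_id]
        r = block.ref_start
        q = block.qprime_start(len(qry[block.qry_id]))
        for n, op in _cigar_runs(block.cigar):
            if op == "=":
                r += n
                q += n
            elif op == "X":
                for i in range(n):
                    ra, aa = rseq[r + i], qseq[q + i]
                    if "N" in (ra, aa):
                        suppressed += 1
                        continue
                    calls.append(VariantCall(block.ref_id, r + i, "snp", ra, aa))
                r += n
                q += n
            elif op == "I":
                payload = qseq[q : q + n]
                pos, payload = _left_normalize_insertion(rseq, r, payload)
                if "N" in payload:
                    suppressed += 1
                else:
                    calls.append(
                        VariantCall(block.ref_id, pos, "insertion", "", payload)
                    )
                q += n
            elif op == "D":
                start, end = _left_normalize_deletion(rseq, r, r + n)
                ref_allele = rseq[start:end]
                if "N" in ref_allele:
                    suppressed += 1
                else:
                    calls.append(
                        VariantCall(block.ref_id, start, "deletion", ref_allele, "")
                    )
                r += n
    if suppressed:
        logger.info("suppressed %d variant calls overlapping ambiguous bases",
                    suppressed)
    calls.sort()
    return calls


# ---------------------------------------------------------------------------
# structural-event classification
# ---------------------------------------------------------------------------

def _weighted_lis(values: List[int], weights: List[int]) -> List[int]:
    """Indices of the maximum-weight strictly increasing subsequence (O(n^2))."""
    n = len(values)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if not n:
        return []
    i = max(range(n), key=lambda x: best[x])
    out = []
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def classify_events(
    blocks: Sequence[AlignmentBlock],
    gap_limit: int = DEFAULT_GAP_LIMIT,
) -> List[StructuralEvent]:
    """Classify junction-level structural differences from 1-to-1 blocks.

    Per reference contig, the dominant (query contig, strand) backbone is
    the maximum-weight collinear chain of blocks.  Each maximal run of
    displaced blocks yields exactly one event: translocation when the run
    maps to a different query contig, inversion when it maps in the
    opposite orientation, relocation otherwise (order inconsistency).
    Additionally, a junction between adjacent backbone blocks whose
    diagonal offset jumps by more than ``gap_limit`` is one relocation.
    """
    events: List[StructuralEvent] = []
    by_ref: Dict[str, List[AlignmentBlock]] = {}
    qry_cover: Dict[str, List[Tuple[int, int, int]]] = {}
    for bid, b in enumerate(blocks):
        by_ref.setdefault(b.ref_id, []).append(b)
        qry_cover.setdefault(b.qry_id, []).append((b.qry_start, b.qry_end, bid))
    block_ids = {id(b): i for i, b in enumerate(blocks)}

    def covered_by_others(qry_id: str, lo: int, hi: int, exclude: set) -> float:
        """Fraction of qry interval [lo, hi) covered by blocks not in exclude."""
        if hi <= lo:
            return 0.0
        covered = 0
        for s, e, bid in qry_cover.get(qry_id, ()):
            if bid in exclude:
                continue
            covered += max(0, min(e, hi) - max(s, lo))
        return covered / (hi - lo)
    for ref_id, group in sorted(by_ref.items()):
        group.sort(key=lambda b: b.ref_start)
        if len(group) < 2:
            continue
        # dominant (qry_id, strand) by aligned reference bases
        weight: Dict[Tuple[str, str], int] = {}
        for b in group:
            key = (b.qry_id, b.strand)
            weight[key] = weight.get(key, 0) + b.ref_len
        dom_qry, dom_strand = max(sorted(weight), key=lambda k: weight[k])
        dom_idx = [
            i for i, b in enumerate(group)
            if b.qry_id == dom_qry and b.strand == dom_strand
        ]
        # backbone: collinear (qry-order-consistent) subset of dominant blocks
        qp = [
            group[i].qry_start if dom_strand == "+" else -group[i].qry_end
            for i in dom_idx
        ]
        lis = _weighted_lis(qp, [group[i].ref_len for i in dom_idx])
        backbone = {dom_idx[i] for i in lis}

        # each maximal displaced run -> one event
        i = 0
        while i < len(group):
            if i in backbone:
                i += 1
                continue
            j = i
            while j + 1 < len(group) and (j + 1) not in backbone:
                j += 1
            run = group[i : j + 1]
            if any(b.qry_id != dom_qry for b in run):
                kind = "translocation"
            elif any(b.strand != dom_strand for b in run):
                kind = "inversion"
            else:
                kind = "relocation"
            events.append(
                StructuralEvent(
                    kind=kind,
                    ref_id=ref_id,
                    qry_id=run[0].qry_id,
                    ref_span=(run[0].ref_start, run[-1].ref_end),
                    qry_span=(
                        min(b.qry_start for b in run),
                        max(b.qry_end for b in run),
                    ),
                )
            )
            i = j + 1

        # offset jumps between reference-adjacent backbone blocks
        bb = sorted(backbone)
        for a_i, b_i in zip(bb, bb[1:]):
            if b_i != a_i + 1:
                continue  # a displaced run between them already made an event
            a, b = group[a_i], group[b_i]
            if dom_strand == "+":
                diag_a = a.qry_start - a.ref_start
                diag_b = b.qry_start - b.ref_start
                gap_lo, gap_hi = a.qry_end, b.qry_start
            else:
                diag_a = a.qry_end + a.ref_start
                diag_b = b.qry_end + b.ref_start
                gap_lo, gap_hi = b.qry_end, a.qry_start
            if abs(diag_b - diag_a) <= gap_limit:
                continue
            # a qry-side gap occupied by other aligned blocks is the
            # re-insertion site of material already counted as its own
            # displaced-run event (relocation or translocation elsewhere)
            exclude = {block_ids[id(a)], block_ids[id(b)]}
            if covered_by_others(dom_qry, gap_lo, gap_hi, exclude) >= 0.5:
                continue
            events.append(
                StructuralEvent(
                    kind="relocation",
                    ref_id=ref_id,
                    qry_id=dom_qry,
                    ref_span=(a.ref_end, b.ref_start),
                    qry_span=(
                        min(a.qry_end, b.qry_start),
                        max(a.qry_end, b.qry_start),
                    ),
                )
            )
    return events


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _union_length(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    for start, end in sorted(intervals):
        total += end - start  # 1-to-1 blocks are disjoint by construction
    return total


def summarize(
    blocks: Sequence[AlignmentBlock],
    variants: Sequence[VariantCall],
    events: Sequence[StructuralEvent],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
) -> ComparisonSummary:
    """Aggregate one comparison into aligned fractions, ANI, and counts."""
    ref_aligned: Dict[str, List[Tuple[int, int]]] = {}
    qry_aligned: Dict[str, List[Tuple[int, int]]] = {}
    total_matches = total_columns = 0
    for b in blocks:
        ref_aligned.setdefault(b.ref_id, []).append((b.ref_start, b.ref_end))
        qry_aligned.setdefault(b.qry_id, []).append((b.qry_start, b.qry_end))
        total_matches += b.matches
        total_columns += b.block_length
    ref_cov = sum(_union_length(v) for v in ref_aligned.values())
    qry_cov = sum(_union_length(v) for v in qry_aligned.values())
    kind_counts = {"relocation": 0, "inversion": 0, "translocation": 0}
    for e in events:
        kind_counts[e.kind] += 1
    return ComparisonSummary(
        ref_aligned_fraction=ref_cov / ref.total_length if ref.total_length else 0.0,
        qry_aligned_fraction=qry_cov / qry.total_length if qry.total_length else 0.0,
        ani=100.0 * total_matches / total_columns if total_columns else 0.0,
        snp_count=sum(1 for v in variants if v.kind == "snp"),
        indel_count=sum(1 for v in variants if v.kind != "snp"),
        relocations=kind_counts["relocation"],
        inversions=kind_counts["inversion"],
        translocations=kind_counts["translocation"],
    )


def compare_genomes(
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    gap_limit: int = DEFAULT_GAP_LIMIT,
    min_contig: int = 1000,
) -> ComparisonResult:
    """Full pairwise comparison of two assemblies.

    Contigs shorter than ``min_contig`` are dropped first so that short
    fragments do not exaggerate structural-difference counts.
    """
    ref_f = filter_short_contigs(ref, min_contig) if min_contig else ref
    qry_f = filter_short_contigs(qry, min_contig) if min_contig else qry
    anchors = find_anchors(ref_f, qry_f, min_anchor)
    blocks = chain_and_align(anchors, ref_f, qry_f, gap_limit)
    variants = call_variants(blocks, ref_f, qry_f)
    events = classify_events(blocks, gap_limit)
    summary = summarize(blocks, variants, events, ref_f, qry_f)
    return ComparisonResult(blocks, variants, events, summary)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def blocks_table(blocks: Sequence[AlignmentBlock]):
    """Alignment blocks as a coords-style DataFrame (1-based inclusive)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ref_id": b.ref_id, "qry_id": b.qry_id,
                "ref_start": b.ref_start + 1, "ref_end": b.ref_end,
                "qry_start": b.qry_start + 1, "qry_end": b.qry_end,
                "strand": b.strand,
                "matches": b.matches, "block_length": b.block_length,
                "identity%": 100.0 * b.matches / b.block_length,
            }
            for b in blocks
        ]
    )


def events_table(events: Sequence[StructuralEvent]):
    """Structural events as a DataFrame (1-based inclusive spans)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "kind": e.kind, "ref_id": e.ref_id, "qry_id": e.qry_id,
                "ref_start": e.ref_span[0] + 1, "ref_end": e.ref_span[1],
                "qry_start": e.qry_span[0] + 1, "qry_end": e.qry_span[1],
            }
            for e in events
        ]
    )


def write_vcf(
    variants: Sequence[VariantCall], ref: GenomeAssembly, path
) -> None:
    """Write calls as a minimal VCF 4.2 file with contig headers.

    Indels are anchored on the preceding reference base per VCF convention
    (the following base when a call sits at position 0).
    """
    lines = ["##fileformat=VCFv4.2", f"##reference={ref.assembly_id}"]
    lines.append(
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant kind">'
    )
    for name, seq in ref.contigs():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants):
        seq = ref[v.ref_id]
        if v.kind == "snp":
            pos1, r_alle, a_alle = v.position + 1, v.ref_allele, v.alt_allele
        elif v.kind == "insertion":
            if v.position > 0:
                anchor = seq[v.position - 1]
                pos1, r_alle, a_alle = v.position, anchor, anchor + v.alt_allele
            else:
                anchor = seq[0]
                pos1, r_alle, a_alle = 1, anchor, v.alt_allele + anchor
        else:  # deletion
            if v.position > 0:
                anchor = seq[v.position - 1]
                pos1 = v.position
                r_alle, a_alle = anchor + v.ref_allele, anchor
            else:
                anchor = seq[len(v.ref_allele)]
                pos1 = 1
                r_alle, a_alle = v.ref_allele + anchor, anchor
        lines.append(
            f"{v.ref_id}\t{pos1}\t.\t{r_alle}\t{a_alle}\t.\tPASS\tTYPE={v.kind}"
        )
    from pathlib import Path as _P

    _P(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, ref: GenomeAssembly) -> List[VariantCall]:
    """Read a VCF (as written by :func:`write_vcf`) back into variant calls."""
    import pysam

    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref_allele = rec.ref
            for alt in rec.alts or ():
                if len(ref_allele) == 1 and len(alt) == 1:
                    calls.append(
                        VariantCall(rec.chrom, rec.pos - 1, "snp", ref_allele, alt)
                    )
                elif len(ref_allele) < len(alt) and alt.startswith(ref_allele):
                    calls.append(
                        VariantCall(
                            rec.chrom, rec.pos - 1 + len(ref_allele),
                            "insertion", "", alt[len(ref_allele):],
                        )
                    )
                elif len(alt) < len(ref_allele) and ref_allele.startswith(alt):
                    calls.append(
                        VariantCall(
                            rec.chrom, rec.pos - 1 + len(alt),
                            "deletion", ref_allele[len(alt):], "",
                        )
                    )
                else:  # complex record: decompose as SNP-like substitution
                    for i, (ra, aa) in enumerate(zip(ref_allele, alt)):
                        if ra != aa:
                            calls.append(
                                VariantCall(rec.chrom, rec.pos - 1 + i, "snp", ra, aa)
                            )
    calls.sort()
    return calls
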