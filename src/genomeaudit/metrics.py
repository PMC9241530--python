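"""Per-assembly summary metrics: N50/L50/N90, GC content, length filters.

The N50 of an assembly is the length of the contig at which the cumulative
sum of descending-sorted contig lengths first reaches at least half of the
total assembly length; L50 is that contig's rank.  N90 is the analogous
statistic at 90%.  GC content is computed over unambiguous bases only, so
runs of N neither count as G+C nor inflate the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import pandas as pd

from .assembly import GenomeAssembly

__all__ = [
    "AssemblyMetrics",
    "compute_metrics",
    "filter_short_contigs",
    "chaff_filter",
    "metrics_table",
]

_GAP_MIN_RUN = 10  # >=10 consecutive N counts as one scaffold gap


@dataclass(frozen=True)
class AssemblyMetrics:
    assembly_id: str
    total_length: int
    contig_count: int
    n50: int
    l50: int
    n90: int
    gc_fraction: float
    min_contig: int
    max_contig: int
    gap_count: int = 0

    @property
    def n50_over_size(self) -> float:
        return self.n50 / self.total_length


def _nx(sorted_desc: list[int], total: int, fraction: float) -> tuple[int, int]:
    """(Nx, Lx): first contig at which the cumulative sum reaches fraction*total."""
    threshold = fraction * total
    cum = 0
    for rank, length in enumerate(sorted_desc, start=1):
        cum += length
        if cum >= threshold:
            return length, rank
    return sorted_desc[-1], len(sorted_desc)


def _count_gap_runs(seq: str, min_run: int = _GAP_MIN_RUN) -> int:
    count = 0
    run = 0
    for ch in seq:
        if ch == "N":
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 0
    if run >= min_run:
        count += 1
    return count


def compute_metrics(assembly: GenomeAssembly) -> AssemblyMetrics:
    """Compute length, contiguity, and composition metrics for one assembly.

    Raises ``ValueError`` on an empty assembly or a zero-length contig.
    """
    if len(assembly) == 0:
        raise ValueError(f"{assembly.assembly_id}: empty assembly")
    lengths = [len(s) for s in assembly.sequences.values()]
    if min(lengths) == 0:
        raise ValueError(f"{assembly.assembly_id}: zero-length contig")
    total = sum(lengths)
    desc = sorted(lengths, reverse=True)
    n50, l50 = _nx(desc, total, 0.5)
    n90, _ = _nx(desc, total, 0.9)
    gc = at = 0
    gaps = 0
    for seq in assembly.sequences.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        gaps += _count_gap_runs(seq)
    if gc + at == 0:
        raise ValueError(f"{assembly.assembly_id}: no unambiguous bases")
    return AssemblyMetrics(
        assembly_id=assembly.assembly_id,
        total_length=total,
        contig_count=len(lengths),
        n50=n50,
        l50=l50,
        n90=n90,
        gc_fraction=gc / (gc + at),
        min_contig=min(lengths),
        max_contig=max(lengths),
        gap_count=gaps,
    )


def filter_short_contigs(assembly: GenomeAssembly, min_len: int) -> GenomeAssembly:
    """Keep contigs of length >= ``min_len`` (boundary inclusive), order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = {name: seq for name, seq in assembly.contigs() if len(seq) >= min_len}
    return GenomeAssembly(assembly.assembly_id, kept)


def chaff_filter(
    assembly: GenomeAssembly,
    coverage: Mapping[str, float],
    len_cutoff: int = 1000,
    depth_fold: float = 3.0,
) -> GenomeAssembly:
    """Remove chaff contigs: shorter than ``len_cutoff`` AND at aberrant depth.

    A contig is chaff only when both conditions hold; depth is aberrant when
    it falls outside [median/depth_fold, median*depth_fold].
    """
    import statistics

    missing = [name for name in assembly.sequences if name not in coverage]
    if missing:
        raise ValueError(f"missing coverage for contigs: {missing}")
    median_depth = statistics.median(coverage[n] for n in assembly.sequences)
    lo, hi = median_depth / depth_fold, median_depth * depth_fold
    kept = {
        name: seq
        for name, seq in assembly.contigs()
        if not (len(seq) < len_cutoff and not lo <= coverage[name] <= hi)
    }
    return GenomeAssembly(assembly.assembly_id, kept)


def metrics_table(metrics: Iterable[AssemblyMetrics]) -> pd.DataFrame:
    """Tabulate metrics with summary-table-style headers."""
    rows = []
    for m in metrics:
        d = asdict(m)
        d["n50_over_size"] = m.n50_over_size
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.rename(
        columns={
            "assembly_id": "Assembly",
            "gc_fraction": "GC content",
            "n50": "N50",
            "l50": "L50",
            "n90": "N90",
            "total_length": "Genome assembly size",
            "n50_over_size": "N50/size ratio",
            "contig_count": "Total contigs",
            "min_contig": "Min contig",
            "max_contig": "Max contig",
            "gap_count": "Gap count",
        }
    )
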