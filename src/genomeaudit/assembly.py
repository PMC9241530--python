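"""Core genome-assembly container and FASTA I/O.

A :class:`GenomeAssembly` is an ordered collection of named nucleotide
sequences (contigs, scaffolds, or closed replicons).  Sequences are stored
as plain upper-case strings; all coordinates elsewhere in the package are
0-based half-open on the forward strand.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GenomeAssembly", "read_fasta", "write_fasta", "revcomp"]

_RC = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_RC)[::-1]


@dataclass
class GenomeAssembly:
    """Named nucleotide sequences of one assembly."""

    assembly_id: str
    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def contigs(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def reverse_complement(self, assembly_id: str | None = None) -> "GenomeAssembly":
        """New assembly with every sequence reverse-complemented."""
        return GenomeAssembly(
            assembly_id or f"{self.assembly_id}_rc",
            {name: revcomp(seq) for name, seq in self.sequences.items()},
        )

    def copy(self, assembly_id: str | None = None) -> "GenomeAssembly":
        return GenomeAssembly(assembly_id or self.assembly_id, dict(self.sequences))


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path, assembly_id: str | None = None) -> GenomeAssembly:
    """Read a (optionally gzipped) FASTA file into a :class:`GenomeAssembly`."""
    path = Path(path)
    if assembly_id is None:
        assembly_id = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if assembly_id.endswith(suffix):
                assembly_id = assembly_id[: -len(suffix)]
    seqs: Dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seqs[record.id] = str(record.seq).upper()
    return GenomeAssembly(assembly_id, seqs)


def write_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    """Write an assembly as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.contigs()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
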