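"""Genome container: ordered chromosomes, lengths, optional sequence.

Coordinates are 0-based half-open throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class Genome:
    """An ordered set of chromosomes with lengths and optional sequence.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp (insertion order is the
        genome order).
    sequence
        Optional mapping chromosome name -> nucleotide string (A/C/G/T/N,
        upper case). When present, each string's length must equal the
        declared chromosome length.
    """

    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.sequence is not None:
            for name, seq in self.sequence.items():
                if name not in self.chrom_lengths:
                    raise ValueError(f"sequence for unknown chromosome {name!r}")
                if len(seq) != self.chrom_lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{self.chrom_lengths[name]} for chromosome {name!r}"
                    )
                extra = set(seq.upper()) - _VALID
                if extra:
                    raise ValueError(f"invalid nucleotides {sorted(extra)} in {name!r}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def has_sequence(self) -> bool:
        return self.sequence is not None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_fasta(cls, path) -> "Genome":
        """Load a genome (with sequence) from a FASTA file."""
        lengths: dict[str, int] = {}
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate chromosome {rec.id!r} in {path}")
            s = str(rec.seq).upper()
            lengths[rec.id] = len(s)
            seqs[rec.id] = s
        if not lengths:
            raise ValueError(f"no sequences found in {path}")
        return cls(chrom_lengths=lengths, sequence=seqs)

    def to_fasta(self, path) -> None:
        if self.sequence is None:
            raise ValueError("genome has no sequence to write")
        records = [
            SeqRecord(Seq(self.sequence[name]), id=name, description="")
            for name in self.chrom_lengths
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Load a sequence-less genome from a two-column chrom-sizes file."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, size = line.split()[:2]
                lengths[name] = int(size)
        return cls(chrom_lengths=lengths)
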