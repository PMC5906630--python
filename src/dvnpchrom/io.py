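"""Readers and writers: BED3 fragments, bedGraph tracks, gene tables,
spike-in count tables.

All formats are plain text, tab-separated, 0-based half-open. Readers
validate coordinates against the genome and report offending line numbers;
writer/reader pairs are exact inverses on valid data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome

FRAGMENT_COLUMNS = ["chrom", "start", "end"]
GENE_COLUMNS = ["id", "chrom", "strand", "tss", "polya"]


# --------------------------------------------------------------- fragments
@dataclass
class FragmentSet:
    """Genomic intervals from one sequencing sample (IP, input, or MNase).

    ``records`` is a DataFrame with columns chrom/start/end (0-based
    half-open). ``size_filter_applied`` records the (min,max) bp range if
    the set has been size-filtered.
    """

    records: pd.DataFrame
    sample_label: str = ""
    size_filter_applied: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        self.records = self.records[FRAGMENT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def validate(self, genome: Genome) -> None:
        """Hard-fail on coordinates outside the genome or empty intervals."""
        for chrom, grp in self.records.groupby("chrom", sort=False):
            if chrom not in genome:
                row = grp.iloc[0]
                raise ValueError(
                    f"fragment ({chrom},{row.start},{row.end}) on unknown chromosome"
                )
            start = grp["start"].to_numpy()
            end = grp["end"].to_numpy()
            bad = (start < 0) | (start >= end) | (end > genome.chrom_lengths[chrom])
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"invalid fragment ({chrom},{start[i]},{end[i]}) "
                    f"on chromosome of length {genome.chrom_lengths[chrom]}"
                )

    def deduplicate(self) -> "FragmentSet":
        return FragmentSet(
            self.records.drop_duplicates(FRAGMENT_COLUMNS),
            sample_label=self.sample_label,
            size_filter_applied=self.size_filter_applied,
        )


def read_fragments(path, genome: Genome, sample_label: str = "") -> FragmentSet:
    """Read a 3+-column BED file of fragments, validating against *genome*.

    Malformed lines and bounds violations raise with the 1-based line
    number of the first offending record.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome.chrom_lengths[chrom]):
                raise ValueError(
                    f"{path}: line {lineno}: interval ({chrom},{start},{end}) out of "
                    f"bounds for chromosome length {genome.chrom_lengths[chrom]}"
                )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    records = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    label = sample_label or str(path)
    return FragmentSet(records, sample_label=label)


def write_fragments(frags: FragmentSet, path) -> None:
    frags.records.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- bedGraph
def write_bedgraph(track, path) -> None:
    """Write a CoverageTrack as bedGraph, merging equal-valued runs.

    Zero runs are written explicitly so the genome-wide mean is
    reconstructible from the file alone.
    """
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            if len(values) == 0:
                continue
            breaks = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(values)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.10g}\n")


def read_bedgraph(path, genome: Genome):
    """Read a bedGraph file back into a CoverageTrack (normalization 'raw')."""
    from .coverage import CoverageTrack

    values = {c: np.zeros(l, dtype=float) for c, l in genome.chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            values[chrom][int(start):int(end)] = float(value)
    return CoverageTrack(values=values)


# -------------------------------------------------------------- gene table
@dataclass
class GeneAnnotation:
    """TSS/polyA anchors for metagene computation.

    ``table`` columns: id, chrom, strand (+/-), tss, polya. For + strand
    genes tss < polya; for - strand genes tss > polya (coordinates are the
    anchor base positions, 0-based).
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        self.table = self.table[GENE_COLUMNS].reset_index(drop=True)
        if len(self.table) and self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lengths(self) -> np.ndarray:
        """Transcribed length (TSS to polyA) in bp, strand-aware."""
        return np.abs(self.table["tss"] - self.table["polya"]).to_numpy()

    def validate(self, genome: Genome) -> None:
        for _, row in self.table.iterrows():
            if row.chrom not in genome:
                raise ValueError(f"gene {row.id!r}: unknown chromosome {row.chrom!r}")
            L = genome.chrom_lengths[row.chrom]
            if not (0 <= row.tss < L and 0 <= row.polya < L):
                raise ValueError(f"gene {row.id!r}: coordinates outside chromosome")
            if row.strand not in ("+", "-"):
                raise ValueError(f"gene {row.id!r}: strand must be + or -")
            if row.tss == row.polya:
                raise ValueError(f"gene {row.id!r}: tss == polya")
            if row.strand == "+" and not row.tss < row.polya:
                raise ValueError(f"gene {row.id!r}: + strand requires tss < polya")
            if row.strand == "-" and not row.tss > row.polya:
                raise ValueError(f"gene {row.id!r}: - strand requires tss > polya")


def read_gene_table(path, genome: Genome | None = None) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "strand": str})
    genes = GeneAnnotation(table)
    if genome is not None:
        genes.validate(genome)
    return genes


def write_gene_table(genes: GeneAnnotation, path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


def gene_table_from_gff(path, genome: Genome | None = None) -> GeneAnnotation:
    """Import shim: map GFF gene start/end to tss/polya by strand.

    GFF is 1-based inclusive; converted to the package's 0-based anchors.
    """
    ids, chroms, strands, tsss, polyas = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            start0, end0 = int(f[3]) - 1, int(f[4]) - 1
            ids.append(gid)
            chroms.append(f[0])
            strands.append(f[6])
            if f[6] == "-":
                tsss.append(end0)
                polyas.append(start0)
            else:
                tsss.append(start0)
                polyas.append(end0)
    genes = GeneAnnotation(pd.DataFrame(
        {"id": ids, "chrom": chroms, "strand": strands, "tss": tsss, "polya": polyas}
    ))
    if genome is not None:
        genes.validate(genome)
    return genes


# ----------------------------------------------------------- spike-in table
SPIKEIN_COLUMNS = ["sample", "genomic_reads", "spike_reads", "spike_mass_added", "dilution"]


def read_spikein_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in SPIKEIN_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"spike-in table missing columns {missing}")
    if (tab[["genomic_reads", "spike_reads"]] < 0).any().any():
        raise ValueError("spike-in read counts must be >= 0")
    return tab[SPIKEIN_COLUMNS]


def write_spikein_table(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
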