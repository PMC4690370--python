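"""Core genome and annotation containers plus FASTA/GFF3 I/O.

A :class:`GenomeRecord` is a single named DNA sequence (typically a closed
circular bacterial chromosome); a :class:`GeneAnnotation` is a protein-coding
interval on it.  Coordinates follow GFF3 conventions: 1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    """Raised for gene annotations that violate the CDS model."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence over {A, C, G, T} with explicit topology."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        seq = self.sequence.upper()
        if set(seq) - _DNA:
            bad = sorted(set(seq) - _DNA)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence
        return (seq.count("G") + seq.count("C")) / len(seq)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(
            id=self.id,
            sequence=reverse_complement(self.sequence),
            topology=self.topology,
        )

    def base(self, position: int) -> str:
        """Base at a 1-based position (wraps for circular genomes)."""
        if self.topology == "circular":
            return self.sequence[(position - 1) % len(self.sequence)]
        return self.sequence[position - 1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS interval, 1-based inclusive, with strand and free-text product."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"{self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def cds_sequence(self, genome: GenomeRecord) -> str:
        """Coding-strand sequence (reverse-complemented for minus genes)."""
        segment = genome.sequence[self.start - 1 : self.end]
        return segment if self.strand == "+" else reverse_complement(segment)


def validate_annotations(
    genome: GenomeRecord, annotations: Sequence[GeneAnnotation]
) -> None:
    """Reject out-of-bounds, non-codon-sized, or overlapping annotations."""
    ordered = sorted(annotations, key=lambda a: a.start)
    previous_end = 0
    previous_id = None
    for ann in ordered:
        if ann.end > len(genome):
            raise AnnotationError(
                f"{ann.gene_id}: end {ann.end} beyond genome length {len(genome)}"
            )
        if len(ann) % 3 != 0:
            raise AnnotationError(
                f"{ann.gene_id}: CDS length {len(ann)} not a multiple of 3"
            )
        if ann.start <= previous_end:
            raise AnnotationError(
                f"{ann.gene_id} overlaps {previous_id} (annotations must be disjoint)"
            )
        previous_end, previous_id = ann.end, ann.gene_id


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path, topology: str = "circular") -> list[GenomeRecord]:
    return [
        GenomeRecord(id=rec.id, sequence=str(rec.seq), topology=topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=f"topology={rec.topology}")
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gff3(
    annotations: Iterable[GeneAnnotation], genome_id: str, path: str | Path
) -> None:
    rows = []
    for ann in annotations:
        attrs = f"ID={ann.gene_id}"
        if ann.product:
            attrs += f";product={ann.product}"
        rows.append(
            (genome_id, "straindelta", "CDS", ann.start, ann.end, ".", ann.strand,
             "0", attrs)
        )
    frame = pd.DataFrame(rows, columns=_GFF_COLUMNS)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        frame.to_csv(handle, sep="\t", header=False, index=False)


def _parse_attributes(raw: str) -> dict[str, str]:
    pairs = (item.split("=", 1) for item in raw.split(";") if "=" in item)
    return {key.strip(): value.strip() for key, value in pairs}


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    frame = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, header=None, dtype=str
    )
    annotations = []
    for _, row in frame.iterrows():
        if row["type"] != "CDS":
            continue
        attrs = _parse_attributes(row["attributes"])
        annotations.append(
            GeneAnnotation(
                gene_id=attrs.get("ID", f"cds_{row['start']}"),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                product=attrs.get("product", ""),
            )
        )
    return sorted(annotations, key=lambda a: a.start)
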