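"""Regulatory and comparative locus analyses.

Three views of how a solventogenesis locus is wired: Spo0A binding-site
(0A box, consensus 5'-TGNCGAA-3') scans upstream of gene starts, intergenic
gap sizes as a proxy for operon tightness, and pairwise DNA/protein percent
identity between orthologous genes under global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._align import nw_matrix, nw_traceback
from .methylome import IupacMotif, scan_motif
from .records import AnnotationError, GeneAnnotation, GenomeRecord

ZERO_A_BOX = "TGNCGAA"

_DNA_ALPHABET = "ACGT"
_DNA_MATRIX = np.full((4, 4), -1, dtype=np.int32)
np.fill_diagonal(_DNA_MATRIX, 1)
_DNA_GAP = 2

_BLOSUM = substitution_matrices.load("BLOSUM62")
_PROTEIN_ALPHABET = str(_BLOSUM.alphabet)
_PROTEIN_MATRIX = np.array(_BLOSUM, dtype=np.int32)
_PROTEIN_GAP = 8


@dataclass(frozen=True)
class ZeroABoxHit:
    gene_id: str
    box_position: int  # 1-based first base on the matching strand's reading
    strand_of_match: str
    distance_upstream: int


@dataclass(frozen=True)
class IdentityResult:
    pct_identity_dna: float | None
    pct_identity_protein: float | None
    alignment_length: int


def scan_0a_boxes(
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    window: int = 300,
    pattern: str = ZERO_A_BOX,
) -> list[ZeroABoxHit]:
    """0A-box matches (either strand) upstream of each gene's start.

    Upstream is 5' of the gene on its own strand; a box counts when it lies
    entirely within `window` bases of the translational start.  The reported
    distance runs from the gene start to the box edge farthest from the gene.
    Circular genomes wrap.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    motif = IupacMotif(pattern)
    plen = len(motif)
    length = len(genome)
    circular = genome.topology == "circular"

    def modular(delta: int) -> int:
        return delta % length if circular else delta

    hits: list[ZeroABoxHit] = []
    sites = scan_motif(genome, motif)
    for gene in annotations:
        for pos, strand in sites:
            lo = pos if strand == "+" else pos - plen + 1
            hi = pos + plen - 1 if strand == "+" else pos
            if gene.strand == "+":
                distance = modular(gene.start - lo)
            else:
                distance = modular(hi - gene.end)
            if plen <= distance <= window:
                hits.append(ZeroABoxHit(gene.gene_id, pos, strand, distance))
    hits.sort(key=lambda h: (h.gene_id, h.distance_upstream))
    return hits


def intergenic_gaps(annotations: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Gaps strictly between consecutive genes (order-invariant input).

    gap = next.start - previous.end - 1; adjacent genes score 0.  Overlapping
    annotations are rejected.
    """
    ordered = sorted(annotations, key=lambda a: a.start)
    rows = []
    for left, right in zip(ordered, ordered[1:]):
        gap = right.start - left.end - 1
        if gap < 0:
            raise AnnotationError(
                f"annotations {left.gene_id} and {right.gene_id} overlap"
            )
        rows.append({"gene_a": left.gene_id, "gene_b": right.gene_id, "gap": gap})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "gap"])


def _encode(seq: str, alphabet: str, label: str) -> np.ndarray:
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains a non-{label} character: {exc}") from exc


def pairwise_identity(a: str, b: str, alphabet: str = "dna") -> IdentityResult:
    """Global-alignment percent identity between two sequences.

    DNA uses match +1 / mismatch -1 / gap -2; protein uses BLOSUM62 with
    gap -8.  Identity is identical columns over total alignment columns
    (gap columns count in the denominator).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if alphabet == "dna":
        codes_a = _encode(a, _DNA_ALPHABET, "DNA")
        codes_b = _encode(b, _DNA_ALPHABET, "DNA")
        matrix, gap = _DNA_MATRIX, _DNA_GAP
    elif alphabet == "protein":
        codes_a = _encode(a, _PROTEIN_ALPHABET, "protein")
        codes_b = _encode(b, _PROTEIN_ALPHABET, "protein")
        matrix, gap = _PROTEIN_MATRIX, _PROTEIN_GAP
    else:
        raise ValueError("alphabet must be 'dna' or 'protein'")
    scores = nw_matrix(codes_a, codes_b, matrix, gap)
    pairs = nw_traceback(codes_a, codes_b, matrix, gap, scores)
    identical = sum(
        1 for i, j in pairs if i >= 0 and j >= 0 and a[i] == b[j]
    )
    pct = 100.0 * identical / len(pairs)
    return IdentityResult(
        pct_identity_dna=pct if alphabet == "dna" else None,
        pct_identity_protein=pct if alphabet == "protein" else None,
        alignment_length=len(pairs),
    )


def gene_identity(
    genome_a: GenomeRecord,
    gene_a: GeneAnnotation,
    genome_b: GenomeRecord,
    gene_b: GeneAnnotation,
) -> IdentityResult:
    """DNA and protein percent identity between two annotated CDSs."""
    from .effects import translate_codon

    cds_a = gene_a.cds_sequence(genome_a)
    cds_b = gene_b.cds_sequence(genome_b)
    dna = pairwise_identity(cds_a, cds_b, "dna")
    protein_a = "".join(
        translate_codon(cds_a[i : i + 3]) for i in range(0, len(cds_a) - 3, 3)
    )
    protein_b = "".join(
        translate_codon(cds_b[i : i + 3]) for i in range(0, len(cds_b) - 3, 3)
    )
    protein = pairwise_identity(protein_a, protein_b, "protein")
    return IdentityResult(
        pct_identity_dna=dna.pct_identity_dna,
        pct_identity_protein=protein.pct_identity_protein,
        alignment_length=dna.alignment_length,
    )


def identity_matrix(sequences: dict[str, str], alphabet: str = "dna") -> pd.DataFrame:
    """Symmetric percent-identity matrix over named sequences."""
    names = list(sequences)
    values = pd.DataFrame(100.0, index=names, columns=names)
    for i, first in enumerate(names):
        for second in names[i + 1 :]:
            result = pairwise_identity(sequences[first], sequences[second], alphabet)
            pct = (
                result.pct_identity_dna
                if alphabet == "dna"
                else result.pct_identity_protein
            )
            values.loc[first, second] = pct
            values.loc[second, first] = pct
    return values


def zero_a_box_table(hits: Sequence[ZeroABoxHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "box_position": [h.box_position for h in hits],
            "strand_of_match": [h.strand_of_match for h in hits],
            "distance_upstream": [h.distance_upstream for h in hits],
        }
    )
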