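"""Codon-aware variant effect classification and deletion-repeat signatures.

Substitutions inside a CDS are translated on the coding strand with the
standard genetic code and partitioned into silent / nonsense / conservative /
nonconservative calls; conservativeness is operationalized as a positive
BLOSUM62 score for the residue pair.  Deletions are classified in-frame or
frameshift, and their endpoints are checked for flanking direct repeats —
the footprint of homologous recombination between short identical sequences,
which removes the intervening segment plus one repeat copy.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .diff import VariantCall, VariantError
from .records import GenomeRecord, GeneAnnotation, reverse_complement

EFFECT_CLASSES = (
    "intergenic",
    "silent",
    "conservative",
    "nonconservative",
    "nonsense",
    "inframe_deletion",
    "inframe_insertion",
    "frameshift",
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def blosum62_score(aa_ref: str, aa_alt: str) -> float:
    return float(_BLOSUM62[aa_ref, aa_alt])


@dataclass(frozen=True)
class EffectCall:
    """A variant decorated with gene context and effect class."""

    variant: VariantCall
    gene_id: str | None
    effect_class: str
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_position: int | None = None
    shorthand: str = ""


@dataclass(frozen=True)
class RepeatSignature:
    """Maximal direct repeat flanking a deletion, with frame context."""

    repeat_length: int
    repeat_sequence: str
    in_frame: bool
    deleted_residue_range: tuple[int, int] | None


def _gene_at(annotations: Sequence[GeneAnnotation], position: int) -> GeneAnnotation | None:
    for gene in annotations:
        if gene.contains(position):
            return gene
    return None


def _deleted_span(call: VariantCall) -> tuple[int, int]:
    """1-based inclusive coordinates of the deleted bases (anchor excluded)."""
    width = len(call.ref_allele) - 1
    return call.position + 1, call.position + width


def classify(
    variant: VariantCall,
    annotations: Sequence[GeneAnnotation],
    genome: GenomeRecord,
) -> EffectCall:
    """Assign a single effect class to a normalized variant.

    Substitutions are mapped to their codon on the coding strand; indels are
    judged by whether they fall wholly inside one CDS and whether their
    length is a multiple of 3.  Deletions spanning a CDS boundary are
    conservatively called frameshift (with a warning).
    """
    if variant.position < 1 or variant.position + len(variant.ref_allele) - 1 > len(genome):
        raise VariantError(f"variant at {variant.position} outside genome bounds")
    if variant.var_type == "substitution":
        return _classify_substitution(variant, annotations, genome)
    return _classify_indel(variant, annotations, genome)


def _classify_substitution(
    variant: VariantCall,
    annotations: Sequence[GeneAnnotation],
    genome: GenomeRecord,
) -> EffectCall:
    gene = _gene_at(annotations, variant.position)
    if gene is None:
        return EffectCall(variant, None, "intergenic", shorthand="No CDS")
    if gene.strand == "+":
        cds_offset = variant.position - gene.start
        alt_base = variant.alt_allele
    else:
        cds_offset = gene.end - variant.position
        alt_base = _COMPLEMENT[variant.alt_allele]
    codon_index, within = divmod(cds_offset, 3)
    cds = gene.cds_sequence(genome)
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    aa_position = codon_index + 1
    if aa_ref == aa_alt:
        effect, shorthand = "silent", "Silent"
    elif aa_alt == "*":
        effect, shorthand = "nonsense", f"{aa_ref}{aa_position}*"
    elif aa_ref != "*" and blosum62_score(aa_ref, aa_alt) > 0:
        effect, shorthand = "conservative", f"{aa_ref}{aa_position}{aa_alt}"
    else:
        effect, shorthand = "nonconservative", f"{aa_ref}{aa_position}{aa_alt}"
    return EffectCall(
        variant, gene.gene_id, effect, aa_ref, aa_alt, aa_position, shorthand
    )


def _classify_indel(
    variant: VariantCall,
    annotations: Sequence[GeneAnnotation],
    genome: GenomeRecord,
) -> EffectCall:
    length = variant.indel_length
    if variant.var_type == "deletion":
        first, last = _deleted_span(variant)
        touching = [
            g for g in annotations if not (last < g.start or first > g.end)
        ]
        if not touching:
            return EffectCall(variant, None, "intergenic", shorthand="No CDS")
        gene = touching[0]
        inside = len(touching) == 1 and gene.start <= first and last <= gene.end
        if not inside:
            warnings.warn(
                f"deletion at {variant.position} spans a CDS boundary; "
                "classified frameshift",
                stacklevel=2,
            )
            return EffectCall(variant, gene.gene_id, "frameshift",
                              shorthand="Frameshift")
        if length % 3 != 0:
            return EffectCall(variant, gene.gene_id, "frameshift",
                              shorthand="Frameshift")
        residues = residue_range(variant, gene, genome)
        shorthand = f"Del. {residues[0]}–{residues[1]}"
        return EffectCall(variant, gene.gene_id, "inframe_deletion",
                          shorthand=shorthand)
    # insertion: inserted between position and position+1
    gene = _gene_at(annotations, variant.position)
    if gene is None or not gene.contains(variant.position + 1):
        return EffectCall(variant, None, "intergenic", shorthand="No CDS")
    if length % 3 != 0:
        return EffectCall(variant, gene.gene_id, "frameshift",
                          shorthand="Frameshift")
    return EffectCall(variant, gene.gene_id, "inframe_insertion",
                      shorthand=f"Ins. {length // 3} aa")


def summarize(effects: Sequence[EffectCall]) -> dict[str, int]:
    """Class-count map over all known classes; counts partition the input."""
    counts = Counter(effect.effect_class for effect in effects)
    return {cls: counts.get(cls, 0) for cls in EFFECT_CLASSES}


def flanking_repeat(
    genome: GenomeRecord,
    deletion: VariantCall,
    annotations: Sequence[GeneAnnotation] = (),
) -> RepeatSignature:
    """Maximal direct repeat at the endpoints of a left-aligned deletion.

    With s the 0-based start of the deleted segment and d its length, the
    repeat is the longest prefix m such that genome[s:s+m] == genome[s+d:s+d+m]
    (capped at d): after recombination between two such repeats the reference
    retains both copies while the mutant keeps one.
    """
    if deletion.var_type != "deletion":
        raise VariantError("flanking_repeat requires a deletion call")
    seq = genome.sequence
    s = deletion.position  # 0-based start of the deleted segment
    d = deletion.indel_length
    limit = min(d, len(seq) - (s + d))
    m = 0
    while m < limit and seq[s + m] == seq[s + d + m]:
        m += 1
    first, last = _deleted_span(deletion)
    gene = next(
        (g for g in annotations if g.start <= first and last <= g.end), None
    )
    in_frame = d % 3 == 0 and gene is not None
    residues = residue_range(deletion, gene, genome) if in_frame else None
    return RepeatSignature(
        repeat_length=m,
        repeat_sequence=seq[s : s + m],
        in_frame=in_frame,
        deleted_residue_range=residues,
    )


def residue_range(
    deletion: VariantCall, gene: GeneAnnotation, genome: GenomeRecord
) -> tuple[int, int]:
    """1-based first and last deleted residue indices on the coding strand.

    Determined by translating the reference and deleted CDS and locating the
    leftmost residue block whose removal turns one protein into the other
    (a translate-and-diff, so codon phase and strand are handled uniformly).
    """
    if deletion.var_type != "deletion":
        raise VariantError("residue_range requires a deletion call")
    first, last = _deleted_span(deletion)
    if not (gene.start <= first and last <= gene.end):
        raise VariantError("deletion not wholly within the CDS")
    d = deletion.indel_length
    if d % 3 != 0:
        raise VariantError("frameshift deletion has no residue range")
    seq = genome.sequence
    mutant = seq[: first - 1] + seq[last:]
    ref_cds = gene.cds_sequence(genome)
    alt_segment = mutant[gene.start - 1 : gene.end - d]
    alt_cds = alt_segment if gene.strand == "+" else reverse_complement(alt_segment)
    ref_protein = "".join(
        translate_codon(ref_cds[i : i + 3]) for i in range(0, len(ref_cds), 3)
    )
    alt_protein = "".join(
        translate_codon(alt_cds[i : i + 3]) for i in range(0, len(alt_cds), 3)
    )
    n_residues = d // 3
    for start in range(len(alt_protein) + 1):
        if (
            ref_protein[:start] == alt_protein[:start]
            and ref_protein[start + n_residues :] == alt_protein[start:]
        ):
            return start + 1, start + n_residues
    raise VariantError("deletion does not reduce to a contiguous residue block")


# ---------------------------------------------------------------------------
# Reporting


def effects_table(
    effects: Sequence[EffectCall], annotations: Sequence[GeneAnnotation]
) -> pd.DataFrame:
    """Per-variant report: locus, mutation type, product, shorthand, class."""
    products = {g.gene_id: g.product for g in annotations}
    type_label = {"substitution": "Sub.", "deletion": "Del.", "insertion": "Ins."}
    rows = []
    for effect in effects:
        rows.append(
            {
                "locus": effect.variant.position,
                "mutation_type": type_label[effect.variant.var_type],
                "product": products.get(effect.gene_id, "No CDS"),
                "shorthand": effect.shorthand,
                "class": effect.effect_class,
            }
        )
    return pd.DataFrame(rows)


def write_summary_json(
    effects: Sequence[EffectCall],
    path: str | Path,
    repeat: RepeatSignature | None = None,
) -> None:
    payload: dict = {"class_counts": summarize(effects), "n_variants": len(effects)}
    if repeat is not None:
        payload["repeat_signature"] = {
            "repeat_length": repeat.repeat_length,
            "repeat_sequence": repeat.repeat_sequence,
            "in_frame": repeat.in_frame,
            "deleted_residue_range": repeat.deleted_residue_range,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
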