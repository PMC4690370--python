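"""Variant calling between two near-identical assembled genomes.

Instead of mapping reads, two finished assemblies are compared directly:
k-mers unique in both genomes act as anchors, a longest-increasing-subsequence
chain selects a collinear anchor backbone, and the short gaps between anchors
are aligned by unit-cost edit distance.  The resulting edit script is emitted
as normalized (left-aligned, parsimonious) variant calls, so that applying all
calls to the reference reconstructs the other assembly exactly.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._align import edit_script
from .records import GenomeRecord

DEFAULT_K = 31
MAX_GAP = 50_000  # longer inter-anchor gaps are treated as structural events


class NoAnchorsError(RuntimeError):
    """Genomes too divergent or too repetitive to share unique k-mers."""


class StructuralVariationError(RuntimeError):
    """An inter-anchor gap is too long for base-level alignment."""


class VariantError(ValueError):
    """A variant call is inconsistent with the reference sequence."""


@dataclass(frozen=True)
class Anchor:
    """An exact k-mer match unique in both genomes (0-based offsets)."""

    ref_pos: int
    alt_pos: int
    length: int

    @property
    def diagonal(self) -> int:
        return self.ref_pos - self.alt_pos


@dataclass(frozen=True)
class VariantCall:
    """A normalized ref->alt difference.

    Substitutions carry single-base alleles.  Indels are VCF-style: the
    position is the 1-based anchor base preceding the event and both alleles
    include that anchor base.
    """

    chrom: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise VariantError("ref and alt alleles must differ")
        if self.position < 1:
            raise VariantError("position must be 1-based and positive")

    @property
    def var_type(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "substitution"
        if len(self.ref_allele) > len(self.alt_allele):
            return "deletion"
        return "insertion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


# ---------------------------------------------------------------------------
# Anchoring


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    positions: dict[str, int] = {}
    duplicated: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in duplicated:
            continue
        if kmer in positions:
            del positions[kmer]
            duplicated.add(kmer)
        else:
            positions[kmer] = i
    return positions


def _anchors_between(ref_seq: str, alt_seq: str, k: int) -> list[Anchor]:
    ref_unique = _unique_kmer_positions(ref_seq, k)
    alt_unique = _unique_kmer_positions(alt_seq, k)
    anchors = [
        Anchor(ref_pos, alt_unique[kmer], k)
        for kmer, ref_pos in ref_unique.items()
        if kmer in alt_unique
    ]
    anchors.sort(key=lambda a: (a.ref_pos, a.alt_pos))
    return anchors


def find_anchors(ref: GenomeRecord, alt: GenomeRecord, k: int = DEFAULT_K) -> list[Anchor]:
    """k-mers occurring exactly once in each genome, sorted by ref offset."""
    if k < 11:
        raise ValueError("k must be at least 11")
    if len(ref) <= k or len(alt) <= k:
        raise ValueError("both genomes must be longer than k")
    anchors = _anchors_between(ref.sequence, alt.sequence, k)
    if not anchors:
        raise NoAnchorsError(
            "no shared unique k-mers: genomes too divergent or too repetitive"
        )
    return anchors


def chain_anchors(anchors: Sequence[Anchor]) -> list[Anchor]:
    """Maximum set of anchors strictly increasing in both coordinates.

    Anchors are scanned in ref order and the longest strictly increasing
    subsequence of alt offsets is extracted (patience sorting); among equal
    extensions the smaller alt offset wins.
    """
    ordered = sorted(anchors, key=lambda a: (a.ref_pos, a.alt_pos))
    tails: list[int] = []  # alt_pos of best chain tail per length
    tail_index: list[int] = []
    parent = [-1] * len(ordered)
    for idx, anchor in enumerate(ordered):
        slot = bisect_left(tails, anchor.alt_pos)
        if slot == len(tails):
            tails.append(anchor.alt_pos)
            tail_index.append(idx)
        elif anchor.alt_pos < tails[slot]:
            tails[slot] = anchor.alt_pos
            tail_index[slot] = idx
        else:
            continue
        parent[idx] = tail_index[slot - 1] if slot > 0 else -1
    if not tails:
        return []
    chain: list[Anchor] = []
    cursor = tail_index[-1]
    while cursor != -1:
        chain.append(ordered[cursor])
        cursor = parent[cursor]
    chain.reverse()
    return chain


def _merge_and_trim(chain: Sequence[Anchor]) -> list[Anchor]:
    """Merge same-diagonal overlaps; trim residual overlaps across diagonals."""
    merged: list[Anchor] = []
    for anchor in chain:
        if merged:
            prev = merged[-1]
            if (
                anchor.diagonal == prev.diagonal
                and anchor.ref_pos <= prev.ref_pos + prev.length
            ):
                extent = anchor.ref_pos + anchor.length - prev.ref_pos
                if extent > prev.length:
                    merged[-1] = replace(prev, length=extent)
                continue
            overlap = max(
                prev.ref_pos + prev.length - anchor.ref_pos,
                prev.alt_pos + prev.length - anchor.alt_pos,
                0,
            )
            if overlap >= anchor.length:
                continue
            if overlap:
                anchor = Anchor(
                    anchor.ref_pos + overlap,
                    anchor.alt_pos + overlap,
                    anchor.length - overlap,
                )
        merged.append(anchor)
    return merged


# ---------------------------------------------------------------------------
# Gap alignment and call construction


def _trim_common(a: str, b: str) -> tuple[str, str, int]:
    """Strip shared prefix/suffix; returns cores and the prefix length."""
    limit = min(len(a), len(b))
    prefix = 0
    while prefix < limit and a[prefix] == b[prefix]:
        prefix += 1
    suffix = 0
    while suffix < limit - prefix and a[-1 - suffix] == b[-1 - suffix]:
        suffix += 1
    a_core = a[prefix : len(a) - suffix]
    b_core = b[prefix : len(b) - suffix]
    return a_core, b_core, prefix


def _calls_from_script(
    ops: str, ref_seq: str, alt_core: str, ref_offset: int, chrom: str
) -> list[VariantCall]:
    """Convert an edit script over (ref core, alt core) into raw calls.

    `ref_offset` is the 0-based position of the ref core within the full
    reference; `ai` indexes into `alt_core` directly.
    """
    calls: list[VariantCall] = []
    ri, ai = ref_offset, 0
    idx = 0
    while idx < len(ops):
        op = ops[idx]
        run = 1
        while idx + run < len(ops) and ops[idx + run] == op:
            run += 1
        if op == "M":
            ri += run
            ai += run
        elif op == "X":
            for step in range(run):
                calls.append(
                    VariantCall(
                        chrom, ri + step + 1, ref_seq[ri + step], alt_core[ai + step]
                    )
                )
            ri += run
            ai += run
        elif op == "D":
            deleted = ref_seq[ri : ri + run]
            if ri > 0:
                call = VariantCall(
                    chrom, ri, ref_seq[ri - 1] + deleted, ref_seq[ri - 1]
                )
            else:  # deletion at contig start: anchor on the following base
                call = VariantCall(chrom, 1, deleted + ref_seq[run], ref_seq[run])
            calls.append(call)
            ri += run
        else:  # insertion
            inserted = alt_core[ai : ai + run]
            if ri > 0:
                call = VariantCall(
                    chrom, ri, ref_seq[ri - 1], ref_seq[ri - 1] + inserted
                )
            else:
                call = VariantCall(chrom, 1, ref_seq[0], inserted + ref_seq[0])
            calls.append(call)
            ai += run
        idx += run
    return calls


def _gap_calls(
    ref_gap: str, alt_gap: str, ref_offset: int, ref_seq: str, chrom: str
) -> list[VariantCall]:
    ref_core, alt_core, prefix = _trim_common(ref_gap, alt_gap)
    if not ref_core and not alt_core:
        return []
    ops = edit_script(ref_core, alt_core)
    return _calls_from_script(ops, ref_seq, alt_core, ref_offset + prefix, chrom)


def _rotate_right(seq: str, amount: int) -> str:
    amount %= len(seq)
    if amount == 0:
        return seq
    return seq[-amount:] + seq[:-amount]


def call_variants(
    ref: GenomeRecord,
    alt: GenomeRecord,
    k: int = DEFAULT_K,
    max_gap: int = MAX_GAP,
) -> list[VariantCall]:
    """Call substitutions and indels turning `ref` into `alt`.

    Circular genome pairs are first brought into a common rotational frame:
    the modal anchor diagonal estimates the rotation between the two FASTA
    starts, and `alt` is rotated to cancel it, so an arbitrary origin choice
    does not produce spurious calls.  Positions are reported on `ref`.
    """
    anchors = find_anchors(ref, alt, k)
    alt_seq = alt.sequence
    backbone = _merge_and_trim(chain_anchors(anchors))
    if ref.topology == "circular" and alt.topology == "circular":
        # A different FASTA origin shows up as a large common anchor diagonal;
        # small indels shift diagonals too, so a candidate rotation is only
        # adopted when it increases collinear anchor coverage.
        diagonal, _ = Counter(a.diagonal for a in anchors).most_common(1)[0]
        if diagonal % len(alt_seq):
            rotated = _rotate_right(alt.sequence, diagonal)
            rotated_anchors = _anchors_between(ref.sequence, rotated, k)
            rotated_backbone = _merge_and_trim(chain_anchors(rotated_anchors))
            if sum(a.length for a in rotated_backbone) > sum(
                a.length for a in backbone
            ):
                alt_seq, backbone = rotated, rotated_backbone
    ref_seq = ref.sequence
    calls: list[VariantCall] = []
    prev_ref = prev_alt = 0
    sentinel = Anchor(len(ref_seq), len(alt_seq), 0)
    for anchor in [*backbone, sentinel]:
        ref_gap = ref_seq[prev_ref : anchor.ref_pos]
        alt_gap = alt_seq[prev_alt : anchor.alt_pos]
        if ref_gap or alt_gap:
            if max(len(ref_gap), len(alt_gap)) > max_gap:
                raise StructuralVariationError(
                    f"inter-anchor gap of {max(len(ref_gap), len(alt_gap))} bp "
                    f"near ref offset {prev_ref} exceeds {max_gap} bp"
                )
            calls.extend(_gap_calls(ref_gap, alt_gap, prev_ref, ref_seq, ref.id))
        prev_ref = anchor.ref_pos + anchor.length
        prev_alt = anchor.alt_pos + anchor.length
    normalized = [
        normalize(call, ref) if call.var_type != "substitution" else call
        for call in calls
    ]
    normalized.sort(key=lambda c: c.position)
    return normalized


# ---------------------------------------------------------------------------
# Normalization and application


def normalize(call: VariantCall, ref: GenomeRecord) -> VariantCall:
    """Left-align an indel against the reference; substitutions pass through.

    Idempotent.  Indels are shifted left one base at a time while the base
    preceding the event equals the last base of the shifted unit (the
    standard VCF left-alignment rule).
    """
    seq = ref.sequence
    if call.var_type == "substitution":
        if seq[call.position - 1] != call.ref_allele:
            raise VariantError(
                f"reference base at {call.position} is {seq[call.position - 1]}, "
                f"call says {call.ref_allele}"
            )
        return call
    if seq[call.position - 1 : call.position - 1 + len(call.ref_allele)] != call.ref_allele:
        raise VariantError(f"call at {call.position} inconsistent with reference")
    if call.position == 1 and (
        (call.var_type == "deletion" and call.ref_allele[-1] == call.alt_allele)
        or (call.var_type == "insertion" and call.alt_allele[-1] == call.ref_allele)
    ):
        # start-of-contig indel anchored on the following base; no left context
        return call
    if call.var_type == "deletion":
        if call.ref_allele[0] != call.alt_allele or len(call.alt_allele) != 1:
            raise VariantError("deletion must be in anchor form (alt = anchor base)")
        start = call.position  # 0-based first deleted base
        width = len(call.ref_allele) - 1
        while start >= 2 and seq[start - 1] == seq[start + width - 1]:
            start -= 1
        return VariantCall(
            call.chrom, start, seq[start - 1 : start + width], seq[start - 1]
        )
    # insertion
    if call.alt_allele[0] != call.ref_allele or len(call.ref_allele) != 1:
        raise VariantError("insertion must be in anchor form (ref = anchor base)")
    inserted = call.alt_allele[1:]
    anchor = call.position - 1  # 0-based anchor index
    while anchor >= 1 and seq[anchor] == inserted[-1]:
        inserted = inserted[-1] + inserted[:-1]
        anchor -= 1
    return VariantCall(
        call.chrom, anchor + 1, seq[anchor], seq[anchor] + inserted
    )


def apply_variants(ref: GenomeRecord | str, calls: Iterable[VariantCall]) -> str:
    """Apply calls to the reference sequence, reconstructing the alt genome."""
    seq = ref.sequence if isinstance(ref, GenomeRecord) else ref
    pieces = list(seq)
    for call in sorted(calls, key=lambda c: c.position, reverse=True):
        start = call.position - 1
        window = "".join(pieces[start : start + len(call.ref_allele)])
        if window != call.ref_allele:
            raise VariantError(
                f"cannot apply call at {call.position}: reference has {window}"
            )
        pieces[start : start + len(call.ref_allele)] = list(call.alt_allele)
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Reporting


def write_vcf(calls: Iterable[VariantCall], genome: GenomeRecord, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=straindelta",
        f"##contig=<ID={genome.id},length={len(genome)}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in sorted(calls, key=lambda c: c.position):
        lines.append(
            f"{call.chrom}\t{call.position}\t.\t{call.ref_allele}\t"
            f"{call.alt_allele}\t.\tPASS\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls = []
    for record in VCF(str(path)):
        calls.append(
            VariantCall(record.CHROM, record.POS, record.REF, record.ALT[0])
        )
    return calls


_TYPE_LABEL = {"substitution": "Sub.", "deletion": "Del.", "insertion": "Ins."}


def variants_table(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """Variant list in the classic resequencing-report layout."""
    return pd.DataFrame(
        {
            "Mut. locus": [c.position for c in calls],
            "Mut. type": [_TYPE_LABEL[c.var_type] for c in calls],
            "Ref.": [c.ref_allele for c in calls],
            "Var.": [c.alt_allele for c in calls],
        }
    )
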