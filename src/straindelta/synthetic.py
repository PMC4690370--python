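"""Synthetic genomes, planted variant truth sets, and simulated kinetics.

The generator emulates the study system the downstream analyses assume: an
AT-rich circular bacterial chromosome carrying non-overlapping CDSs on both
strands, a derived mutant genome with a configured mix of substitutions by
effect class plus one in-frame deletion flanked by direct repeats, and SMRT
kinetics in which IPD ratios follow context-dependent log-normal
distributions and modification QVs separate methylated from unmethylated
motif sites.

Planted substitutions are rejection-sampled against the *same* effect
classifier used downstream, so the planted class labels are consistent with
the classification rule by construction.  The deletion is planted by writing
repeat+spacer+repeat into the target CDS (in whole codons, at a codon phase
chosen so no internal stop appears) and deleting repeat+spacer from the
mutant — the reference therefore carries both repeat copies, exactly the
homologous-recombination footprint the repeat detector looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diff import VariantCall, apply_variants, write_vcf
from .effects import classify
from .methylome import (
    IpdTrack,
    IupacMotif,
    cytosine_context_codes,
    modified_site_coordinates,
)
from .records import GeneAnnotation, GenomeRecord

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Deleted allele and flanking repeat of the canonical worked example: an
# in-frame 24-bp deletion in the sporulation master-regulator gene, bounded
# by two identical 8-bp direct repeats.
SPO0A_DELETED_ALLELE = "ATACCATAAATAAATTATTTGGAT"
SPO0A_REPEAT = "ATACCATA"

MAX_ATTEMPTS = 10_000  # rejection-sampling cap per planted variant


class InfeasibleProfileError(RuntimeError):
    """Gene geometry cannot be realized on the requested genome."""


class UnsatisfiableQuotaError(RuntimeError):
    """A substitution class quota could not be met within the attempt cap."""


@dataclass(frozen=True)
class DeletionSpec:
    """An in-frame, direct-repeat-flanked deletion to plant in one CDS."""

    deleted_sequence: str = SPO0A_DELETED_ALLELE
    repeat_sequence: str = SPO0A_REPEAT
    gene_index: int = 0
    codon: int = 235

    def __post_init__(self) -> None:
        if len(self.deleted_sequence) % 3 != 0 or not self.deleted_sequence:
            raise ValueError("deleted_sequence length must be a positive multiple of 3")
        if not self.deleted_sequence.startswith(self.repeat_sequence):
            raise ValueError("repeat_sequence must be a prefix of deleted_sequence")
        if len(self.repeat_sequence) >= len(self.deleted_sequence):
            raise ValueError("repeat_sequence must be a proper prefix")
        if self.codon < 2:
            raise ValueError("target codon must follow the start codon")


@dataclass(frozen=True)
class GeneratorProfile:
    genome_length: int = 200_000
    gc_fraction: float = 0.30
    n_genes: int = 150
    mean_gene_length: int = 900
    substitution_quota: dict[str, int] = field(default_factory=dict)
    deletion_spec: DeletionSpec | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.mean_gene_length % 3 != 0:
            raise ValueError("mean_gene_length must be a multiple of 3")
        if any(count < 0 for count in self.substitution_quota.values()):
            raise ValueError("substitution quotas must be non-negative")

    @property
    def total_substitutions(self) -> int:
        return sum(self.substitution_quota.values())


def table1_profile(seed: int = 42) -> GeneratorProfile:
    """Desk-scale profile mirroring the study's variant partition.

    200 kb at 30 % GC with 150 genes stands in for the 4.35-Mb chromosome;
    the quotas reproduce the printed partition of the 67 mutant variants:
    10 intergenic, 14 silent, 14 conservative, 27 nonconservative and one
    nonsense substitution, plus the repeat-flanked 24-bp in-frame deletion.
    """
    return GeneratorProfile(
        genome_length=200_000,
        gc_fraction=0.30,
        n_genes=150,
        mean_gene_length=900,
        substitution_quota={
            "intergenic": 10,
            "silent": 14,
            "conservative": 14,
            "nonconservative": 27,
            "nonsense": 1,
        },
        deletion_spec=DeletionSpec(),
        seed=seed,
    )


@dataclass(frozen=True)
class TruthVariant:
    position: int
    ref_allele: str
    alt_allele: str
    planted_class: str

    def as_call(self, chrom: str) -> VariantCall:
        return VariantCall(chrom, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class KineticsModel:
    """Context-dependent log-normal IPD model plus a QV detection model.

    Log-normals are parameterized so the *arithmetic* mean of each context
    equals the configured mean.  Context means default to the in-text IPD
    averages for cytosine contexts (first C of CGCG 1.25, second C 1.11,
    CG 0.89, other C 0.86) over a background of 1.0; detection fractions
    default to the per-motif detected percentages of the methylome table.
    """

    background_mean_ipd: float = 1.0
    context_means: dict[str, float] = field(
        default_factory=lambda: {
            "C_other": 0.86,
            "CG_firstC": 0.89,
            "CGCG_firstC": 1.25,
            "CGCG_secondC": 1.11,
        }
    )
    lognormal_sigma: float = 0.25
    m6a_detection_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "GATC": 0.9914,
            "GRTAAAG": 0.9965,
            "AAGNNNNNCTCC": 0.9961,
            "GGAGNNNNNCTT": 0.9903,
            "CAAAAAR": 0.9710,
        }
    )
    qv_modified_mean: float = 85.0
    qv_unmodified_mean: float = 5.0
    qv_sd: float = 10.0
    qv_call_threshold: float = 30.0
    coverage_mean: float = 58.0

    def __post_init__(self) -> None:
        if self.background_mean_ipd <= 0 or any(
            mean <= 0 for mean in self.context_means.values()
        ):
            raise ValueError("all IPD means must be positive")
        if any(not 0 <= f <= 1 for f in self.m6a_detection_fraction.values()):
            raise ValueError("detection fractions must lie in [0, 1]")
        if not (
            self.qv_modified_mean > self.qv_call_threshold > self.qv_unmodified_mean
        ):
            raise ValueError(
                "QV scale must satisfy modified mean > threshold > unmodified mean"
            )


DEFAULT_MOTIFS = (
    IupacMotif("GATC", 2),
    IupacMotif("GRTAAAG", 6),
    IupacMotif("AAGNNNNNCTCC", 2),
    IupacMotif("GGAGNNNNNCTT", 3),
    IupacMotif("CAAAAAR", 6),
)


# ---------------------------------------------------------------------------
# Sequence construction


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n == 0:
        return ""
    at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=n, p=[at, gc / 2.0, gc / 2.0, at])
    return _BASES[idx].tobytes().decode("ascii")


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """n_codons stop-free codons drawn base-i.i.d. at the profile GC."""
    if n_codons == 0:
        return ""
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    rows = rng.choice(4, size=(n_codons, 3), p=probs)
    while True:
        is_t = rows[:, 0] == 3
        is_a1 = rows[:, 1] == 0
        is_g1 = rows[:, 1] == 2
        third_ag = (rows[:, 2] == 0) | (rows[:, 2] == 2)
        stops = is_t & ((is_a1 & third_ag) | (is_g1 & (rows[:, 2] == 0)))
        if not stops.any():
            break
        rows[stops] = rng.choice(4, size=(int(stops.sum()), 3), p=probs)
    return _BASES[rows.reshape(-1)].tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    n_codons = length // 3
    internal = _random_codons(rng, n_codons - 2, gc)
    stop = _STOPS[int(rng.integers(3))]
    return "ATG" + internal + stop


def _plan_repeat_block(deleted: str, repeat: str) -> tuple[str, str | None, int]:
    """Choose a whole-codon block embedding repeat+spacer+repeat stop-free.

    Returns (block, forced_next_codon_or_None, payload_phase).  The payload
    (deleted+repeat) sits at `phase` within the block; lead/tail filler bases
    are chosen so neither the reference block nor the post-deletion block
    contains a stop codon, the base before the deleted segment differs from
    its last base (so left-alignment cannot shift it), and the base after the
    second repeat copy breaks any longer repeat match.
    """
    payload = deleted + repeat
    after_repeat = deleted[len(repeat)]
    has_stop = lambda s: any(s[i : i + 3] in _STOPS for i in range(0, len(s), 3))
    for phase in (1, 2):
        tail_len = (3 - (phase + len(payload)) % 3) % 3
        for lead in _strings(phase):
            if lead[-1] == deleted[-1]:
                continue
            for tail in _strings(tail_len):
                if tail and tail[0] == after_repeat:
                    continue
                block = lead + payload + tail
                mutant_block = lead + repeat + tail
                if has_stop(block) or has_stop(mutant_block):
                    continue
                if tail_len == 0:
                    next_codon = next(
                        codon
                        for codon in _all_codons()
                        if codon[0] != after_repeat and codon not in _STOPS
                    )
                else:
                    next_codon = None
                return block, next_codon, phase
    raise InfeasibleProfileError(
        "no stop-free codon embedding exists for the requested deletion"
    )


def _strings(n: int) -> list[str]:
    if n == 0:
        return [""]
    alphabet = "ACGT"
    out = [""]
    for _ in range(n):
        out = [s + b for s in out for b in alphabet]
    return out


def _all_codons() -> list[str]:
    return _strings(3)


def _block_layout(gene: GeneAnnotation, spec: DeletionSpec) -> tuple[int, str, str | None, int]:
    """(block 0-based genomic start, block, next codon, payload phase)."""
    block, next_codon, phase = _plan_repeat_block(
        spec.deleted_sequence, spec.repeat_sequence
    )
    block_start = (gene.start - 1) + (spec.codon - 1) * 3
    return block_start, block, next_codon, phase


def _write_block(seq: str, gene: GeneAnnotation, spec: DeletionSpec) -> tuple[str, int]:
    """Overwrite the target CDS with the repeat block; returns (seq, seg start).

    The segment start is the 0-based coordinate of the first deleted base.
    """
    if gene.strand != "+":
        raise InfeasibleProfileError("the deletion target CDS must be plus-strand")
    block_start, block, next_codon, phase = _block_layout(gene, spec)
    extent = len(block) + (3 if next_codon else 0)
    if block_start + extent > gene.end - 3:  # keep the stop codon intact
        raise InfeasibleProfileError(
            f"gene {gene.gene_id} too short to host the deletion block at codon "
            f"{spec.codon}"
        )
    replacement = block + (next_codon or "")
    new_seq = seq[:block_start] + replacement + seq[block_start + extent :]
    return new_seq, block_start + phase


def generate_reference(
    profile: GeneratorProfile,
) -> tuple[GenomeRecord, list[GeneAnnotation]]:
    """Simulate the parent chromosome and its CDS annotations.

    Intergenic spacers are i.i.d. at the profile GC; CDSs are built codon by
    codon excluding stop codons, so annotations are non-overlapping and free
    of internal stops by construction.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(profile.seed)
    length, n = profile.genome_length, profile.n_genes
    if n == 0:
        seq = _random_bases(rng, length, profile.gc_fraction)
        return GenomeRecord("synthetic_ref", seq, "circular"), []
    low = max(99, int(profile.mean_gene_length * 0.7)) // 3
    high = int(profile.mean_gene_length * 1.3) // 3
    gene_lengths = rng.integers(low, high + 1, size=n) * 3
    spec = profile.deletion_spec
    if spec is not None:
        block, next_codon, _ = _plan_repeat_block(
            spec.deleted_sequence, spec.repeat_sequence
        )
        block_codons = len(block) // 3 + (1 if next_codon else 0)
        needed = (spec.codon + block_codons + 2) * 3
        gene_lengths[spec.gene_index] = max(gene_lengths[spec.gene_index], needed)
    min_spacer = 25
    occupied = int(gene_lengths.sum()) + (n + 1) * min_spacer
    if occupied > length:
        raise InfeasibleProfileError(
            f"{n} genes need {occupied} bp but the genome is {length} bp"
        )
    spacers = min_spacer + rng.multinomial(length - occupied, [1.0 / (n + 1)] * (n + 1))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    if spec is not None:
        strands[spec.gene_index] = "+"
    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    position = 1
    for i in range(n):
        parts.append(_random_bases(rng, int(spacers[i]), profile.gc_fraction))
        position += int(spacers[i])
        coding = _random_cds(rng, int(gene_lengths[i]), profile.gc_fraction)
        genomic = coding if strands[i] == "+" else _revcomp(coding)
        annotations.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:04d}",
                start=position,
                end=position + int(gene_lengths[i]) - 1,
                strand=str(strands[i]),
                product=f"synthetic protein {i + 1}",
            )
        )
        parts.append(genomic)
        position += int(gene_lengths[i])
    parts.append(_random_bases(rng, int(spacers[n]), profile.gc_fraction))
    seq = "".join(parts)
    if spec is not None:
        seq, _ = _write_block(seq, annotations[spec.gene_index], spec)
    return GenomeRecord("synthetic_ref", seq, "circular"), annotations


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Variant planting


def plant_variants(
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    profile: GeneratorProfile,
) -> tuple[GenomeRecord, GenomeRecord, list[TruthVariant]]:
    """Plant the quota substitutions and the repeat-flanked deletion.

    Returns (reference, mutant, truth).  The reference is the input genome
    with the repeat block written into the target CDS (unchanged if no
    deletion is requested or the block is already present); the mutant
    carries every planted variant.  Each substitution is rejection-sampled
    until the shared classifier assigns exactly the requested class.
    """
    rng = np.random.default_rng([profile.seed, 1])
    ref_seq = genome.sequence
    truths: list[TruthVariant] = []
    exclusion: tuple[int, int] | None = None
    spec = profile.deletion_spec
    if spec is not None:
        gene = annotations[spec.gene_index]
        block, next_codon, phase = _plan_repeat_block(
            spec.deleted_sequence, spec.repeat_sequence
        )
        payload = spec.deleted_sequence + spec.repeat_sequence
        block_start = (gene.start - 1) + (spec.codon - 1) * 3
        seg_start = block_start + phase  # 0-based first deleted base
        if ref_seq[seg_start : seg_start + len(payload)] != payload:
            ref_seq, seg_start = _write_block(ref_seq, gene, spec)
        d = len(spec.deleted_sequence)
        truths.append(
            TruthVariant(
                position=seg_start,  # 1-based anchor base preceding the segment
                ref_allele=ref_seq[seg_start - 1 : seg_start + d],
                alt_allele=ref_seq[seg_start - 1],
                planted_class="inframe_deletion",
            )
        )
        extent = len(block) + (3 if next_codon else 0)
        exclusion = (block_start - 40, block_start + extent + 40)
    reference = GenomeRecord(genome.id, ref_seq, genome.topology)

    coding_mask = np.zeros(len(ref_seq), dtype=bool)
    for ann in annotations:
        coding_mask[ann.start - 1 : ann.end] = True
    pools = {
        True: np.flatnonzero(coding_mask) + 1,
        False: np.flatnonzero(~coding_mask) + 1,
    }
    planted_positions: list[int] = []
    min_separation = 12
    order = ("intergenic", "silent", "conservative", "nonconservative", "nonsense")
    extra = [c for c in profile.substitution_quota if c not in order]
    if extra:
        raise ValueError(f"unknown substitution classes in quota: {extra}")
    for target_class in order:
        quota = profile.substitution_quota.get(target_class, 0)
        pool = pools[target_class != "intergenic"]
        if quota and pool.size == 0:
            raise UnsatisfiableQuotaError(
                f"no candidate positions for class {target_class!r}"
            )
        for _ in range(quota):
            for attempt in range(MAX_ATTEMPTS):
                position = int(pool[rng.integers(len(pool))])
                if exclusion and exclusion[0] <= position <= exclusion[1]:
                    continue
                if any(
                    abs(position - prev) < min_separation
                    for prev in planted_positions
                ):
                    continue
                ref_base = ref_seq[position - 1]
                alt_base = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
                candidate = VariantCall(reference.id, position, ref_base, alt_base)
                effect = classify(candidate, annotations, reference)
                if effect.effect_class == target_class:
                    truths.append(
                        TruthVariant(position, ref_base, alt_base, target_class)
                    )
                    planted_positions.append(position)
                    break
            else:
                raise UnsatisfiableQuotaError(
                    f"could not plant a {target_class} substitution in "
                    f"{MAX_ATTEMPTS} attempts"
                )
    calls = [t.as_call(reference.id) for t in truths]
    mutant_seq = apply_variants(ref_seq, calls)
    mutant = GenomeRecord("synthetic_mut", mutant_seq, genome.topology)
    return reference, mutant, sorted(truths, key=lambda t: t.position)


# ---------------------------------------------------------------------------
# Kinetics simulation


def simulate_kinetics(
    genome: GenomeRecord,
    model: KineticsModel,
    motifs: Sequence[IupacMotif] = DEFAULT_MOTIFS,
    seed: int = 7,
) -> IpdTrack:
    """Draw one IPD ratio and one modification QV per position and strand.

    IPD ratios are log-normal with the arithmetic mean set by the most
    specific matching cytosine context (background elsewhere); modification
    QVs are Gaussian around the unmodified mean except at motif sites that a
    Bernoulli draw (per-motif detection fraction) marks as methylated.
    """
    rng = np.random.default_rng(seed)
    length = len(genome)
    codes = cytosine_context_codes(genome)
    sigma = model.lognormal_sigma
    mean_by_code = np.array(
        [
            model.background_mean_ipd,
            model.context_means["C_other"],
            model.context_means["CG_firstC"],
            model.context_means["CGCG_firstC"],
            model.context_means["CGCG_secondC"],
        ]
    )
    data: dict[str, list[np.ndarray]] = {}
    for strand in "+-":
        mu = np.log(mean_by_code[codes[strand]]) - sigma * sigma / 2.0
        ipd = rng.lognormal(mean=mu, sigma=sigma)
        qv = np.clip(rng.normal(model.qv_unmodified_mean, model.qv_sd, length), 0, None)
        coverage = rng.poisson(model.coverage_mean, length).astype(float)
        data[strand] = [ipd, qv, coverage]
    for motif in motifs:
        fraction = model.m6a_detection_fraction.get(motif.pattern)
        if fraction is None:
            continue
        by_strand: dict[str, list[int]] = {"+": [], "-": []}
        for pos, strand in modified_site_coordinates(genome, motif):
            by_strand[strand].append(pos - 1)
        for strand in "+-":
            idx = np.array(by_strand[strand], dtype=int)
            if idx.size == 0:
                continue
            methylated = idx[rng.random(idx.size) < fraction]
            data[strand][1][methylated] = np.clip(
                rng.normal(model.qv_modified_mean, model.qv_sd, methylated.size),
                0,
                None,
            )
    return IpdTrack(length, {s: tuple(arrs) for s, arrs in data.items()})


def random_genome(
    length: int,
    gc: float,
    seed: int,
    genome_id: str = "synthetic_random",
    topology: str = "circular",
) -> GenomeRecord:
    """An annotation-free i.i.d. genome (used for kinetics calibration runs)."""
    rng = np.random.default_rng(seed)
    return GenomeRecord(genome_id, _random_bases(rng, length, gc), topology)


# ---------------------------------------------------------------------------
# Worked-example fixture


def spo0a_fixture(
    flank: int = 400, seed: int = 2015
) -> tuple[GenomeRecord, GenomeRecord, GeneAnnotation, TruthVariant]:
    """Parent/mutant pair around the canonical repeat-flanked 24-bp deletion.

    Builds a single plus-strand CDS whose codons 235 onward host the printed
    deleted allele followed by its flanking repeat, embeds it in random
    flanks, and derives the mutant by excising repeat+spacer.  Returns
    (reference, mutant, gene annotation, deletion truth record).
    """
    rng = np.random.default_rng(seed)
    spec = DeletionSpec()
    n_codons = 306
    cds = _random_cds(rng, n_codons * 3, 0.30)
    left = _random_bases(rng, flank, 0.30)
    right = _random_bases(rng, flank, 0.30)
    gene = GeneAnnotation(
        "spo0A",
        start=flank + 1,
        end=flank + len(cds),
        strand="+",
        product="Stage 0 sporulation protein A",
    )
    seq = left + cds + right
    seq, seg_start = _write_block(seq, gene, spec)
    d = len(spec.deleted_sequence)
    reference = GenomeRecord("spo0A_region_ref", seq, "linear")
    mutant = GenomeRecord(
        "spo0A_region_mut", seq[:seg_start] + seq[seg_start + d :], "linear"
    )
    truth = TruthVariant(
        position=seg_start,
        ref_allele=seq[seg_start - 1 : seg_start + d],
        alt_allele=seq[seg_start - 1],
        planted_class="inframe_deletion",
    )
    return reference, mutant, gene, truth


# ---------------------------------------------------------------------------
# Truth-set export


def write_truth_vcf(
    truths: Sequence[TruthVariant], genome: GenomeRecord, path: str | Path
) -> None:
    write_vcf([t.as_call(genome.id) for t in truths], genome, path)


def write_truth_table(truths: Sequence[TruthVariant], path: str | Path) -> None:
    """Truth set as a TSV in the resequencing-report layout plus the class."""
    type_label = lambda t: "Del." if len(t.ref_allele) > 1 else "Sub."
    frame = pd.DataFrame(
        {
            "Mut. locus": [t.position for t in truths],
            "Mut. type": [type_label(t) for t in truths],
            "Ref.": [t.ref_allele for t in truths],
            "Var.": [t.alt_allele for t in truths],
            "class": [t.planted_class for t in truths],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
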