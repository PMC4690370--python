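"""Effect classification, repeat signatures, and residue ranges."""

from __future__ import annotations

import itertools

import pytest

from straindelta import (
    GeneAnnotation,
    GenomeRecord,
    VariantCall,
    classify,
    flanking_repeat,
    residue_range,
    reverse_complement,
    spo0a_fixture,
    summarize,
)
from straindelta.diff import VariantError
from straindelta.effects import blosum62_score, translate_codon

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

# one codon per amino acid, used to build CDSs with a prescribed protein
CODON_OF = {}
for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
    CODON_OF.setdefault(translate_codon(codon), codon)


def _gene_genome(codons: list[str], flank: str = "ACCGTT" * 20):
    """Single plus-strand gene assembled from explicit codons."""
    cds = "ATG" + "".join(codons) + "TAA"
    genome = GenomeRecord("g", flank + cds + flank, "linear")
    gene = GeneAnnotation(
        "geneA", len(flank) + 1, len(flank) + len(cds), "+", "test protein"
    )
    return genome, gene


def test_alanine_to_valine_at_codon_267_gets_canonical_shorthand():
    codons = [CODON_OF["G"]] * 300
    codons[267 - 2] = "GCA"  # codon 267 of the CDS (ATG is codon 1)
    genome, gene = _gene_genome(codons)
    position = gene.start + (267 - 1) * 3 + 1  # middle base of codon 267
    call = VariantCall("g", position, "C", "T")  # GCA -> GTA
    effect = classify(call, [gene], genome)
    assert effect.shorthand == "A267V"
    assert effect.aa_position == 267
    # A/V scores 0 in BLOSUM62, so the >0 rule calls it nonconservative
    assert effect.effect_class == "nonconservative"


def test_every_single_base_codon_change_is_classified_by_the_translation_rule():
    """Exhaustive 64-codon sweep: silent <=> synonymous, nonsense <=> stop,
    conservative <=> positive BLOSUM62 score."""
    for ref_codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
        if ref_codon in STOPS:
            continue
        codons = [CODON_OF["L"], ref_codon, CODON_OF["K"]]
        genome, gene = _gene_genome(codons)
        codon_start = gene.start + 3 + 3 - 1  # 0-based genomic codon start
        for within, alt_base in itertools.product(range(3), BASES):
            if ref_codon[within] == alt_base:
                continue
            alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
            call = VariantCall(
                "g", codon_start + within + 1, ref_codon[within], alt_base
            )
            effect = classify(call, [gene], genome)
            aa_ref, aa_alt = translate_codon(ref_codon), translate_codon(alt_codon)
            if aa_ref == aa_alt:
                expected = "silent"
            elif aa_alt == "*":
                expected = "nonsense"
            elif blosum62_score(aa_ref, aa_alt) > 0:
                expected = "conservative"
            else:
                expected = "nonconservative"
            assert effect.effect_class == expected, (ref_codon, alt_codon)


def test_valine_isoleucine_is_conservative():
    codons = [CODON_OF["T"], "GTA", CODON_OF["K"]]  # V at codon 3
    genome, gene = _gene_genome(codons)
    call = VariantCall("g", gene.start + 6, "G", "A")  # GTA -> ATA (V -> I)
    effect = classify(call, [gene], genome)
    assert blosum62_score("V", "I") > 0
    assert effect.effect_class == "conservative"
    assert effect.shorthand == "V3I"


def test_minus_strand_classification_mirrors_plus_strand(rng):
    """Classifying on a minus-strand gene equals classifying the
    reverse-complemented construct on a plus-strand gene."""
    for _ in range(40):
        n_codons = 20
        codons = [
            CODON_OF[aa]
            for aa in rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_codons)
        ]
        genome, gene = _gene_genome(codons)
        mirrored = GenomeRecord("m", reverse_complement(genome.sequence), "linear")
        length = len(genome)
        mirror_gene = GeneAnnotation(
            gene.gene_id,
            length - gene.end + 1,
            length - gene.start + 1,
            "-",
            gene.product,
        )
        position = int(rng.integers(gene.start, gene.end + 1))
        ref_base = genome.sequence[position - 1]
        alt_base = BASES.replace(ref_base, "")[int(rng.integers(3))]
        plus_effect = classify(
            VariantCall("g", position, ref_base, alt_base), [gene], genome
        )
        comp = dict(zip("ACGT", "TGCA"))
        minus_effect = classify(
            VariantCall(
                "m", length - position + 1, comp[ref_base], comp[alt_base]
            ),
            [mirror_gene],
            mirrored,
        )
        assert plus_effect.effect_class == minus_effect.effect_class
        assert plus_effect.shorthand == minus_effect.shorthand


def test_summarize_partitions_every_call(table1_run):
    effects = [
        classify(call, table1_run.annotations, table1_run.reference)
        for call in table1_run.calls
    ]
    counts = summarize(effects)
    assert sum(counts.values()) == len(effects)
    assert summarize([]) == {cls: 0 for cls in counts}


def test_classifier_agrees_with_planted_truth(table1_run):
    """On synthetic data the classifier must recover every planted class."""
    by_site = {
        (c.position, c.ref_allele, c.alt_allele): c for c in table1_run.calls
    }
    for truth in table1_run.truths:
        call = by_site[(truth.position, truth.ref_allele, truth.alt_allele)]
        effect = classify(call, table1_run.annotations, table1_run.reference)
        assert effect.effect_class == truth.planted_class


# ---------------------------------------------------------------------------
# Flanking repeats


def test_spo0a_deletion_repeat_signature():
    reference, mutant, gene, truth = spo0a_fixture()
    deletion = VariantCall("g", truth.position, truth.ref_allele, truth.alt_allele)
    signature = flanking_repeat(reference, deletion, [gene])
    assert signature.repeat_length == 8
    assert signature.repeat_sequence == "ATACCATA"
    assert signature.in_frame
    first, last = signature.deleted_residue_range
    assert last - first + 1 == 8


def test_repeat_free_deletion_scores_zero():
    genome = GenomeRecord("g", "TTTAAAGGGTTT", "linear")
    deletion = VariantCall("g", 3, "TAAA", "T")  # deletes AAA, followed by GGG
    assert flanking_repeat(genome, deletion).repeat_length == 0
    with pytest.raises(VariantError):
        flanking_repeat(genome, VariantCall("g", 3, "T", "A"))


def test_flanking_repeat_matches_exhaustive_scan(rng):
    for _ in range(200):
        seq = "".join(rng.choice(list("AC"), size=120))  # repeat-rich alphabet
        start = int(rng.integers(10, 60))
        width = int(rng.integers(1, 20))
        genome = GenomeRecord("g", seq, "linear")
        deletion = VariantCall(
            "g", start, seq[start - 1 : start + width], seq[start - 1]
        )
        signature = flanking_repeat(genome, deletion)
        s, d = start, width  # 0-based segment start and length
        oracle = max(
            m
            for m in range(min(d, len(seq) - s - d) + 1)
            if seq[s : s + m] == seq[s + d : s + d + m]
        )
        assert signature.repeat_length == oracle


# ---------------------------------------------------------------------------
# Residue ranges


def test_phase_aligned_deletion_reports_printed_residue_range():
    aa_cycle = "ACDEFGHIKLMNPQRSTW"  # no period-8 repeats
    codons = [CODON_OF[aa_cycle[i % 18]] for i in range(260)]
    genome, gene = _gene_genome(codons)
    first_codon = 235
    seg_start = gene.start - 1 + (first_codon - 1) * 3  # 0-based
    deleted = genome.sequence[seg_start : seg_start + 24]
    mutant_piece = genome.sequence[seg_start - 1]
    deletion = VariantCall("g", seg_start, mutant_piece + deleted, mutant_piece)
    assert residue_range(deletion, gene, genome) == (235, 242)


def test_single_codon_deletion_at_gene_start():
    codons = [CODON_OF["M"], CODON_OF["K"], CODON_OF["W"]]
    genome, gene = _gene_genome(codons)
    # delete the first codon after the start codon boundary: bases 1-3 of CDS
    seg_start = gene.start - 1  # 0-based start of the ATG
    deleted = genome.sequence[seg_start : seg_start + 3]
    anchor = genome.sequence[seg_start - 1]
    deletion = VariantCall("g", seg_start, anchor + deleted, anchor)
    assert residue_range(deletion, gene, genome) == (1, 1)


def test_minus_strand_residue_range_verified_by_translation(rng):
    for _ in range(20):
        codons = [
            CODON_OF[aa]
            for aa in rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40)
        ]
        cds = "ATG" + "".join(codons) + "TAA"
        flank = "".join(rng.choice(list(BASES), size=30))
        genome = GenomeRecord("g", flank + reverse_complement(cds) + flank, "linear")
        gene = GeneAnnotation("minus", 31, 30 + len(cds), "-", "p")
        codon_index = int(rng.integers(2, 38))  # 1-based CDS codon
        n_codons_deleted = int(rng.integers(1, 4))
        # genomic segment of the deleted codons (minus-strand gene)
        seg_end = gene.end - (codon_index - 1) * 3
        seg_start0 = seg_end - n_codons_deleted * 3  # 0-based
        anchor = genome.sequence[seg_start0 - 1]
        deleted = genome.sequence[seg_start0 : seg_start0 + n_codons_deleted * 3]
        deletion = VariantCall("g", seg_start0, anchor + deleted, anchor)
        first, last = residue_range(deletion, gene, genome)
        assert last - first + 1 == n_codons_deleted
        # oracle: removing those residues from the reference protein must
        # give the mutant protein
        ref_cds = gene.cds_sequence(genome)
        ref_protein = "".join(
            translate_codon(ref_cds[i : i + 3]) for i in range(0, len(ref_cds), 3)
        )
        mutant_seq = (
            genome.sequence[: seg_start0]
            + genome.sequence[seg_start0 + n_codons_deleted * 3 :]
        )
        alt_cds = reverse_complement(
            mutant_seq[gene.start - 1 : gene.end - n_codons_deleted * 3]
        )
        alt_protein = "".join(
            translate_codon(alt_cds[i : i + 3]) for i in range(0, len(alt_cds), 3)
        )
        assert (
            ref_protein[: first - 1] + ref_protein[last:] == alt_protein
        )


def test_boundary_spanning_deletion_is_frameshift_with_warning():
    codons = [CODON_OF["K"]] * 10
    genome, gene = _gene_genome(codons)
    seg_start0 = gene.start - 4  # starts in the flank, ends inside the CDS
    anchor = genome.sequence[seg_start0 - 1]
    deleted = genome.sequence[seg_start0 : seg_start0 + 9]
    deletion = VariantCall("g", seg_start0, anchor + deleted, anchor)
    with pytest.warns(UserWarning, match="spans a CDS boundary"):
        effect = classify(deletion, [gene], genome)
    assert effect.effect_class == "frameshift"
    with pytest.raises(VariantError):
        residue_range(deletion, gene, genome)
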