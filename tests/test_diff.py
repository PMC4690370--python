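"""Anchored assembly diff: anchors, chaining, calling, normalization."""

from __future__ import annotations

import itertools

import edlib
import numpy as np
import pytest

from straindelta import (
    Anchor,
    GenomeRecord,
    VariantCall,
    apply_variants,
    call_variants,
    chain_anchors,
    find_anchors,
    normalize,
    spo0a_fixture,
)
from straindelta.diff import (
    NoAnchorsError,
    StructuralVariationError,
    _merge_and_trim,
    read_vcf,
    write_vcf,
)

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def _mutate(rng, seq, n_subs=0, n_dels=0, n_ins=0, spacing=40):
    """Plant well-separated random edits; returns the mutated sequence."""
    positions = np.sort(
        rng.choice(
            np.arange(spacing, len(seq) - spacing, spacing),
            size=n_subs + n_dels + n_ins,
            replace=False,
        )
    )[::-1]
    kinds = ["sub"] * n_subs + ["del"] * n_dels + ["ins"] * n_ins
    rng.shuffle(kinds)
    out = seq
    for pos, kind in zip(positions, kinds):
        pos = int(pos)
        if kind == "sub":
            alt = BASES.replace(out[pos], "")[rng.integers(3)]
            out = out[:pos] + alt + out[pos + 1 :]
        elif kind == "del":
            width = int(rng.integers(1, 12))
            out = out[:pos] + out[pos + width :]
        else:
            insert = _random_seq(rng, int(rng.integers(1, 12)))
            out = out[:pos] + insert + out[pos:]
    return out


# ---------------------------------------------------------------------------
# Anchors


def test_identical_genomes_anchor_backbone_covers_everything(rng):
    seq = _random_seq(rng, 1000)
    genome = GenomeRecord("g", seq, "linear")
    anchors = find_anchors(genome, genome, k=31)
    assert all(a.ref_pos == a.alt_pos for a in anchors)
    backbone = _merge_and_trim(chain_anchors(anchors))
    assert len(backbone) == 1
    assert backbone[0].ref_pos == 0 and backbone[0].length == 1000


def test_periodic_genome_has_no_unique_kmers():
    genome = GenomeRecord("p", "ACGT" * 300, "linear")
    with pytest.raises(NoAnchorsError):
        find_anchors(genome, genome, k=31)


def test_anchors_absent_only_in_windows_overlapping_substitutions(rng):
    k = 31
    seq = _random_seq(rng, 10_000)
    alt = _mutate(rng, seq, n_subs=5, spacing=200)
    sub_sites = {i for i, (a, b) in enumerate(zip(seq, alt)) if a != b}
    assert len(sub_sites) == 5
    ref = GenomeRecord("r", seq, "linear")
    anchors = find_anchors(ref, GenomeRecord("a", alt, "linear"), k=k)
    anchored = {a.ref_pos for a in anchors}
    for start in range(len(seq) - k + 1):
        overlaps = any(start <= site < start + k for site in sub_sites)
        if overlaps:
            assert start not in anchored
        else:
            # the k-mer census is the oracle: unique and unchanged => anchor
            if seq.count(seq[start : start + k]) == 1:
                assert start in anchored


def test_chain_keeps_collinear_and_drops_transposed_anchor():
    collinear = [Anchor(100 * i, 100 * i + 7, 31) for i in range(10)]
    assert chain_anchors(collinear) == collinear
    anchors = list(collinear)
    anchors[4] = Anchor(400, 5000, 31)  # transposed: breaks monotonicity

    def is_increasing(chain):
        return all(
            a.ref_pos < b.ref_pos and a.alt_pos < b.alt_pos
            for a, b in zip(chain, chain[1:])
        )

    best = max(
        (
            subset
            for r in range(len(anchors) + 1)
            for subset in itertools.combinations(anchors, r)
            if is_increasing(list(subset))
        ),
        key=len,
    )
    chained = chain_anchors(anchors)
    assert len(chained) == len(best) == 9
    assert anchors[4] not in chained
    assert chain_anchors([]) == []


# ---------------------------------------------------------------------------
# Variant calling


def test_single_substitution_called_at_exact_position(rng):
    seq = _random_seq(rng, 800)
    pos = 399  # 0-based
    alt_base = BASES.replace(seq[pos], "")[0]
    alt = seq[:pos] + alt_base + seq[pos + 1 :]
    calls = call_variants(
        GenomeRecord("r", seq, "linear"), GenomeRecord("a", alt, "linear")
    )
    assert calls == [VariantCall("r", pos + 1, seq[pos], alt_base)]


def test_spo0a_fixture_yields_single_24bp_deletion():
    reference, mutant, _, truth = spo0a_fixture()
    calls = call_variants(reference, mutant)
    assert len(calls) == 1
    (call,) = calls
    assert call.var_type == "deletion"
    assert call.indel_length == 24
    assert (call.position, call.ref_allele, call.alt_allele) == (
        truth.position,
        truth.ref_allele,
        truth.alt_allele,
    )


def _full_dp_oracle_calls(ref_seq, alt_seq):
    """Independent whole-sequence edit-distance caller (no anchoring).

    Plain-Python DP sharing the documented tie-break policy: extend an open
    gap, then diagonal, then deletion, then insertion.
    """
    n, m = len(ref_seq), len(alt_seq)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        score[i][0] = i
    for j in range(m + 1):
        score[0][j] = j
    for i in range(1, n + 1):
        row, above = score[i], score[i - 1]
        a_char = ref_seq[i - 1]
        for j in range(1, m + 1):
            cost = 0 if a_char == alt_seq[j - 1] else 1
            row[j] = min(above[j - 1] + cost, above[j] + 1, row[j - 1] + 1)
    ops = []
    i, j, last = n, m, "M"
    while i > 0 or j > 0:
        cost = 1
        diag = dele = ins = False
        if i > 0 and j > 0:
            cost = 0 if ref_seq[i - 1] == alt_seq[j - 1] else 1
            diag = score[i][j] == score[i - 1][j - 1] + cost
        dele = i > 0 and score[i][j] == score[i - 1][j] + 1
        ins = j > 0 and score[i][j] == score[i][j - 1] + 1
        if last == "D" and dele:
            op = "D"
        elif last == "I" and ins:
            op = "I"
        elif diag:
            op = "M" if cost == 0 else "X"
        elif dele:
            op = "D"
        else:
            op = "I"
        ops.append(op)
        last = op
        if op in ("M", "X"):
            i, j = i - 1, j - 1
        elif op == "D":
            i -= 1
        else:
            j -= 1
    from straindelta.diff import _calls_from_script

    calls = _calls_from_script("".join(reversed(ops)), ref_seq, alt_seq, 0, "r")
    genome = GenomeRecord("r", ref_seq, "linear")
    return sorted(
        (normalize(c, genome) if c.var_type != "substitution" else c for c in calls),
        key=lambda c: (c.position, c.ref_allele, c.alt_allele),
    )


def test_small_pairs_match_full_dp_oracle(rng):
    """On instances small enough for a full quadratic DP, the anchored
    pipeline produces the oracle's normalized variant set exactly."""
    for trial in range(20):
        seq = _random_seq(rng, 400)
        alt = _mutate(
            rng,
            seq,
            n_subs=int(rng.integers(0, 3)),
            n_dels=int(rng.integers(0, 3)),
            n_ins=int(rng.integers(0, 3)),
        )
        ref = GenomeRecord("r", seq, "linear")
        calls = call_variants(ref, GenomeRecord("a", alt, "linear"), k=15)
        assert apply_variants(ref, calls) == alt  # round trip
        oracle = _full_dp_oracle_calls(seq, alt)
        mine = sorted(
            calls, key=lambda c: (c.position, c.ref_allele, c.alt_allele)
        )
        assert [
            (c.position, c.ref_allele, c.alt_allele) for c in mine
        ] == [(c.position, c.ref_allele, c.alt_allele) for c in oracle], trial


def test_random_pairs_are_cost_optimal_and_round_trip(rng):
    """On up-to-2-kb pairs the called edit cost equals the true edit
    distance (edlib as the independent optimality oracle) and applying the
    calls reconstructs the other assembly."""
    for trial in range(25):
        seq = _random_seq(rng, int(rng.integers(500, 2000)))
        alt = _mutate(
            rng,
            seq,
            n_subs=int(rng.integers(0, 5)),
            n_dels=int(rng.integers(0, 4)),
            n_ins=int(rng.integers(0, 4)),
        )
        ref = GenomeRecord("r", seq, "linear")
        calls = call_variants(ref, GenomeRecord("a", alt, "linear"))
        assert apply_variants(ref, calls) == alt
        cost = sum(
            1 if c.var_type == "substitution" else c.indel_length for c in calls
        )
        assert cost == edlib.align(alt, seq, mode="NW")["editDistance"]


def test_truth_set_recovered_exactly_and_round_trips(table1_run):
    truth = {
        (t.position, t.ref_allele, t.alt_allele) for t in table1_run.truths
    }
    called = {
        (c.position, c.ref_allele, c.alt_allele) for c in table1_run.calls
    }
    assert called == truth
    assert (
        apply_variants(table1_run.reference, table1_run.calls)
        == table1_run.mutant.sequence
    )


def test_rotated_circular_assembly_gives_same_calls(rng):
    seq = _random_seq(rng, 5000)
    pos = 2500
    alt_base = BASES.replace(seq[pos], "")[0]
    alt = seq[:pos] + alt_base + seq[pos + 1 :]
    rotated = alt[1700:] + alt[:1700]  # different arbitrary FASTA start
    calls = call_variants(
        GenomeRecord("r", seq, "circular"), GenomeRecord("a", rotated, "circular")
    )
    assert calls == [VariantCall("r", pos + 1, seq[pos], alt_base)]


def test_long_diverged_gap_raises_structural_error(rng):
    left, right = _random_seq(rng, 300), _random_seq(rng, 300)
    ref = GenomeRecord("r", left + _random_seq(rng, 60_000) + right, "linear")
    alt = GenomeRecord("a", left + _random_seq(rng, 60_000) + right, "linear")
    with pytest.raises(StructuralVariationError):
        call_variants(ref, alt)


# ---------------------------------------------------------------------------
# Normalization


def test_deletion_in_homopolymer_left_aligns_to_first_placement():
    #        123456789
    seq = "GGTAAAACC"
    genome = GenomeRecord("g", seq, "linear")
    # deleting any single A is equivalent; the rightmost placement must
    # normalize to the leftmost anchor (position 3, segment at 4)
    equivalent = []
    for anchor in range(3, 7):  # anchor base before each deletable A
        call = VariantCall("g", anchor, seq[anchor - 1 : anchor + 1], seq[anchor - 1])
        assert apply_variants(genome, [call]) == "GGTAAACC"
        equivalent.append(normalize(call, genome))
    assert len({(c.position, c.ref_allele, c.alt_allele) for c in equivalent}) == 1
    assert equivalent[0].position == 3


def test_normalize_is_idempotent_and_preserves_application(rng):
    for _ in range(50):
        seq = _random_seq(rng, 300)
        start = int(rng.integers(20, 250))
        width = int(rng.integers(1, 10))
        genome = GenomeRecord("g", seq, "linear")
        call = VariantCall(
            "g", start, seq[start - 1 : start + width], seq[start - 1]
        )
        once = normalize(call, genome)
        assert normalize(once, genome) == once
        assert apply_variants(genome, [once]) == apply_variants(genome, [call])


def test_normalize_leaves_substitutions_and_context_free_indels_alone():
    genome = GenomeRecord("g", "AAACGTTT", "linear")
    sub = VariantCall("g", 4, "C", "G")
    assert normalize(sub, genome) == sub
    deletion = VariantCall("g", 3, "ACG", "A")  # preceding A != deleted G
    assert normalize(deletion, genome) == deletion


def test_vcf_round_trip(tmp_path, table1_run):
    path = tmp_path / "calls.vcf"
    write_vcf(table1_run.calls, table1_run.reference, path)
    loaded = read_vcf(path)
    assert [
        (c.position, c.ref_allele, c.alt_allele) for c in loaded
    ] == [
        (c.position, c.ref_allele, c.alt_allele)
        for c in sorted(table1_run.calls, key=lambda c: c.position)
    ]
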