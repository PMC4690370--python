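"""Classify called variants and characterize the deletion's repeat signature.

Substitutions in a CDS are translated on the coding strand: identical
residue = silent, stop gained = nonsense, positive BLOSUM62 score =
conservative, otherwise nonconservative.  The in-frame deletion's endpoints
are scanned for the maximal flanking direct repeat - the footprint of
homologous recombination between two identical short sequences.
"""

from straindelta import (
    call_variants,
    classify,
    flanking_repeat,
    generate_reference,
    plant_variants,
    summarize,
    table1_profile,
)

profile = table1_profile(seed=42)
genome, annotations = generate_reference(profile)
reference, mutant, _ = plant_variants(genome, annotations, profile)
calls = call_variants(reference, mutant)

effects = [classify(call, annotations, reference) for call in calls]
counts = {cls: n for cls, n in summarize(effects).items() if n}
print("class counts:", counts)

deletion = next(c for c in calls if c.var_type == "deletion")
signature = flanking_repeat(reference, deletion, annotations)
print(f"deletion: {deletion.indel_length} bp at position {deletion.position}")
print(f"flanking direct repeat: {signature.repeat_length} bp "
      f"({signature.repeat_sequence}), in frame: {signature.in_frame}")
print("deleted residues:", signature.deleted_residue_range)
# The 24-bp deletion is flanked by the 8-bp repeat ATACCATA and removes
# exactly eight residues without shifting the reading frame.
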