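"""Shared fixtures: one full synthetic strain pair and one kinetics run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from straindelta import (
    GeneAnnotation,
    GenomeRecord,
    KineticsModel,
    TruthVariant,
    VariantCall,
    call_variants,
    generate_reference,
    plant_variants,
    random_genome,
    simulate_kinetics,
    table1_profile,
)
from straindelta.methylome import IpdTrack
from straindelta.synthetic import DEFAULT_MOTIFS, GeneratorProfile


@dataclass(frozen=True)
class StrainPair:
    profile: GeneratorProfile
    reference: GenomeRecord
    mutant: GenomeRecord
    annotations: list[GeneAnnotation]
    truths: list[TruthVariant]
    calls: list[VariantCall]


@pytest.fixture(scope="session")
def table1_run() -> StrainPair:
    """Full desk-scale run: generate, plant the 67-variant truth set, diff."""
    profile = table1_profile(seed=42)
    genome, annotations = generate_reference(profile)
    reference, mutant, truths = plant_variants(genome, annotations, profile)
    calls = call_variants(reference, mutant, k=31)
    return StrainPair(profile, reference, mutant, annotations, truths, calls)


@dataclass(frozen=True)
class KineticsRun:
    genome: GenomeRecord
    model: KineticsModel
    track: IpdTrack


@pytest.fixture(scope="session")
def kinetics_run() -> KineticsRun:
    """Default kinetics model on a genome with several thousand CGCG sites."""
    genome = random_genome(600_000, 0.5, seed=7, genome_id="kinetics_calib")
    model = KineticsModel()
    track = simulate_kinetics(genome, model, DEFAULT_MOTIFS, seed=7)
    return KineticsRun(genome, model, track)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
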