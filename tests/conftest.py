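"""Shared fixtures: small seeded populations exercised by several suites."""

from __future__ import annotations

import numpy as np
import pytest

from retrohome import (
    PlantingPlan,
    SimConfig,
    SyntheticIntronSpec,
    survey,
)
from retrohome.simulate import generate_population


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def ebs_population():
    """One strain, one EBS-consensus intron: 26 full-length copies + 17 free sites."""
    config = SimConfig(
        n_strains=1,
        chromosome_length=150_000,
        intron_specs=(SyntheticIntronSpec(name="Syn.I1"),),
        plans=(PlantingPlan(intron="Syn.I1", n_full_length=26, n_free_sites=17),),
        seed=1,
    )
    return generate_population(config)


@pytest.fixture(scope="session")
def ebs_survey(ebs_population):
    pop = ebs_population
    return survey(pop.genomes, pop.library, pop.model_specs, pop.overrides)


@pytest.fixture(scope="session")
def classc_population():
    """One strain, one class C intron: 2 copies + 17 terminator-gated free sites."""
    config = SimConfig(
        n_strains=1,
        chromosome_length=120_000,
        intron_specs=(
            SyntheticIntronSpec(name="Syn.C1", orf_class="C", ribozyme_group="IIC"),
        ),
        plans=(PlantingPlan(intron="Syn.C1", n_full_length=2, n_free_sites=17),),
        n_decoy_terminators=5,
        seed=7,
    )
    return generate_population(config)


@pytest.fixture(scope="session")
def classc_survey(classc_population):
    pop = classc_population
    return survey(pop.genomes, pop.library, pop.model_specs, pop.overrides)


@pytest.fixture(scope="session")
def ortho_population():
    """Six strains with orthology groups, retrohoming loci and one island transfer."""
    config = SimConfig(
        n_strains=6,
        chromosome_length=80_000,
        intron_specs=(SyntheticIntronSpec(name="Syn.I1"),),
        plans=(
            PlantingPlan(
                intron="Syn.I1",
                strain=0,
                orthology_groups=((0, 1, 2), (1, 2), (3, 4), (4, 5)),
                n_retrohoming_loci=3,
                n_mge_transfers=1,
            ),
        ),
        seed=11,
    )
    return generate_population(config)


@pytest.fixture(scope="session")
def ortho_survey(ortho_population):
    pop = ortho_population
    return survey(pop.genomes, pop.library, pop.model_specs, pop.overrides)
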