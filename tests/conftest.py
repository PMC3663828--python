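"""Shared fixtures: small deterministic genomes and the study-scale bundle."""

import numpy as np
import pytest

from nucleoform import (
    GenomeAssembly,
    ThermoParams,
    fit_position_independent,
    generate_genome,
    invert_energy,
    sample_reads,
)
from nucleoform.pipeline import invert_from_reads
from nucleoform.simulate import study_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_genome():
    """50-kb i.i.d. uniform-composition genome, two chromosomes."""
    r = np.random.default_rng(777)
    return GenomeAssembly({
        "uA": "".join(r.choice(list("ACGT"), size=30_000)),
        "uB": "".join(r.choice(list("ACGT"), size=20_000)),
    })


@pytest.fixture(scope="session")
def study_bundle():
    """Study-scale synthetic dataset: 2 Mb genome, 200k equilibrium reads.

    Shared (read-only) across the parameter-recovery, model-agreement and
    sign-flip tests; includes the sigma=20 pre-processing and the fitted
    order-2 position-independent model.
    """
    cfg = study_config(seed=1)
    genome = generate_genome(cfg)
    reads, truth = sample_reads(genome, cfg)
    energy20, mask20, pair20 = invert_from_reads(reads, genome, sigma=20)
    pi = fit_position_independent(energy20, genome)
    return {
        "config": cfg,
        "genome": genome,
        "reads": reads,
        "truth": truth,
        "energy20": energy20,
        "mask20": mask20,
        "pair20": pair20,
        "pi": pi,
    }
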