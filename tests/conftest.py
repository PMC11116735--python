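"""Shared fixtures: small synthetic families reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mitannot.refdb import build_index
from mitannot.simulate import SimulationSpec, simulate_genome_family, simulate_taxonomy

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for p in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[p] = rng.choice(bases[bases != arr[p]])
    return arr.tobytes().decode()


@pytest.fixture(scope="session")
def identity_family():
    """Zero-divergence family: 5 identical annotated genomes, distinct labels."""
    spec = SimulationSpec(
        seed=11, n_taxa=10, n_genomes=5, genome_length=6000,
        n_protein_genes=5, n_rna_genes=2, substitution_rate=0.0,
    )
    tree = simulate_taxonomy(spec)
    genomes, annotations, truth = simulate_genome_family(spec, tree)
    return spec, tree, genomes, annotations, truth


@pytest.fixture(scope="session")
def identity_index(identity_family):
    _, _, genomes, annotations, _ = identity_family
    return build_index(genomes, annotations, k=24)


@pytest.fixture(scope="session")
def diverged_family():
    """Family of 4 genomes diverged by point substitutions."""
    spec = SimulationSpec(
        seed=7, n_taxa=8, n_genomes=4, genome_length=6000,
        n_protein_genes=5, n_rna_genes=2, substitution_rate=0.005,
    )
    tree = simulate_taxonomy(spec)
    genomes, annotations, truth = simulate_genome_family(spec, tree)
    return spec, tree, genomes, annotations, truth


@pytest.fixture(scope="session")
def diverged_index(diverged_family):
    _, _, genomes, annotations, _ = diverged_family
    return build_index(genomes, annotations, k=24)
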