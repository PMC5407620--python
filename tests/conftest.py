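"""Shared fixtures: small gene-set libraries and a reduced-scale synthetic
study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from temponet.genesets import GeneSet, GeneSetLibrary
from temponet.gsea import nes_matrix
from temponet.network import build_network
from temponet.synthetic import SyntheticSpec, simulate

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_sets(spec: dict[str, set[str]]) -> GeneSetLibrary:
    """Helper: library from {name: genes} (insertion order preserved)."""
    return GeneSetLibrary([GeneSet(name=k, genes=frozenset(v)) for k, v in spec.items()])


@pytest.fixture
def toy_library() -> GeneSetLibrary:
    return make_sets(
        {
            "alpha": {"G1", "G2", "G3"},
            "beta": {"G2", "G4"},
            "gamma": {"G5", "G6"},
        }
    )


def random_library(rng: np.random.Generator, n_sets: int, n_genes: int,
                   min_size: int = 2, max_size: int = 10) -> GeneSetLibrary:
    genes = np.array([f"G{i}" for i in range(n_genes)], dtype=object)
    sets = []
    for i in range(n_sets):
        k = int(rng.integers(min_size, max_size + 1))
        sets.append(GeneSet(name=f"S{i:03d}", genes=frozenset(rng.choice(genes, k, replace=False))))
    return GeneSetLibrary(sets)


SMALL_SPEC = SyntheticSpec(
    n_genes=600,
    n_processes=40,
    t_points=5,
    path_length=5,
    seed=42,
)


@pytest.fixture(scope="session")
def small_study():
    """Reduced-scale planted study: (library, matrix, probes, truth, nes, network).

    The enrichment grid is computed directly from the generated matrix (the
    probe/preprocess route has its own dedicated tests).
    """
    library, matrix, probes, truth = simulate(SMALL_SPEC)
    nm = nes_matrix(matrix, library, n_perm=200, seed=7)
    G = build_network(library)
    return library, matrix, probes, truth, nm, G
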