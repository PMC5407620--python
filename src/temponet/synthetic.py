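"""Synthetic gene-set libraries, fold-change matrices and probe tables with
a planted perturbed path, so every pipeline stage is testable end to end.

The generator emulates the structure the analysis assumes: a heavy-tailed
(power-law-like) set-size distribution with a hard minimum of 16 genes,
shared-gene connectivity between processes, and per-time-point perturbation.
A chain of ``path_length`` processes is planted: consecutive chain members
deliberately share at least one "connector" gene, and the genes of chain
process j receive a large fold change (``effect_size``) at time point j.
Background cells are centered noise, with a small per-cell rate of sporadic
moderate perturbations so that a realistic fraction of genes survives the
never-perturbed drop of the preprocessing stage (real temporal microarray
data keeps roughly two thirds of genes there).

All generators are pure functions of (spec, seed): the same spec reproduces
bitwise-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

import pandas as pd

from ._util import log, rng_from
from .genesets import GeneSet, GeneSetLibrary
from .preprocess import ProbeTable

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "sample_set_sizes",
    "size_distribution_pmf",
    "make_library",
    "make_fc_matrix",
    "make_probe_table",
    "simulate",
]

#: Day labels of the canonical 10-point schedule (used when T == 10).
CANONICAL_DAYS = (1, 6, 10, 14, 35, 56, 77, 98, 119, 140)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults describe the standard test conditions: 2000 genes, 120
    processes, 10 time points, a planted chain of length 10, effect size 3
    (log2) against background noise 0.2.
    """

    n_genes: int = 2000
    n_processes: int = 120
    t_points: int = 10
    path_length: int = 10
    size_exponent: float = 2.5
    min_size: int = 16
    max_size: int | None = None
    overlap_rate: float = 1.0
    effect_size: float = 3.0
    noise_scale: float = 0.2
    replicate_noise: float = 0.2
    background_perturb_rate: float = 0.25
    background_perturb_low: float = 1.2
    background_perturb_high: float = 2.0
    planted_signs: str = "random"  # or "positive"
    extra_probe_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_processes < self.path_length:
            raise ValueError("need n_processes >= path_length")
        if self.path_length > self.t_points:
            raise ValueError("planted path cannot be longer than t_points")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ValueError("overlap_rate must lie in [0, 1]")
        if self.effect_size != 0 and self.effect_size <= self.noise_scale:
            # effect 0 is the explicit no-signal null model; any actual
            # signal must rise above the background noise
            raise ValueError("effect_size must exceed noise_scale (or be 0 for a null model)")
        if self.planted_signs not in ("random", "positive"):
            raise ValueError("planted_signs must be 'random' or 'positive'")

    @property
    def timepoint_labels(self) -> tuple[str, ...]:
        days = CANONICAL_DAYS if self.t_points == 10 else tuple(range(1, self.t_points + 1))
        return tuple(f"Day {d}" for d in days)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PlantedTruth:
    """Bookkeeping of what was planted, for recovery tests.

    ``chain`` is the ordered planted process sequence; ``connectors[j]`` is
    the gene deliberately shared by chain[j] and chain[j+1];
    ``planted_cells`` pairs each chain process with its perturbed time
    point; ``planted_genes`` maps each chain process to its member genes.
    """

    chain: tuple[str, ...]
    connectors: tuple[str, ...]
    planted_cells: tuple[tuple[str, str], ...] = ()
    planted_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "chain": list(self.chain),
                    "connectors": list(self.connectors),
                    "planted_cells": [list(c) for c in self.planted_cells],
                    "planted_genes": {k: list(v) for k, v in self.planted_genes.items()},
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            chain=tuple(d["chain"]),
            connectors=tuple(d["connectors"]),
            planted_cells=tuple((a, b) for a, b in d["planted_cells"]),
            planted_genes={k: tuple(v) for k, v in d["planted_genes"].items()},
        )


# ---------------------------------------------------------------------------
# Set sizes
# ---------------------------------------------------------------------------


def sample_set_sizes(
    n: int,
    exponent: float = 2.5,
    min_size: int = 16,
    max_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Heavy-tailed set sizes: floor of a truncated Pareto with the given
    tail exponent, clipped to [min_size, max_size]."""
    if exponent <= 1:
        raise ValueError("size_exponent must exceed 1")
    rng = rng or np.random.default_rng()
    max_size = max_size or 8 * min_size
    u = rng.random(n)
    raw = min_size * (1.0 - u) ** (-1.0 / (exponent - 1.0))
    return np.minimum(np.floor(raw), max_size).astype(int)


def size_distribution_pmf(
    sizes: Sequence[int], exponent: float, min_size: int, max_size: int
) -> np.ndarray:
    """Analytic pmf of the floored, clipped Pareto at the given integer
    sizes — the reference for goodness-of-fit checks on sampled sizes."""

    def cdf(x: float) -> float:
        if x < min_size:
            return 0.0
        return 1.0 - (x / min_size) ** (-(exponent - 1.0))

    out = []
    for k in sizes:
        if k < max_size:
            out.append(cdf(k + 1) - cdf(k))
        elif k == max_size:
            out.append(1.0 - cdf(k))
        else:
            out.append(0.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------


def _gene_names(n: int) -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"G{i:0{width}d}" for i in range(n)], dtype=object)


def make_library(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[GeneSetLibrary, PlantedTruth]:
    """Generate the gene-set library with the planted connected chain.

    ``overlap_rate`` is the fraction of each set drawn from the common gene
    pool (shared-prone); the remainder comes from a private, per-set block.
    Rate 1 samples everything from the common pool (overlap arises from
    birthday collisions, as in real libraries); rate 0 makes non-chain sets
    pairwise disjoint. Infeasible private allocations raise.
    """
    rng = rng or rng_from(spec.seed, 0)
    genes = _gene_names(spec.n_genes)
    sizes = sample_set_sizes(
        spec.n_processes, spec.size_exponent, spec.min_size, spec.max_size, rng
    )
    sizes = np.minimum(sizes, spec.n_genes)
    n_private = np.round(sizes * (1.0 - spec.overlap_rate)).astype(int)
    total_private = int(n_private.sum())
    if total_private > spec.n_genes:
        raise ValueError(
            f"infeasible overlap constraints: {total_private} private genes "
            f"needed but only {spec.n_genes} available"
        )
    # Private blocks come off the tail of the gene list; the head is the pool.
    pool = genes[: spec.n_genes - total_private]
    if spec.overlap_rate > 0 and pool.size == 0:
        raise ValueError("infeasible overlap constraints: empty common pool")
    width = len(str(spec.n_processes - 1))
    names = [f"P{i:0{width}d}" for i in range(spec.n_processes)]
    sets: list[set[str]] = []
    cursor = spec.n_genes - total_private
    for i in range(spec.n_processes):
        n_shared = int(sizes[i] - n_private[i])
        members: set[str] = set()
        if n_shared:
            members |= set(rng.choice(pool, size=min(n_shared, pool.size), replace=False))
        if n_private[i]:
            members |= set(genes[cursor : cursor + n_private[i]])
            cursor += int(n_private[i])
        sets.append(members)
    # Plant the chain on the largest sets: a wide top block of perturbed
    # genes makes the planted process separable from partially overlapping
    # background sets, which is the point of a positive control.
    largest = np.argsort(-sizes, kind="stable")[: spec.path_length]
    chain_idx = [int(i) for i in rng.permutation(largest)]
    connectors = []
    for a, b in zip(chain_idx, chain_idx[1:]):
        shared = sets[a] & sets[b]
        if shared:
            connector = sorted(shared)[0]
        else:
            connector = sorted(sets[a])[int(rng.integers(len(sets[a])))]
            sets[b].add(connector)
        connectors.append(connector)
    library = GeneSetLibrary(
        [
            GeneSet(name=names[i], genes=frozenset(sets[i]), description="synthetic")
            for i in range(spec.n_processes)
        ]
    )
    chain = tuple(names[i] for i in chain_idx)
    log.info(
        "synthetic library: %d sets over %d genes, planted chain of %d",
        len(library), len(library.universe), len(chain),
    )
    return library, PlantedTruth(chain=chain, connectors=tuple(connectors))


# ---------------------------------------------------------------------------
# Fold-change matrix
# ---------------------------------------------------------------------------


def make_fc_matrix(
    spec: SyntheticSpec,
    library: GeneSetLibrary,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Gene x time-point log2 fold changes with the planted signal.

    Background cells ~ N(0, noise_scale); a ``background_perturb_rate``
    fraction of cells get sporadic moderate perturbations (uniform magnitude
    in [low, high], random sign); the genes of planted chain process j get
    +-``effect_size`` (plus noise) at time point j. Returns the matrix and
    the truth manifest extended with planted cells and genes.
    """
    rng = rng or rng_from(spec.seed, 1)
    labels = spec.timepoint_labels
    # All spec genes are "measured", whether or not any set contains them.
    gene_list = sorted(set(_gene_names(spec.n_genes)) | set(library.universe))
    n, t = len(gene_list), len(labels)
    gidx = {g: i for i, g in enumerate(gene_list)}
    values = rng.normal(0.0, spec.noise_scale, size=(n, t))
    sporadic = rng.random((n, t)) < spec.background_perturb_rate
    n_spor = int(sporadic.sum())
    mags = rng.uniform(spec.background_perturb_low, spec.background_perturb_high, size=n_spor)
    signs = rng.choice((-1.0, 1.0), size=n_spor)
    values[sporadic] = mags * signs
    gene_sign = (
        rng.choice((-1.0, 1.0), size=n)
        if spec.planted_signs == "random"
        else np.ones(n)
    )
    planted_cells = []
    planted_genes = {}
    for j, proc in enumerate(truth.chain):
        members = sorted(library[proc].genes)
        rows = [gidx[g] for g in members]
        values[rows, j] = gene_sign[rows] * spec.effect_size + rng.normal(
            0.0, spec.noise_scale, size=len(rows)
        )
        planted_cells.append((proc, labels[j]))
        planted_genes[proc] = tuple(members)
    matrix = pd.DataFrame(values, index=gene_list, columns=list(labels))
    out_truth = PlantedTruth(
        chain=truth.chain,
        connectors=truth.connectors,
        planted_cells=tuple(planted_cells),
        planted_genes=planted_genes,
    )
    return matrix, out_truth


# ---------------------------------------------------------------------------
# Probe table
# ---------------------------------------------------------------------------


def make_probe_table(
    spec: SyntheticSpec,
    matrix: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> ProbeTable:
    """Probe-level replicate table whose preprocessing reproduces ``matrix``.

    Every gene gets a primary probe: replicate triplets are the matrix value
    plus N(0, replicate_noise); p-values are small where the underlying cell
    is perturbed (|value| > 1) and uninformative elsewhere. A fraction of
    genes (``extra_probe_rate``) gets a second, attenuated probe with larger
    p-values — these exercise the secondary-fill branches (sub-threshold
    values, mixed signs) without ever outranking the primary probe.
    """
    rng = rng or rng_from(spec.seed, 2)
    genes = list(matrix.index)
    labels = list(matrix.columns)
    vals = matrix.to_numpy(dtype=float)
    n, t = vals.shape
    probe_ids: list[str] = []
    gene_symbols: list[str] = []
    reps_list: list[np.ndarray] = []
    pvals_list: list[np.ndarray] = []

    def add_probe(g_i: int, suffix: str, scale: float, primary: bool) -> None:
        base = vals[g_i] * scale
        reps = base[:, None] + rng.normal(0.0, spec.replicate_noise, size=(t, 3))
        if primary:
            # informative p-values: small where the underlying cell is perturbed
            perturbed = np.abs(base) > 1.0
            p = np.where(
                perturbed,
                rng.uniform(1e-5, 1e-3, size=t),
                rng.uniform(0.05, 0.95, size=t),
            )
        else:
            # attenuated secondary probes never outrank the primary
            p = rng.uniform(0.2, 0.95, size=t)
        probe_ids.append(f"{genes[g_i]}_{suffix}")
        gene_symbols.append(genes[g_i])
        reps_list.append(reps)
        pvals_list.append(p)

    for g_i in range(n):
        add_probe(g_i, "p1", 1.0, primary=True)
        if rng.random() < spec.extra_probe_rate:
            add_probe(g_i, "p2", 0.4, primary=False)
    return ProbeTable(
        probe_ids=np.array(probe_ids, dtype=object),
        gene_symbols=np.array(gene_symbols, dtype=object),
        timepoints=labels,
        replicates=np.stack(reps_list),
        pvalues=np.stack(pvals_list),
    )


def simulate(spec: SyntheticSpec) -> tuple[GeneSetLibrary, pd.DataFrame, ProbeTable, PlantedTruth]:
    """Convenience wrapper: library, fold-change matrix, probe table, truth."""
    library, truth = make_library(spec, rng_from(spec.seed, 0))
    matrix, truth = make_fc_matrix(spec, library, truth, rng_from(spec.seed, 1))
    probes = make_probe_table(spec, matrix, rng_from(spec.seed, 2))
    return library, matrix, probes, truth
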