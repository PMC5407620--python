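"""The shared-gene process network and its degree-preserving null model.

Nodes are processes (gene sets); an undirected edge joins two processes iff
they share at least one gene, and the edge remembers the shared genes. The
null model randomizes topology by repeated double-edge swaps, which conserve
every node's degree exactly; counting how often an observed edge recurs
across many randomized networks estimates the probability of seeing that
edge by degree alone. Edges much rarer than expected from degree are the
interesting ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import int_seed, log
from .genesets import GeneSetLibrary

__all__ = [
    "build_network",
    "distributions",
    "degree_preserving_shuffle",
    "edge_probabilities",
    "EdgeProbabilityTable",
    "compare_link_probability_sets",
    "ComparisonReport",
    "write_edge_list",
    "read_edge_list",
]


def build_network(library: GeneSetLibrary) -> nx.Graph:
    """All-pairs shared-gene network of a library.

    Node attribute ``size`` = set size; edge attributes ``shared``
    (frozenset of shared genes) and ``weight`` (their count). No self-edges.
    """
    if len(library) < 2:
        raise ValueError("need at least 2 sets to build a network")
    G = nx.Graph()
    for s in library:
        G.add_node(s.name, size=s.size)
    gene2sets: dict[str, list[str]] = {}
    for s in library:
        for g in s.genes:
            gene2sets.setdefault(g, []).append(s.name)
    shared: dict[tuple[str, str], set[str]] = {}
    for g, names in gene2sets.items():
        if len(names) < 2:
            continue
        for a, b in combinations(sorted(names), 2):
            shared.setdefault((a, b), set()).add(g)
    for (a, b), genes in shared.items():
        G.add_edge(a, b, shared=frozenset(genes), weight=len(genes))
    return G


def distributions(network: nx.Graph, bin_width: int = 1) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Total-normalized histograms of set sizes and node degrees.

    Returns (size_hist, degree_hist) as DataFrames with columns
    ``bin_start`` and ``fraction`` (each histogram sums to 1). The size
    histogram is None when nodes carry no ``size`` attribute.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")

    def hist(values: Sequence[int]) -> pd.DataFrame:
        values = np.asarray(values)
        lo, hi = int(values.min()), int(values.max())
        edges = np.arange(lo, hi + 2 * bin_width, bin_width)
        counts, _ = np.histogram(values, bins=edges)
        return pd.DataFrame({"bin_start": edges[:-1], "fraction": counts / counts.sum()})

    degs = [d for _, d in network.degree()]
    sizes = [network.nodes[n].get("size") for n in network.nodes]
    size_hist = hist([s for s in sizes if s is not None]) if all(s is not None for s in sizes) else None
    return size_hist, hist(degs)


def degree_preserving_shuffle(
    network: nx.Graph, seed: int | None = None, swap_factor: int = 10
) -> nx.Graph:
    """Randomize topology with ``swap_factor * |E|`` attempted double-edge
    swaps; swaps creating self-edges or duplicate edges are rejected.

    The degree sequence of the result is identical to the input's. Shared-
    gene annotations are dropped: the null is topology-only. Networks where
    no legal swap exists (e.g. a triangle, or any complete graph) come back
    as an identical copy with a logged note.
    """
    H = nx.Graph()
    H.add_nodes_from(network.nodes())
    H.add_edges_from(network.edges())
    n_attempts = swap_factor * H.number_of_edges()
    if n_attempts == 0:
        log.debug("no edges; returning identical copy")
        return H
    try:
        nx.double_edge_swap(H, nswap=n_attempts, max_tries=n_attempts, seed=seed)
    except nx.NetworkXAlgorithmError:
        # Attempt budget exhausted before n_attempts *successful* swaps --
        # this is the expected stopping condition under attempt semantics.
        pass
    except nx.NetworkXError as exc:
        log.debug("graph admits no double-edge swap (%s); identical copy returned", exc)
    return H


@dataclass
class EdgeProbabilityTable:
    """Per observed edge, the fraction of randomized networks containing it."""

    probabilities: dict[tuple[str, str], float]
    n_random: int

    def values(self) -> np.ndarray:
        return np.array(list(self.probabilities.values()), dtype=float)

    def __getitem__(self, pair: Iterable[str]) -> float:
        a, b = sorted(pair)
        return self.probabilities[(a, b)]

    def __contains__(self, pair: Iterable[str]) -> bool:
        a, b = sorted(pair)
        return (a, b) in self.probabilities

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"process_a": a, "process_b": b, "probability": p}
            for (a, b), p in self.probabilities.items()
        ]
        return pd.DataFrame(rows)


def edge_probabilities(
    network: nx.Graph,
    n_random: int = 10000,
    seed: int | None = None,
    swap_factor: int = 10,
) -> EdgeProbabilityTable:
    """Estimate, for every observed edge, the probability of occurring in a
    degree-preserving random network.

    Probabilities are computed only for observed edges (the question the
    null answers), not the full pair space.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    edges = [tuple(sorted(e)) for e in network.edges()]
    counts = dict.fromkeys(edges, 0)
    for i in range(n_random):
        H = degree_preserving_shuffle(
            network, seed=None if seed is None else int_seed(seed, i), swap_factor=swap_factor
        )
        for e in edges:
            if H.has_edge(*e):
                counts[e] += 1
    probs = {e: c / n_random for e, c in counts.items()}
    return EdgeProbabilityTable(probabilities=probs, n_random=n_random)


@dataclass
class ComparisonReport:
    """Two-sample location comparison: means +- SD, t-test and Mann-Whitney U."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    t_pvalue: float
    u_stat: float
    u_pvalue: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"A: {self.mean_a:.4f}+-{self.sd_a:.4f} (n={self.n_a}) | "
            f"B: {self.mean_b:.4f}+-{self.sd_b:.4f} (n={self.n_b}) | "
            f"t={self.t_stat:.3f} (p={self.t_pvalue:.3g}), "
            f"U={self.u_stat:.1f} (p={self.u_pvalue:.3g})"
        )


def compare_link_probability_sets(
    probs_subset: Sequence[float], probs_all: Sequence[float]
) -> ComparisonReport:
    """Compare edge-probability samples (e.g. perturbed-path edges vs all
    edges) with a two-sample t-test and a Mann-Whitney U-test."""
    a = np.asarray(probs_subset, dtype=float)
    b = np.asarray(probs_all, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    if np.ptp(np.concatenate([a, b])) == 0:
        u_stat, u_p = float(a.size * b.size / 2), 1.0
    else:
        u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonReport(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=a.size,
        n_b=b.size,
        t_stat=float(t_stat) if np.isfinite(t_stat) else 0.0,
        t_pvalue=float(t_p) if np.isfinite(t_p) else 1.0,
        u_stat=float(u_stat),
        u_pvalue=float(u_p),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV: process_a, process_b, shared_gene_count, shared_genes."""
    rows = []
    for a, b, data in network.edges(data=True):
        a, b = sorted((a, b))
        genes = sorted(data.get("shared", ()))
        rows.append(
            {
                "process_a": a,
                "process_b": b,
                "shared_gene_count": len(genes),
                "shared_genes": ";".join(genes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for _, row in df.iterrows():
        genes = frozenset(str(row["shared_genes"]).split(";")) if row["shared_gene_count"] else frozenset()
        G.add_edge(row["process_a"], row["process_b"], shared=genes, weight=int(row["shared_gene_count"]))
    return G


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    """GraphML export for network viewers (shared-gene sets joined to strings)."""
    H = nx.Graph()
    H.add_nodes_from(network.nodes(data=True))
    for a, b, data in network.edges(data=True):
        H.add_edge(a, b, weight=int(data.get("weight", 1)), shared=";".join(sorted(data.get("shared", ()))))
    nx.write_graphml(H, path)
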