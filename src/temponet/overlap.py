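"""Overlap-factor statistics on sets of temporal paths.

Paths produced by the branching search converge: distinct choice sequences
reuse the same process-pair edge at the same transition. The overlap factor
of an edge e_i^{j,j+1} within a path set is the set of *other* paths using
the same unordered process pair at the same transition j; the overlap factor
of a path is the union of its edges' sets, reported numerically as the
union's cardinality. Edge equality requires the same transition index: an
identical process pair used at different transitions does not match.

High overlap across a path set means the set concentrates on a small family
of shared routes rather than scattering; resampled random-path sets of equal
size calibrate how much overlap arises by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import log, rng_from
from .paths import PathSet

__all__ = [
    "edge_overlap_factor",
    "path_overlap_factor",
    "overlap_cardinalities",
    "OverlapSummary",
    "overlap_summary",
    "resampled_null",
    "MannWhitneyReport",
    "compare_overlap_distributions",
    "BestCover",
    "best_covering",
    "path_bundle_data",
    "path_bundle_plot",
]


def _edge_group_masks(paths: PathSet) -> list[dict[frozenset, int]]:
    """Per transition j, map each distinct edge to a bitmask of the path
    indices that use it (bit i set <=> path i uses the edge at j)."""
    T = paths.T
    groups: list[dict[frozenset, int]] = [dict() for _ in range(T - 1)]
    for i, p in enumerate(paths):
        bit = 1 << i
        for j, e in enumerate(p.edges()):
            groups[j][e] = groups[j].get(e, 0) | bit
    return groups


def _mask_to_indices(mask: int) -> set[int]:
    out = set()
    i = 0
    while mask:
        if mask & 1:
            out.add(i)
        mask >>= 1
        i += 1
    return out


def edge_overlap_factor(paths: PathSet, path_index: int, transition: int) -> set[int]:
    """Indices of the other paths whose edge at ``transition`` equals path
    ``path_index``'s edge there (same unordered pair, same transition)."""
    if not 0 <= path_index < len(paths):
        raise IndexError(f"path index {path_index} out of range")
    if not 0 <= transition < paths.T - 1:
        raise IndexError(f"transition {transition} out of range")
    edge = paths[path_index].edges()[transition]
    members = {
        m for m, p in enumerate(paths) if m != path_index and p.edges()[transition] == edge
    }
    return members


def path_overlap_factor(paths: PathSet, path_index: int) -> tuple[set[int], int]:
    """Union over transitions of the edge overlap sets; the numeric overlap
    factor is the union's cardinality. A path never belongs to its own set."""
    groups = _edge_group_masks(paths)
    mask = 0
    for j, e in enumerate(paths[path_index].edges()):
        mask |= groups[j][e]
    mask &= ~(1 << path_index)
    return _mask_to_indices(mask), mask.bit_count()


def overlap_cardinalities(paths: PathSet) -> np.ndarray:
    """|O(P_i)| for every path i (vectorized over the whole set)."""
    groups = _edge_group_masks(paths)
    out = np.empty(len(paths), dtype=float)
    for i, p in enumerate(paths):
        mask = 0
        for j, e in enumerate(p.edges()):
            mask |= groups[j][e]
        mask &= ~(1 << i)
        out[i] = mask.bit_count()
    return out


@dataclass
class OverlapSummary:
    """Set-level means plus the per-path vectors for histogramming."""

    mean_overlap_factor: float
    mean_mean_nes: float
    overlap_factors: np.ndarray
    mean_nes_values: np.ndarray


def overlap_summary(paths: PathSet) -> OverlapSummary:
    if len(paths) == 0:
        raise ValueError("empty path set")
    card = overlap_cardinalities(paths)
    nes = paths.mean_nes_values()
    return OverlapSummary(
        mean_overlap_factor=float(card.mean()),
        mean_mean_nes=_finite_mean(nes),
        overlap_factors=card,
        mean_nes_values=nes,
    )


def _finite_mean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else float("nan")


def resampled_null(
    random_path_pool: PathSet,
    set_size: int = 1024,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of (mean nes, mean overlap factor) from repeated
    size-``set_size`` resamples (without replacement within a rep) of a
    random-path pool."""
    M = len(random_path_pool)
    if M < set_size:
        raise ValueError(f"pool of {M} paths is smaller than set_size={set_size}")
    rng = rng_from(seed if seed is not None else 0, 1)
    mean_nes = np.empty(n_reps)
    mean_overlap = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(M, size=set_size, replace=False)
        sub = PathSet(
            [random_path_pool[i] for i in idx],
            provenance="resample",
            timepoints=random_path_pool.timepoints,
        )
        mean_overlap[r] = overlap_cardinalities(sub).mean()
        mean_nes[r] = _finite_mean(sub.mean_nes_values())
    return mean_nes, mean_overlap


@dataclass
class MannWhitneyReport:
    """Mann-Whitney U comparison of two path sets, on overlap factors and on
    mean-nes vectors."""

    u_overlap: float
    p_overlap: float
    u_nes: float
    p_nes: float
    tie_note: str = ""


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2), 1.0, "all values tied"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p), ""


def compare_overlap_distributions(set_a: PathSet, set_b: PathSet) -> MannWhitneyReport:
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("both sets need >= 2 paths")
    u_o, p_o, note_o = _mwu(overlap_cardinalities(set_a), overlap_cardinalities(set_b))
    u_n, p_n, note_n = _mwu(set_a.mean_nes_values(), set_b.mean_nes_values())
    note = "; ".join(filter(None, [note_o and f"overlap: {note_o}", note_n and f"nes: {note_n}"]))
    return MannWhitneyReport(u_overlap=u_o, p_overlap=p_o, u_nes=u_n, p_nes=p_n, tie_note=note)


@dataclass
class BestCover:
    """Coverage-maximizing selection of k representative paths.

    ``combos`` lists every tied optimum. Coverage counts the chosen paths
    themselves: covered = |O(P_a) u O(P_b) u {a, b}|.
    """

    k: int
    combos: list[tuple[int, ...]]
    covered: int
    fraction: float


_PAIR_GUARD = 5000  # exhaustive k=2 search is quadratic; refuse absurd sizes


def best_covering(paths: PathSet, k: int) -> BestCover:
    """k=1: the path whose overlap set is largest; k=2: exhaustive pair
    search maximizing joint coverage. All tied optima are returned."""
    M = len(paths)
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if k > M:
        raise ValueError(f"k={k} exceeds set size {M}")
    groups = _edge_group_masks(paths)
    masks = []
    for i, p in enumerate(paths):
        m = 1 << i  # include the path itself in its own coverage
        for j, e in enumerate(p.edges()):
            m |= groups[j][e]
        masks.append(m)
    if k == 1:
        covered = [m.bit_count() for m in masks]
        best = max(covered)
        combos = [(i,) for i, c in enumerate(covered) if c == best]
        log.info("best single path covers %d/%d (excluding itself: %d)", best, M, best - 1)
        return BestCover(k=1, combos=combos, covered=best, fraction=best / M)
    if M > _PAIR_GUARD:
        raise ValueError(f"pair search over {M} paths exceeds the {_PAIR_GUARD}-path guard")
    best = -1
    combos = []
    for a, b in combinations(range(M), 2):
        c = (masks[a] | masks[b]).bit_count()
        if c > best:
            best, combos = c, [(a, b)]
        elif c == best:
            combos.append((a, b))
    log.info("best pair covers %d/%d paths (%d tied optima)", best, M, len(combos))
    return BestCover(k=2, combos=combos, covered=best, fraction=best / M)


# ---------------------------------------------------------------------------
# Bundle plot data
# ---------------------------------------------------------------------------


def path_bundle_data(paths: PathSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables for the time-vs-process bundle display.

    Edge rows carry thickness = that edge's overlap cardinality (number of
    *other* paths sharing it); node rows carry the count of paths through
    the (time point, process) position.
    """
    if len(paths) == 0:
        raise ValueError("empty path set")
    cols = paths.timepoints or tuple(f"t{j + 1}" for j in range(paths.T))
    edge_counts: dict[tuple[int, frozenset], int] = {}
    node_counts: dict[tuple[int, str], int] = {}
    for p in paths:
        for j, proc in enumerate(p.processes):
            node_counts[(j, proc)] = node_counts.get((j, proc), 0) + 1
        for j, e in enumerate(p.edges()):
            edge_counts[(j, e)] = edge_counts.get((j, e), 0) + 1
    edge_rows = []
    for (j, e), c in sorted(edge_counts.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))):
        a, b = sorted(e)
        edge_rows.append(
            {
                "transition": j,
                "time_a": str(cols[j]),
                "time_b": str(cols[j + 1]),
                "process_a": a,
                "process_b": b,
                "n_paths": c,
                "thickness": c - 1,
            }
        )
    node_rows = [
        {"position": j, "timepoint": str(cols[j]), "process": proc, "n_paths": c}
        for (j, proc), c in sorted(node_counts.items())
    ]
    return pd.DataFrame(edge_rows), pd.DataFrame(node_rows)


def path_bundle_plot(paths: PathSet, path: str | Path | None = None):
    """Time-vs-process plot with edge thickness proportional to overlap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, nodes = path_bundle_data(paths)
    procs = sorted(nodes["process"].unique())
    y = {p: i for i, p in enumerate(procs)}
    fig, ax = plt.subplots(figsize=(8, max(3, len(procs) * 0.25)))
    for _, row in edges.iterrows():
        ax.plot(
            [row["transition"], row["transition"] + 1],
            [y[row["process_a"]], y[row["process_b"]]],
            lw=0.5 + 2.5 * row["thickness"] / max(1, len(paths)),
            color="tab:blue",
            alpha=0.7,
        )
    ax.scatter(nodes["position"], [y[p] for p in nodes["process"]], s=nodes["n_paths"], zorder=3)
    ax.set_xlabel("time point")
    ax.set_yticks(range(len(procs)))
    ax.set_yticklabels(procs, fontsize=6)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
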