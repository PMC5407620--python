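"""Temporal paths through the process network.

A temporal path visits one process per time point, with consecutive
processes adjacent in the shared-gene network; its score is the mean of each
process's nes at its own time point. The systematic search is a greedy
depth-first enumeration: at time point 1 the candidate pool is *all*
processes, afterwards the network neighbors of the previous process; at each
selection instance the top ``branch`` candidates by nes (or the bottom, for
the "unperturbed" control) each spawn a branch, giving ``branch**T`` paths.
Random walks over the network provide the baseline path population.

Revisiting a process at a later time point is allowed; immediate repetition
cannot happen because the network has no self-edges. Converging duplicate
paths are retained (not deduplicated) so path counts and overlap statistics
follow the branch**T accounting; the number of distinct paths is logged.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import int_seed, log
from .gsea import NesMatrix

__all__ = [
    "TemporalPath",
    "PathSet",
    "systematic_paths",
    "random_paths",
    "path_mean_nes",
    "write_paths_jsonl",
    "read_paths_jsonl",
    "paths_frame",
]


@dataclass(frozen=True)
class TemporalPath:
    """An ordered sequence of processes, one per time point."""

    processes: tuple[str, ...]
    per_position_nes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.processes) != len(self.per_position_nes):
            raise ValueError("processes and per-position nes must align")
        if len(self.processes) < 2:
            raise ValueError("a path needs at least 2 positions")

    @property
    def T(self) -> int:
        return len(self.processes)

    @property
    def mean_nes(self) -> float:
        return float(np.mean(self.per_position_nes))

    def edges(self) -> tuple[frozenset[str], ...]:
        """Unordered process pairs at transitions 1..T-1."""
        return tuple(
            frozenset((self.processes[j], self.processes[j + 1])) for j in range(self.T - 1)
        )


@dataclass
class PathSet:
    """An ordered collection of equal-length paths with a provenance tag."""

    paths: list[TemporalPath]
    provenance: str
    timepoints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.paths:
            T = self.paths[0].T
            if any(p.T != T for p in self.paths):
                raise ValueError("all paths in a set must share the same length")
            if self.timepoints and len(self.timepoints) != T:
                raise ValueError("timepoints must match path length")

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self) -> Iterator[TemporalPath]:
        return iter(self.paths)

    def __getitem__(self, i: int) -> TemporalPath:
        return self.paths[i]

    @property
    def T(self) -> int:
        return self.paths[0].T if self.paths else 0

    def mean_nes_values(self) -> np.ndarray:
        return np.array([p.mean_nes for p in self.paths], dtype=float)


def _nes_lookup(nes: NesMatrix) -> tuple[list[str], list[dict[str, float]]]:
    """Per-time-point {process: nes} dicts, NaN cells omitted."""
    cols = nes.timepoints
    table = nes.nes
    out: list[dict[str, float]] = []
    for tp in cols:
        col = table[tp]
        out.append({p: float(v) for p, v in col.items() if np.isfinite(v)})
    return list(cols), out


def systematic_paths(
    nes: NesMatrix,
    network: nx.Graph,
    branch: int = 2,
    direction: str = "max",
) -> PathSet:
    """Greedy branching enumeration of high- (or low-) nes temporal paths.

    At each of the T selection instances the top ``branch`` candidates by
    nes at that time point spawn branches (``direction="min"`` takes the
    bottom ``branch``, producing the unperturbed control set). Ties in nes
    break by ascending process name, making the enumeration deterministic.
    Pools smaller than ``branch`` branch over whatever exists (logged);
    branches stranded on an isolated node are aborted and counted.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    if branch < 1:
        raise ValueError("branch must be >= 1")
    cols, lookup = _nes_lookup(nes)
    T = len(cols)
    if T < 2:
        raise ValueError("need at least 2 time points")
    all_nodes = [n for n in network.nodes if n in nes.nes.index]
    if not all_nodes:
        raise ValueError("no network node has nes values")
    sign = -1.0 if direction == "max" else 1.0

    deficit_logged = [False]
    aborted = [0]
    results: list[TemporalPath] = []

    def top_candidates(pool: Sequence[str], j: int) -> list[tuple[str, float]]:
        scored = [(p, lookup[j][p]) for p in pool if p in lookup[j]]
        scored.sort(key=lambda pv: (sign * pv[1], pv[0]))
        if 0 < len(scored) < branch and not deficit_logged[0]:
            log.info("candidate pool smaller than branch=%d at time %s", branch, cols[j])
            deficit_logged[0] = True
        return scored[:branch]

    def recurse(prefix: list[str], nes_acc: list[float]) -> None:
        j = len(prefix)
        if j == T:
            results.append(TemporalPath(tuple(prefix), tuple(nes_acc)))
            return
        pool = all_nodes if j == 0 else list(network.neighbors(prefix[-1]))
        cands = top_candidates(pool, j)
        if not cands:
            aborted[0] += 1
            return
        for proc, val in cands:
            prefix.append(proc)
            nes_acc.append(val)
            recurse(prefix, nes_acc)
            prefix.pop()
            nes_acc.pop()

    recurse([], [])
    if aborted[0]:
        log.warning("%d branch(es) aborted on isolated or nes-less nodes", aborted[0])
    n_distinct = len({p.processes for p in results})
    log.info(
        "systematic-%s: %d paths (%d distinct) over %d time points",
        direction, len(results), n_distinct, T,
    )
    return PathSet(results, provenance=f"systematic-{direction}", timepoints=tuple(cols))


def random_paths(
    network: nx.Graph,
    length: int = 10,
    count: int = 1000,
    seed: int | None = None,
    nes: NesMatrix | None = None,
) -> PathSet:
    """Uniform random walks on the network as a baseline path population.

    Each walk starts at a uniformly random non-isolated node and takes
    uniform random steps to neighbors. When ``nes`` is given (with exactly
    ``length`` time points) paths are annotated with per-position nes; cells
    missing from the grid become NaN.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if count < 1:
        raise ValueError("count must be >= 1")
    non_isolated = sorted(n for n in network.nodes if network.degree(n) > 0)
    if not non_isolated:
        raise ValueError("network has no non-isolated node")
    adj = {n: sorted(network.neighbors(n)) for n in non_isolated}
    rng = random.Random(int_seed(seed if seed is not None else 0, 0) if seed is not None else None)
    lookup: list[dict[str, float]] | None = None
    cols: tuple[str, ...] = ()
    if nes is not None:
        c, lookup = _nes_lookup(nes)
        if len(c) != length:
            raise ValueError(f"nes grid has {len(c)} time points, walks have {length}")
        cols = tuple(c)
    paths: list[TemporalPath] = []
    nan = float("nan")
    for _ in range(count):
        node = rng.choice(non_isolated)
        procs = [node]
        for _step in range(length - 1):
            node = rng.choice(adj[node])
            procs.append(node)
        if lookup is None:
            vals = (nan,) * length
        else:
            vals = tuple(lookup[j].get(p, nan) for j, p in enumerate(procs))
        paths.append(TemporalPath(tuple(procs), vals))
    return PathSet(paths, provenance="random", timepoints=cols)


def path_mean_nes(path: TemporalPath, nes: NesMatrix) -> float:
    """Recompute a path's mean nes from the grid (one value per position).

    The path length must equal the grid's number of time points; a missing
    or NaN cell raises, naming the offending process and time point.
    """
    cols = nes.timepoints
    if path.T != len(cols):
        raise ValueError(f"path length {path.T} != {len(cols)} time points")
    total = 0.0
    for j, proc in enumerate(path.processes):
        tp = cols[j]
        if proc not in nes.nes.index:
            raise ValueError(f"process {proc!r} absent from nes grid (time {tp})")
        v = float(nes.nes.at[proc, tp])
        if not np.isfinite(v):
            raise ValueError(f"nes missing for process {proc!r} at time {tp}")
        total += v
    return total / path.T


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_paths_jsonl(paths: PathSet, path: str | Path) -> None:
    """One JSON record per path: processes, per-position nes, mean nes."""
    with Path(path).open("w") as fh:
        header = {
            "provenance": paths.provenance,
            "timepoints": list(paths.timepoints),
            "n_paths": len(paths),
        }
        fh.write(json.dumps({"_header": header}) + "\n")
        for p in paths:
            rec = {
                "processes": list(p.processes),
                "per_position_nes": [None if not np.isfinite(v) else v for v in p.per_position_nes],
                "mean_nes": None if not np.isfinite(p.mean_nes) else p.mean_nes,
            }
            fh.write(json.dumps(rec) + "\n")


def read_paths_jsonl(path: str | Path) -> PathSet:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty path file")
    header = json.loads(lines[0])["_header"]
    nan = float("nan")
    paths = []
    for line in lines[1:]:
        rec = json.loads(line)
        vals = tuple(nan if v is None else float(v) for v in rec["per_position_nes"])
        paths.append(TemporalPath(tuple(rec["processes"]), vals))
    return PathSet(paths, provenance=header["provenance"], timepoints=tuple(header["timepoints"]))


def paths_frame(paths: PathSet) -> pd.DataFrame:
    """Flat table: one row per path with columns per position plus mean nes."""
    cols = paths.timepoints or tuple(f"t{j + 1}" for j in range(paths.T))
    rows = []
    for i, p in enumerate(paths):
        row: dict[str, object] = {"path_index": i, "mean_nes": p.mean_nes}
        for label, proc in zip(cols, p.processes):
            row[str(label)] = proc
        rows.append(row)
    return pd.DataFrame(rows)
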