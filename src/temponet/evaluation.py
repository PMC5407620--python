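"""Cross-dataset precision of selected paths, and gene-process path graphs.

A path found in a source dataset is scored in other datasets by recomputing
the mean nes of its processes there. When a comparison dataset has fewer
time points (k < T), the path's *last k* processes align to its k time
points. Precision treats each comparison value at least as high as the
source value as a false positive (the decision threshold sits just below
the source value, so a tie counts against the method).

The gene-process graph is the bipartite display of one path: process nodes
at their time positions, joined to the member genes whose fold change at
that time exceeds the cutoff; genes shared by consecutive processes are
flagged as connectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import log
from .genesets import GeneSetLibrary
from .gsea import NesMatrix
from .paths import TemporalPath

__all__ = [
    "path_nes_in_dataset",
    "precision_from_counts",
    "exceedance_probability",
    "PrecisionReport",
    "path_precision",
    "process_precision_baseline",
    "gene_process_graph",
    "graph_table",
]


def path_nes_in_dataset(path: TemporalPath, other_nes: NesMatrix) -> float:
    """Mean nes of a path evaluated in another dataset's nes grid.

    With k < T time points, the path's last k processes align to the
    dataset's k time points in order. Processes absent from the grid (or
    with a NaN cell) are excluded from the mean with a warning.
    """
    cols = other_nes.timepoints
    k = len(cols)
    if k > path.T:
        raise ValueError(f"dataset has {k} time points but the path only {path.T}")
    procs = path.processes[-k:]
    vals = []
    for j, proc in enumerate(procs):
        if proc not in other_nes.nes.index:
            log.warning("process %r absent from dataset; excluded from path mean", proc)
            continue
        v = float(other_nes.nes.at[proc, cols[j]])
        if not np.isfinite(v):
            log.warning("nes missing for %r at %s; excluded from path mean", proc, cols[j])
            continue
        vals.append(v)
    if not vals:
        log.warning("no path process measurable in dataset; mean nes undefined")
        return float("nan")
    return float(np.mean(vals))


def precision_from_counts(true_positives: int, false_positives: int) -> float:
    """Precision percentage, 100 * tp / (tp + fp).

    Returned at full precision; round for the integer-percent convention
    (e.g. 1 true and 10 false positives -> 100/11 = 9.09... -> 9%).
    """
    if true_positives < 0 or false_positives < 0:
        raise ValueError("counts must be non-negative")
    total = true_positives + false_positives
    if total == 0:
        raise ValueError("precision undefined with no positive calls")
    return 100.0 * true_positives / total


def exceedance_probability(n_exceed: int, n_total: int) -> float:
    """Fraction of comparison values at least as high as the source value."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_exceed <= n_total:
        raise ValueError("need 0 <= n_exceed <= n_total")
    return n_exceed / n_total


@dataclass
class PrecisionReport:
    """Outcome of a source-vs-decoys exceedance analysis.

    ``comparisons`` holds one row per comparison value (dataset, aligned
    length, value, whether it ties or exceeds the source).
    """

    source_value: float
    n_comparisons: int
    n_exceed: int
    precision_pct: float
    exceedance_prob: float
    comparisons: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def precision_pct_rounded(self) -> int:
        return round(self.precision_pct)


def _exceedance_report(source_value: float, rows: list[dict]) -> PrecisionReport:
    df = pd.DataFrame(rows)
    finite = df[np.isfinite(df["value"])] if len(df) else df
    n_exceed = int((finite["value"] >= source_value).sum()) if len(finite) else 0
    return PrecisionReport(
        source_value=float(source_value),
        n_comparisons=len(finite),
        n_exceed=n_exceed,
        precision_pct=precision_from_counts(1, n_exceed),
        exceedance_prob=exceedance_probability(n_exceed, max(1, len(finite))),
        comparisons=df,
    )


def path_precision(
    path: TemporalPath,
    source_nes: NesMatrix,
    other_nes: Mapping[str, NesMatrix],
) -> PrecisionReport:
    """Precision of predicting the source dataset from a path's mean nes.

    The source value is the path's mean nes in its own grid; every other
    dataset contributes one (possibly suffix-aligned) mean nes. Values >=
    the source count as false positives.
    """
    source_value = path_nes_in_dataset(path, source_nes)
    rows = []
    for name, nm in other_nes.items():
        rows.append(
            {
                "dataset": name,
                "aligned_positions": len(nm.timepoints),
                "value": path_nes_in_dataset(path, nm),
            }
        )
    return _exceedance_report(source_value, rows)


def process_precision_baseline(
    process: str,
    source_nes: NesMatrix,
    source_timepoint: str,
    other_nes: Mapping[str, NesMatrix],
) -> PrecisionReport:
    """Single-process baseline: compare one process's nes at its source time
    point against the same process at every *other* time point of the source
    dataset and every time point of every other dataset."""
    if process not in source_nes.nes.index:
        raise ValueError(f"process {process!r} not in the source dataset")
    source_value = float(source_nes.nes.at[process, source_timepoint])
    rows = []
    for tp in source_nes.timepoints:
        if tp == source_timepoint:
            continue
        rows.append(
            {"dataset": "source", "timepoint": tp, "value": float(source_nes.nes.at[process, tp])}
        )
    for name, nm in other_nes.items():
        if process not in nm.nes.index:
            log.warning("process %r absent from dataset %s; skipped", process, name)
            continue
        for tp in nm.timepoints:
            rows.append({"dataset": name, "timepoint": tp, "value": float(nm.nes.at[process, tp])})
    return _exceedance_report(source_value, rows)


# ---------------------------------------------------------------------------
# Gene-process bipartite graph
# ---------------------------------------------------------------------------


def gene_process_graph(
    path: TemporalPath,
    library: GeneSetLibrary,
    matrix: pd.DataFrame,
    fc_cutoff_log2: float = 1.0,
    timepoints: Sequence[str] | None = None,
) -> nx.Graph:
    """Bipartite graph of one path: processes at their time positions joined
    to member genes whose |log2 FC| exceeds the cutoff at that time.

    Gene nodes carry per-time fold changes; genes linking consecutive
    processes get ``connector=True``, and genes spanning >= 3 consecutive
    processes additionally ``multi_connector=True``. A process with no gene
    above the cutoff keeps its node (with a warning) but has no gene edges.
    """
    cols = list(timepoints) if timepoints is not None else list(matrix.columns)
    if path.T > len(cols):
        raise ValueError(f"path has {path.T} positions but only {len(cols)} time points given")
    G = nx.Graph()
    gene_positions: dict[str, list[int]] = {}
    for j, proc in enumerate(path.processes):
        if proc not in library:
            raise ValueError(f"path process {proc!r} not in the library")
        tp = cols[j]
        node = f"{proc}@{tp}"
        G.add_node(node, kind="process", process=proc, position=j, timepoint=str(tp))
        hits = 0
        for gene in sorted(library[proc].genes):
            if gene not in matrix.index:
                continue
            fc = float(matrix.at[gene, tp])
            if abs(fc) <= fc_cutoff_log2:
                continue
            if gene not in G:
                G.add_node(gene, kind="gene", connector=False, multi_connector=False, fold_changes={})
            G.nodes[gene]["fold_changes"][str(tp)] = fc
            G.add_edge(node, gene, fold_change=fc)
            gene_positions.setdefault(gene, []).append(j)
            hits += 1
        if hits == 0:
            log.warning("process %r has no gene above %.2g-fold cutoff at %s", proc, 2**fc_cutoff_log2, tp)
    for gene, positions in gene_positions.items():
        positions = sorted(set(positions))
        runs = _consecutive_run_lengths(positions)
        if max(runs) >= 2:
            G.nodes[gene]["connector"] = True
        if max(runs) >= 3:
            G.nodes[gene]["multi_connector"] = True
    return G


def _consecutive_run_lengths(positions: list[int]) -> list[int]:
    runs, run = [], 1
    for a, b in zip(positions, positions[1:]):
        if b == a + 1:
            run += 1
        else:
            runs.append(run)
            run = 1
    runs.append(run)
    return runs


def graph_table(graph: nx.Graph) -> pd.DataFrame:
    """Flat per-edge table of a gene-process graph: timepoint, process,
    gene, fold change, connector flags."""
    rows = []
    for u, v, data in graph.edges(data=True):
        pnode, gnode = (u, v) if graph.nodes[u]["kind"] == "process" else (v, u)
        pdata = graph.nodes[pnode]
        gdata = graph.nodes[gnode]
        rows.append(
            {
                "timepoint": pdata["timepoint"],
                "position": pdata["position"],
                "process": pdata["process"],
                "gene": gnode,
                "log2_fold_change": data["fold_change"],
                "abs_fold_change": 2 ** abs(data["fold_change"]),
                "connector": gdata["connector"],
                "multi_connector": gdata["multi_connector"],
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["position", "process", "gene"]).reset_index(drop=True) if len(df) else df


def write_gene_process_graphml(graph: nx.Graph, path) -> None:
    """GraphML export (dict-valued attributes flattened to strings)."""
    H = nx.Graph()
    for n, data in graph.nodes(data=True):
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat[key] = ";".join(f"{t}={fc:.4g}" for t, fc in sorted(value.items()))
            else:
                flat[key] = value
        H.add_node(n, **flat)
    for u, v, data in graph.edges(data=True):
        H.add_edge(u, v, **data)
    nx.write_graphml(H, path)
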