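"""Probe-level replicate fold changes -> gene x time-point log2 fold-change matrix.

Input is a probe table: per probe and per time point, three replicate log2
fold changes (treated vs control) and one t-test p-value. The pipeline:

* **Primary fill** — a (gene, time point) cell is filled with the replicate
  mean of a probe whose three replicates all exceed 2-fold (|log2 FC| > 1);
  among qualifying probes of a gene the one with minimum p-value wins.
* **Secondary fill** — remaining empty cells of genes that were filled
  somewhere are back-filled from probes with at least two of three
  replicates outside [-1, 1] (or, failing that, probes entirely inside the
  interval). The chosen probe's same-sign replicate mean is inserted unless
  it falls inside the (-0.8, 0.8) band, in which case the dummy value 0.001
  marks the cell as "measured but unperturbed".
* **Time-point merge** — two labels measuring the same day (by default
  "Day 14" and "Week 0") are combined: same-direction perturbations are
  averaged, conflicting directions get the dummy, a single perturbation wins
  outright, and unperturbed pairs keep the first label's value.
* **Never-perturbed drop** — genes whose |value| never exceeds 1 at any time
  point are removed.

Week labels are converted to day equivalents as ``days = 7*week + 14``
(weeks were counted from day 14 of the experiment).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import log

__all__ = [
    "ProbeTable",
    "day_number",
    "read_probe_table",
    "step1_primary_fill",
    "step23_secondary_fill",
    "secondary_fill",
    "merge_timepoints",
    "drop_never_perturbed",
    "preprocess_pipeline",
    "read_fc_matrix",
    "write_fc_matrix",
]

DUMMY = 0.001

_DAY_RE = re.compile(r"^\s*day[\s_]*(\d+)\s*$", re.IGNORECASE)
_WEEK_RE = re.compile(r"^\s*week[\s_]*(\d+)\s*$", re.IGNORECASE)


def day_number(label: str) -> int:
    """Day equivalent of a time-point label. ``Week w`` maps to ``7*w + 14``."""
    m = _DAY_RE.match(label)
    if m:
        return int(m.group(1))
    m = _WEEK_RE.match(label)
    if m:
        return 7 * int(m.group(1)) + 14
    raise ValueError(f"unrecognized time-point label: {label!r}")


@dataclass
class ProbeTable:
    """Replicate-level probe measurements across time points.

    ``replicates`` has shape (n_probes, n_timepoints, 3); ``pvalues`` has
    shape (n_probes, n_timepoints). Probe ids are unique; several probes may
    map to one gene symbol.
    """

    probe_ids: np.ndarray
    gene_symbols: np.ndarray
    timepoints: list[str]
    replicates: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        t = len(self.timepoints)
        if self.replicates.shape != (n, t, 3):
            raise ValueError(
                f"replicates shape {self.replicates.shape} != ({n}, {t}, 3)"
            )
        if self.pvalues.shape != (n, t):
            raise ValueError(f"pvalues shape {self.pvalues.shape} != ({n}, {t})")
        if len(set(self.probe_ids)) != n:
            raise ValueError("probe ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(self.pvalues) & ((self.pvalues < 0) | (self.pvalues > 1))
        if bad.any():
            raise ValueError("p-values must lie in [0, 1] or be missing")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mapping: Mapping[str, Mapping[str, object]]) -> "ProbeTable":
        """Build from a flat table plus a column mapping.

        ``mapping`` names, per time-point label, the three replicate columns
        and the p-value column::

            {"Day 1": {"replicates": ["d1_r1", "d1_r2", "d1_r3"], "pvalue": "d1_p"}}
        """
        labels = sorted(mapping, key=day_number)
        reps = np.empty((len(df), len(labels), 3), dtype=float)
        pvals = np.empty((len(df), len(labels)), dtype=float)
        for t, label in enumerate(labels):
            spec = mapping[label]
            rep_cols = list(spec["replicates"])  # type: ignore[index]
            if len(rep_cols) != 3:
                raise ValueError(f"{label}: expected exactly 3 replicate columns")
            reps[:, t, :] = df[rep_cols].to_numpy(dtype=float)
            pvals[:, t] = df[spec["pvalue"]].to_numpy(dtype=float)  # type: ignore[index]
        return cls(
            probe_ids=df["probe_id"].to_numpy(dtype=object),
            gene_symbols=df["gene_symbol"].astype(str).str.upper().to_numpy(dtype=object),
            timepoints=labels,
            replicates=reps,
            pvalues=pvals,
        )

    def to_frame(self, mapping: Mapping[str, Mapping[str, object]] | None = None) -> pd.DataFrame:
        """Flatten back to a table; default column names are ``<label>_r{1..3}``
        and ``<label>_p``."""
        data: dict[str, np.ndarray] = {
            "probe_id": self.probe_ids,
            "gene_symbol": self.gene_symbols,
        }
        for t, label in enumerate(self.timepoints):
            if mapping is not None:
                rep_cols = list(mapping[label]["replicates"])  # type: ignore[index]
                p_col = mapping[label]["pvalue"]  # type: ignore[index]
            else:
                rep_cols = [f"{label}_r{i + 1}" for i in range(3)]
                p_col = f"{label}_p"
            for i, col in enumerate(rep_cols):
                data[str(col)] = self.replicates[:, t, i]
            data[str(p_col)] = self.pvalues[:, t]
        return pd.DataFrame(data)


def default_mapping(timepoints: Sequence[str]) -> dict[str, dict[str, object]]:
    """Column mapping matching :meth:`ProbeTable.to_frame` defaults."""
    return {
        label: {"replicates": [f"{label}_r{i + 1}" for i in range(3)], "pvalue": f"{label}_p"}
        for label in timepoints
    }


def read_probe_table(path: str | Path, mapping: str | Path | Mapping) -> ProbeTable:
    """Read a probe TSV plus a column-mapping config (dict, JSON or YAML)."""
    if not isinstance(mapping, Mapping):
        text = Path(mapping).read_text()
        mapping = yaml.safe_load(text) if str(mapping).endswith((".yaml", ".yml")) else json.loads(text)
    df = pd.read_csv(path, sep="\t")
    return ProbeTable.from_frame(df, mapping)


# ---------------------------------------------------------------------------
# Fill steps
# ---------------------------------------------------------------------------


def _ordered_labels(labels: Sequence[str]) -> list[str]:
    return sorted(labels, key=day_number)


def step1_primary_fill(probes: ProbeTable, threshold_log2: float = 1.0) -> pd.DataFrame:
    """Primary fill: cells where some probe has all three replicates beyond
    the threshold get that probe's replicate mean (min-p probe wins among
    several; p ties broken by probe id). Everything else is left NaN.

    Rows of the result are exactly the genes filled at >= 1 time point.
    """
    reps = probes.replicates
    qual = (np.abs(reps) > threshold_log2).all(axis=2)  # (n, T)
    if not qual.any():
        raise ValueError("no probe qualifies at any time point; nothing to fill")
    means = reps.mean(axis=2)
    pi, ti = np.nonzero(qual)
    cand = pd.DataFrame(
        {
            "gene": probes.gene_symbols[pi],
            "t": ti,
            "p": probes.pvalues[pi, ti],
            "probe_id": probes.probe_ids[pi],
            "value": means[pi, ti],
        }
    )
    cand = cand.sort_values(["gene", "t", "p", "probe_id"], kind="mergesort")
    best = cand.drop_duplicates(["gene", "t"], keep="first")
    genes = sorted(best["gene"].unique())
    labels = _ordered_labels(probes.timepoints)
    matrix = pd.DataFrame(np.nan, index=genes, columns=probes.timepoints, dtype=float)
    matrix = matrix[labels]
    gidx = {g: i for i, g in enumerate(genes)}
    col_of = {t: probes.timepoints[t] for t in range(len(probes.timepoints))}
    arr = matrix.to_numpy()
    col_pos = {c: j for j, c in enumerate(matrix.columns)}
    for g, t, v in zip(best["gene"], best["t"], best["value"]):
        arr[gidx[g], col_pos[col_of[t]]] = v
    return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)


def _probe_secondary_value(triplet: np.ndarray) -> tuple[int, float]:
    """Classify one replicate triplet for the secondary fill.

    Returns (sign_class, value): sign_class 3 when all three replicates share
    a strict sign (value = three-replicate mean), 2 when exactly two share a
    sign (value = mean of that pair), 0 when no same-sign pair exists (zero
    breaks same-sign status; value is NaN).
    """
    pos = triplet > 0
    neg = triplet < 0
    if pos.all() or neg.all():
        return 3, float(triplet.mean())
    if pos.sum() == 2:
        return 2, float(triplet[pos].mean())
    if neg.sum() == 2:
        return 2, float(triplet[neg].mean())
    return 0, float("nan")


def step23_secondary_fill(
    probes: ProbeTable,
    gene: str,
    timepoint: str,
    threshold_log2: float = 1.0,
    dummy_band: float = 0.8,
    dummy: float = DUMMY,
) -> float:
    """Secondary fill value for one empty (gene, time point) cell.

    Candidate probes are those with >= 2 of 3 replicates outside
    [-threshold, threshold]; if the gene has none, probes entirely inside the
    interval are used instead. Within the candidate group, probes whose
    replicates all share a sign are preferred (three-replicate mean), then
    probes with a same-sign pair (pair mean); ties break on p-value then
    probe id. Averages inside the (-band, band) window, and cells with no
    usable probe, yield the dummy value.
    """
    t = probes.timepoints.index(timepoint)
    rows = np.nonzero(probes.gene_symbols == gene)[0]
    if rows.size == 0:
        log.warning("gene %r has no probes; inserting dummy at %s", gene, timepoint)
        return dummy
    n_outside = (np.abs(probes.replicates[rows, t, :]) > threshold_log2).sum(axis=1)
    group_a = rows[n_outside >= 2]
    group_b = rows[n_outside == 0]
    chosen_group = group_a if group_a.size else group_b
    if chosen_group.size == 0:
        log.debug("no candidate probe for (%s, %s); inserting dummy", gene, timepoint)
        return dummy
    best_key: tuple | None = None
    best_value = float("nan")
    for r in chosen_group:
        klass, value = _probe_secondary_value(probes.replicates[r, t, :])
        if klass == 0:
            continue
        key = (-klass, probes.pvalues[r, t], str(probes.probe_ids[r]))
        if best_key is None or key < best_key:
            best_key, best_value = key, value
    if best_key is None:
        log.debug("candidate probes for (%s, %s) have no same-sign pair; dummy", gene, timepoint)
        return dummy
    if -dummy_band < best_value < dummy_band:
        return dummy
    return best_value


def secondary_fill(
    probes: ProbeTable,
    matrix: pd.DataFrame,
    threshold_log2: float = 1.0,
    dummy_band: float = 0.8,
    dummy: float = DUMMY,
) -> pd.DataFrame:
    """Apply the secondary fill to every NaN cell of ``matrix`` (in a copy).

    Primary-fill cells are never overwritten.
    """
    out = matrix.copy()
    # Group probe rows by gene once; the per-cell rule then only scans the
    # handful of probes of that gene.
    order = np.argsort(probes.gene_symbols, kind="mergesort")
    sym_sorted = probes.gene_symbols[order]
    starts = np.searchsorted(sym_sorted, np.asarray(out.index, dtype=object), side="left")
    ends = np.searchsorted(sym_sorted, np.asarray(out.index, dtype=object), side="right")
    col_t = {c: probes.timepoints.index(c) for c in out.columns}
    arr = out.to_numpy()
    for gi, gene in enumerate(out.index):
        rows = order[starts[gi] : ends[gi]]
        for cj, col in enumerate(out.columns):
            if not np.isnan(arr[gi, cj]):
                continue
            arr[gi, cj] = _secondary_cell(
                probes, rows, col_t[col], threshold_log2, dummy_band, dummy
            )
    return pd.DataFrame(arr, index=out.index, columns=out.columns)


def _secondary_cell(
    probes: ProbeTable,
    rows: np.ndarray,
    t: int,
    threshold_log2: float,
    dummy_band: float,
    dummy: float,
) -> float:
    if rows.size == 0:
        return dummy
    n_outside = (np.abs(probes.replicates[rows, t, :]) > threshold_log2).sum(axis=1)
    group = rows[n_outside >= 2]
    if group.size == 0:
        group = rows[n_outside == 0]
    if group.size == 0:
        return dummy
    best_key: tuple | None = None
    best_value = float("nan")
    for r in group:
        klass, value = _probe_secondary_value(probes.replicates[r, t, :])
        if klass == 0:
            continue
        key = (-klass, probes.pvalues[r, t], str(probes.probe_ids[r]))
        if best_key is None or key < best_key:
            best_key, best_value = key, value
    if best_key is None:
        return dummy
    if -dummy_band < best_value < dummy_band:
        return dummy
    return best_value


# ---------------------------------------------------------------------------
# Merge and drop
# ---------------------------------------------------------------------------


def merge_timepoints(
    matrix: pd.DataFrame,
    label_a: str = "Day 14",
    label_b: str = "Week 0",
    perturb_threshold: float = 1.0,
    dummy: float = DUMMY,
) -> pd.DataFrame:
    """Combine two columns measuring the same day into one (labelled
    ``label_a``).

    Per gene: both perturbed (|v| > threshold) in the same direction -> mean;
    perturbed in opposite directions -> dummy; exactly one perturbed -> that
    value; neither perturbed -> the ``label_a`` value (a fixed, reproducible
    choice).
    """
    for lab in (label_a, label_b):
        if lab not in matrix.columns:
            raise ValueError(f"column {lab!r} not present")
    a = matrix[label_a].to_numpy()
    b = matrix[label_b].to_numpy()
    pa = np.abs(a) > perturb_threshold
    pb = np.abs(b) > perturb_threshold
    merged = a.copy()  # covers "neither" and "only a"
    same_dir = pa & pb & (np.sign(a) == np.sign(b))
    opp_dir = pa & pb & (np.sign(a) != np.sign(b))
    only_b = pb & ~pa
    merged[same_dir] = (a[same_dir] + b[same_dir]) / 2.0
    merged[opp_dir] = dummy
    merged[only_b] = b[only_b]
    out = matrix.drop(columns=[label_b]).copy()
    out[label_a] = merged
    return out[_ordered_labels(out.columns)]


def drop_never_perturbed(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Remove genes whose |value| never exceeds ``threshold`` at any time point."""
    if matrix.isna().any().any():
        raise ValueError("matrix must be fully filled before the drop step")
    keep = (matrix.abs() > threshold).any(axis=1)
    if not keep.any():
        raise ValueError("every gene would be dropped; degenerate input")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d never-perturbed gene(s)", n_drop)
    return matrix.loc[keep]


def preprocess_pipeline(
    probes: ProbeTable,
    threshold_log2: float = 1.0,
    merge_pair: tuple[str, str] | None = ("Day 14", "Week 0"),
    dummy_band: float = 0.8,
    dummy: float = DUMMY,
) -> pd.DataFrame:
    """Full probe-table -> final fold-change matrix pipeline.

    Columns of the result are ordered by day equivalent; every cell is either
    a replicate mean produced by one of the fill rules or exactly the dummy
    value.
    """
    matrix = step1_primary_fill(probes, threshold_log2)
    matrix = secondary_fill(probes, matrix, threshold_log2, dummy_band, dummy)
    if merge_pair is not None:
        a, b = merge_pair
        if a in matrix.columns and b in matrix.columns:
            matrix = merge_timepoints(matrix, a, b, threshold_log2, dummy)
        else:
            log.info("merge pair %r not present; skipping merge", merge_pair)
    return drop_never_perturbed(matrix, threshold_log2)


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------


def write_fc_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_fc_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = df.index.astype(str).str.upper()
    return df[_ordered_labels(df.columns)]
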