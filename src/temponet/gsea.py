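"""Weighted gene-set enrichment over time points.

For each time point the genes are ranked by descending absolute log2 fold
change. For a gene set S of size ``N_H`` inside a ranked list of ``N`` genes
with signed weights ``r_j``, the running sum at position ``i`` is::

    P_hit(S, i)  = sum_{g_j in S, j <= i} |r_j| / N_R,   N_R = sum_{g_j in S} |r_j|
    P_miss(S, i) = sum_{g_j not in S, j <= i} 1 / (N - N_H)

The enrichment score is the **maximum plus the minimum** of
``P_hit - P_miss`` over all positions — not the classic single
max-deviation statistic (available via ``statistic="max_deviation"`` for
comparison). The null distribution comes from random permutations of gene
labels, implemented equivalently (and cheaply) by sampling ``N_H`` hit
positions uniformly at random. The normalized score divides es by the mean
of the sign-matched portion of the null; the p-value is the fraction of all
null draws at least as extreme as es on the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from zlib import crc32

import numpy as np
import pandas as pd

from ._util import log, rng_from
from .genesets import GeneSet, GeneSetLibrary, restrict_to_universe

__all__ = [
    "RankedGeneList",
    "NesMatrix",
    "rank_genes",
    "running_sum",
    "enrichment_score",
    "permutation_null",
    "normalize_and_pvalue",
    "nes_matrix",
    "write_nes_long",
    "read_nes_long",
]

STATISTICS = ("max_plus_min", "max_deviation")


@dataclass
class RankedGeneList:
    """Genes ordered by descending |log2 FC| at one time point.

    ``weights`` carries the signed fold change; ties in |weight| are ordered
    by gene symbol so the ranking is deterministic.
    """

    genes: np.ndarray
    weights: np.ndarray
    _index: dict[str, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must align")
        absw = np.abs(self.weights)
        if (np.diff(absw) > 1e-12).any():
            raise ValueError("|weights| must be non-increasing along the list")

    @property
    def N(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.genes)}
        return self._index

    def positions(self, genes: Iterable[str]) -> np.ndarray:
        """Rank positions (0-based) of the given genes that are in the list."""
        idx = self.index
        return np.array(sorted(idx[g] for g in genes if g in idx), dtype=int)


def rank_genes(matrix: pd.DataFrame, timepoint: str) -> RankedGeneList:
    """Rank one matrix column by |value| descending, gene symbol ascending on ties."""
    if timepoint not in matrix.columns:
        raise ValueError(f"unknown time point {timepoint!r}")
    values = matrix[timepoint].to_numpy(dtype=float)
    genes = np.asarray(matrix.index, dtype=object)
    order = np.lexsort((genes, -np.abs(values)))
    return RankedGeneList(genes=genes[order], weights=values[order])


def _hit_mask(ranked: RankedGeneList, gene_set: GeneSet | Iterable[str]) -> np.ndarray:
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    mask = np.zeros(ranked.N, dtype=bool)
    pos = ranked.positions(genes)
    mask[pos] = True
    return mask


def _running_sum_from_mask(absr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = absr.size
    n_h = int(mask.sum())
    if n_h == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if n_h == n:
        raise ValueError("gene set covers the whole ranked list; P_miss undefined")
    n_r = absr[mask].sum()
    p_hit = np.cumsum(np.where(mask, absr, 0.0)) / n_r
    p_miss = np.cumsum(~mask) / (n - n_h)
    return p_hit - p_miss


def running_sum(ranked: RankedGeneList, gene_set: GeneSet | Iterable[str]) -> np.ndarray:
    """The P_hit - P_miss vector over all list positions.

    Its final element is 0 up to numerical tolerance: both cumulative
    fractions reach 1.
    """
    return _running_sum_from_mask(np.abs(ranked.weights), _hit_mask(ranked, gene_set))


def _score(rs: np.ndarray, statistic: str) -> float:
    if statistic == "max_plus_min":
        return float(rs.max() + rs.min())
    if statistic == "max_deviation":
        return float(rs[np.argmax(np.abs(rs))])
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: GeneSet | Iterable[str],
    statistic: str = "max_plus_min",
) -> float:
    """Enrichment score of a gene set against a ranked list."""
    return _score(running_sum(ranked, gene_set), statistic)


def _null_batch(
    absr: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    statistic: str = "max_plus_min",
) -> np.ndarray:
    """Vectorized null: es for ``n_perm`` uniformly random size-``set_size``
    subsets of rank positions (equivalent to permuting gene labels)."""
    n = absr.size
    picks = rng.random((n_perm, n)).argpartition(set_size - 1, axis=1)[:, :set_size]
    mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(mask, picks, True, axis=1)
    w = np.where(mask, absr[None, :], 0.0)
    p_hit = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~mask, axis=1) / (n - set_size)
    rs = p_hit - p_miss
    if statistic == "max_plus_min":
        return rs.max(axis=1) + rs.min(axis=1)
    if statistic == "max_deviation":
        flat = np.take_along_axis(rs, np.argmax(np.abs(rs), axis=1)[:, None], axis=1)
        return flat[:, 0]
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_null(
    ranked: RankedGeneList,
    set_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    statistic: str = "max_plus_min",
) -> np.ndarray:
    """Null distribution of es for random gene-label permutations."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < set_size < ranked.N:
        raise ValueError(f"set_size must lie strictly between 0 and N={ranked.N}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _null_batch(np.abs(ranked.weights), set_size, n_perm, rng, statistic)


def normalize_and_pvalue(es: float, null: np.ndarray) -> tuple[float, float]:
    """(nes, p-value) from an observed es and its permutation null.

    nes = es / mean(|sign-matched null portion|), carrying es's sign; the
    p-value is the fraction of *all* null draws >= es (for es > 0) or <= es
    (for es < 0), ties counted. With an empty sign-matched portion nes is
    undefined (NaN) and the p-value is floored at 1/n_perm.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    n = null.size
    if es == 0:
        return 0.0, 1.0
    if es > 0:
        portion = null[null > 0]
        p = float((null >= es).sum()) / n
    else:
        portion = null[null < 0]
        p = float((null <= es).sum()) / n
    if portion.size == 0:
        log.warning("sign-matched null portion empty; nes undefined, p floored at 1/%d", n)
        return float("nan"), 1.0 / n
    nes = es / abs(portion.mean())
    return float(nes), p


@dataclass
class NesMatrix:
    """Process x time-point grids of es, nes and p-values.

    ``sizes`` holds the effective set size N_H (within the measured gene
    universe). ``notes`` records cells that could not be computed and why;
    those cells are NaN, never silent zeros.
    """

    es: pd.DataFrame
    nes: pd.DataFrame
    pvalue: pd.DataFrame
    sizes: pd.Series
    notes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df in (self.nes, self.pvalue):
            if not (df.index.equals(self.es.index) and df.columns.equals(self.es.columns)):
                raise ValueError("es/nes/pvalue grids must share index and columns")

    @property
    def processes(self) -> list[str]:
        return list(self.es.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.es.columns)

    def value(self, process: str, timepoint: str, which: str = "nes") -> float:
        return float(getattr(self, which).at[process, timepoint])


def nes_matrix(
    matrix: pd.DataFrame,
    library: GeneSetLibrary,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "max_plus_min",
) -> NesMatrix:
    """Compute es/nes/p for every library set at every matrix time point.

    The null distribution for a given time point depends only on the ranked
    weights and the set size, so nulls are computed once per (time point,
    effective size) and shared across same-sized sets; the seed of each null
    is derived from the master seed, a stable hash of the time-point label
    and the size, which keeps the grid reproducible regardless of evaluation
    or column order.
    """
    lib = restrict_to_universe(library, set(matrix.index))
    processes = lib.names
    cols = list(matrix.columns)
    shape = (len(processes), len(cols))
    es_a = np.full(shape, np.nan)
    nes_a = np.full(shape, np.nan)
    p_a = np.full(shape, np.nan)
    notes: dict[tuple[str, str], str] = {}
    sizes = pd.Series({s.name: s.size for s in lib.sets}, dtype=int)
    for t_idx, tp in enumerate(cols):
        tp_key = crc32(str(tp).encode())
        ranked = rank_genes(matrix, tp)
        absr = np.abs(ranked.weights)
        null_cache: dict[int, np.ndarray] = {}
        for s_idx, s in enumerate(lib.sets):
            mask = _hit_mask(ranked, s)
            n_h = int(mask.sum())
            if n_h == 0:
                notes[(s.name, tp)] = "no set genes in ranked list"
                continue
            if n_h == ranked.N:
                notes[(s.name, tp)] = "set covers whole ranked list"
                continue
            es = _score(_running_sum_from_mask(absr, mask), statistic)
            if n_h not in null_cache:
                null_cache[n_h] = _null_batch(
                    absr, n_h, n_perm, rng_from(seed, tp_key, n_h), statistic
                )
            nes, p = normalize_and_pvalue(es, null_cache[n_h])
            es_a[s_idx, t_idx] = es
            nes_a[s_idx, t_idx] = nes
            p_a[s_idx, t_idx] = p
        log.info("gsea: time point %s done (%d sets, %d null sizes)", tp, len(processes), len(null_cache))
    mk = lambda a: pd.DataFrame(a, index=processes, columns=cols)
    return NesMatrix(es=mk(es_a), nes=mk(nes_a), pvalue=mk(p_a), sizes=sizes, notes=notes)


# ---------------------------------------------------------------------------
# I/O and plotting
# ---------------------------------------------------------------------------


def nes_long_frame(nm: NesMatrix) -> pd.DataFrame:
    """Long-format table: process, timepoint, size, es, nes, pvalue."""
    rows = []
    for proc in nm.processes:
        for tp in nm.timepoints:
            rows.append(
                {
                    "process": proc,
                    "timepoint": tp,
                    "size": int(nm.sizes[proc]),
                    "es": nm.es.at[proc, tp],
                    "nes": nm.nes.at[proc, tp],
                    "pvalue": nm.pvalue.at[proc, tp],
                }
            )
    return pd.DataFrame(rows)


def write_nes_long(nm: NesMatrix, path: str | Path) -> None:
    nes_long_frame(nm).to_csv(path, sep="\t", index=False)


def read_nes_long(path: str | Path) -> NesMatrix:
    df = pd.read_csv(path, sep="\t")
    from .preprocess import day_number

    cols = sorted(df["timepoint"].unique(), key=day_number)

    def piv(v: str) -> pd.DataFrame:
        wide = df.pivot(index="process", columns="timepoint", values=v)[cols]
        wide.index.name = None
        wide.columns.name = None
        return wide

    sizes = df.drop_duplicates("process").set_index("process")["size"]
    sizes.index.name = None
    return NesMatrix(es=piv("es"), nes=piv("nes"), pvalue=piv("pvalue"), sizes=sizes)


def plot_running_sum(
    ranked: RankedGeneList, gene_set: GeneSet | Iterable[str], path: str | Path | None = None
):
    """Three-panel display: running sum, hit positions, |log2 FC| profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rs = running_sum(ranked, gene_set)
    mask = _hit_mask(ranked, gene_set)
    fig, axes = plt.subplots(3, 1, figsize=(7, 6), sharex=True)
    axes[0].plot(rs)
    axes[0].set_ylabel("P_hit - P_miss")
    axes[1].vlines(np.nonzero(mask)[0], 0, 1)
    axes[1].set_ylabel("hits")
    axes[2].plot(np.abs(ranked.weights))
    axes[2].set_ylabel("|log2 FC|")
    axes[2].set_xlabel("rank")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
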