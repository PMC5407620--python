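"""Gene-set libraries in GMT format and the filters that produce the working
process list.

A "process" here is a named gene set (e.g. a GO Biological Process term with
its member genes). Two filters reduce a raw library to the processes used by
the downstream enrichment and network stages:

1. subset minimality — a process is kept only if no *other* process is a
   proper subset of it (larger, redundant supersets are discarded);
2. a size cutoff — only processes with strictly more than ``min_exclusive``
   genes (default 15, i.e. at least 16) are kept.

Gene symbols are case-folded to uppercase at parse time so that library and
expression-matrix symbols join reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from ._util import log

__all__ = [
    "GeneSet",
    "GeneSetLibrary",
    "read_gmt",
    "write_gmt",
    "filter_subset_minimal",
    "filter_min_size",
    "restrict_to_universe",
    "apply_filters",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (uppercase strings).

    ``description`` carries the second GMT field; it is preserved as metadata
    and ignored by all computation.
    """

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetLibrary:
    """An ordered collection of gene sets with pairwise-distinct names."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene-set name: {dup!r}")
        self._by_name = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member gene sets."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    @property
    def sizes(self) -> pd.Series:
        return pd.Series({s.name: s.size for s in self.sets}, dtype=int)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file (tab-separated: name, description, gene, gene, ...).

    Gene symbols are uppercased, empty tokens dropped and duplicates within a
    line collapsed. Lines whose gene list is empty after cleaning are skipped
    with a warning. Raises on malformed lines (< 3 fields), duplicate set
    names and empty files.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line "
                    f"({len(fields)} fields, expected >= 3)"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            genes = frozenset(tok.strip().upper() for tok in fields[2:] if tok.strip())
            if not genes:
                log.warning("%s:%d: set %r has no genes after cleaning; skipped", path.name, lineno, name)
                continue
            sets.append(GeneSet(name=name, genes=genes, description=description))
    if not sets:
        raise ValueError(f"{path}: empty gene-set library")
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in the same GMT dialect read by :func:`read_gmt`."""
    with Path(path).open("w") as fh:
        for s in library:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def filter_subset_minimal(library: GeneSetLibrary) -> GeneSetLibrary:
    """Keep a process only if no other process is a proper subset of it.

    Sets with identical gene content are all retained: neither is a *proper*
    subset of the other. Idempotent.
    """
    if len(library) == 0:
        raise ValueError("cannot filter an empty library")
    sets = library.sets
    n_dup = len(sets) - len({s.genes for s in sets})
    if n_dup:
        log.warning(
            "library contains %d set(s) with identical gene content; "
            "proper-subset semantics retains all of them", n_dup,
        )
    keep = [
        p
        for p in sets
        if not any(q is not p and len(q.genes) < len(p.genes) and q.genes < p.genes for q in sets)
    ]
    return GeneSetLibrary(keep)


def filter_min_size(library: GeneSetLibrary, min_exclusive: int = 15) -> GeneSetLibrary:
    """Keep sets with strictly more than ``min_exclusive`` genes."""
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    keep = [s for s in library if s.size > min_exclusive]
    if not keep:
        log.warning("size filter (> %d) removed every set", min_exclusive)
    return GeneSetLibrary(keep)


def restrict_to_universe(library: GeneSetLibrary, genes: Iterable[str]) -> GeneSetLibrary:
    """Intersect every set with ``genes``; drop sets that become empty.

    Used before enrichment so that set members not measured in the expression
    matrix are ignored.
    """
    universe = frozenset(genes)
    kept: list[GeneSet] = []
    n_dropped = 0
    for s in library:
        inter = s.genes & universe
        if inter:
            kept.append(GeneSet(name=s.name, genes=frozenset(inter), description=s.description))
        else:
            n_dropped += 1
    if n_dropped:
        log.warning("restrict_to_universe dropped %d set(s) with no measured genes", n_dropped)
    return GeneSetLibrary(kept)


def apply_filters(
    library: GeneSetLibrary, min_size_exclusive: int = 15
) -> tuple[GeneSetLibrary, pd.DataFrame]:
    """Subset-minimality filter followed by the size filter, with a report.

    Returns the filtered library and a per-set TSV-ready report
    (name, size, retained, reason).
    """
    after_subset = filter_subset_minimal(library)
    subset_names = set(after_subset.names)
    final = filter_min_size(after_subset, min_size_exclusive)
    final_names = set(final.names)
    rows = []
    for s in library:
        if s.name not in subset_names:
            retained, reason = False, "contains another set as proper subset"
        elif s.name not in final_names:
            retained, reason = False, f"size <= {min_size_exclusive}"
        else:
            retained, reason = True, ""
        rows.append({"name": s.name, "size": s.size, "retained": retained, "reason": reason})
    return final, pd.DataFrame(rows)
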