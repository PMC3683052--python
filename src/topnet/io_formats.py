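"""Readers/writers for the external formats the pipeline touches.

All tabular inputs are plain TSV; gene sets use GMT semantics. Gene symbols
are matched case-insensitively by uppercasing at read time, because symbol
case drifts between PPI databases and array annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "PPIGraph",
    "GeneCatalog",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_ppi",
    "write_ppi",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
]


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class ExpressionStudy:
    """A gene x sample log2-intensity matrix with a sample->state design.

    Parameters
    ----------
    genes : ordered unique gene symbols (rows of ``values``)
    samples : ordered unique sample ids (columns of ``values``)
    values : 2-D float array of log2 intensities, shape ``(genes, samples)``
    design : mapping sample id -> state label, covering every sample
    states : ordered state labels (defaults to order of first appearance
        in ``design``)
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    design: dict[str, str]
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = [_norm(g) for g in self.genes]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = {g for g in self.genes if self.genes.count(g) > 1}
            raise ValueError(f"duplicate gene symbols: {sorted(dupes)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.samples if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if not self.states:
            seen: list[str] = []
            for s in self.samples:
                st = self.design[s]
                if st not in seen:
                    seen.append(st)
            self.states = seen
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[_norm(gene)]]

    def state_samples(self, state: str) -> list[str]:
        """Sample ids of a state, in study order."""
        out = [s for s in self.samples if self.design[s] == state]
        if not out:
            raise KeyError(f"state {state!r} has no samples")
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        """A new study restricted to ``sample_ids`` (order preserved)."""
        idx = [self._sample_index[s] for s in sample_ids]
        return ExpressionStudy(
            genes=list(self.genes),
            samples=list(sample_ids),
            values=self.values[:, idx],
            design={s: self.design[s] for s in sample_ids},
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        keep = [_norm(g) for g in genes if _norm(g) in self._gene_index]
        idx = [self._gene_index[g] for g in keep]
        return ExpressionStudy(
            genes=keep,
            samples=list(self.samples),
            values=self.values[idx, :],
            design=dict(self.design),
            states=list(self.states),
        )


@dataclass
class PPIGraph:
    """A simple undirected graph over gene symbols.

    Edges are stored as sorted 2-tuples, so ``(a, b)`` and ``(b, a)`` are
    the same edge; self-loops are rejected.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cleaned: set[tuple[str, str]] = set()
        for a, b in self.edges:
            a, b = _norm(a), _norm(b)
            if a == b:
                raise ValueError(f"self-loop {a!r} not allowed in PPIGraph")
            cleaned.add((a, b) if a < b else (b, a))
        self.edges = cleaned

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        a, b = _norm(a), _norm(b)
        return ((a, b) if a < b else (b, a)) in self.edges

    def add_edge(self, a: str, b: str) -> None:
        a, b = _norm(a), _norm(b)
        if a == b:
            raise ValueError(f"self-loop {a!r} not allowed")
        self.edges.add((a, b) if a < b else (b, a))


@dataclass
class GeneCatalog:
    """A set of annotated gene symbols with an optional category each."""

    symbols: set[str]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = {_norm(s) for s in self.symbols}
        self.categories = {_norm(k): v for k, v in self.categories.items()}

    def __contains__(self, symbol: str) -> bool:
        return _norm(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def category(self, symbol: str) -> str | None:
        return self.categories.get(_norm(symbol))


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            self.sets[name] = {_norm(m) for m in members}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    collapse_rule: str = "max_mean",
    log2_transform: bool = False,
) -> ExpressionStudy:
    """Read a gene x sample TSV matrix plus a ``sample<TAB>state`` design.

    Duplicate gene symbols are collapsed per ``collapse_rule``:
    ``"max_mean"`` keeps the row with the highest mean intensity,
    ``"mean"`` averages the duplicate rows. With ``log2_transform`` the
    raw values are mapped through ``log2(x + 1)``.
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    if collapse_rule not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse_rule {collapse_rule!r}")
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix: {matrix_path}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = bad
    df.index = [_norm(g) for g in df.index.astype(str)]

    if df.index.has_duplicates:
        if collapse_rule == "max_mean":
            means = df.mean(axis=1)
            order = np.argsort(-means.values, kind="stable")
            df = df.iloc[order]
            df = df[~df.index.duplicated(keep="first")]
        else:
            df = df.groupby(level=0, sort=False).mean()

    design_df = pd.read_csv(
        design_path, sep="\t", header=None, names=["sample", "state"], comment="#"
    )
    design = dict(zip(design_df["sample"].astype(str), design_df["state"].astype(str)))
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    states: list[str] = []
    for st in design_df["state"]:
        if st not in states:
            states.append(st)

    values = df.values.astype(float)
    if log2_transform:
        values = np.log2(values + 1.0)
    return ExpressionStudy(
        genes=list(df.index),
        samples=[str(c) for c in df.columns],
        values=values,
        design={s: design[s] for s in df.columns},
        states=states,
    )


def write_expression(
    study: ExpressionStudy, matrix_path: str | Path, design_path: str | Path
) -> None:
    df = pd.DataFrame(study.values, index=study.genes, columns=study.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    with open(design_path, "w") as fh:
        for s in study.samples:
            fh.write(f"{s}\t{study.design[s]}\n")


def read_ppi(path: str | Path) -> PPIGraph:
    """Read a two-column TSV of interacting symbol pairs.

    Self-loops and duplicate pairs (either orientation) are dropped and
    counted in the log; extra columns are ignored.
    """
    edges: set[tuple[str, str]] = set()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >=2 fields, got {line!r}")
            a, b = _norm(fields[0]), _norm(fields[1])
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                n_dup += 1
            else:
                edges.add(key)
    if n_self or n_dup:
        logger.info(
            "read_ppi(%s): dropped %d self-loops, %d duplicate pairs", path, n_self, n_dup
        )
    return PPIGraph(edges=edges)


def write_ppi(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> GeneCatalog:
    """Read a one-symbol-per-line catalog with an optional category column."""
    symbols: set[str] = set()
    categories: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            sym = _norm(fields[0])
            symbols.add(sym)
            if len(fields) > 1 and fields[1].strip():
                categories[sym] = fields[1].strip()
    if not symbols:
        raise ValueError(f"empty gene list: {path}")
    return GeneCatalog(symbols=symbols, categories=categories)


def write_gene_list(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(catalog.symbols):
            cat = catalog.categories.get(sym)
            fh.write(f"{sym}\t{cat}\n" if cat else f"{sym}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT needs name, description and >=1 member"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = {_norm(m) for m in members}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
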