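"""Trend-of-progression gene selection over a disease-state sequence.

A gene is selected when its network degree D and clustering coefficient C
grow toward the final state of an ordered state sequence, it is a hub
(D above a floor with positive C) in at least one state, and — in the
DEG-filtered variant — it is differentially expressed versus the first
state. Early-detection markers are the subset with a sharp degree jump
already at the intermediate state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .diffexpr import DEGConfig, DEGRecord, is_deg
from .ggin import GeneNetStats
from .io_formats import GeneCatalog

__all__ = [
    "TrendRecord",
    "ToPConfig",
    "EarlyMarkerConfig",
    "SelectionResult",
    "build_trend_records",
    "top_select",
    "tps_select",
    "combine_sequences",
    "partition_category_counts",
    "hit_rate",
    "early_markers",
]


@dataclass
class TrendRecord:
    """Per-gene (D, C) along an ordered state sequence."""

    gene: str
    sequence: tuple[str, ...]
    D: tuple[float, ...]
    C: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.D) == len(self.C)):
            raise ValueError("sequence, D and C must have equal length")
        if any(d < 0 for d in self.D):
            raise ValueError("D must be >= 0")
        if any(not (0.0 <= c <= 1.0 + 1e-12) for c in self.C):
            raise ValueError("C must be in [0, 1]")


@dataclass
class ToPConfig:
    """Selection knobs.

    ``min_hub_degree`` is exclusive (a hub needs D strictly above it);
    ``trend_mode`` controls the growth predicate: ``into_final_strict``
    requires the final-state D to exceed every earlier state's D and the
    final C to be >= every earlier C minus ``c_tolerance`` (first-to-
    intermediate reversals are thereby unconstrained); ``into_final_weak``
    relaxes D to >=; ``monotone`` requires non-decreasing D and C across
    every consecutive transition. ``joint_hub`` demands the hub-degree and
    positive-C conditions hold in the same state.
    """

    min_hub_degree: float = 4.0
    require_positive_C: bool = True
    trend_mode: str = "into_final_strict"
    c_tolerance: float = 0.0
    joint_hub: bool = True

    def __post_init__(self) -> None:
        if self.min_hub_degree < 0:
            raise ValueError("min_hub_degree must be >= 0")
        if self.c_tolerance < 0:
            raise ValueError("c_tolerance must be >= 0")
        if self.trend_mode not in ("into_final_strict", "into_final_weak", "monotone"):
            raise ValueError(f"unknown trend_mode {self.trend_mode!r}")


@dataclass
class EarlyMarkerConfig:
    degree_fold: float = 5.0
    deg_p_threshold: float = 1e-4
    exclusivity: bool = True

    def __post_init__(self) -> None:
        if self.degree_fold <= 1:
            raise ValueError("degree_fold must be > 1")
        if not (0.0 < self.deg_p_threshold < 1.0):
            raise ValueError("deg_p_threshold must be in (0, 1)")


@dataclass
class SelectionResult:
    """A named gene selection with per-gene trend evidence and summary."""

    genes: set[str]
    records: dict[str, TrendRecord] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    partition: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        if self.partition is not None:
            total = (
                len(self.partition["exclusive_a"])
                + len(self.partition["common"])
                + len(self.partition["exclusive_b"])
            )
            if total != len(self.genes):
                raise ValueError("partition counts inconsistent with union size")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def build_trend_records(
    stats_by_state: Mapping[str, Iterable[GeneNetStats]],
    sequence: Iterable[str],
    gene_universe: Iterable[str] | None = None,
) -> list[TrendRecord]:
    """Assemble TrendRecords from per-state aggregated gene stats.

    Genes missing from a state's stats get D = C = 0 there.
    """
    sequence = tuple(sequence)
    missing = [s for s in sequence if s not in stats_by_state]
    if missing:
        raise KeyError(f"states missing from stats: {missing}")
    tables = {
        st: {s.gene: (s.D, s.C) for s in stats_by_state[st]} for st in sequence
    }
    if gene_universe is None:
        gene_universe = sorted({g for t in tables.values() for g in t})
    out = []
    for gene in sorted(set(gene_universe)):
        dc = [tables[st].get(gene, (0.0, 0.0)) for st in sequence]
        out.append(
            TrendRecord(
                gene=gene,
                sequence=sequence,
                D=tuple(d for d, _ in dc),
                C=tuple(c for _, c in dc),
            )
        )
    return out


def _is_hub(record: TrendRecord, config: ToPConfig) -> bool:
    if config.joint_hub:
        return any(
            d > config.min_hub_degree and (c > 0 or not config.require_positive_C)
            for d, c in zip(record.D, record.C)
        )
    deg_ok = any(d > config.min_hub_degree for d in record.D)
    c_ok = any(c > 0 for c in record.C) or not config.require_positive_C
    return deg_ok and c_ok


def _trend_holds(record: TrendRecord, config: ToPConfig) -> bool:
    d, c, eps = record.D, record.C, config.c_tolerance
    if config.trend_mode == "into_final_strict":
        return all(d[-1] > d[i] for i in range(len(d) - 1)) and all(
            c[-1] >= c[i] - eps for i in range(len(c) - 1)
        )
    if config.trend_mode == "into_final_weak":
        return all(d[-1] >= d[i] for i in range(len(d) - 1)) and all(
            c[-1] >= c[i] - eps for i in range(len(c) - 1)
        )
    # monotone
    return all(d[i] <= d[i + 1] for i in range(len(d) - 1)) and all(
        c[i] <= c[i + 1] + eps for i in range(len(c) - 1)
    )


def top_select(
    records: list[TrendRecord], config: ToPConfig | None = None
) -> SelectionResult:
    """Select genes whose network prominence grows toward the final state.

    A gene passes iff (a) it appears in at least one network of the
    sequence (some D > 0); (b) it is a hub in at least one state; and
    (c) the configured trend predicate holds.
    """
    config = config or ToPConfig()
    if not records:
        raise ValueError("no trend records supplied")
    seq = records[0].sequence
    if len(seq) < 3:
        raise ValueError(f"sequence needs >= 3 states, got {seq}")
    selected: set[str] = set()
    evidence: dict[str, TrendRecord] = {}
    for rec in records:
        if rec.sequence != seq:
            raise ValueError(f"record {rec.gene} spans a different sequence")
        if not any(d > 0 for d in rec.D):
            continue
        if not _is_hub(rec, config):
            continue
        if not _trend_holds(rec, config):
            continue
        selected.add(rec.gene)
        evidence[rec.gene] = rec
    return SelectionResult(
        genes=selected,
        records=evidence,
        provenance={"sequence": seq, "config": config, "method": "top"},
    )


def _as_table(deg_records: Iterable[DEGRecord]) -> dict[str, DEGRecord]:
    return {r.gene: r for r in deg_records}


def tps_select(
    top_result: SelectionResult,
    deg_x_vs_nor: Iterable[DEGRecord],
    deg_final_vs_nor: Iterable[DEGRecord],
    deg_config: DEGConfig | None = None,
) -> SelectionResult:
    """Restrict a ToP selection to genes that are DEGs in at least one of
    the intermediate-vs-first or final-vs-first contrasts."""
    deg_config = deg_config or DEGConfig()
    tab_x, tab_f = _as_table(deg_x_vs_nor), _as_table(deg_final_vs_nor)
    kept: set[str] = set()
    for gene in top_result.genes:
        in_x, in_f = gene in tab_x, gene in tab_f
        if not in_x and not in_f:
            raise KeyError(f"ToP gene {gene!r} missing from both DEG tables")
        if (in_x and is_deg(tab_x[gene], deg_config, mode="tps")) or (
            in_f and is_deg(tab_f[gene], deg_config, mode="tps")
        ):
            kept.add(gene)
    return SelectionResult(
        genes=kept,
        records={g: top_result.records[g] for g in kept if g in top_result.records},
        provenance={**top_result.provenance, "method": "tps"},
    )


def combine_sequences(
    result_a: SelectionResult, result_b: SelectionResult
) -> SelectionResult:
    """Union of two selections with exclusive-A / common / exclusive-B
    partition bookkeeping."""
    a, b = result_a.genes, result_b.genes
    partition = {
        "exclusive_a": a - b,
        "common": a & b,
        "exclusive_b": b - a,
    }
    records = {**result_b.records, **result_a.records}
    union = a | b
    return SelectionResult(
        genes=union,
        records={g: r for g, r in records.items() if g in union},
        provenance={
            "method": "combine",
            "a": result_a.provenance,
            "b": result_b.provenance,
        },
        summary={
            "n_exclusive_a": len(partition["exclusive_a"]),
            "n_common": len(partition["common"]),
            "n_exclusive_b": len(partition["exclusive_b"]),
            "n_union": len(union),
        },
        partition=partition,
    )


def partition_category_counts(
    combined: SelectionResult, catalog: GeneCatalog
) -> dict[str, int]:
    """Catalog-member counts per origin partition of a combined selection."""
    if combined.partition is None:
        raise ValueError("selection has no sequence partition")
    counts = {
        key: sum(1 for g in genes if g in catalog)
        for key, genes in combined.partition.items()
    }
    counts["total"] = sum(counts.values())
    return counts


def hit_rate(selected: Iterable[str] | SelectionResult, catalog: GeneCatalog) -> float:
    """Percentage of the selection present in the catalog."""
    genes = selected.genes if isinstance(selected, SelectionResult) else set(selected)
    if not genes:
        raise ValueError("empty selection")
    return 100.0 * sum(1 for g in genes if g in catalog) / len(genes)


def early_markers(
    tps_result: SelectionResult,
    records: Iterable[TrendRecord] | Mapping[str, TrendRecord],
    deg_x_vs_nor: Iterable[DEGRecord],
    deg_other_vs_nor: Iterable[DEGRecord] | None,
    config: EarlyMarkerConfig | None = None,
    state: str | None = None,
    deg_config: DEGConfig | None = None,
) -> SelectionResult:
    """Markers flagged already at intermediate state ``state``.

    A TPS gene qualifies when its degree at ``state`` is at least
    ``degree_fold`` times its first-state degree (a first-state degree of 0
    passes when the intermediate degree reaches ``degree_fold``), its raw
    DEG p-value in the state-vs-first contrast is below
    ``deg_p_threshold``, and — with ``exclusivity`` — it is not a
    tps-mode DEG in the other intermediate state's contrast.
    """
    config = config or EarlyMarkerConfig()
    deg_config = deg_config or DEGConfig()
    rec_map = (
        dict(records) if isinstance(records, Mapping) else {r.gene: r for r in records}
    )
    tab_x = _as_table(deg_x_vs_nor)
    tab_other = _as_table(deg_other_vs_nor) if deg_other_vs_nor is not None else {}
    seq0 = tps_result.provenance.get("sequence")
    if seq0 is None and rec_map:
        seq0 = next(iter(rec_map.values())).sequence
    if state is not None and seq0 is not None and state not in seq0:
        raise KeyError(f"state {state!r} not in sequence {tuple(seq0)}")
    kept: set[str] = set()
    for gene in tps_result.genes:
        rec = rec_map.get(gene)
        if rec is None:
            continue
        seq = rec.sequence
        state_x = state if state is not None else seq[1]
        xi = seq.index(state_x)
        d_first, d_x = rec.D[0], rec.D[xi]
        if d_first == 0:
            fold_ok = d_x >= config.degree_fold
        else:
            fold_ok = d_x >= config.degree_fold * d_first
        if not fold_ok:
            continue
        deg = tab_x.get(gene)
        if deg is None or deg.p >= config.deg_p_threshold:
            continue
        if config.exclusivity and gene in tab_other:
            if is_deg(tab_other[gene], deg_config, mode="tps"):
                continue
        kept.add(gene)
    return SelectionResult(
        genes=kept,
        records={g: rec_map[g] for g in kept},
        provenance={**tps_result.provenance, "method": "early_markers", "state": state},
    )
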