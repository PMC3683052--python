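"""Randomization null models and permutation p-values for gene selections.

Type-1 scrambles each gene's intensities across all arrays (conserves the
per-gene value distribution, destroys pairwise correlation). Type-2
replaces every network link by a uniformly drawn distinct gene pair
(conserves the link count, destroys the topology). A topology-conserving
type-3 is intentionally unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Sequence

import numpy as np

from .diffexpr import DEGConfig, two_class_test
from .ggin import GGINConfig, StateNetwork, aggregate_gene_stats, subsample_ensemble
from .io_formats import ExpressionStudy, GeneCatalog, PPIGraph
from .trend import (
    SelectionResult,
    ToPConfig,
    build_trend_records,
    hit_rate,
    top_select,
    tps_select,
)

__all__ = [
    "NullRun",
    "PermutationSummary",
    "SelectionPipelineSpec",
    "run_selection_pipeline",
    "randomize_type1",
    "randomize_type2",
    "randomize_type3",
    "null_ensemble",
    "permutation_p",
]


@dataclass
class NullRun:
    rand_type: str
    replicate: int
    seed: int
    n_selected: int
    hit_rate: float | None

    def __post_init__(self) -> None:
        if self.n_selected < 0:
            raise ValueError("n_selected must be >= 0")
        if self.hit_rate is not None and not (0.0 <= self.hit_rate <= 100.0):
            raise ValueError("hit_rate must be in [0, 100]")


@dataclass
class PermutationSummary:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_replicates: int


@dataclass
class SelectionPipelineSpec:
    """Everything needed to rerun a ToP/TPS selection from scratch."""

    study: ExpressionStudy
    ppi: PPIGraph
    sequence: tuple[str, ...]
    ggin_config: GGINConfig = field(default_factory=GGINConfig)
    top_config: ToPConfig = field(default_factory=ToPConfig)
    deg_config: DEGConfig = field(default_factory=DEGConfig)
    selection_mode: str = "top"  # top | tps
    catalog: GeneCatalog | None = None
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.selection_mode not in ("top", "tps"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        self.sequence = tuple(self.sequence)


def run_selection_pipeline(
    spec: SelectionPipelineSpec,
    study: ExpressionStudy | None = None,
    rewire_seed: int | None = None,
) -> SelectionResult:
    """Build per-state ensembles, aggregate gene stats, and select.

    ``study`` overrides the spec's study (used for type-1 nulls);
    ``rewire_seed``, when given, applies type-2 rewiring to every network
    before aggregation.
    """
    study = study if study is not None else spec.study
    ppi_nodes = spec.ppi.nodes
    universe = sorted(set(study.genes) & ppi_nodes)
    stats_by_state = {}
    rewire_counter = 0
    for st in spec.sequence:
        ensemble = subsample_ensemble(study, st, spec.ppi, spec.ggin_config)
        if rewire_seed is not None:
            rewired = []
            for net in ensemble:
                rewired.append(
                    randomize_type2(net, universe, seed=(rewire_seed, rewire_counter))
                )
                rewire_counter += 1
            ensemble = rewired
        stats_by_state[st] = aggregate_gene_stats(
            ensemble, universe, aggregate=spec.aggregate
        )
    records = build_trend_records(stats_by_state, spec.sequence, universe)
    result = top_select(records, spec.top_config)
    if spec.selection_mode == "tps":
        first, mid, final = spec.sequence[0], spec.sequence[1], spec.sequence[-1]
        deg_mid = two_class_test(
            study, study.state_samples(mid), study.state_samples(first),
            config=spec.deg_config,
        )
        deg_final = two_class_test(
            study, study.state_samples(final), study.state_samples(first),
            config=spec.deg_config,
        )
        result = tps_select(result, deg_mid, deg_final, spec.deg_config)
    result.summary["n_selected"] = len(result)
    if spec.catalog is not None and len(result) > 0:
        result.summary["hit_rate"] = hit_rate(result, spec.catalog)
    return result


def randomize_type1(study: ExpressionStudy, seed: int | tuple = 0) -> ExpressionStudy:
    """Scramble each gene's intensities independently across all arrays.

    One sweep over the genes; the per-gene multiset of values is conserved
    exactly while pairwise correlation is destroyed.
    """
    rng = np.random.default_rng(seed)
    values = study.values.copy()
    for i in range(values.shape[0]):
        rng.shuffle(values[i])
    return ExpressionStudy(
        genes=list(study.genes),
        samples=list(study.samples),
        values=values,
        design=dict(study.design),
        states=list(study.states),
    )


def randomize_type2(
    network: StateNetwork, gene_universe: Sequence[str], seed: int | tuple = 0
) -> StateNetwork:
    """Assign each link a uniformly random distinct gene pair.

    Conserves the edge count; the result is a simple graph (no self-loops,
    no duplicate edges) over ``gene_universe``.
    """
    universe = sorted(set(gene_universe))
    n = len(universe)
    if n < 3:
        raise ValueError("gene universe must have >= 3 genes")
    m = network.n_edges
    if m > comb(n, 2):
        raise ValueError(f"cannot place {m} distinct edges on {n} genes")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        draw = rng.integers(0, n, size=2 * (m - len(chosen) + 4))
        for i in range(0, len(draw) - 1, 2):
            a, b = int(draw[i]), int(draw[i + 1])
            if a == b:
                continue
            chosen.add((a, b) if a < b else (b, a))
            if len(chosen) == m:
                break
    out = StateNetwork(state=network.state, subsample_id=network.subsample_id)
    for (a, b), (r, p) in zip(sorted(chosen), network.edges.values()):
        out.add_edge(universe[a], universe[b], r, p)
    return out


def randomize_type3(*_args, **_kwargs):
    """Topology-conserving node relabeling — rejected as not a true
    randomization; calling it is an error by design."""
    raise NotImplementedError("type-3 topology-conserving randomization is unsupported")


def null_ensemble(
    spec: SelectionPipelineSpec,
    rand_type: str,
    n_replicates: int,
    seed: int = 0,
    joint: bool = True,
) -> list[NullRun]:
    """Rerun the selection on randomized data ``n_replicates`` times.

    ``type1`` scrambles intensities before network building. ``type2`` on a
    ToP/TPS spec scrambles intensities (type-1) *and* rewires every network
    link (type-2) jointly, matching how the selection nulls were run;
    ``joint=False`` restricts it to link rewiring only.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rand_type not in ("type1", "type2"):
        raise ValueError(f"unknown randomization type {rand_type!r}")
    runs: list[NullRun] = []
    for rep in range(n_replicates):
        rep_seed = (seed, rep)
        if rand_type == "type1":
            study = randomize_type1(spec.study, seed=rep_seed)
            rewire = None
        else:
            study = (
                randomize_type1(spec.study, seed=rep_seed) if joint else None
            )
            rewire = seed * 1_000_003 + rep
        rep_spec = replace(
            spec, ggin_config=replace(spec.ggin_config, seed=seed + 7919 * (rep + 1))
        )
        result = run_selection_pipeline(rep_spec, study=study, rewire_seed=rewire)
        runs.append(
            NullRun(
                rand_type=rand_type,
                replicate=rep,
                seed=seed,
                n_selected=len(result),
                hit_rate=result.summary.get("hit_rate"),
            )
        )
    return runs


def permutation_p(
    observed: float, null_values: Sequence[float], direction: str = "greater"
) -> PermutationSummary:
    """Add-one permutation p-value: (1 + #extreme) / (1 + N)."""
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValueError("need at least one null value")
    if direction == "greater":
        extreme = int(np.sum(null_values >= observed))
    elif direction == "less":
        extreme = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return PermutationSummary(
        observed=float(observed),
        null_mean=float(null_values.mean()),
        null_sd=float(null_values.std(ddof=1)) if null_values.size > 1 else 0.0,
        p_value=(1 + extreme) / (1 + null_values.size),
        n_replicates=int(null_values.size),
    )
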