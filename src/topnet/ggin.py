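"""State-specific gene-gene interaction networks (GGINs) and their metrics.

An edge enters a network iff (1) the Pearson p-value of the gene pair on the
selected arrays is at most ``p0`` and (2) the pair is a PPI edge. Networks
contain only genes incident to at least one surviving edge.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionStudy, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GGINConfig",
    "CorrelationEdge",
    "StateNetwork",
    "NetworkSummary",
    "GeneNetStats",
    "pearson_p",
    "build_network",
    "subsample_ensemble",
    "clustering_coefficient",
    "summarize_network",
    "aggregate_gene_stats",
    "degree_cc_profile",
]


@dataclass
class GGINConfig:
    """Knobs for network construction.

    ``p0`` is the Pearson p-value inclusion threshold. States with more than
    ``subsample_size`` arrays get an ensemble of ``n_subsamples`` networks,
    each built from ``subsample_size`` arrays drawn without replacement.
    """

    p0: float = 0.01
    subsample_size: int = 8
    n_subsamples: int = 100
    seed: int = 0
    aggregate: str = "mean"  # mean | median | single_network

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 <= 1.0):
            raise ValueError(f"p0 must be in (0, 1], got {self.p0}")
        if self.subsample_size < 3:
            raise ValueError("subsample_size must be >= 3")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


@dataclass
class CorrelationEdge:
    gene_a: str
    gene_b: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"r out of range: {self.r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


class StateNetwork:
    """One GGIN: a simple undirected graph with (r, p) per edge."""

    def __init__(
        self,
        state: str,
        subsample_id: int = 0,
        edges: dict[tuple[str, str], tuple[float, float]] | None = None,
    ) -> None:
        self.state = state
        self.subsample_id = subsample_id
        self.edges: dict[tuple[str, str], tuple[float, float]] = {}
        self._adj: dict[str, set[str]] = {}
        if edges:
            for (a, b), (r, p) in edges.items():
                self.add_edge(a, b, r, p)

    def add_edge(self, a: str, b: str, r: float, p: float) -> None:
        if a == b:
            raise ValueError("self-loop")
        key = (a, b) if a < b else (b, a)
        self.edges[key] = (float(r), float(p))
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    def neighbors(self, gene: str) -> set[str]:
        return self._adj[gene]

    def connected_components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in self._adj:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    power_law_exponent: float
    mean_clustering: float
    giant_component_size: int


@dataclass
class GeneNetStats:
    """Ensemble-aggregated degree/clustering of one gene in one state."""

    gene: str
    state: str
    D: float
    C: float
    presence_fraction: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not (0.0 <= self.C <= 1.0 + 1e-12):
            raise ValueError("C must be in [0, 1]")


# ---------------------------------------------------------------------------


def pearson_p(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    gene_a: str = "a",
    gene_b: str = "b",
    method: str = "t",
    n_permutations: int = 10000,
    seed: int = 0,
) -> CorrelationEdge:
    """Pearson correlation with a two-sided p-value.

    The default p comes from ``t = r * sqrt((n-2)/(1-r^2))`` against the t
    distribution with ``n - 2`` degrees of freedom; ``method="permutation"``
    instead permutes one vector ``n_permutations`` times (add-one estimator).
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance vector")
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if method == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        hits = 0
        for _ in range(n_permutations):
            rp = float(np.dot(za, rng.permutation(zb))) / n
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationEdge(gene_a=gene_a, gene_b=gene_b, r=r, p=min(p, 1.0))


def _edge_candidates(
    study: ExpressionStudy, ppi: PPIGraph
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """PPI edges with both genes measured, as index arrays into the study."""
    gi = {g: i for i, g in enumerate(study.genes)}
    pairs = [(a, b) for a, b in ppi.edges if a in gi and b in gi]
    ia = np.array([gi[a] for a, _ in pairs], dtype=int)
    ib = np.array([gi[b] for _, b in pairs], dtype=int)
    return pairs, ia, ib


def build_network(
    study_subset: ExpressionStudy,
    ppi: PPIGraph,
    config: GGINConfig,
    state: str | None = None,
    subsample_id: int = 0,
    _candidates: tuple | None = None,
) -> StateNetwork:
    """Build one GGIN from the arrays in ``study_subset``.

    Every PPI edge with both genes measured is tested; an edge is kept iff
    its Pearson p-value is at most ``config.p0``. Genes with zero-variance
    profiles are skipped with a warning.
    """
    n = study_subset.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 arrays to build a network, got {n}")
    if state is None:
        states = {study_subset.design[s] for s in study_subset.samples}
        state = states.pop() if len(states) == 1 else "+".join(sorted(states))

    pairs, ia, ib = (
        _candidates if _candidates is not None else _edge_candidates(study_subset, ppi)
    )
    net = StateNetwork(state=state, subsample_id=subsample_id)
    if not pairs:
        return net

    vals = study_subset.values
    sd = vals.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "build_network: skipping %d zero-variance genes", int(zero_var.sum())
        )
    mean = vals.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd[:, None]
    r = np.einsum("ij,ij->i", z[ia], z[ib]) / n
    ok = ~(zero_var[ia] | zero_var[ib])
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    keep = ok & (p <= config.p0)
    for k in np.flatnonzero(keep):
        a, b = pairs[k]
        net.add_edge(a, b, float(r[k]), float(p[k]))
    return net


def subsample_ensemble(
    study: ExpressionStudy, state: str, ppi: PPIGraph, config: GGINConfig
) -> list[StateNetwork]:
    """Networks for one state: a single network when the state has exactly
    ``subsample_size`` arrays, else ``n_subsamples`` networks each from a
    seeded draw of ``subsample_size`` arrays without replacement."""
    samples = study.state_samples(state)  # raises KeyError when state absent
    if len(samples) < config.subsample_size:
        raise ValueError(
            f"state {state!r} has {len(samples)} samples < subsample_size "
            f"{config.subsample_size}"
        )
    candidates = _edge_candidates(study, ppi)
    if len(samples) == config.subsample_size:
        sub = study.subset_samples(samples)
        return [build_network(sub, ppi, config, state=state, _candidates=candidates)]
    rng = np.random.default_rng((config.seed, zlib.crc32(state.encode())))
    nets = []
    for rep in range(config.n_subsamples):
        pick = rng.choice(len(samples), size=config.subsample_size, replace=False)
        sub = study.subset_samples([samples[i] for i in sorted(pick)])
        nets.append(
            build_network(
                sub, ppi, config, state=state, subsample_id=rep, _candidates=candidates
            )
        )
    return nets


def clustering_coefficient(network: StateNetwork, gene: str) -> float:
    """C = 2e / (k (k - 1)) with e the edge count among the gene's
    neighbors; genes of degree < 2 get C = 0 by convention."""
    if gene not in network:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = network.neighbors(gene)
    k = len(nbrs)
    if k < 2:
        return 0.0
    e = 0
    nbr_list = list(nbrs)
    for i, u in enumerate(nbr_list):
        adj_u = network.neighbors(u)
        for v in nbr_list[i + 1 :]:
            if v in adj_u:
                e += 1
    return 2.0 * e / (k * (k - 1))


def mean_degree(n_nodes: int, n_edges: int) -> float:
    """<k> = 2 E / N."""
    if n_nodes <= 0:
        raise ValueError("need at least one node")
    return 2.0 * n_edges / n_nodes


def power_law_exponent(degrees: list[int] | np.ndarray) -> float:
    """Slope of the least-squares fit of log10(count(k)) on log10(k) over
    degrees k >= 1 with nonzero counts. Descriptive, not inferential."""
    degrees = np.asarray(degrees, dtype=int)
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if len(ks) < 2:
        return float("nan")
    x = np.log10(ks.astype(float))
    y = np.log10(counts.astype(float))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def summarize_network(network: StateNetwork) -> NetworkSummary:
    """Structural summary: size, <k> = 2E/N, power-law exponent of the
    degree histogram, mean clustering coefficient, giant component size."""
    if network.n_nodes == 0:
        raise ValueError("cannot summarize an empty network")
    nodes = sorted(network.nodes)
    degrees = [network.degree(g) for g in nodes]
    cs = [clustering_coefficient(network, g) for g in nodes]
    comps = network.connected_components()
    return NetworkSummary(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        mean_degree=mean_degree(network.n_nodes, network.n_edges),
        power_law_exponent=power_law_exponent(degrees),
        mean_clustering=float(np.mean(cs)),
        giant_component_size=max(len(c) for c in comps),
    )


def aggregate_gene_stats(
    ensemble: list[StateNetwork],
    gene_universe: list[str] | set[str],
    aggregate: str = "mean",
) -> list[GeneNetStats]:
    """Per-gene (D, C) aggregated over an ensemble of networks.

    ``mean`` (default): D averaged with absent-from-network counting as 0;
    C averaged over the networks where the gene is present (0 if never).
    ``median`` replaces the mean by the median with the same absence rules;
    ``single_network`` uses the first network only.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if aggregate not in ("mean", "median", "single_network"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    state = ensemble[0].state
    nets = ensemble[:1] if aggregate == "single_network" else ensemble
    n = len(nets)
    out: list[GeneNetStats] = []
    reduce = np.median if aggregate == "median" else np.mean
    for gene in sorted(set(gene_universe)):
        ds = np.zeros(n)
        cs: list[float] = []
        present = 0
        for i, net in enumerate(nets):
            if gene in net:
                present += 1
                ds[i] = net.degree(gene)
                cs.append(clustering_coefficient(net, gene))
        out.append(
            GeneNetStats(
                gene=gene,
                state=state,
                D=float(reduce(ds)),
                C=float(reduce(cs)) if cs else 0.0,
                presence_fraction=present / n,
            )
        )
    return out


def degree_cc_profile(
    ensemble: list[StateNetwork],
    c_bin_edges: np.ndarray | None = None,
    max_degree: int | None = None,
) -> pd.DataFrame:
    """Joint percentage histogram of genes over degree x clustering range.

    Degree-1 genes are excluded; percentages are of shown genes and are
    averaged across the ensemble. Returns a tidy frame with columns
    ``degree``, ``c_low``, ``c_high``, ``percent``.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if c_bin_edges is None:
        c_bin_edges = np.linspace(0.0, 1.0, 6)
    c_bin_edges = np.asarray(c_bin_edges, dtype=float)
    n_cbins = len(c_bin_edges) - 1
    if max_degree is None:
        max_degree = max(
            (net.degree(g) for net in ensemble for g in net.nodes), default=2
        )
    rows: dict[tuple[int, int], float] = {}
    for net in ensemble:
        shown = [g for g in net.nodes if net.degree(g) >= 2]
        if not shown:
            continue
        for g in shown:
            k = min(net.degree(g), max_degree)
            c = clustering_coefficient(net, g)
            ci = min(int(np.searchsorted(c_bin_edges, c, side="right")) - 1, n_cbins - 1)
            ci = max(ci, 0)
            rows[(k, ci)] = rows.get((k, ci), 0.0) + 100.0 / (len(shown) * len(ensemble))
    records = [
        {
            "degree": k,
            "c_low": c_bin_edges[ci],
            "c_high": c_bin_edges[ci + 1],
            "percent": pct,
        }
        for (k, ci), pct in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(
        records, columns=["degree", "c_low", "c_high", "percent"]
    )
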