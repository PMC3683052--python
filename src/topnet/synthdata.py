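"""Synthetic multi-state cohorts with planted progression structure.

Module members in state ``s`` are drawn as

    x = baseline_gene + delta_s + noise_sd * (sqrt(rho_s) * f + sqrt(1 - rho_s) * eps)

with ``f`` a per-sample factor shared across the module and ``eps`` i.i.d.
noise, so the expected pairwise correlation between two members equals
``rho_s`` exactly. The PPI scaffold is a simplified configuration-model
scale-free graph, with every within-module pair added as an edge so that
planted correlation edges can pass the PPI filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import ExpressionStudy, PPIGraph

__all__ = [
    "PlantedModule",
    "SynthConfig",
    "SynthTruth",
    "simulate_study",
    "make_fixture",
    "FIXTURE_PROFILES",
]


@dataclass
class PlantedModule:
    """A gene module with per-state correlation and mean shift.

    ``rho`` and ``delta`` are ordered like ``SynthConfig.states``:
    ``rho[s]`` is the within-module pairwise correlation in state ``s``
    and ``delta[s]`` a mean shift in log2 units.
    """

    members: list[str]
    rho: tuple[float, ...]
    delta: tuple[float, ...]


@dataclass
class SynthConfig:
    n_genes: int
    states: list[str]
    samples_per_state: dict[str, int]
    planted_modules: list[PlantedModule] = field(default_factory=list)
    ppi_degree_exponent: float = 2.5
    n_ppi_edges: int = 200
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for st in self.states:
            if self.samples_per_state.get(st, 0) < 3:
                raise ValueError(f"state {st!r} needs >= 3 samples")
        for mod in self.planted_modules:
            if len(mod.rho) != len(self.states) or len(mod.delta) != len(self.states):
                raise ValueError("rho/delta must have one entry per state")
            for r in mod.rho:
                if not (0.0 <= r < 1.0):
                    raise ValueError(f"rho must be in [0, 1), got {r}")
            if len(mod.members) > self.n_genes:
                raise ValueError("module larger than the gene universe")


@dataclass
class SynthTruth:
    """Ground truth of a simulated study."""

    trend_genes: set[str]
    module_map: dict[int, list[str]]
    ppi: PPIGraph


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _scale_free_scaffold(
    genes: list[str], n_edges: int, exponent: float, rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Simplified configuration-model graph trimmed/padded to ``n_edges``."""
    n = len(genes)
    degrees = rng.zipf(exponent, size=n)
    degrees = np.clip(degrees, 1, max(2, n // 4))
    # scale toward the requested edge budget before building stubs
    target_sum = 2 * n_edges
    degrees = np.maximum(1, np.round(degrees * target_sum / degrees.sum()).astype(int))
    if degrees.sum() % 2:
        degrees[int(rng.integers(n))] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    edges = {tuple(sorted((genes[u], genes[v]))) for u, v in g.edges()}
    edges = set(list(edges))
    if len(edges) > n_edges:
        keep = rng.choice(len(edges), size=n_edges, replace=False)
        ordered = sorted(edges)
        edges = {ordered[i] for i in keep}
    while len(edges) < n_edges:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        e = tuple(sorted((genes[i], genes[j])))
        edges.add(e)
    return edges


def simulate_study(config: SynthConfig) -> tuple[ExpressionStudy, PPIGraph, SynthTruth]:
    """Simulate an expression study, PPI scaffold and ground truth.

    Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for mod in config.planted_modules:
        unknown = [m for m in mod.members if m.upper() not in gene_index]
        if unknown:
            raise ValueError(f"planted members outside gene universe: {unknown}")

    samples: list[str] = []
    design: dict[str, str] = {}
    for st in config.states:
        for k in range(config.samples_per_state[st]):
            sid = f"{st}_{k:02d}"
            samples.append(sid)
            design[sid] = st

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.empty((config.n_genes, len(samples)))
    col = 0
    for si, st in enumerate(config.states):
        n_s = config.samples_per_state[st]
        block = baseline[:, None] + config.noise_sd * rng.standard_normal(
            (config.n_genes, n_s)
        )
        for mod in config.planted_modules:
            rho, delta = mod.rho[si], mod.delta[si]
            f = rng.standard_normal(n_s)
            idx = [gene_index[m.upper()] for m in mod.members]
            eps = rng.standard_normal((len(idx), n_s))
            block[idx, :] = (
                baseline[idx, None]
                + delta
                + config.noise_sd * (np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * eps)
            )
        values[:, col : col + n_s] = block
        col += n_s

    edges = _scale_free_scaffold(
        genes, config.n_ppi_edges, config.ppi_degree_exponent, rng
    )
    module_map: dict[int, list[str]] = {}
    trend_genes: set[str] = set()
    for mi, mod in enumerate(config.planted_modules):
        members = [m.upper() for m in mod.members]
        module_map[mi] = members
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges.add((a, b) if a < b else (b, a))
        rising = all(mod.rho[k] <= mod.rho[k + 1] for k in range(len(mod.rho) - 1))
        if rising and mod.rho[-1] > mod.rho[0]:
            trend_genes.update(members)

    ppi = PPIGraph(edges=edges)
    study = ExpressionStudy(
        genes=genes, samples=samples, values=values, design=design,
        states=list(config.states),
    )
    return study, ppi, SynthTruth(trend_genes=trend_genes, module_map=module_map, ppi=ppi)


def _tiny_config() -> SynthConfig:
    return SynthConfig(
        n_genes=40,
        states=["S0", "S1", "S2"],
        samples_per_state={"S0": 8, "S1": 8, "S2": 8},
        planted_modules=[
            PlantedModule(
                members=[f"G{i:02d}" for i in range(8)],
                rho=(0.1, 0.5, 0.9),
                delta=(0.0, 1.0, 2.0),
            )
        ],
        n_ppi_edges=60,
        seed=101,
    )


def _paper_shaped_config(seed: int = 202) -> SynthConfig:
    members_a = [f"G{i:03d}" for i in range(12)]
    members_b = [f"G{i:03d}" for i in range(12, 24)]
    return SynthConfig(
        n_genes=250,
        states=["Nor", "Ade", "IBD", "CRC"],
        samples_per_state={"Nor": 8, "Ade": 15, "IBD": 15, "CRC": 15},
        planted_modules=[
            PlantedModule(members=members_a, rho=(0.2, 0.6, 0.6, 0.9),
                          delta=(0.0, 1.0, 1.0, 2.0)),
            PlantedModule(members=members_b, rho=(0.2, 0.6, 0.6, 0.9),
                          delta=(0.0, 1.0, 1.0, 2.0)),
        ],
        n_ppi_edges=500,
        seed=seed,
    )


FIXTURE_PROFILES = ("tiny", "paper_shaped")


def make_fixture(profile_name: str, seed: int | None = None):
    """Build a deterministic named fixture study.

    ``tiny`` is a 40-gene, 3-state cohort that runs end-to-end in seconds;
    ``paper_shaped`` mimics a 4-state cohort with 8/15/15/15 samples and two
    planted modules whose correlation grows toward the final state. ``seed``
    overrides the profile's fixed seed (fixtures stay deterministic per seed).
    """
    if profile_name == "tiny":
        cfg = _tiny_config()
    elif profile_name == "paper_shaped":
        cfg = _paper_shaped_config()
    else:
        raise ValueError(
            f"unknown profile {profile_name!r}; available: {FIXTURE_PROFILES}"
        )
    if seed is not None:
        cfg.seed = seed
    return simulate_study(cfg)
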