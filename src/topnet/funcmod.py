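"""Functional-module assignment, FFN reduction and gene-set enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .diffexpr import bh_adjust
from .ggin import StateNetwork
from .io_formats import GeneSetCollection

__all__ = [
    "ModuleAssignment",
    "FFN",
    "EnrichmentRecord",
    "assign_modules",
    "reduce_to_ffn",
    "overlap_percentage",
    "hypergeom_enrich",
]

# modules below this many genes are flagged as small (kept, not dropped)
SMALL_MODULE_FLOOR = 70


@dataclass
class ModuleAssignment:
    """Per-module genes of a network and intra-module link sets."""

    genes: dict[str, set[str]]
    links: dict[str, set[tuple[str, str]]]
    small: set[str] = field(default_factory=set)
    network_edges: set[tuple[str, str]] = field(default_factory=set)
    network_size: int = 0


@dataclass
class FFN:
    """Function-function network: modules as nodes, link counts as weights."""

    sizes: dict[str, int]
    intra_links_per_gene: dict[str, float]
    edge_weights: dict[tuple[str, str], int]


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    selection_size: int
    universe_size: int
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.selection_size):
            raise ValueError("overlap exceeds set or selection size")

    @property
    def percent(self) -> float:
        """Share of the selection annotated to the set, in percent."""
        return 100.0 * self.overlap / self.selection_size


def assign_modules(
    network: StateNetwork,
    sets: GeneSetCollection,
    small_floor: int = SMALL_MODULE_FLOOR,
) -> ModuleAssignment:
    """Map each gene set onto the network.

    A gene may belong to several modules; intra-module links are network
    edges with both endpoints in the module. Modules with fewer than
    ``small_floor`` genes in the network are flagged, not dropped.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    nodes = network.nodes
    genes: dict[str, set[str]] = {}
    links: dict[str, set[tuple[str, str]]] = {}
    small: set[str] = set()
    for name in sets.names():
        members = sets[name] & nodes
        genes[name] = members
        links[name] = {
            (a, b) for (a, b) in network.edges if a in members and b in members
        }
        if len(members) < small_floor:
            small.add(name)
    return ModuleAssignment(
        genes=genes,
        links=links,
        small=small,
        network_edges=set(network.edges),
        network_size=network.n_nodes,
    )


def reduce_to_ffn(assignment: ModuleAssignment) -> FFN:
    """Collapse a module assignment to a function-function network.

    Node weight = intra-module links per gene; edge weight = number of
    network links whose endpoints fall in the two (different) modules.
    With multi-membership a physical link can contribute to several module
    pairs; totals may therefore double-count.
    """
    sizes = {m: len(g) for m, g in assignment.genes.items()}
    ilpg = {
        m: (len(assignment.links[m]) / sizes[m]) if sizes[m] else 0.0
        for m in assignment.genes
    }
    names = sorted(assignment.genes)
    weights: dict[tuple[str, str], int] = {}
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            w = 0
            g1, g2 = assignment.genes[m1], assignment.genes[m2]
            for a, b in assignment.network_edges:
                if (a in g1 and b in g2) or (a in g2 and b in g1):
                    w += 1
            if w:
                weights[(m1, m2)] = w
    return FFN(sizes=sizes, intra_links_per_gene=ilpg, edge_weights=weights)


def overlap_percentage(
    assignment_a: ModuleAssignment, assignment_b: ModuleAssignment, module: str
) -> float:
    """Common in-module links as a percentage of the smaller link set."""
    try:
        la, lb = assignment_a.links[module], assignment_b.links[module]
    except KeyError:
        raise KeyError(f"module {module!r} missing from an assignment") from None
    if not la or not lb:
        raise ValueError(f"module {module!r} has no links in one of the networks")
    return 100.0 * len(la & lb) / min(len(la), len(lb))


def hypergeom_enrich(
    selection: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment P(X >= overlap) per set,
    BH-adjusted across sets. Set members are intersected with the
    universe first; the selection must be a subset of the universe."""
    universe = {u.upper() for u in universe}
    if not universe:
        raise ValueError("empty universe")
    selection = {s.upper() for s in selection}
    stray = selection - universe
    if stray:
        raise ValueError(f"selection not within universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selection)
    raw: list[tuple[str, int, int, float]] = []
    for name in sets.names():
        members = sets[name] & universe
        k = len(members & selection)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        raw.append((name, k, K, min(p, 1.0)))
    adj = bh_adjust([p for _, _, _, p in raw])
    return [
        EnrichmentRecord(
            set_name=name,
            overlap=k,
            set_size=K,
            selection_size=n,
            universe_size=N,
            p=p,
            p_adj=float(pa),
        )
        for (name, k, K, p), pa in zip(raw, adj)
    ]
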