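"""Co-occurrence networks and modularity-based community detection.

Edge lists become unweighted, unipartite graphs; modules are found by the
spin-glass simulated-annealing search of Reichardt & Bornholdt (igraph's
``community_spinglass``) maximizing Newman-Girvan modularity

    Q = sum_c [ L_c / m - (D_c / 2m)^2 ],

where m is the edge count, L_c the number of within-group edges of group c
and D_c its summed degree.  The annealing search needs a connected graph, so
disconnected inputs are partitioned per connected component with offset
labels.  Species present in the matrix but sharing no site with anyone are
isolated: they are excluded from module detection and recorded explicitly so
downstream comparisons can log them.
"""
from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .errors import CoverageError, DegenerateNetworkError
from .occurrence import EdgeList
from .partition import Partition

log = logging.getLogger(__name__)

#: annealing defaults: 100 spins, start temperature 1.0, stop temperature
#: 0.01, cooling factor 0.99 (gamma = 1, unweighted graphs)
DEFAULT_SA_PARAMS = {
    "spins": 100,
    "start_temp": 1.0,
    "stop_temp": 0.01,
    "cooling": 0.99,
}


@dataclass(frozen=True)
class Network:
    """Simple unweighted graph over species plus an explicit isolate list."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    isolated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_igraph(self) -> ig.Graph:
        index = {v: i for i, v in enumerate(self.nodes)}
        g = ig.Graph(
            n=len(self.nodes), edges=[(index[a], index[b]) for a, b in self.edges]
        )
        g.vs["name"] = list(self.nodes)
        return g


@dataclass(frozen=True)
class ModularityResult:
    partition: Partition
    q: float
    params: dict = field(default_factory=dict)
    seed: int = 0
    n_components: int = 1


def build_network(e: EdgeList, all_species: list[str] | None = None) -> Network:
    """Graph with one node per species in any pair, one edge per pair.

    ``all_species`` (e.g. the occurrence matrix's species list) lets species
    absent from every pair be recorded as isolated.
    """
    if not e.pairs:
        raise DegenerateNetworkError("empty edge list")
    nodes: list[str] = []
    seen: set[str] = set()
    for a, b in e.pairs:
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                nodes.append(v)
    isolated = tuple(s for s in (all_species or []) if s not in seen)
    if isolated:
        log.info("%d isolated species excluded from the network: %s",
                 len(isolated), list(isolated))
    return Network(nodes=tuple(nodes), edges=tuple(e.pairs), isolated=isolated)


def modularity_score(g: Network, p: Partition) -> float:
    """Newman-Girvan modularity of a partition on g."""
    missing = [v for v in g.nodes if v not in p.assignment]
    if missing:
        raise CoverageError(f"partition misses nodes: {missing}")
    m = g.n_edges
    if m == 0:
        raise DegenerateNetworkError("modularity undefined on an edgeless graph")
    k = p.k
    within = np.zeros(k)
    degree = np.zeros(k)
    for a, b in g.edges:
        ga, gb = p.assignment[a] - 1, p.assignment[b] - 1
        degree[ga] += 1
        degree[gb] += 1
        if ga == gb:
            within[ga] += 1
    return float(np.sum(within / m - (degree / (2 * m)) ** 2))


def detect_modules_sa(
    g: Network,
    params: dict | None = None,
    seed: int = 0,
    restarts: int = 1,
) -> ModularityResult:
    """Spin-glass simulated-annealing module detection.

    Runs igraph's spin-glass search per connected component (the search
    requires connectivity), offsets the labels, and reports the global
    modularity of the combined partition.  ``restarts`` > 1 reruns the
    annealing with derived seeds and keeps the highest-Q result.
    Deterministic given ``seed``.
    """
    if g.n_nodes == 0:
        raise DegenerateNetworkError("empty network")
    p = dict(DEFAULT_SA_PARAMS, **(params or {}))
    graph = g.to_igraph()
    components = graph.connected_components()
    if len(components) > 1:
        log.info("network has %d connected components; detecting per component",
                 len(components))

    best: tuple[float, Partition] | None = None
    for r in range(max(1, restarts)):
        run_seed = seed + r
        labels: dict[str, int] = {}
        offset = 0
        for comp in components:
            sub = graph.induced_subgraph(comp)
            names = sub.vs["name"]
            if sub.vcount() == 1:
                membership = [0]
            else:
                ig.set_random_number_generator(random.Random(run_seed + 7919 * offset))
                membership = sub.community_spinglass(
                    spins=p["spins"],
                    start_temp=p["start_temp"],
                    stop_temp=p["stop_temp"],
                    cool_fact=p["cooling"],
                    gamma=1.0,
                ).membership
            for name, lab in zip(names, membership):
                labels[name] = lab + 1 + offset
            offset += max(membership) + 1
        part = Partition.from_labels(
            list(g.nodes), [labels[v] for v in g.nodes], source="module"
        )
        q = modularity_score(g, part)
        if best is None or q > best[0]:
            best = (q, part)
    q, part = best
    return ModularityResult(
        partition=part, q=q, params=p, seed=seed, n_components=len(components)
    )
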