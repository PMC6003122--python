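"""Network metrics: density, isolated modules, hub ranking, comparisons.

"Module" is operationalized as a connected component with at least two
nodes; in the source analyses modules were shaded by hand on the figure, and
non-overlapping isolated sub-networks coincide with components.  Density
counts realized edges over all K(K-1)/2 variable pairs *including isolated
nodes*, so densities are comparable across strata analyzed with the same
variable roster.  Hubs are ranked purely by degree (ties broken by name) —
no other centrality is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import MultiLevelNetwork

__all__ = [
    "ModuleSet",
    "NetworkComparison",
    "density",
    "modules",
    "hub_ranking",
    "compare_networks",
    "metrics_report",
]


@dataclass(frozen=True)
class ModuleSet:
    """Disjoint connected components of size >= 2, named by dominant level.

    A module is named after the level held by a strict majority of its
    nodes; if no level exceeds half, it is "mixed".  Modules are ordered by
    descending size, then name.
    """

    modules: tuple[frozenset, ...]
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(zip(self.names, self.modules))

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.modules)


def _module_name(nodes: frozenset, level_of) -> str:
    counts = Counter(level_of(n) for n in nodes)
    top = max(counts.values())
    if 2 * top > len(nodes):
        return min(lvl for lvl, c in counts.items() if c == top)
    return "mixed"


def density(net: MultiLevelNetwork) -> float:
    """Realized edges over all K(K-1)/2 pairs, isolated nodes included."""
    k = net.n_nodes
    if k < 2:
        raise ValueError("density needs at least 2 nodes")
    return net.n_edges / (k * (k - 1) / 2)


def modules(net: MultiLevelNetwork) -> ModuleSet:
    """Connected components of size >= 2, auto-named and ordered."""
    comps = [
        frozenset(c)
        for c in nx.connected_components(net.graph)
        if len(c) >= 2
    ]
    named = [(c, _module_name(c, net.level)) for c in comps]
    named.sort(key=lambda item: (-len(item[0]), item[1], sorted(item[0])))
    return ModuleSet(
        modules=tuple(c for c, _ in named),
        names=tuple(name for _, name in named),
    )


def hub_ranking(net: MultiLevelNetwork, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree (descending), ties broken by name (ascending)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.graph.nodes, key=lambda n: (-net.graph.degree[n], n))
    return [(n, int(net.graph.degree[n])) for n in ranked[:k]]


@dataclass(frozen=True)
class NetworkComparison:
    """Density, edge-overlap and hub agreement between two networks."""

    density_a: float
    density_b: float
    density_diff: float
    edge_jaccard: float
    hub_overlap: int
    shared_variables: int


def compare_networks(a: MultiLevelNetwork, b: MultiLevelNetwork,
                     k: int = 5) -> NetworkComparison:
    """Compare two networks that share at least one variable.

    Densities use each network's own full node set; the edge Jaccard index
    is computed on the subgraphs induced by the shared variables (1.0 when
    both induced edge sets are empty); hub overlap counts common members of
    the two top-k degree rankings.
    """
    shared = set(a.graph.nodes) & set(b.graph.nodes)
    if not shared:
        raise ValueError("networks share no variables")
    ea = {frozenset(e) for e in a.graph.subgraph(shared).edges}
    eb = {frozenset(e) for e in b.graph.subgraph(shared).edges}
    union = ea | eb
    jaccard = 1.0 if not union else len(ea & eb) / len(union)
    hubs_a = {n for n, _ in hub_ranking(a, k)}
    hubs_b = {n for n, _ in hub_ranking(b, k)}
    da, db = density(a), density(b)
    return NetworkComparison(
        density_a=da,
        density_b=db,
        density_diff=da - db,
        edge_jaccard=jaccard,
        hub_overlap=len(hubs_a & hubs_b),
        shared_variables=len(shared),
    )


def metrics_report(net: MultiLevelNetwork, k: int = 5) -> dict:
    """Flat summary of one network, suitable for a CSV row."""
    mods = modules(net)
    comp_sizes = mods.sizes()
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "density": density(net),
        "n_modules": len(mods),
        "largest_module_size": max(comp_sizes) if comp_sizes else 0,
        "largest_module_fraction": (
            max(comp_sizes) / net.n_nodes if comp_sizes else 0.0
        ),
        "n_isolated": sum(1 for n in net.graph.nodes
                          if net.graph.degree[n] == 0),
        "module_names": ";".join(mods.names),
        "top_hubs": ";".join(f"{n}:{d}" for n, d in hub_ranking(net, k)),
        "p_threshold": net.p_threshold,
    }


def comparison_frame(items: list[tuple[str, str, NetworkComparison]]) -> pd.DataFrame:
    rows = [
        {
            "network_a": a, "network_b": b,
            "density_a": c.density_a, "density_b": c.density_b,
            "density_diff": c.density_diff, "edge_jaccard": c.edge_jaccard,
            "hub_overlap": c.hub_overlap, "shared_variables": c.shared_variables,
        }
        for a, b, c in items
    ]
    return pd.DataFrame(rows)
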