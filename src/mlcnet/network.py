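"""Signed, rho-weighted multi-level correlation networks.

Nodes are variables carrying their measurement level; an edge joins two
variables whose Spearman correlation is valid and has two-tailed p strictly
below the inclusion threshold (default 0.01).  Edges keep the signed rho, an
absolute-value weight, the p-value and the pairwise n.  Isolated nodes are
retained — density denominators and the record of which variables entered
the analysis depend on them — and exports mark them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTable, VariableMeta
from .correlation import SpearmanCorrelation

__all__ = [
    "MultiLevelNetwork",
    "build_network",
    "export_network",
    "read_graphml",
    "CorrelationNetwork",
]

EXPORT_FORMATS = ("graphml", "sif", "edge_table")


@dataclass
class MultiLevelNetwork:
    """A signed correlation network over level-labelled variables."""

    graph: nx.Graph
    p_threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def level(self, node: str) -> str:
        return self.graph.nodes[node]["level"]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b in sorted(self.graph.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted((a, b))
            d = self.graph.edges[a, b]
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "rho": d["rho"],
                    "abs_rho": d["weight"],
                    "p": d["p"],
                    "n": d["n"],
                    "sign": d["sign"],
                }
            )
        return pd.DataFrame(
            rows, columns=["source", "target", "rho", "abs_rho", "p", "n", "sign"]
        )


def _level_map(meta) -> Mapping[str, str]:
    if isinstance(meta, CohortTable):
        return meta.levels
    if isinstance(meta, Mapping):
        return meta
    if isinstance(meta, pd.DataFrame):
        return dict(zip(meta["name"], meta["level"]))
    try:
        return {m.name: m.level for m in meta}
    except (TypeError, AttributeError):
        raise TypeError(
            "meta must be a CohortTable, mapping, metadata frame or "
            "sequence of VariableMeta"
        ) from None


def build_network(
    corr: SpearmanCorrelation,
    meta,
    p_threshold: float = 0.01,
) -> MultiLevelNetwork:
    """Threshold a fitted correlation matrix into a multi-level network.

    An edge is added for every *valid* pair with ``p < p_threshold``
    (strict, matching the "p < 0.01" convention); invalid pairs never form
    edges regardless of their stored p.  All variables become nodes, so
    unconnected variables stay in the graph as isolated nodes.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    levels = _level_map(meta)
    missing = [v for v in corr.variables_ if v not in levels]
    if missing:
        raise ValueError(f"metadata missing for variables: {missing}")

    g = nx.Graph(p_threshold=float(p_threshold))
    for v in corr.variables_:
        g.add_node(v, level=levels[v])
    k = len(corr.variables_)
    for i in range(k):
        for j in range(i + 1, k):
            if not corr.valid_[i, j]:
                continue
            p = corr.p_value_[i, j]
            if np.isfinite(p) and p < p_threshold:
                rho = float(corr.rho_[i, j])
                g.add_edge(
                    corr.variables_[i],
                    corr.variables_[j],
                    rho=rho,
                    weight=abs(rho),
                    p=float(p),
                    n=int(corr.n_pairs_[i, j]),
                    sign="pos" if rho >= 0 else "neg",
                )
    return MultiLevelNetwork(graph=g, p_threshold=float(p_threshold))


# -------------------------------------------------------------------- export

def export_network(net: MultiLevelNetwork, path, format: str = "graphml") -> Path:
    """Write a network in a Cytoscape-importable format.

    ``graphml`` preserves all node/edge attributes and round-trips through
    :func:`read_graphml`; ``sif`` encodes edge sign as the interaction label
    (``pos``/``neg``) and lists isolated nodes on their own lines;
    ``edge_table`` is a CSV of source, target, rho, abs_rho, p, n, sign.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    elif format == "sif":
        lines = []
        for a, b in sorted(net.graph.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted((a, b))
            lines.append(f"{a}\t{net.graph.edges[a, b]['sign']}\t{b}")
        for node in sorted(net.graph.nodes):
            if net.graph.degree[node] == 0:
                lines.append(node)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge_table":
        net.edge_table().to_csv(path, index=False)
    else:
        raise ValueError(
            f"unknown export format {format!r}; choose from {EXPORT_FORMATS}"
        )
    return path


def read_graphml(path) -> MultiLevelNetwork:
    """Read a network previously written by :func:`export_network` (graphml)."""
    g = nx.read_graphml(Path(path))
    g = nx.Graph(g)
    thr = float(g.graph.get("p_threshold", np.nan))
    for _, _, d in g.edges(data=True):
        for key in ("rho", "weight", "p"):
            d[key] = float(d[key])
        d["n"] = int(d["n"])
    return MultiLevelNetwork(graph=g, p_threshold=thr)


# --------------------------------------------------------------- estimator

class CorrelationNetwork(BaseEstimator):
    """Cohort-to-network estimator: Spearman matrix plus thresholding.

    Parameters mirror :class:`~mlcnet.correlation.SpearmanCorrelation` plus
    the edge-inclusion ``p_threshold``.  ``fit`` accepts a
    :class:`~mlcnet.cohort.CohortTable` (levels taken from its metadata) or a
    DataFrame with an explicit ``levels`` mapping.

    Attributes (after fit): ``correlation_`` (fitted SpearmanCorrelation),
    ``network_`` (:class:`MultiLevelNetwork`), ``density_``, ``module_set_``.
    """

    def __init__(self, p_threshold: float = 0.01, min_n: int = 5,
                 exact_max_n: int = 9, n_permutations: int = 20000,
                 permutation_seed: int = 0):
        self.p_threshold = p_threshold
        self.min_n = min_n
        self.exact_max_n = exact_max_n
        self.n_permutations = n_permutations
        self.permutation_seed = permutation_seed

    def fit(self, X, y=None, levels: Mapping[str, str] | None = None):
        from .metrics import density, modules  # avoid import cycle

        if levels is None:
            if not isinstance(X, CohortTable):
                raise ValueError(
                    "levels mapping required when X is not a CohortTable"
                )
            levels = X.levels
        self.correlation_ = SpearmanCorrelation(
            min_n=self.min_n, exact_max_n=self.exact_max_n,
            n_permutations=self.n_permutations,
            permutation_seed=self.permutation_seed,
        ).fit(X)
        self.network_ = build_network(self.correlation_, levels,
                                      self.p_threshold)
        self.density_ = density(self.network_)
        self.module_set_ = modules(self.network_)
        return self
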