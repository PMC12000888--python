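"""Correlation-based co-occurrence networks and their topology metrics.

Nodes are taxa, DOM components and environmental variables; edges are
Spearman correlations passing both an effect-size threshold (|rho| >= rho_min)
and a Benjamini–Hochberg FDR threshold (q <= q_max) across all tested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import bh_qvalues, spearman_rho_p
from .community import FeatureTable
from .errors import FdomlinkError, UndefinedMetricError

__all__ = [
    "CoocNetwork",
    "NetworkMetrics",
    "prevalence_filter",
    "build_network",
    "network_metrics",
    "average_path_length",
]

log = logging.getLogger(__name__)


@dataclass
class CoocNetwork:
    nodes: pd.DataFrame   # columns: id, kind
    edges: pd.DataFrame   # columns: i, j, rho, p, q, sign (i < j positions)
    rho_min: float
    q_max: float
    skipped: list[str] = field(default_factory=list)  # constant variables

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["id"], kind=row["kind"])
        ids = list(self.nodes["id"])
        for _, row in self.edges.iterrows():
            g.add_edge(ids[int(row["i"])], ids[int(row["j"])],
                       rho=float(row["rho"]), p=float(row["p"]),
                       q=float(row["q"]), sign=row["sign"],
                       weight=abs(float(row["rho"])))
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def edge_csv(self, path) -> None:
        ids = list(self.nodes["id"])
        out = self.edges.copy()
        out.insert(0, "source", [ids[int(i)] for i in out["i"]])
        out.insert(1, "target", [ids[int(j)] for j in out["j"]])
        out.drop(columns=["i", "j"]).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    average_path_length: float | None
    n_components: int
    modularity: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "average_degree": self.average_degree,
            "average_path_length": self.average_path_length,
            "n_components": self.n_components,
            "modularity": self.modularity,
        }


def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.5,
                      min_mean_rel_abund: float = 0.0) -> FeatureTable:
    """Keep ASVs present in enough samples and abundant enough on average."""
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_rel_abund <= 1):
        raise FdomlinkError("thresholds must lie in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    mean_rel = table.relative_abundance().mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_rel_abund)
    if not keep.any():
        raise FdomlinkError("prevalence filter removed every ASV")
    kept_ids = [a for a, k in zip(table.asv_ids, keep) if k]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = table.taxonomy.loc[table.taxonomy.index.isin(kept_ids)]
    return FeatureTable(table.counts[keep], kept_ids, list(table.sample_ids),
                        taxonomy)


def build_network(features: pd.DataFrame, kinds: dict[str, str] | None = None,
                  rho_min: float = 0.6, q_max: float = 0.05) -> CoocNetwork:
    """Build a co-occurrence network from a (variables × samples) table.

    All pairwise Spearman correlations are tested; constant variables are
    skipped (logged, not errored); BH q-values are computed across all tested
    pairs. Isolated nodes are retained with degree 0.
    """
    if features.shape[1] < 4:
        raise FdomlinkError("need at least 4 samples")
    if features.shape[0] < 2:
        raise FdomlinkError("need at least 2 variables")
    names = list(features.index.astype(str))
    x = features.to_numpy(dtype=float)
    kinds = kinds or {}
    constant = [names[i] for i in range(len(names)) if np.ptp(x[i]) == 0]
    for name in constant:
        log.warning("variable %r is constant; its pairs are skipped", name)
    ok = np.array([np.ptp(row) > 0 for row in x])

    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not (ok[i] and ok[j]):
                continue
            rho, p = spearman_rho_p(x[i], x[j])
            pairs.append((i, j, rho, p))
    if pairs:
        qvals = bh_qvalues([p for *_, p in pairs])
    else:
        qvals = np.array([])
    rows = []
    for (i, j, rho, p), q in zip(pairs, qvals):
        if abs(rho) >= rho_min and q <= q_max:
            rows.append({"i": i, "j": j, "rho": rho, "p": p, "q": q,
                         "sign": "positive" if rho > 0 else "negative"})
    edges = pd.DataFrame(rows, columns=["i", "j", "rho", "p", "q", "sign"])
    nodes = pd.DataFrame({"id": names,
                          "kind": [kinds.get(n, "taxon") for n in names]})
    return CoocNetwork(nodes=nodes, edges=edges, rho_min=rho_min, q_max=q_max,
                       skipped=constant)


def average_path_length(net: CoocNetwork) -> float:
    """Mean unweighted shortest-path length within the largest connected component."""
    g = net.to_networkx()
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("average path length undefined on an edgeless network")
    largest = max(nx.connected_components(g), key=len)
    return float(nx.average_shortest_path_length(g.subgraph(largest)))


def network_metrics(net: CoocNetwork, with_modularity: bool = False) -> NetworkMetrics:
    """Topology summary. Path length is None (undefined) for edgeless networks."""
    g = net.to_networkx()
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    n_pos = int((net.edges["sign"] == "positive").sum())
    n_neg = int((net.edges["sign"] == "negative").sum())
    try:
        apl = average_path_length(net)
    except UndefinedMetricError:
        apl = None
    modularity = None
    if with_modularity and n_edges > 0:
        communities = nx.algorithms.community.greedy_modularity_communities(
            g, weight="weight")
        modularity = float(nx.algorithms.community.modularity(
            g, communities, weight="weight"))
    return NetworkMetrics(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_pos,
        n_negative=n_neg,
        average_degree=2.0 * n_edges / n_nodes if n_nodes else 0.0,
        average_path_length=apl,
        n_components=nx.number_connected_components(g) if n_nodes else 0,
        modularity=modularity,
    )
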