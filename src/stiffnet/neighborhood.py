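"""First-order-neighbor (FON) graphs and biomarker subgroup mining.

Given the taxa classified as significantly increased or decreased
biomarkers, the FON graph is the subgraph induced on the biomarkers and
their direct neighbors in a cohort network.  Nodes are partitioned into
cluster I (increased biomarkers and their neighbors), cluster II
(decreased biomarkers and theirs) and shared neighbors adjacent to both
biomarker classes.  P/N edge-sign ratios between the clusters summarize
cooperative versus competitive structure; "allies" subgroups are
positively connected components among the biomarkers themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork, format_pn, pn_ratio_from_signs

logger = logging.getLogger(__name__)

BIOMARKER_INC = "BIOMARKER_INC"
BIOMARKER_DEC = "BIOMARKER_DEC"
NN_INC = "NN_INC"
NN_DEC = "NN_DEC"
SHARED_NN = "SHARED_NN"


@dataclass
class FonGraph:
    """Biomarker-centered first-order-neighbor subgraph.

    ``graph`` is an undirected networkx graph with node attribute
    ``role`` and edge attributes ``weight`` (magnitude) and ``sign``.
    """

    graph: nx.Graph
    cohort_tag: str = "A"

    @property
    def roles(self) -> dict[str, str]:
        return nx.get_node_attributes(self.graph, "role")

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]


@dataclass
class Subgroup:
    """A positively connected component of biomarker taxa ("allies")."""

    taxa: list[str]
    edges: list[tuple[str, str, float]]   # (i, j, signed weight)
    all_pairs_connected: bool = False

    @property
    def size(self) -> int:
        return len(self.taxa)

    @property
    def mean_abs_weight(self) -> float:
        if not self.edges:
            return 0.0
        return float(np.mean([abs(w) for _, _, w in self.edges]))


def _signed_graph(net: CooccurrenceNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.taxa)
    for i, j in net.edges():
        g.add_edge(net.taxa[i], net.taxa[j],
                   weight=float(net.W[i, j]),
                   sign=int(net.sign[i, j]))
    return g


def extract_fon(net: CooccurrenceNetwork, increased: set[str],
                decreased: set[str], cohort_tag: str = "A") -> FonGraph:
    """Induced subgraph on biomarkers and their first-order neighbors.

    Shared neighbors (adjacent to at least one biomarker of EACH class)
    take precedence over single-class neighbor roles; biomarker nodes
    keep their biomarker role regardless of adjacency.
    """
    increased, decreased = set(increased), set(decreased)
    if increased & decreased:
        raise ValueError("biomarker sets must be disjoint")
    unknown = (increased | decreased) - set(net.taxa)
    if unknown:
        raise ValueError(f"biomarkers not in network: {sorted(unknown)}")
    full = _signed_graph(net)
    if not increased and not decreased:
        logger.warning("empty biomarker sets: FON graph is empty")
        return FonGraph(graph=nx.Graph(), cohort_tag=cohort_tag)
    biomarkers = increased | decreased
    neighbors = set()
    for b in biomarkers:
        neighbors.update(full.neighbors(b))
    nodes = biomarkers | neighbors
    sub = full.subgraph(nodes).copy()
    for node in sub.nodes:
        if node in increased:
            role = BIOMARKER_INC
        elif node in decreased:
            role = BIOMARKER_DEC
        else:
            near_inc = any(nb in increased for nb in sub.neighbors(node))
            near_dec = any(nb in decreased for nb in sub.neighbors(node))
            if near_inc and near_dec:
                role = SHARED_NN
            elif near_inc:
                role = NN_INC
            else:
                role = NN_DEC
        sub.nodes[node]["role"] = role
    return FonGraph(graph=sub, cohort_tag=cohort_tag)


def fon_pn_table(fon: FonGraph) -> pd.DataFrame:
    """P/N ratios between biomarker clusters and their neighbor sets.

    Four between-cluster edge sets are counted (biomarker-internal edges
    are excluded): cluster I ↔ its own neighbors, cluster I ↔ shared
    neighbors, cluster II ↔ its own neighbors, cluster II ↔ shared
    neighbors.  A cell with positive edges only serializes as "–".
    """
    roles = fon.roles
    cells = [
        ("cluster_I_vs_NN", BIOMARKER_INC, NN_INC),
        ("cluster_I_vs_shared_NN", BIOMARKER_INC, SHARED_NN),
        ("cluster_II_vs_NN", BIOMARKER_DEC, NN_DEC),
        ("cluster_II_vs_shared_NN", BIOMARKER_DEC, SHARED_NN),
    ]
    rows = []
    for name, role_a, role_b in cells:
        signs = [d["sign"] for u, v, d in fon.graph.edges(data=True)
                 if {roles.get(u), roles.get(v)} == {role_a, role_b}]
        ratio = pn_ratio_from_signs(signs)
        pos = sum(1 for s in signs if s > 0)
        neg = sum(1 for s in signs if s < 0)
        rows.append({"cell": name, "cohort": fon.cohort_tag,
                     "n_positive": pos, "n_negative": neg,
                     "pn_ratio": ratio, "pn_display": format_pn(ratio)})
    return pd.DataFrame(rows)


def mine_subgroups(net: CooccurrenceNetwork, biomarkers: set[str],
                   min_size: int = 3) -> list[Subgroup]:
    """Positively connected biomarker components ("allies" subgroups).

    The subgraph induced on the biomarkers is restricted to positive
    edges; its connected components of size >= min_size are returned,
    largest (then strongest mean |weight|) first, each with its internal
    edge list and a flag marking fully connected (all-pairs) subgroups.
    """
    biomarkers = set(biomarkers)
    unknown = biomarkers - set(net.taxa)
    if unknown:
        raise ValueError(f"biomarkers not in network: {sorted(unknown)}")
    full = _signed_graph(net)
    sub = full.subgraph(biomarkers)
    positive = nx.Graph()
    positive.add_nodes_from(sub.nodes)
    for u, v, d in sub.edges(data=True):
        if d["sign"] > 0:
            positive.add_edge(u, v, **d)
    groups = []
    order = {t: k for k, t in enumerate(net.taxa)}
    for comp in nx.connected_components(positive):
        if len(comp) < min_size:
            continue
        members = sorted(comp, key=order.get)
        comp_graph = positive.subgraph(comp)
        edges = [(u, v, d["sign"] * d["weight"])
                 for u, v, d in comp_graph.edges(data=True)]
        n = len(members)
        complete = comp_graph.number_of_edges() == n * (n - 1) // 2
        groups.append(Subgroup(taxa=members, edges=edges,
                               all_pairs_connected=complete))
    groups.sort(key=lambda g: (-g.size, -g.mean_abs_weight))
    return groups


def write_fon_graphml(fon: FonGraph, path) -> None:
    """GraphML export with role and sign attributes for graph viewers."""
    nx.write_graphml(fon.graph, path)
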