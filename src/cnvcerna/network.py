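"""Dysregulated ceRNA network assembly, Newman modularity and multilevel
(Louvain) community detection.

Edges are unweighted for community detection; dR, direction, permutation p and
the driving gene are retained as edge attributes. A pair reported for two
different drivers collapses to a single undirected edge carrying both driver
records.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx

from .dysregulation import DysregulatedPair


def build_network(
    pairs: list[DysregulatedPair],
    feature_class: dict[str, str] | None = None,
) -> nx.Graph:
    """Undirected graph of dysregulated ceRNA pairs. Node attributes:
    feature_class, is_cnv_driver, driver_states; edge attribute ``records``
    holds one dict per (driver, dR, direction, perm_p) supporting the edge."""
    if not pairs:
        raise ValueError("cannot build a network from an empty pair set")
    feature_class = feature_class or {}
    g = nx.Graph()
    for p in pairs:
        for node in (p.cerna1_id, p.cerna2_id):
            if node not in g:
                g.add_node(node, feature_class=feature_class.get(node, "mRNA"),
                           is_cnv_driver=False, driver_states=[])
        if p.cerna1_id == p.cerna2_id:
            continue  # no self-loops
        rec = dict(driver_gene_id=p.driver_gene_id, driver_state=p.driver_state,
                   delta_r=p.delta_r, direction=p.direction, perm_p=p.perm_p)
        if g.has_edge(p.cerna1_id, p.cerna2_id):
            g.edges[p.cerna1_id, p.cerna2_id]["records"].append(rec)
        else:
            g.add_edge(p.cerna1_id, p.cerna2_id, records=[rec])
    for p in pairs:
        if p.driver_gene_id in g:
            attrs = g.nodes[p.driver_gene_id]
            attrs["is_cnv_driver"] = True
            if p.driver_state not in attrs["driver_states"]:
                attrs["driver_states"].append(p.driver_state)
    return g


def modularity(g: nx.Graph, assignment: dict[str, int]) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) on the unweighted graph."""
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"unassigned node(s): {missing[:5]}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    e = {}  # within-community edge fraction
    a = {}  # community end fraction
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            e[assignment[u]] = e.get(assignment[u], 0) + 1
    for node in g.nodes:
        a[assignment[node]] = a.get(assignment[node], 0) + g.degree(node)
    return float(sum(e.get(c, 0) / m - (a[c] / (2 * m)) ** 2 for c in a))


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity_q: float


def detect_communities(g: nx.Graph, seed: int = 0, restarts: int = 10) -> CommunityPartition:
    """Multilevel (Louvain-style) modularity optimisation; the best of
    ``restarts`` seeded runs is reported. Falls back to the single-community
    partition (Q = 0) if no run beats it."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        return CommunityPartition({n: i for i, n in enumerate(nodes)}, 0.0)
    index = {n: i for i, n in enumerate(nodes)}
    h = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])
    best: CommunityPartition | None = None
    for r in range(restarts):
        ig.set_random_number_generator(random.Random((seed & 0x7FFFFFFF) + r))
        membership = h.community_multilevel().membership
        assignment = {n: int(membership[index[n]]) for n in nodes}
        q = modularity(g, assignment)
        if best is None or q > best.modularity_q:
            best = CommunityPartition(assignment, q)
    baseline = CommunityPartition({n: 0 for n in nodes}, 0.0)
    return best if best.modularity_q >= baseline.modularity_q else baseline


def largest_community(partition: CommunityPartition) -> set[str]:
    """Most-node community; ties broken by community id for determinism."""
    sizes: dict[int, list[str]] = {}
    for node, c in partition.assignment.items():
        sizes.setdefault(c, []).append(node)
    best = max(sorted(sizes), key=lambda c: len(sizes[c]))
    return set(sizes[best])


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    for n, attrs in g.nodes(data=True):
        a = dict(attrs)
        a["driver_states"] = json.dumps(a.get("driver_states", []))
        out.add_node(n, **a)
    for u, v, attrs in g.edges(data=True):
        a = dict(attrs)
        a["records"] = json.dumps(a.get("records", []))
        out.add_edge(u, v, **a)
    nx.write_graphml(out, path)


def import_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, attrs in g.nodes(data=True):
        a = dict(attrs)
        a["driver_states"] = json.loads(a.get("driver_states", "[]"))
        out.add_node(n, **a)
    for u, v, attrs in g.edges(data=True):
        a = dict(attrs)
        a["records"] = json.loads(a.get("records", "[]"))
        out.add_edge(u, v, **a)
    return out


def export_sif(g: nx.Graph, path: str | Path) -> None:
    """SIF-style edge list: one row per supporting driver record."""
    with open(path, "w") as fh:
        fh.write("cerna1\tcerna2\tdriver_gene\tdriver_state\tdelta_r\tdirection\tperm_p\n")
        for u, v, attrs in sorted(g.edges(data=True)):
            for rec in attrs.get("records", []):
                fh.write(
                    f"{u}\t{v}\t{rec['driver_gene_id']}\t{rec['driver_state']}\t"
                    f"{rec['delta_r']:.6g}\t{rec['direction']}\t{rec['perm_p']:.6g}\n"
                )
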