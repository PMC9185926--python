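"""Chromatin + RNA interaction graph, communities, and spring-energy layout.

Nodes are loop anchors mapped to promoters/CREs where possible; edges carry
contact-count weights and a kind label (chromatin or rna). The layout
minimizes the spring energy E = sum over connected pairs of
(1/2) k (d(i,j) - s(i,j))^2, with d the Euclidean distance and s the natural
spring length, by gradient descent with backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import IntervalIndex, assign_bin
from .loops import promoter_region


def _node_for_bin(chrom, start, end, cre_index, prom_index):
    iv_hits = prom_index.query_point(chrom, (start + end) // 2) if prom_index else []
    if iv_hits:
        gid = iv_hits[0][0]
        return f"gene:{gid}", "gene"
    hits = cre_index.query_point(chrom, (start + end) // 2) if cre_index else []
    if hits:
        c = sorted(hits, key=lambda c: (not c.is_promoter, c.id))[0]
        return f"cre:{c.id}", c.cre_class
    return f"anchor:{chrom}:{start}", "anchor"


def build_graph(loops=(), trans_contacts=(), cres=(), genes=(), min_weight: float = 1.0,
                bin_size: int = 5000) -> nx.Graph:
    """Combined chromatin-chromatin + RNA-chromatin interaction graph.

    Loop anchors map to gene promoters or CREs when one overlaps the anchor
    midpoint; parallel edges merge by weight sum with a multi-label kind.
    Self-edges and edges below ``min_weight`` are dropped.
    """
    cre_index = IntervalIndex(cres, key=lambda c: c.interval) if cres else None
    prom_index = None
    if genes:
        proms = [(g.gene_id, promoter_region(g, cre_index)) for g in genes]
        prom_index = IntervalIndex(proms, key=lambda t: t[1])

    g = nx.Graph()

    def _add(u, ut, v, vt, w, kind):
        if u == v or w <= 0:
            return
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
            g[u][v]["kind"].add(kind)
        else:
            g.add_node(u, type=ut)
            g.add_node(v, type=vt)
            g.add_edge(u, v, weight=float(w), kind={kind})
        g.nodes[u]["type"] = ut if g.nodes[u].get("type") == "anchor" else g.nodes[u]["type"]

    for lp in loops:
        u, ut = _node_for_bin(lp.chrom, lp.anchor1.start, lp.anchor1.end, cre_index, prom_index)
        v, vt = _node_for_bin(lp.chrom, lp.anchor2.start, lp.anchor2.end, cre_index, prom_index)
        _add(u, ut, v, vt, lp.contact_count, "chromatin")
    for p in trans_contacts:
        if p.source_gene is None:
            continue
        u, ut = f"gene:{p.source_gene}", "gene"
        dna_bin = assign_bin(p.dna_pos, bin_size, chrom=p.dna_chrom)
        v, vt = _node_for_bin(p.dna_chrom, dna_bin.start, dna_bin.end, cre_index, prom_index)
        _add(u, ut, v, vt, 1.0, "rna")

    drop = [(u, v) for u, v, w in g.edges(data="weight") if w < min_weight]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g


def detect_communities(graph: nx.Graph, method: str = "components",
                       seed: int = 0) -> dict[str, int]:
    """Node -> community id; ids ordered by decreasing community size
    (ties by smallest member node for determinism)."""
    if len(graph) == 0:
        raise ValueError("graph is empty")
    if method == "components":
        groups = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "louvain":
        groups = [sorted(c) for c in
                  nx.community.louvain_communities(graph, weight="weight", seed=seed)]
    else:
        raise ValueError(f"unknown community method {method!r}")
    groups.sort(key=lambda c: (-len(c), c[0]))
    return {node: cid for cid, group in enumerate(groups) for node in group}


def _spring_lengths(graph: nx.Graph, s) -> dict:
    if np.isscalar(s):
        return {e: float(s) for e in graph.edges}
    return {e: float(s[e]) for e in graph.edges}


def layout_energy(coords: dict, graph: nx.Graph, k: float = 1.0, s=1.0) -> float:
    """E = sum over connected pairs of (1/2) k (d - s)^2, each unordered pair
    counted once."""
    slen = _spring_lengths(graph, s)
    e = 0.0
    for (u, v), sval in slen.items():
        if u not in coords or v not in coords:
            raise ValueError(f"missing coordinate for node {u if u not in coords else v}")
        d = float(np.hypot(coords[u][0] - coords[v][0], coords[u][1] - coords[v][1]))
        e += 0.5 * k * (d - sval) ** 2
    return e


@dataclass
class LayoutState:
    coords: dict
    k: float
    energy: float
    energy_trace: list[float]


def fr_layout(graph: nx.Graph, k: float = 1.0, s=1.0, n_iter: int = 500,
              step: float = 0.1, seed: int = 0, tol: float = 1e-14) -> LayoutState:
    """Spring layout by gradient descent on the layout energy.

    The step is backtracked whenever a move would raise the energy, so the
    energy trace is monotone non-increasing (within numerical tolerance).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if len(graph) == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1, 1, size=(len(nodes), 2))
    slen = _spring_lengths(graph, s)
    edges = [(idx[u], idx[v], sval) for (u, v), sval in slen.items()]

    def energy(p):
        e = 0.0
        for i, j, sval in edges:
            d = np.hypot(*(p[i] - p[j]))
            e += 0.5 * k * (d - sval) ** 2
        return e

    def grad(p):
        g = np.zeros_like(p)
        for i, j, sval in edges:
            diff = p[i] - p[j]
            d = np.hypot(*diff)
            if d < 1e-12:
                diff = rng.uniform(-1e-6, 1e-6, 2)
                d = np.hypot(*diff)
            f = k * (d - sval) / d * diff
            g[i] += f
            g[j] -= f
        return g

    e = energy(pos)
    trace = [e]
    for _ in range(n_iter):
        gvec = grad(pos)
        gnorm = np.abs(gvec).max()
        if gnorm < 1e-12:
            trace.append(e)
            continue
        moved = False
        for _try in range(30):
            cand = pos - step * gvec
            e_new = energy(cand)
            if e_new <= e + tol:
                pos, e = cand, e_new
                step *= 1.1
                moved = True
                break
            step *= 0.5
        trace.append(e)
        if not moved:
            break
    coords = {n: (float(pos[i, 0]), float(pos[i, 1])) for n, i in idx.items()}
    return LayoutState(coords=coords, k=k, energy=float(e), energy_trace=trace)
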