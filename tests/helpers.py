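"""Shared builders and independent oracles for the test suite.

The oracles deliberately use different algorithms (and libraries) than the
package: union-find for connected components, networkx all-pairs BFS for
isolation, and an exhaustive pixel-pair scan for label-map adjacency.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from revfiber.core import FiberRecord, SectionGraph


def build_graph(n, edges, revertant, area=1.0, section_id="s"):
    """Section with fibers 1..n, the given edges and revertant id set."""
    revertant = set(revertant)
    fibers = tuple(
        FiberRecord(i, (float(i), 0.0), 100.0, i in revertant) for i in range(1, n + 1)
    )
    return SectionGraph(section_id, fibers, tuple(edges), area)


def path_graph(n, revertant, area=1.0):
    """Chain 1-2-...-n."""
    return build_graph(n, [(i, i + 1) for i in range(1, n)], revertant, area)


def random_section(rng, max_nodes=50, edge_prob=0.08, rev_prob=0.3):
    n = int(rng.integers(1, max_nodes + 1))
    edges = [
        (a, b)
        for a in range(1, n + 1)
        for b in range(a + 1, n + 1)
        if rng.random() < edge_prob
    ]
    revertant = {i for i in range(1, n + 1) if rng.random() < rev_prob}
    return build_graph(n, edges, revertant)


def uf_components(ids, edges):
    """Union-find connected components of `ids` under `edges` (both endpoints
    must be in `ids` for an edge to count)."""
    ids = set(ids)
    parent = {i: i for i in ids}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in edges:
        if a in ids and b in ids:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in comps.values()), key=sorted)


def bfs_isolated(graph: SectionGraph, min_separation: int):
    """All-pairs BFS oracle for isolation: a revertant fiber is isolated iff
    every other revertant fiber is at graph distance >= min_separation + 1."""
    g = nx.Graph()
    g.add_nodes_from(f.fiber_id for f in graph.fibers)
    g.add_edges_from(graph.edges)
    revertant = sorted(graph.revertant_ids())
    isolated = set()
    for src in revertant:
        lengths = nx.single_source_shortest_path_length(g, src)
        near = [
            other
            for other in revertant
            if other != src and lengths.get(other, np.inf) <= min_separation
        ]
        if not near:
            isolated.add(src)
    return frozenset(isolated)


def labelmap_edges_bruteforce(lab: np.ndarray, connectivity: int):
    """Exhaustive scan of every pixel pair at the relevant offsets."""
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    h, w = lab.shape
    edges = set()
    for y in range(h):
        for x in range(w):
            a = lab[y, x]
            if a == 0:
                continue
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    b = lab[yy, xx]
                    if b != 0 and b != a:
                        edges.add((min(a, b), max(a, b)))
    return edges


def random_labelmap(rng, max_side=32, n_labels=6):
    """Random tessellation-ish label map: nearest-seed partition with some
    background, guaranteeing contiguous-ish regions."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    k = int(rng.integers(1, n_labels + 1))
    seeds = rng.uniform(0, [h, w], size=(k, 2))
    ys, xs = np.mgrid[0:h, 0:w]
    d = (ys[..., None] - seeds[:, 0]) ** 2 + (xs[..., None] - seeds[:, 1]) ** 2
    lab = np.argmin(d, axis=-1).astype(np.int32) + 1
    background = rng.random((h, w)) < 0.15
    lab[background] = 0
    return lab
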