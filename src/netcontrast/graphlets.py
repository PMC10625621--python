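"""Seeded graphlet enumeration and a degree-preserving null model.

Graphlets here are the nine connected non-isomorphic undirected graphs
on 2-4 nodes (edge; 3-path; triangle; 4-path; 3-star; 4-cycle; tailed
triangle; diamond; 4-clique).  Enumeration is restricted to *seeded*
instances — connected induced subgraphs that contain at least one seed
gene — because the downstream network construction only cares about the
interactome region around the seeds.  The null model rewires edges
while preserving the exact degree sequence, carrying edge confidence
weights along with the rewired endpoints.

Internally nodes are mapped to integers and candidate subgraphs to
bitmasks, so growth, deduplication and shape classification are integer
arithmetic rather than graph operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .errors import SeedError

__all__ = [
    "GRAPHLET_TYPES",
    "classify_graphlet",
    "GraphletCensus",
    "enumerate_seeded_graphlets",
    "degree_preserving_rewire",
]

GRAPHLET_TYPES: tuple[str, ...] = (
    "edge",
    "path_3",
    "triangle",
    "path_4",
    "star_4",
    "cycle_4",
    "tailed_triangle",
    "diamond",
    "clique_4",
)


def _classify_indices(idxs: list[int], adj_mask: list[int]) -> Optional[str]:
    """Shape of the induced subgraph on 2-4 node indices (None if not
    connected).  On 4 nodes the (edge count, max degree) pair separates
    all six connected shapes."""
    k = len(idxs)
    degs = [0] * k
    m = 0
    for i in range(k):
        ai = adj_mask[idxs[i]]
        for j in range(i + 1, k):
            if ai >> idxs[j] & 1:
                m += 1
                degs[i] += 1
                degs[j] += 1
    if k == 2:
        return "edge" if m == 1 else None
    if k == 3:
        if 0 in degs:
            return None
        return "triangle" if m == 3 else "path_3"
    # k == 4
    if m < 3 or 0 in degs:
        return None
    if m == 3:
        # 3 edges, all degrees >= 1: either a path or a star (both
        # connected) — a triangle + isolate is excluded by the 0-degree
        # check above
        return "star_4" if max(degs) == 3 else "path_4"
    if m == 4:
        return "tailed_triangle" if max(degs) == 3 else "cycle_4"
    if m == 5:
        return "diamond"
    return "clique_4"


def classify_graphlet(g: nx.Graph, nodes: Iterable) -> Optional[str]:
    """Classify the induced subgraph on 2-4 nodes, or None if disconnected."""
    nodes = list(nodes)
    if not 2 <= len(nodes) <= 4:
        raise ValueError(f"graphlets are defined on 2-4 nodes, got {len(nodes)}")
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [0] * len(nodes)
    for i, u in enumerate(nodes):
        for v in g.neighbors(u):
            j = idx.get(v)
            if j is not None:
                adj[i] |= 1 << j
    return _classify_indices(list(range(len(nodes))), adj)


@dataclass
class GraphletCensus:
    """Result of a seeded enumeration.

    ``instances`` maps each graphlet type to the distinct node sets
    realising it; ``counts`` are the corresponding sizes (kept even in
    count-only mode, where instances are not stored).
    """

    counts: dict[str, int]
    instances: dict[str, list[frozenset]] = field(default_factory=dict)
    dropped_seeds: list = field(default_factory=list)
    subsampled: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _bit_indices(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


_T4 = ("star_4", "tailed_triangle", "diamond", "clique_4")


def _enumerate_from_root(v: int, adj_mask: list[int], forbidden: int):
    """Yield (nodes, type) for every connected 2-4-node induced set
    containing root ``v`` and no forbidden node, each exactly once.

    Sets are generated pattern-wise by how many members are direct
    neighbours of the root, which makes every set reachable through
    exactly one generation rule — no deduplication needed.
    """
    not_v = ~(1 << v)
    nv_mask = adj_mask[v] & ~forbidden
    nv = _bit_indices(nv_mask)
    excl = nv_mask | forbidden | (1 << v)
    for a in nv:
        yield (v, a), "edge"
    n_nv = len(nv)
    for i in range(n_nv):
        a = nv[i]
        am = adj_mask[a]
        # two root neighbours
        for j in range(i + 1, n_nv):
            b = nv[j]
            yield (v, a, b), ("triangle" if am >> b & 1 else "path_3")
        # one root neighbour plus its own neighbour
        for b in _bit_indices(am & ~excl):
            yield (v, a, b), "path_3"
    # 4-node sets, by |S ∩ N(v)| = 3, 2, 1
    for i in range(n_nv):
        a = nv[i]
        am = adj_mask[a]
        for j in range(i + 1, n_nv):
            b = nv[j]
            bm = adj_mask[b]
            e_ab = am >> b & 1
            for k in range(j + 1, n_nv):
                c = nv[k]
                x = e_ab + (am >> c & 1) + (bm >> c & 1)
                yield (v, a, b, c), _T4[x]
            for c in _bit_indices((am | bm) & ~excl):
                e_ac = am >> c & 1
                e_bc = bm >> c & 1
                m = 2 + e_ab + e_ac + e_bc
                if m == 3:
                    t = "path_4"
                elif m == 4:
                    t = "cycle_4" if (e_ac and e_bc) else "tailed_triangle"
                else:
                    t = "diamond"
                yield (v, a, b, c), t
    for a in nv:
        am = adj_mask[a]
        r = _bit_indices(am & ~excl)
        n_r = len(r)
        for i in range(n_r):
            b = r[i]
            bm = adj_mask[b]
            for j in range(i + 1, n_r):
                c = r[j]
                yield (v, a, b, c), (
                    "tailed_triangle" if bm >> c & 1 else "star_4"
                )
            # second-layer chain: c reachable only through b
            for c in _bit_indices(bm & ~am & ~excl & not_v & ~(1 << a)):
                yield (v, a, b, c), "path_4"


def _count_from_root(v: int, adj_mask: list[int], forbidden: int) -> dict[str, int]:
    """Exact per-type counts of the sets `_enumerate_from_root` yields,
    via popcount identities instead of per-instance work.

    For the three-root-neighbour class the shape is determined by the
    number x of edges among the triple, so the four counts follow from
    the edge count e, adjacent-edge-pair count P2 and triangle count T
    inside the root's neighbourhood: n(x=3) = T, n(x=2) = P2 - 3T,
    n(x=1) = e(d-2) - 2 n(x=2) - 3 n(x=3), n(x=0) the remainder.
    """
    counts = dict.fromkeys(GRAPHLET_TYPES, 0)
    nv_mask = adj_mask[v] & ~forbidden
    nv = _bit_indices(nv_mask)
    d = len(nv)
    excl = nv_mask | forbidden | (1 << v)
    counts["edge"] = d
    e_in = 0  # edges within N(v)
    p2 = 0  # adjacent edge pairs within N(v)
    t3 = 0  # 3x triangles within N(v)
    out_deg_sum = 0
    for a in nv:
        am = adj_mask[a]
        deg_in = (am & nv_mask).bit_count()
        e_in += deg_in
        p2 += deg_in * (deg_in - 1) // 2
        out_deg_sum += (am & ~excl).bit_count()
    e_in //= 2
    counts["triangle"] = e_in
    counts["path_3"] = d * (d - 1) // 2 - e_in + out_deg_sum
    # 4-node, three root neighbours
    for i in range(d):
        a = nv[i]
        am = adj_mask[a]
        for b in _bit_indices(am & nv_mask):
            if b > a:
                t3 += (am & adj_mask[b] & nv_mask).bit_count()
    n3 = t3 // 3
    n2 = p2 - 3 * n3
    n1 = e_in * (d - 2) - 2 * n2 - 3 * n3
    n0 = d * (d - 1) * (d - 2) // 6 - n1 - n2 - n3
    counts["clique_4"] = n3
    counts["diamond"] = n2
    counts["tailed_triangle"] = n1
    counts["star_4"] = n0
    # 4-node, two root neighbours: c adjacent to one or both of (a, b)
    for i in range(d):
        a = nv[i]
        am = adj_mask[a]
        a_out = am & ~excl
        for j in range(i + 1, d):
            b = nv[j]
            b_out = adj_mask[b] & ~excl
            n_both = (a_out & b_out).bit_count()
            n_one = (a_out | b_out).bit_count() - n_both
            if am >> b & 1:
                counts["diamond"] += n_both
                counts["tailed_triangle"] += n_one
            else:
                counts["cycle_4"] += n_both
                counts["path_4"] += n_one
    # 4-node, one root neighbour
    not_va = ~(1 << v)
    for a in nv:
        am = adj_mask[a]
        r_mask = am & ~excl
        r = r_mask.bit_count()
        e_r = 0
        chain = 0
        for b in _bit_indices(r_mask):
            bm = adj_mask[b]
            e_r += (bm & r_mask).bit_count()
            chain += (bm & ~am & ~excl & not_va & ~(1 << a)).bit_count()
        e_r //= 2
        counts["tailed_triangle"] += e_r
        counts["star_4"] += r * (r - 1) // 2 - e_r
        counts["path_4"] += chain
    return counts


def enumerate_seeded_graphlets(
    g: nx.Graph,
    seeds: Iterable,
    max_per_seed: int = 50_000,
    rng: Optional[np.random.Generator] = None,
    store_instances: bool = True,
) -> GraphletCensus:
    """Enumerate all distinct 2-4-node graphlet instances touching a seed.

    Enumeration is exhaustive per seed unless the number of connected
    node sets grown from that seed exceeds ``max_per_seed``, in which
    case a uniform reservoir subsample of that size is kept (requires
    ``rng``).  With ``store_instances=False`` only per-type counts are
    computed (closed-form, always exhaustive) — used for the rewired
    null replicas.  Seeds absent from the graph are dropped and
    reported; if none remain a :class:`SeedError` is raised.
    """
    seeds = sorted(set(seeds), key=repr)
    present = [s for s in seeds if s in g]
    dropped = [s for s in seeds if s not in g]
    if not present:
        raise SeedError(f"no seed present in graph; missing: {dropped}")
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj_mask = [0] * n
    for u, v in g.edges():
        adj_mask[idx[u]] |= 1 << idx[v]
        adj_mask[idx[v]] |= 1 << idx[u]

    counts = {t: 0 for t in GRAPHLET_TYPES}
    instances: dict[str, list[frozenset]] = {t: [] for t in GRAPHLET_TYPES}
    subsampled = False
    forbidden = 0  # earlier seeds: their supersets were already enumerated
    if not store_instances:
        for seed in present:
            root = idx[seed]
            for gtype, c in _count_from_root(root, adj_mask, forbidden).items():
                counts[gtype] += c
            forbidden |= 1 << root
        return GraphletCensus(
            counts=counts, instances={}, dropped_seeds=dropped, subsampled=False
        )
    for seed in present:
        root = idx[seed]
        kept: list[tuple[tuple[int, ...], str]] = []
        n_seen = 0
        for item in _enumerate_from_root(root, adj_mask, forbidden):
            n_seen += 1
            if n_seen <= max_per_seed:
                kept.append(item)
            else:
                subsampled = True
                if rng is None:
                    raise ValueError(
                        "per-seed instance count exceeds max_per_seed; "
                        "an rng is required for subsampling"
                    )
                r = int(rng.integers(n_seen))
                if r < max_per_seed:
                    kept[r] = item
        forbidden |= 1 << root
        for node_idxs, gtype in kept:
            counts[gtype] += 1
            if store_instances:
                instances[gtype].append(frozenset(nodes[i] for i in node_idxs))
    return GraphletCensus(
        counts=counts,
        instances=instances if store_instances else {},
        dropped_seeds=dropped,
        subsampled=subsampled,
    )


def degree_preserving_rewire(
    g: nx.Graph,
    n_swaps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    rng_seed: Optional[int] = None,
) -> nx.Graph:
    """Randomize edges by pair swaps, preserving every node's degree.

    Each attempt picks two edges (u,v), (x,y) and rewires them to
    (u,x), (v,y); attempts creating self-loops or duplicate edges are
    skipped.  Edge weights travel with the surviving (first-endpoint)
    half of each swapped edge.  Defaults to ``4 * |E|`` attempts.
    """
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    edges = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
    edge_set = {frozenset((u, v)) for u, v, _ in edges}
    m = len(edges)
    if n_swaps is None:
        n_swaps = 4 * m
    pairs = rng.integers(m, size=(n_swaps, 2))
    flips = rng.integers(2, size=n_swaps)
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            continue
        u, v, w1 = edges[i]
        x, y, w2 = edges[j]
        if flip:
            x, y = y, x
        # candidate rewiring: (u, x) and (v, y)
        if len({u, v, x, y}) < 4:
            continue
        e1, e2 = frozenset((u, x)), frozenset((v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (u, x, w1)
        edges[j] = (v, y, w2)
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    for u, v, w in edges:
        out.add_edge(u, v, weight=w)
    return out
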