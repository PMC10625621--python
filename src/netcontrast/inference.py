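"""Disease-network inference: graphlet-guided network, PageRank, flux.

The inference runs in three steps, anchored on a set of seed genes
(recurrently mutated genes, or known drivers):

1. *Graphlet-guided network (GGN).*  Seeded 2-4-node graphlet instances
   are enumerated in the reference interactome; each graphlet type's
   instance count is compared with counts in degree-preserving rewired
   replicas, and the union of instances of significantly enriched types
   forms the GGN — the seed-associated region of the interactome.
2. *Personalized PageRank.*  A random walk with restart over the whole
   weighted interactome, restarting uniformly on the seeds, scores every
   node.  ``alpha`` is the probability of stepping to a neighbour, so
   the restart probability is ``1 - alpha``.
3. *Flux edge selection.*  Each edge is scored by the PageRank mass
   pushed across it, normalized by node strength; the top-ranked GGN
   edges above the ``tau``-quantile of the flux distribution are kept,
   stopping once the network reaches ``edge_cap`` interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import SeedError
from .graphlets import (
    GRAPHLET_TYPES,
    GraphletCensus,
    degree_preserving_rewire,
    enumerate_seeded_graphlets,
)

__all__ = [
    "InferenceParams",
    "GGN",
    "DiseaseNetwork",
    "read_interactome",
    "personalized_pagerank",
    "edge_flux",
    "build_ggn",
    "select_network",
    "infer_network",
]


@dataclass(frozen=True)
class InferenceParams:
    """Tunable parameters of the three-step inference.

    ``alpha`` is the neighbour-walk probability of the random walk
    (restart probability = 1 - alpha); ``tau`` the flux-quantile cutoff
    for edge selection; ``edge_cap`` the hard stop on network size;
    ``n_rewires`` the number of rewired replicas in the graphlet null;
    ``z_threshold`` the one-sided z cutoff for a graphlet type to count
    as enriched.
    """

    alpha: float = 0.5
    tau: float = 0.8
    edge_cap: int = 2000
    n_rewires: int = 100
    z_threshold: float = 1.65
    max_per_seed: int = 50_000
    flux_mode: str = "min"  # "min" (bottleneck) or "sum" of directed fluxes
    pagerank_scope: str = "full"  # "full" interactome or "ggn" only
    tol: float = 1e-12
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must be in [0, 1)")


def read_interactome(path, preset: str = "default") -> nx.Graph:
    """Read a weighted edge list (node_a, node_b, weight) TSV.

    The ``hippie`` preset accepts the 4+-column dialect where the score
    sits in the third numeric column after two symbol columns; self
    loops are discarded and duplicate pairs keep the highest weight.
    """
    df = pd.read_csv(path, sep="\t")
    if preset == "hippie":
        sym_cols = [c for c in df.columns if df[c].dtype == object][:2]
        score_col = next(c for c in df.columns if "score" in c.lower())
        df = df[[sym_cols[0], sym_cols[1], score_col]]
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "weight"]
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        a, b = str(a).strip().upper(), str(b).strip().upper()
        w = float(w)
        if a == b or w <= 0:
            continue
        if not g.has_edge(a, b) or g[a][b]["weight"] < w:
            g.add_edge(a, b, weight=w)
    return g


def personalized_pagerank(
    g: nx.Graph,
    seeds: Iterable,
    alpha: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> dict:
    """Random walk with restart on the seed set, over edge weights.

    Solves ``pr = (1 - alpha) r + alpha M^T pr`` by power iteration,
    with ``r`` uniform over the seeds and ``M`` the weight-normalized
    transition matrix (each undirected edge walkable in both
    directions).  Zero-strength (isolated) nodes hand their mass back to
    the restart vector, so scores always sum to 1.
    """
    seeds = [s for s in set(seeds) if s in g]
    if not seeds:
        raise SeedError("personalized PageRank needs at least one seed in the graph")
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    r = np.zeros(n)
    for s in seeds:
        r[idx[s]] = 1.0 / len(seeds)
    rows, cols, vals = [], [], []
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        rows.append(idx[u]); cols.append(idx[v]); vals.append(w)
        rows.append(idx[v]); cols.append(idx[u]); vals.append(w)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    strength = np.asarray(W.sum(axis=1)).ravel()
    dangling = strength == 0
    inv_s = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, strength))
    M = sp.diags(inv_s) @ W  # row-stochastic on non-dangling rows
    MT = M.T.tocsr()
    pr = r.copy()
    for _ in range(max_iter):
        walked = MT @ pr
        lost = pr[dangling].sum()  # dangling mass restarts
        new = (1.0 - alpha) * r + alpha * (walked + lost * r)
        if np.abs(new - pr).sum() < tol:
            pr = new
            break
        pr = new
    return {u: float(pr[idx[u]]) for u in nodes}


def edge_flux(
    g: nx.Graph, pr: dict, mode: str = "min"
) -> dict[tuple, float]:
    """Score each edge by PageRank mass pushed across it.

    The directed flux ``f(u->v) = pr(u) w(u,v) / s(u)`` (s = node
    strength) measures mass flowing u to v; the edge score is the
    minimum of the two directions ("min", bottleneck convention — both
    endpoints must push mass) or their sum ("sum").  Fluxes are
    invariant to a global rescaling of the weights.
    """
    strength = {u: 0.0 for u in g.nodes}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        strength[u] += w
        strength[v] += w
    flux = {}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        fuv = pr[u] * w / strength[u] if strength[u] > 0 else 0.0
        fvu = pr[v] * w / strength[v] if strength[v] > 0 else 0.0
        key = (u, v) if u <= v else (v, u)
        flux[key] = min(fuv, fvu) if mode == "min" else fuv + fvu
    return flux


@dataclass
class GGN:
    """Graphlet-guided network: seed-associated interactome region."""

    graph: nx.Graph
    significant_types: dict[str, float]  # type -> z-score
    type_zscores: dict[str, float]
    census: Optional[GraphletCensus] = None
    fallback: bool = False
    dropped_seeds: list = field(default_factory=list)


def _zscores(obs: dict[str, int], null_counts: dict[str, list[int]]) -> dict[str, float]:
    z = {}
    for t in GRAPHLET_TYPES:
        null = np.asarray(null_counts[t], dtype=float)
        mu, sd = null.mean(), null.std(ddof=1) if len(null) > 1 else 0.0
        if sd == 0:
            z[t] = 0.0 if obs[t] == mu else np.copysign(np.inf, obs[t] - mu)
        else:
            z[t] = (obs[t] - mu) / sd
    return z


def build_ggn(g: nx.Graph, seeds: Iterable, params: InferenceParams) -> GGN:
    """Build the graphlet-guided network around the seeds.

    A graphlet type is significant when its seeded-instance count is
    enriched (one-sided empirical z >= ``z_threshold``) over
    ``n_rewires`` degree-preserving rewired replicas.  The GGN is the
    union of the induced edges of every seeded instance of a significant
    type; if no type reaches significance the seeds' incident edges are
    used as a fallback (with a warning).
    """
    rng = np.random.default_rng(params.rng_seed)
    census = enumerate_seeded_graphlets(
        g, seeds, max_per_seed=params.max_per_seed, rng=rng
    )
    present_seeds = [s for s in set(seeds) if s in g]
    null_counts: dict[str, list[int]] = {t: [] for t in GRAPHLET_TYPES}
    for _ in range(params.n_rewires):
        rewired = degree_preserving_rewire(g, rng=rng)
        null = enumerate_seeded_graphlets(
            rewired, present_seeds, max_per_seed=params.max_per_seed,
            rng=rng, store_instances=False,
        )
        for t in GRAPHLET_TYPES:
            null_counts[t].append(null.counts[t])
    z = _zscores(census.counts, null_counts)
    significant = {
        t: z[t] for t in GRAPHLET_TYPES
        if census.counts[t] > 0 and z[t] >= params.z_threshold
    }
    edges: set[frozenset] = set()
    if significant:
        for t in significant:
            for node_set in census.instances[t]:
                sub = g.subgraph(node_set)
                edges.update(frozenset(e) for e in sub.edges())
    else:
        warnings.warn(
            "no graphlet type significantly enriched; falling back to "
            "seed-incident edges", stacklevel=2,
        )
        for s in present_seeds:
            edges.update(frozenset((s, v)) for v in g.neighbors(s))
    ggn_graph = nx.Graph()
    for e in edges:
        u, v = tuple(e)
        ggn_graph.add_edge(u, v, weight=g[u][v].get("weight", 1.0))
    return GGN(
        graph=ggn_graph,
        significant_types=significant,
        type_zscores=z,
        census=census,
        fallback=not significant,
        dropped_seeds=census.dropped_seeds,
    )


@dataclass
class DiseaseNetwork:
    """Inferred disease-specific subnetwork.

    ``graph`` nodes carry ``pagerank``, ``role`` (seed / tf / target /
    other) and ``is_seed`` attributes; edges carry ``weight``, ``flux``
    and ``rank``.
    """

    graph: nx.Graph
    seeds: list
    missing_seeds: list = field(default_factory=list)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": u,
                "pagerank": d.get("pagerank", np.nan),
                "role": d.get("role", "other"),
                "is_seed": bool(d.get("is_seed", False)),
            }
            for u, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene", "pagerank", "role", "is_seed"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "a": min(u, v),
                "b": max(u, v),
                "weight": d.get("weight", np.nan),
                "flux": d.get("flux", np.nan),
                "rank": d.get("rank", -1),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: r["rank"])
        return pd.DataFrame(rows, columns=["a", "b", "weight", "flux", "rank"])


def select_network(
    ggn: GGN,
    flux: dict[tuple, float],
    pr: dict,
    params: InferenceParams,
    seeds: Iterable,
) -> DiseaseNetwork:
    """Keep the top-flux GGN edges above the tau-quantile, capped.

    Edges are ranked by flux descending (ties: higher min-endpoint
    PageRank, then lexicographic edge key) and added while their flux is
    at or above the ``tau``-quantile of the GGN flux distribution and
    the edge count is below ``edge_cap``.
    """
    g = ggn.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot select edges from an empty GGN")
    seeds = sorted(set(seeds))
    keys = []
    for u, v in g.edges():
        key = (u, v) if u <= v else (v, u)
        keys.append(key)
    fluxes = np.array([flux[k] for k in keys])
    threshold = float(np.quantile(fluxes, params.tau))
    order = sorted(
        keys,
        key=lambda k: (-flux[k], -min(pr.get(k[0], 0.0), pr.get(k[1], 0.0)), k),
    )
    out = nx.Graph()
    rank = 0
    for k in order:
        if flux[k] < threshold or rank >= params.edge_cap:
            break
        u, v = k
        out.add_edge(u, v, weight=g[u][v]["weight"], flux=flux[k], rank=rank)
        rank += 1
    seed_set = set(seeds)
    for u in out.nodes:
        out.nodes[u]["pagerank"] = pr.get(u, 0.0)
        out.nodes[u]["is_seed"] = u in seed_set
        out.nodes[u]["role"] = "seed" if u in seed_set else "other"
    missing = [s for s in seeds if s not in out.nodes]
    return DiseaseNetwork(graph=out, seeds=list(seeds), missing_seeds=missing)


def infer_network(
    g: nx.Graph, seeds: Iterable, params: Optional[InferenceParams] = None
) -> DiseaseNetwork:
    """Full three-step inference: GGN -> PageRank -> flux selection."""
    if params is None:
        params = InferenceParams()
    ggn = build_ggn(g, seeds, params)
    scope = g if params.pagerank_scope == "full" else ggn.graph
    pr = personalized_pagerank(
        scope, [s for s in set(seeds) if s in scope], alpha=params.alpha,
        tol=params.tol,
    )
    flux_all = edge_flux(scope, pr, mode=params.flux_mode)
    flux = {}
    for u, v in ggn.graph.edges():
        key = (u, v) if u <= v else (v, u)
        flux[key] = flux_all.get(key, 0.0)
    net = select_network(ggn, flux, pr, params, seeds)
    net.ggn = ggn  # kept for diagnostics
    return net
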