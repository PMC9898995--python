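"""MCODE module detection and CytoHubba-style hub centralities.

MCODE (Bader-Hogue) weights each vertex by k * density of the densest k-core
of its closed neighborhood, then grows complexes outward from the
highest-weight unvisited seeds, admitting neighbors whose weight is at least
(1 - vwp) times the seed weight.  Module score is density x node count; the
signature ("disease-defining genes") is the union of the top passing module
per regulation direction under the score > 3 and node number > 5 criteria.

Centralities: degree; MNC (size of the largest connected component of the
open-neighborhood subgraph); DMNC (edges / nodes^epsilon of that component,
epsilon 1.7); MCC (sum of (|C|-1)! over maximal cliques C containing the
node, isolated nodes scoring 0! = 1); and EPC, a Monte-Carlo edge-percolation
score (per trial, a retention probability is drawn uniformly and each edge
kept independently with that probability; the score is the mean size of the
node's surviving component).
"""
from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .config import McodeParams
from .io import GeneNetwork, SignatureCollection

logger = logging.getLogger(__name__)

CENTRALITY_METHODS = ("degree", "mnc", "dmnc", "mcc", "epc")


@dataclasses.dataclass
class McodeModule:
    nodes: frozenset
    score: float
    seed_node: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def module_score(g: GeneNetwork, nodes) -> float:
    """MCODE module score: density x node count of the induced subgraph."""
    sub = g.subgraph(nodes)
    return _density(sub) * sub.number_of_nodes()


def _vertex_weights(g: GeneNetwork) -> dict:
    """MCODE vertex weighting: highest k-core of the closed neighborhood."""
    weights = {}
    for v in g.nodes():
        closed = set(g[v]) | {v}
        sub = g.subgraph(closed)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        k_max = max(core.values())
        core_nodes = [n for n, c in core.items() if c == k_max]
        weights[v] = k_max * _density(sub.subgraph(core_nodes))
    return weights


def mcode_modules(g: GeneNetwork, params: McodeParams | None = None) -> list[McodeModule]:
    """Bader-Hogue complex prediction; modules sorted by descending score."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    params = params or McodeParams()
    weights = _vertex_weights(g)
    visited: set = set()
    modules: list[McodeModule] = []
    for seed in sorted(g.nodes(), key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.vwp)
        members = {seed}
        frontier = [(seed, 0)]
        visited.add(seed)
        while frontier:
            node, depth = frontier.pop()
            if depth >= params.max_depth:
                continue
            for nb in g[node]:
                if nb in visited or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    visited.add(nb)
                    frontier.append((nb, depth + 1))
        if params.fluff:
            boundary = set()
            for node in members:
                for nb in g[node]:
                    if nb in members or nb in boundary:
                        continue
                    closed = set(g[nb]) | {nb}
                    if _density(g.subgraph(closed)) > params.fluff_density:
                        boundary.add(nb)
            members |= boundary
        if params.haircut:
            core2 = nx.k_core(g.subgraph(members), k=2)
            if core2.number_of_nodes() >= 2:
                members = set(core2.nodes())
        if len(members) < 2:
            continue
        score = module_score(g, members)
        if score <= 0:
            continue
        modules.append(McodeModule(nodes=frozenset(members), score=score, seed_node=seed))
    modules.sort(key=lambda m: (-m.score, -m.n_nodes, str(m.seed_node)))
    return modules


def select_ddgs(
    up_modules: list[McodeModule],
    down_modules: list[McodeModule],
    min_score: float = 3.0,
    min_nodes: int = 5,
    all_passing: bool = False,
) -> SignatureCollection:
    """Signature genes: top passing MCODE module per regulation direction.

    A module passes with score > ``min_score`` and node count > ``min_nodes``.
    If one direction has no passing module a warning is logged; if neither
    does, it is a hard error.
    """
    def passing(modules):
        ok = [m for m in modules if m.score > min_score and m.n_nodes > min_nodes]
        if not ok:
            return []
        return ok if all_passing else ok[:1]

    up = passing(up_modules)
    down = passing(down_modules)
    if not up and not down:
        raise ValueError(
            "no MCODE module passes the score/nodes criteria; review network or parameters"
        )
    sets = {}
    if up:
        sets["DDG_up"] = sorted(set().union(*(m.nodes for m in up)))
    else:
        warnings.warn("no up-regulated module passes the criteria")
    if down:
        sets["DDG_down"] = sorted(set().union(*(m.nodes for m in down)))
    else:
        warnings.warn("no down-regulated module passes the criteria")
    combined = sorted(set(sets.get("DDG_up", [])) | set(sets.get("DDG_down", [])))
    sets["DDG"] = combined
    return SignatureCollection(
        sets=sets,
        descriptions={name: "disease-defining genes" for name in sets},
    )


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _largest_neighborhood_component(g: GeneNetwork, v) -> nx.Graph:
    """Largest connected component of the open-neighborhood subgraph of v.

    Ties on size are broken by edge count, then by smallest member symbol.
    Returns an empty graph for isolated nodes.
    """
    nb = list(g[v])
    if not nb:
        return nx.Graph()
    sub = g.subgraph(nb)
    comps = sorted(
        (sub.subgraph(c) for c in nx.connected_components(sub)),
        key=lambda c: (-c.number_of_nodes(), -c.number_of_edges(), min(map(str, c.nodes()))),
    )
    return comps[0]


def _mnc(g: GeneNetwork) -> dict:
    return {v: _largest_neighborhood_component(g, v).number_of_nodes() for v in g.nodes()}


def _dmnc(g: GeneNetwork, epsilon: float = 1.7) -> dict:
    out = {}
    for v in g.nodes():
        comp = _largest_neighborhood_component(g, v)
        n = comp.number_of_nodes()
        out[v] = comp.number_of_edges() / (n ** epsilon) if n > 0 else 0.0
    return out


def _mcc(g: GeneNetwork) -> dict:
    scores = {v: 0.0 for v in g.nodes()}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def _epc(g: GeneNetwork, iters: int, seed: int, retention_prob: float | None = None) -> dict:
    if iters < 1:
        raise ValueError("epc requires iters >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes())
    edges = list(g.edges())
    totals = dict.fromkeys(nodes, 0.0)
    for _ in range(iters):
        p = retention_prob if retention_prob is not None else rng.uniform()
        keep = rng.random(len(edges)) < p
        trial = nx.Graph()
        trial.add_nodes_from(nodes)
        trial.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(trial):
            size = len(comp)
            for v in comp:
                totals[v] += size
    return {v: t / iters for v, t in totals.items()}


def centrality_scores(
    g: GeneNetwork,
    method: str,
    epc_iters: int = 100,
    seed: int = 0,
    epsilon: float = 1.7,
    retention_prob: float | None = None,
) -> dict:
    """One of the five hub scores for every node of the graph."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if method == "degree":
        return {v: float(d) for v, d in g.degree()}
    if method == "mnc":
        return {v: float(s) for v, s in _mnc(g).items()}
    if method == "dmnc":
        return _dmnc(g, epsilon=epsilon)
    if method == "mcc":
        return _mcc(g)
    if method == "epc":
        return _epc(g, iters=epc_iters, seed=seed, retention_prob=retention_prob)
    raise ValueError(f"unknown centrality method {method!r}")


def all_centralities(
    g: GeneNetwork,
    epc_iters: int = 100,
    seed: int = 0,
    epsilon: float = 1.7,
) -> dict:
    return {
        m: centrality_scores(g, m, epc_iters=epc_iters, seed=seed, epsilon=epsilon)
        for m in CENTRALITY_METHODS
    }


@dataclasses.dataclass
class HubScoreTable:
    """Per-gene centrality scores, top-k flags and the selected-count tally."""

    table: pd.DataFrame  # index: gene; columns: the 5 scores, in_top_*, selected_count
    k: int
    min_degree: int
    flagged: list = dataclasses.field(default_factory=list)

    def selected(self, min_methods: int = 1) -> list:
        t = self.table
        return list(t.index[t["selected_count"] >= min_methods])


def top_k_aggregate(tables: dict, k: int = 10, min_degree: int = 10) -> HubScoreTable:
    """Per-method top-k membership with the degree-exclusion rule.

    Ties at the top-k boundary break by descending degree, then symbol.  Genes
    with degree < ``min_degree`` are struck from every top-k after selection.
    """
    missing = [m for m in CENTRALITY_METHODS if m not in tables]
    if missing:
        raise ValueError(f"missing centrality tables: {missing}")
    degree = tables["degree"]
    genes = sorted(degree)
    n = len(genes)
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; clamped")
        k = n
    df = pd.DataFrame({m: pd.Series(tables[m]) for m in CENTRALITY_METHODS}).loc[genes]
    for m in CENTRALITY_METHODS:
        ranked = sorted(genes, key=lambda v: (-df.at[v, m], -degree[v], str(v)))
        top = [v for v in ranked[:k] if degree[v] >= min_degree]
        df[f"in_top_{m}"] = [g in top for g in genes]
    df["selected_count"] = df[[f"in_top_{m}" for m in CENTRALITY_METHODS]].sum(axis=1)
    return HubScoreTable(table=df, k=k, min_degree=min_degree)
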