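"""Co-mention network construction and centrality ranking.

Two experts are linked when they are mentioned in at least one common news
article; the graph is simple, undirected and unweighted (repeat co-mentions
do not strengthen an edge).  Four centrality measures rank the experts —
the "four P's":

* degree (prestige):      C_D(v) = deg(v) / (n − 1)
* betweenness (power):    C_B(v) = Σ_{s≠v≠t} σ_st(v) / σ_st  over unordered
  pairs, unnormalized (σ_st counts geodesics from s to t)
* closeness (prominence): C_C(v) = 1 / Σ_{t≠v} d_G(v, t)
* eigenvector (importance): C_E(v) = (1/λ) Σ_{u∈M(v)} C_E(u), the principal
  eigenvector of the adjacency matrix, max-normalized to 1

Closeness and eigenvector assume connectivity, so they (and by default the
degree denominator n) are computed per connected component; analysis
focuses on the largest component.  Ties in every ranking break by person id
for reproducible top-k lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class CentralityError(ValueError):
    pass


METRICS = ("mentions", "c_deg", "c_btw", "c_clo", "c_eig")


def build_graph(article_persons: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Unweighted co-mention graph from per-article person-id sets.

    Every person mentioned anywhere becomes a vertex; an edge joins u ≠ v
    iff some article mentions both.  Insertion order is sorted, so the
    result is invariant to article order.
    """
    g = nx.Graph()
    for doc_id in sorted(article_persons):
        persons = sorted(set(article_persons[doc_id]))
        g.add_nodes_from(persons)
        for i, u in enumerate(persons):
            for v in persons[i + 1:]:
                g.add_edge(u, v)
    return g


def connected_components(g: nx.Graph) -> list[list]:
    """Components as sorted vertex lists, largest first (ties by smallest id)."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def degree_centrality(g: nx.Graph) -> dict:
    """deg(v)/(n−1) with n taken from the graph passed in."""
    n = g.number_of_nodes()
    if n < 2:
        raise CentralityError("degree centrality undefined for n < 2")
    return {v: g.degree(v) / (n - 1) for v in g.nodes}


def betweenness_centrality(g: nx.Graph) -> dict:
    """Unnormalized betweenness over unordered source/target pairs."""
    return nx.betweenness_centrality(g, normalized=False)


def closeness_centrality(g: nx.Graph) -> dict:
    """1 / Σ_t d(v, t), within each vertex's connected component.

    An isolated vertex has no finite distances; its value is reported as
    NaN (missing).
    """
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for v in comp:
            if len(comp) < 2:
                out[v] = math.nan
                continue
            total = sum(nx.single_source_shortest_path_length(sub, v).values())
            out[v] = 1.0 / total
    return out


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[dict, float]:
    """Principal-eigenvector centrality by power iteration, max-normalized.

    Iterates x ← (A + I)x (the identity shift guarantees convergence on
    bipartite components) until the iterate moves less than ``tol`` in the
    infinity norm; λ is the Rayleigh quotient with A itself.  Returns
    ``(scores, λ)`` with max(score) = 1.  Requires a connected graph with
    at least two vertices; non-convergence raises with the residual.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 2 or not nx.is_connected(g):
        raise CentralityError(
            "eigenvector centrality needs a connected component with >= 2 vertices"
        )
    a = nx.to_numpy_array(g, nodelist=nodes)
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    else:
        resid = float(np.abs(a @ x - (x @ a @ x) * x).max())
        raise CentralityError(
            f"power iteration did not converge in {max_iter} steps "
            f"(residual {resid:.2e})"
        )
    lam = float(x @ a @ x)
    scores = x / x.max()
    return {v: float(s) for v, s in zip(nodes, scores)}, lam


def centrality_table(
    g: nx.Graph,
    mention_counts: Mapping[str, int],
    use_global_n: bool = False,
) -> pd.DataFrame:
    """Per-person mention frequency and the four centralities.

    Closeness and eigenvector are computed within each connected component;
    the degree denominator uses the component size (or the whole-graph n
    when ``use_global_n``).  Vertices in components too small for a measure
    get NaN.  Rows are indexed by person id, sorted.
    """
    nodes = sorted(g.nodes)
    df = pd.DataFrame(index=pd.Index(nodes, name="person_id"))
    df["mentions"] = [int(mention_counts.get(v, 0)) for v in nodes]
    btw = betweenness_centrality(g)
    clo = closeness_centrality(g)
    deg: dict = {}
    eig: dict = {}
    comp_ix: dict = {}
    for k, comp in enumerate(connected_components(g)):
        sub = g.subgraph(comp)
        n_eff = g.number_of_nodes() if use_global_n else len(comp)
        for v in comp:
            comp_ix[v] = k
            deg[v] = g.degree(v) / (n_eff - 1) if n_eff > 1 else math.nan
        if len(comp) >= 2:
            scores, _lam = eigenvector_centrality(sub)
            eig.update(scores)
        else:
            eig[comp[0]] = math.nan
    df["c_deg"] = [deg[v] for v in nodes]
    df["c_btw"] = [btw[v] for v in nodes]
    df["c_clo"] = [clo[v] for v in nodes]
    df["c_eig"] = [eig[v] for v in nodes]
    df["component"] = [comp_ix[v] for v in nodes]
    return df


@dataclass
class RankingResult:
    table: pd.DataFrame                      # with rank_<metric> columns
    top_k: dict[str, list[str]]              # metric -> ranked person ids
    union: list[str]                         # sorted ids in any top-k
    qualifying: dict[str, list[str]]         # id -> metrics it qualified on


def rank_experts(table: pd.DataFrame, k: int = 20) -> RankingResult:
    """Top-k lists per metric and their union.

    Each metric sorts descending with ties broken by person id; NaN values
    never rank.  The union list collects every person in any top-k together
    with the metrics they qualified on.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    table = table.copy()
    top_k: dict[str, list[str]] = {}
    for metric in METRICS:
        valid = table[metric].dropna()
        order = sorted(valid.index, key=lambda v: (-valid[v], v))
        ranks = pd.Series(
            {v: r + 1 for r, v in enumerate(order)}, dtype="float64"
        )
        table[f"rank_{metric}"] = ranks.reindex(table.index)
        top_k[metric] = order[:k]
    qualifying: dict[str, list[str]] = {}
    for metric, ids in top_k.items():
        for pid in ids:
            qualifying.setdefault(pid, []).append(metric)
    union = sorted(qualifying)
    qualifying = {pid: sorted(ms) for pid, ms in qualifying.items()}
    return RankingResult(table=table, top_k=top_k, union=union,
                         qualifying=qualifying)
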