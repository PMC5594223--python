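"""Global graph-theoretic summaries of a weighted connectivity matrix.

Each band-averaged channel x channel matrix is turned into a weighted
directed graph (absolute values, zeroed diagonal, weights rescaled to
[0, 1] by the matrix maximum) and reduced to five global metrics:

- assortativity: Pearson correlation of out-degree (source) vs in-degree
  (sink) over directed edges
- global efficiency: mean over ordered node pairs of 1/shortest-path
  length with edge length 1/weight; disconnected pairs contribute 0
- clustering: Fagiolo's directed weighted clustering coefficient
  (geometric-mean triangles), averaged over nodes
- modularity: best Q of the deterministic Clauset-Newman-Moore greedy
  agglomeration on the symmetrized weight matrix
- transitivity: total geometric-mean triangle weight over total weighted
  triple count (directed generalization of the triangle/triple ratio)

No thresholding or binarization is applied: the fully weighted graphs are
used as-is.  Degenerate graphs (fewer than 2 edges) yield NaN for
assortativity, flagged for downstream imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isnan

import networkx as nx
import numpy as np
from numpy.typing import NDArray
from scipy.sparse.csgraph import dijkstra

from .constants import GRAPH_METRICS

__all__ = ["GraphSummary", "connectivity_to_graph", "graph_summary"]

logger = logging.getLogger(__name__)


@dataclass
class GraphSummary:
    measure: str | None
    band: str | None
    assortativity: float
    efficiency: float
    clustering: float
    modularity: float
    transitivity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GRAPH_METRICS}

    def feature_values(self) -> dict[str, float]:
        """Metric values with flagged-missing (NaN) imputed to 0."""
        out = {}
        for name, v in self.as_dict().items():
            if isnan(v):
                logger.info(
                    "graph metric %s missing for %s/%s; imputed to 0",
                    name, self.measure, self.band,
                )
                v = 0.0
            out[name] = v
        return out


def connectivity_to_graph(matrix: NDArray[np.float64]) -> NDArray[np.float64]:
    """Normalize a connectivity matrix into a weighted adjacency matrix.

    Absolute values, diagonal zeroed, rescaled to [0, 1] by the maximum.
    W[i, j] is the weight of the directed edge j -> i (source -> sink,
    matching the connectivity orientation).  Idempotent.
    """
    W = np.abs(np.asarray(matrix, dtype=float)).copy()
    if not np.all(np.isfinite(W)):
        raise ValueError("connectivity matrix contains non-finite values")
    np.fill_diagonal(W, 0.0)
    mx = W.max()
    if mx > 0:
        W = W / mx
    return W


def _digraph(W: NDArray[np.float64]) -> nx.DiGraph:
    # connectivity (i, j) = source j -> sink i, so the adjacency is W.T
    return nx.from_numpy_array(W.T, create_using=nx.DiGraph)


def _assortativity(G: nx.DiGraph) -> float:
    if G.number_of_edges() < 2:
        return float("nan")
    import warnings

    try:
        with warnings.catch_warnings():
            # constant degree sequences (e.g. complete graphs) have no
            # defined degree correlation; report flagged-missing instead
            warnings.simplefilter("ignore")
            r = nx.degree_pearson_correlation_coefficient(
                G, x="out", y="in", weight="weight"
            )
    except (ValueError, ZeroDivisionError):
        return float("nan")
    return float(r) if np.isfinite(r) else float("nan")


def _efficiency(W: NDArray[np.float64]) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        length = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    # dijkstra on directed lengths; adjacency row=from, col=to, so use W.T
    lt = np.where(W.T > 0, 1.0 / np.where(W.T > 0, W.T, 1.0), np.inf)
    dist = dijkstra(lt, directed=True)
    inv = np.zeros_like(dist)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def _clustering(G: nx.DiGraph) -> float:
    if G.number_of_edges() == 0:
        return 0.0
    vals = nx.clustering(G, weight="weight")
    return float(np.mean(list(vals.values())))


def _transitivity(W: NDArray[np.float64]) -> float:
    """Weighted directed triangle/triple ratio (Fagiolo numerator)."""
    A = (W > 0).astype(float)
    Wc = np.cbrt(W)
    M = Wc + Wc.T
    triangles = np.diagonal(M @ M @ M) / 2.0  # per-node 2*t_i summed forms
    d_tot = A.sum(0) + A.sum(1)
    d_bi = np.diagonal(A @ A)
    triples = d_tot * (d_tot - 1) - 2 * d_bi
    denom = triples.sum()
    if denom <= 0:
        return 0.0
    return float(triangles.sum() / denom)


def _modularity(W: NDArray[np.float64]) -> float:
    sym = (W + W.T) / 2.0
    G = nx.from_numpy_array(sym)
    if G.number_of_edges() == 0:
        return 0.0
    comms = nx.community.greedy_modularity_communities(G, weight="weight")
    return float(nx.community.modularity(G, comms, weight="weight"))


def graph_summary(
    W: NDArray[np.float64], measure: str | None = None, band: str | None = None
) -> GraphSummary:
    """Compute the five global metrics of a normalized adjacency matrix.

    ``W`` should come from :func:`connectivity_to_graph` (weights in
    [0, 1], zero diagonal).
    """
    W = np.asarray(W, dtype=float)
    G = _digraph(W)
    return GraphSummary(
        measure=measure,
        band=band,
        assortativity=_assortativity(G),
        efficiency=_efficiency(W),
        clustering=_clustering(G),
        modularity=_modularity(W),
        transitivity=_transitivity(W),
    )
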