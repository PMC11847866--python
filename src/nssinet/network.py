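"""Correlation network over the one-hot nodes: build, style, lay out, analyse.

The network's nodes are the 25 one-hot indicator columns; edges come from
pairwise Pearson correlations.  Two views are supported, mirroring the
study's workflow: the untresholded matrix (every pair forms an edge,
styled by sign and magnitude, for visual export) and the thresholded
adjacency ``EDGE_ij = 1 iff |r_ij| > theta`` (default theta = 0.2, strict
inequality) on which degree and betweenness centrality are computed.

* degree centrality ``DC_n = k_n``: number of incident edges;
* betweenness centrality ``BC_n = sum over unordered pairs {s,t}, s != n != t,
  of sigma_st(n) / sigma_st`` — the fraction of shortest paths through
  ``n`` — computed with Brandes' accumulation, unnormalized; pairs in
  different components contribute 0;
* density ``2E / (N (N - 1))``.

Correlations are pairwise-complete; a pair with a zero-variance member is
undefined, reported as masked and treated as 0 when thresholding.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .cohort import EncodedMatrix


class NetworkError(ValueError):
    pass


DEFAULT_THETA = 0.2


@dataclass
class CorrelationNetwork:
    """Node labels, Pearson matrix (NaN = undefined), optional adjacency."""

    node_labels: tuple[str, ...]
    r: np.ndarray
    theta: float | None = None
    adjacency: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        if self.adjacency is None:
            raise NetworkError("no adjacency: call threshold() first")
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        return network_density(self.n_nodes, self.n_edges)

    def threshold(self, theta: float = DEFAULT_THETA) -> "CorrelationNetwork":
        return CorrelationNetwork(
            self.node_labels, self.r, theta, threshold_adjacency(self.r, theta)
        )


def pairwise_pearson(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlations of an ``n x p`` matrix.

    Missing cells are NaN.  Pairs with fewer than 2 complete rows or a
    zero-variance member over the complete rows are NaN (undefined).
    """
    df = pd.DataFrame(values)
    r = df.corr(method="pearson", min_periods=2).to_numpy()
    # pandas leaves the diagonal 1 even for constant columns; mark columns
    # with no variance over their observed rows as undefined off-diagonal
    # but keep r_ii = 1 for observed non-constant columns only.
    p = values.shape[1]
    for j in range(p):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or np.all(obs == obs[0]):
            r[j, :] = np.nan
            r[:, j] = np.nan
    return r


def correlation_matrix(encoded: EncodedMatrix) -> CorrelationNetwork:
    """Pairwise-complete correlation network over the encoded columns."""
    values = np.asarray(encoded.values, dtype=float)
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        bad = [encoded.column_labels[j] for j in np.flatnonzero(all_missing)]
        raise NetworkError(f"columns with all values missing: {bad}")
    r = pairwise_pearson(values)
    return CorrelationNetwork(tuple(encoded.column_labels), r)


def threshold_adjacency(r: np.ndarray, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Binary adjacency: edge iff ``|r_ij| > theta`` (strict), no self loops.

    Undefined (NaN) correlations never form an edge.
    """
    r = np.asarray(r, dtype=float)
    if r.shape[0] != r.shape[1]:
        raise NetworkError("correlation matrix must be square")
    with np.errstate(invalid="ignore"):
        adj = (np.abs(r) > theta).astype(int)
    adj[np.isnan(r)] = 0
    np.fill_diagonal(adj, 0)
    return adj


def network_density(n_nodes: int, n_edges: int) -> float:
    """``2E / (N (N - 1))`` — fraction of possible undirected edges."""
    if n_nodes < 2:
        raise NetworkError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def degree_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Per-node degree ``k_n`` (row sums of the adjacency)."""
    adj = np.asarray(adjacency)
    return adj.sum(axis=1).astype(int)


def betweenness_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs (Brandes' algorithm).

    Each unordered pair {s, t} with s != n != t contributes
    ``sigma_st(n) / sigma_st``; disconnected pairs contribute nothing.
    """
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counts (BFS, unweighted)
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair was accumulated from both ends


def rank_nodes(labels: tuple[str, ...], values: np.ndarray) -> list[str]:
    """Labels sorted by value descending; ties keep the frozen label order."""
    order = sorted(range(len(labels)), key=lambda i: (-values[i], i))
    return [labels[i] for i in order]


# ---------------------------------------------------------------------------
# Edge styling


@dataclass(frozen=True)
class EdgeStyle:
    i: int
    j: int
    r: float
    width: float
    sign: str  # 'positive' / 'negative'
    intensity: int  # decile rank of |r|, 0 (weakest) .. 9 (strongest)


def edge_styles(network: CorrelationNetwork, omega: float = 5.0) -> list[EdgeStyle]:
    """One style per unordered pair: ``width = omega |r|``, colour class by
    sign and |r| decile.  Undefined correlations style as r = 0."""
    r = network.r
    n = network.n_nodes
    styles = []
    for i in range(n):
        for j in range(i + 1, n):
            rij = r[i, j]
            if math.isnan(rij):
                rij = 0.0
            a = abs(rij)
            intensity = min(int(a * 10), 9)
            styles.append(
                EdgeStyle(
                    i, j, rij, omega * a,
                    "negative" if rij < 0 else "positive", intensity,
                )
            )
    return styles


# ---------------------------------------------------------------------------
# Spring layout


@dataclass
class LayoutParams:
    """Force-directed layout parameters.

    Attraction between connected nodes follows ``k log(d / d0)`` toward
    the neighbour (zero at the desired distance ``d0``, pulling together
    beyond it, pushing apart inside it); repulsion ``c / d^2`` acts
    between all pairs.  ``alpha`` scales each displacement step and
    decays geometrically.
    """

    d0: float = 1.0
    k: float = 1.0
    c: float = 0.1
    alpha: float = 0.1
    alpha_decay: float = 0.99
    max_iterations: int = 1000
    movement_tolerance: float = 1e-4
    seed: int = 0
    jitter_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("d0", "k", "c", "alpha", "movement_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LayoutResult:
    positions: np.ndarray  # n x 2
    iterations_run: int
    converged: bool
    final_max_displacement: float


def spring_layout(
    network: CorrelationNetwork,
    params: LayoutParams | None = None,
    initial_positions: np.ndarray | None = None,
) -> LayoutResult:
    """Iterative force-directed node placement, deterministic under seed.

    Updates ``P_new = P_old + alpha (F_attraction + F_repulsion)`` resolved
    along inter-node unit vectors; stops when the largest node displacement
    falls below the tolerance or the iteration cap is reached.  Coincident
    nodes are jittered by a small epsilon rather than dividing by zero.
    """
    params = params or LayoutParams()
    # unthresholded view: every defined correlation pair attracts
    adj = (
        network.adjacency
        if network.adjacency is not None
        else threshold_adjacency(network.r, 0.0)
    )
    n = network.n_nodes
    rng = np.random.default_rng(params.seed)
    if initial_positions is not None:
        pos = np.asarray(initial_positions, dtype=float).copy()
        if pos.shape != (n, 2):
            raise NetworkError("initial_positions must be n x 2")
    else:
        pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    if n == 1:
        return LayoutResult(pos, 0, True, 0.0)
    alpha = params.alpha
    iterations = 0
    max_disp = math.inf
    for iterations in range(1, params.max_iterations + 1):
        diff = pos[None, :, :] - pos[:, None, :]  # vector from i to j
        dist = np.linalg.norm(diff, axis=-1)
        coincident = (dist < params.jitter_epsilon) & ~np.eye(n, dtype=bool)
        if coincident.any():
            pos = pos + rng.normal(scale=params.jitter_epsilon, size=pos.shape)
            diff = pos[None, :, :] - pos[:, None, :]
            dist = np.linalg.norm(diff, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(dist[..., None] > 0, diff / np.maximum(dist, 1e-300)[..., None], 0.0)
            attract_mag = np.where(adj > 0, params.k * np.log(np.maximum(dist, 1e-300) / params.d0), 0.0)
            repulse_mag = np.where(~np.eye(n, dtype=bool), params.c / np.maximum(dist, 1e-300) ** 2, 0.0)
        np.fill_diagonal(attract_mag, 0.0)
        force = ((attract_mag - repulse_mag)[..., None] * unit).sum(axis=1)
        step = alpha * force
        pos = pos + step
        alpha *= params.alpha_decay
        max_disp = float(np.linalg.norm(step, axis=1).max())
        if max_disp < params.movement_tolerance:
            return LayoutResult(pos, iterations, True, max_disp)
    return LayoutResult(pos, iterations, False, max_disp)


# ---------------------------------------------------------------------------
# Centrality bundle + exports


@dataclass
class CentralityResult:
    node_labels: tuple[str, ...]
    degree: np.ndarray
    betweenness: np.ndarray

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "node": self.node_labels,
                "degree": self.degree,
                "betweenness": self.betweenness,
            }
        )
        df["degree_rank"] = [
            rank_nodes(self.node_labels, self.degree).index(lab) + 1
            for lab in self.node_labels
        ]
        df["betweenness_rank"] = [
            rank_nodes(self.node_labels, self.betweenness).index(lab) + 1
            for lab in self.node_labels
        ]
        return df


def centralities(network: CorrelationNetwork) -> CentralityResult:
    """Degree and betweenness on the thresholded network."""
    if network.adjacency is None:
        raise NetworkError("network has no adjacency; call threshold() first")
    return CentralityResult(
        network.node_labels,
        degree_centrality(network.adjacency),
        betweenness_centrality(network.adjacency),
    )


def to_json_dict(
    network: CorrelationNetwork,
    positions: np.ndarray | None = None,
    omega: float = 5.0,
) -> dict:
    """JSON-serialisable dict of nodes (with positions) and styled edges."""
    nodes = []
    for i, lab in enumerate(network.node_labels):
        node = {"id": lab}
        if positions is not None:
            node["x"], node["y"] = float(positions[i, 0]), float(positions[i, 1])
        nodes.append(node)
    edges = []
    for s in edge_styles(network, omega):
        edge = {
            "source": network.node_labels[s.i],
            "target": network.node_labels[s.j],
            "r": None if math.isnan(network.r[s.i, s.j]) else float(network.r[s.i, s.j]),
            "width": s.width,
            "sign": s.sign,
            "intensity": s.intensity,
        }
        if network.adjacency is not None:
            edge["thresholded"] = bool(network.adjacency[s.i, s.j])
        edges.append(edge)
    out = {"nodes": nodes, "edges": edges}
    if network.theta is not None:
        out["theta"] = network.theta
        out["density"] = network.density
    return out


def write_json(network: CorrelationNetwork, path, positions=None, omega: float = 5.0) -> None:
    with open(path, "w") as fh:
        json.dump(to_json_dict(network, positions, omega), fh, indent=1)


def write_graphml(network: CorrelationNetwork, path, positions=None) -> None:
    """Minimal GraphML export: nodes with optional x/y, edges with r and
    the thresholded flag."""
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    keys = [("d_r", "edge", "r", "double"), ("d_th", "edge", "thresholded", "boolean"),
            ("d_x", "node", "x", "double"), ("d_y", "node", "y", "double")]
    for kid, dom, name, typ in keys:
        ET.SubElement(root, "key", id=kid, **{"for": dom, "attr.name": name, "attr.type": typ})
    graph = ET.SubElement(root, "graph", edgedefault="undirected")
    for i, lab in enumerate(network.node_labels):
        node = ET.SubElement(graph, "node", id=lab)
        if positions is not None:
            for kid, val in (("d_x", positions[i, 0]), ("d_y", positions[i, 1])):
                data = ET.SubElement(node, "data", key=kid)
                data.text = repr(float(val))
    n = network.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            rij = network.r[i, j]
            if math.isnan(rij):
                continue
            edge = ET.SubElement(
                graph, "edge",
                source=network.node_labels[i], target=network.node_labels[j],
            )
            data = ET.SubElement(edge, "data", key="d_r")
            data.text = repr(float(rij))
            if network.adjacency is not None:
                data = ET.SubElement(edge, "data", key="d_th")
                data.text = "true" if network.adjacency[i, j] else "false"
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
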