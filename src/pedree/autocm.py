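"""Auto Contractive Map: association strengths and the semantic connectivity map.

The Auto-CM is an unsupervised three-layer network (input → hidden → output,
all of width N) whose training *contracts* each record through two banks of
weights bounded by a contraction parameter C. After training, the
hidden→output weight matrix encodes pairwise association strengths; turning
strengths into distances (d = 1 − strength) and extracting the minimum
spanning tree yields a "semantic connectivity map" in which each variable
hangs off the variable it is most strongly bound to.

Update rules, for one record m (components scaled to [0,1]):

    hidden:   h_s  = m_s · (1 − v_s/C)
    net:      Net_j = (1/N) · Σ_s h_s · (1 − w_sj/C)
    output:   o_j  = h_j · (1 − Net_j/C)
    Δv_s  = α · m_s · (1 − v_s/C)
    Δw_sj = α · h_s · o_j · (1 − w_sj/C)

Weights start at zero (training is fully deterministic) and remain in
[0, C]; training stops when the mean output activation — the residual the
network has not yet absorbed — falls below a tolerance. The mono-weights v
are the contraction clock: each absorbs its input at rate α and grows
towards C, squeezing the hidden layer (and hence the output) to zero,
while w accrues pairwise association mass Hebbian-style, in proportion to
how strongly two variables co-activate before the input is fully absorbed
— so co-varying variables end up with the largest hidden→output weights.
Net is normalised by the fan-in N so that the output tracks the
contracting hidden layer and the output energy decays monotonically.
These rules are this package's definition of the algorithm; they satisfy
the documented contract (contraction, determinism, correlation ordering)
and are isolated here so a variant transcription can be swapped in without
touching consumers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateVariableError, InvalidConfigError, DataContractError


def scale_unit(data: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale each column to [0, 1]; returns (scaled, mins, ranges)."""
    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    mins = x.min(axis=0)
    rng = x.max(axis=0) - mins
    flat = np.nonzero(rng == 0)[0]
    if flat.size:
        raise DegenerateVariableError(
            f"constant column(s): {[names[i] for i in flat]}"
        )
    return (x - mins) / rng, mins, rng


@dataclass
class AutoCmModel:
    """A trained Auto-CM: mono weights v (N,) and full weights w (N, N)."""

    variable_names: list[str]
    v: np.ndarray
    w: np.ndarray
    C: float
    epochs_run: int
    converged: bool
    energy_history: list[float] = field(default_factory=list)


def train_autocm(
    scaled: np.ndarray,
    variable_names: list[str] | None = None,
    C: float | None = None,
    max_epochs: int = 200,
    tolerance: float = 1e-4,
    learning_rate: float = 0.1,
) -> AutoCmModel:
    """Train an Auto-CM on a [0,1]-scaled matrix (records × variables).

    ``C`` defaults to the number of variables. Records are presented in
    fixed order each epoch; with zero-initialised weights the whole
    procedure is deterministic.
    """
    x = np.asarray(scaled, dtype=float)
    if x.ndim != 2:
        raise InvalidConfigError("scaled matrix must be 2-D")
    if x.min() < -1e-12 or x.max() > 1 + 1e-12:
        raise InvalidConfigError("entries must lie in [0, 1]; apply scale_unit first")
    n_rec, n_var = x.shape
    if C is None:
        C = float(n_var)
    if C < 1:
        raise InvalidConfigError(f"contraction parameter C must be >= 1, got {C}")
    names = variable_names if variable_names is not None else [f"x{i}" for i in range(n_var)]

    v = np.zeros(n_var)
    w = np.zeros((n_var, n_var))
    history: list[float] = []
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        energy = 0.0
        for m in x:
            h = m * (1.0 - v / C)
            net = (h @ (1.0 - w / C)) / n_var
            out = h * (1.0 - net / C)
            v += learning_rate * m * (1.0 - v / C)
            w += learning_rate * h[:, None] * out[None, :] * (1.0 - w / C)
            np.clip(v, 0.0, C, out=v)
            np.clip(w, 0.0, C, out=w)
            energy += float(np.mean(np.abs(out)))
        history.append(energy / n_rec)
        if history[-1] < tolerance:
            converged = True
            break
    if max_epochs == 0:
        epoch = 0
    return AutoCmModel(names, v, w, C, epoch, converged, history)


def distance_matrix(model: AutoCmModel) -> np.ndarray:
    """Symmetric variable distances in [0,1]: d = 1 − ((w_ij + w_ji)/2)/C."""
    strength = (model.w + model.w.T) / (2.0 * model.C)
    d = 1.0 - strength
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ConnectivityMap:
    """The MST over variable distances, with strengths = 1 − distance."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, strength in [0,1])
    is_tree: bool
    central_node: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "nodes": self.nodes,
            "edges": [{"source": a, "target": b, "strength": s} for a, b, s in self.edges],
            "central_node": self.central_node,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_dot(self, path: str | Path | None = None) -> str:
        lines = ["graph connectivity {"]
        for node in self.nodes:
            shape = "doublecircle" if node == self.central_node else "ellipse"
            lines.append(f'  "{node}" [shape={shape}];')
        for a, b, s in self.edges:
            lines.append(f'  "{a}" -- "{b}" [label="{s:.3f}"];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def minimum_spanning_tree(
    distances: np.ndarray, variable_names: list[str] | None = None
) -> ConnectivityMap:
    """Kruskal MST of a symmetric zero-diagonal distance matrix.

    Edges are inserted in lexicographic (i, j) order, so equal-weight ties
    resolve lexicographically (stable sort) — reproducible across platforms.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise DataContractError("distance matrix must be square and symmetric")
    if np.any(d < 0) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise DataContractError("distances must be non-negative with zero diagonal")
    names = variable_names if variable_names is not None else [f"x{i}" for i in range(n)]

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(d[i, j]))
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted((min(a, b), max(a, b)) for a, b in tree.edges)
    cm = ConnectivityMap(
        nodes=list(names),
        edges=[(names[a], names[b], 1.0 - float(d[a, b])) for a, b in edges],
        is_tree=True,
    )
    cm.central_node = central_node(cm)
    return cm


def central_node(cmap: ConnectivityMap) -> str:
    """The variable left after recursively pruning leaves from the tree.

    When two nodes remain, the one with the larger summed incident strength
    wins; remaining ties break lexicographically.
    """
    n = len(cmap.nodes)
    if not cmap.is_tree or len(cmap.edges) != n - 1:
        raise DataContractError("central node is defined for trees only")
    if n == 1:
        return cmap.nodes[0]
    adj: dict[str, set[str]] = {v: set() for v in cmap.nodes}
    strength_sum = {v: 0.0 for v in cmap.nodes}
    for a, b, s in cmap.edges:
        adj[a].add(b)
        adj[b].add(a)
        strength_sum[a] += s
        strength_sum[b] += s
    alive = set(cmap.nodes)
    while len(alive) > 2:
        leaves = [v for v in alive if len(adj[v]) <= 1]
        for leaf in leaves:
            alive.discard(leaf)
            for nb in adj[leaf]:
                adj[nb].discard(leaf)
            adj[leaf] = set()
    if len(alive) == 1:
        return next(iter(alive))
    a, b = sorted(alive)
    return b if strength_sum[b] > strength_sum[a] else a


def brute_force_mst_weight(distances: np.ndarray) -> float:
    """Exhaustive minimum spanning-tree weight (test oracle; feasible N ≤ 8)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(all_edges, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = min(best, sum(d[i, j] for i, j in combo))
    return float(best)


def semantic_map(
    data: pd.DataFrame,
    C: float | None = None,
    max_epochs: int = 200,
    tolerance: float = 1e-4,
) -> tuple[AutoCmModel, ConnectivityMap]:
    """Convenience: scale → train → distances → MST, in one call."""
    scaled, _, _ = scale_unit(data)
    model = train_autocm(scaled, list(data.columns), C=C,
                         max_epochs=max_epochs, tolerance=tolerance)
    return model, minimum_spanning_tree(distance_matrix(model), model.variable_names)
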