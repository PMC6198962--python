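"""Chlorotype distance matrices, minimum spanning networks, centrality.

Two metrics are supported on equal-length chlorotype strings:

* ``hamming`` — count of differing panel positions (novel symbols are
  distinct from both ``0`` and ``1``);
* ``nei`` — per-site haploid Nei distance, ``-ln(m/L)`` with ``m``
  matching positions out of ``L``; strings with no matching position get
  an infinite sentinel and their pair is excluded from networks.

A minimum spanning network (MSN) is a minimum spanning tree augmented
with every alternative edge whose weight ties (within 1e-9) an edge it
could replace: Kruskal processed by weight class, adding all
component-bridging edges of a class before merging the components the
class connects. Edges added in the same class form one tie group.

Eigenvector centrality is computed on edge affinities (default
``1/weight``; zero-weight edges get the largest finite affinity) by
power iteration to relative tolerance 1e-10, normalised so the maximum
score is 1. Disconnected networks are scored per component with a
warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "HaploNetwork",
    "pairwise_distances",
    "squared_distance_matrix",
    "minimum_spanning_network",
    "eigenvector_centrality",
]

log = logging.getLogger(__name__)

TIE_TOL = 1e-9


def _encode(chlorotypes: Sequence[str]) -> np.ndarray:
    lengths = {len(c) for c in chlorotypes}
    if len(lengths) > 1:
        raise ValueError(f"chlorotype length mismatch: {sorted(lengths)}")
    return np.array([list(c) for c in chlorotypes])


def squared_distance_matrix(chlorotypes: Sequence[str], metric: str = "hamming") -> np.ndarray:
    """Pairwise squared distances between chlorotype strings.

    ``hamming`` counts differing positions (= squared Euclidean on 0/1
    vectors); ``nei`` uses -ln(m/L) directly as the squared distance.
    """
    X = _encode(chlorotypes)
    diff = (X[:, None, :] != X[None, :, :]).sum(axis=-1).astype(float)
    if metric == "hamming":
        return diff
    if metric == "nei":
        L = X.shape[1]
        with np.errstate(divide="ignore"):
            d = -np.log((L - diff) / L)
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def pairwise_distances(chlorotypes: Sequence[str], metric: str = "hamming") -> DistanceMatrix:
    if any("?" in c for c in chlorotypes):
        raise ValueError("chlorotypes contain '?'; distances are undefined")
    return DistanceMatrix(tuple(chlorotypes), squared_distance_matrix(chlorotypes, metric), metric)


@dataclass
class HaploNetwork:
    """MSN over chlorotypes: a weighted :class:`networkx.Graph` whose nodes
    carry frequencies (and optional per-group composition) and whose
    edges carry weight and tie-group id."""

    graph: nx.Graph
    metric: str
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "weight": d["weight"], "tie_group": d["tie_group"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "tie_group"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            row = {"chlorotype": n, "frequency": d.get("frequency", 1)}
            comp = d.get("composition")
            if comp:
                row["composition"] = ";".join(f"{g}:{c}" for g, c in sorted(comp.items()))
            rows.append(row)
        return pd.DataFrame(rows)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            comp = d.pop("composition", None)
            if comp:
                d["composition"] = ";".join(f"{k}:{v}" for k, v in sorted(comp.items()))
        nx.write_graphml(g, str(path))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def minimum_spanning_network(
    dist: DistanceMatrix,
    node_freqs: Mapping[str, int] | None = None,
    node_composition: Mapping[str, Mapping[str, int]] | None = None,
) -> HaploNetwork:
    """Build the tie-retaining minimum spanning network of a distance
    matrix. Pairs at infinite distance are excluded with a warning; node
    frequencies default to 1."""
    labels = list(dist.labels)
    if not labels:
        raise ValueError("empty distance matrix")
    n = len(labels)
    d = dist.values

    finite_pairs = []
    excluded = []
    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(d[i, j]):
            finite_pairs.append((i, j))
        else:
            excluded.append((labels[i], labels[j]))
    if excluded:
        log.warning("excluding %d infinite-distance pairs from the network", len(excluded))

    g = nx.Graph()
    for name in labels:
        freq = int(node_freqs.get(name, 1)) if node_freqs else 1
        attrs = {"frequency": freq}
        if node_composition and name in node_composition:
            attrs["composition"] = dict(node_composition[name])
        g.add_node(name, **attrs)

    if finite_pairs:
        weights = sorted({float(d[i, j]) for i, j in finite_pairs})
        # collapse weights closer than the tie tolerance into one class
        classes: list[float] = []
        for w in weights:
            if not classes or w - classes[-1] > TIE_TOL:
                classes.append(w)
        uf = _UnionFind(n)
        for tie_group, w in enumerate(classes):
            bridging = [
                (i, j)
                for i, j in finite_pairs
                if abs(d[i, j] - w) <= TIE_TOL and uf.find(i) != uf.find(j)
            ]
            for i, j in bridging:
                g.add_edge(labels[i], labels[j], weight=float(d[i, j]), tie_group=tie_group)
            for i, j in bridging:
                uf.union(i, j)
            if len({uf.find(i) for i in range(n)}) == 1:
                break
    return HaploNetwork(g, dist.metric, excluded)


def _component_scores(sub: nx.Graph, affinity: str, rtol: float) -> dict[str, float]:
    nodes = list(sub.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    idx = {n: i for i, n in enumerate(nodes)}
    weights = [d["weight"] for _, _, d in sub.edges(data=True)]
    positive = [w for w in weights if w > 0]
    if affinity == "inverse":
        max_aff = max((1.0 / w for w in positive), default=1.0)
        aff = lambda w: 1.0 / w if w > 0 else max_aff
    elif affinity == "max-minus":
        wmax = max(weights, default=0.0)
        wmin = min(weights, default=0.0)
        # keep the weakest edge strictly positive so the graph stays connected
        offset = (wmax - wmin) * 1e-3 or 1.0
        aff = lambda w: wmax - w + offset
    else:
        raise ValueError(f"unknown affinity {affinity!r}")

    A = np.zeros((len(nodes), len(nodes)))
    for a, b, dd in sub.edges(data=True):
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = aff(dd["weight"])
    # diagonal shift: keeps the principal eigenvector, makes the dominant
    # eigenvalue strictly largest in magnitude so power iteration cannot
    # oscillate on bipartite graphs
    shift = A.sum(axis=1).max()
    A = A + shift * np.eye(len(nodes))
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(10000):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.max(np.abs(y - x)) <= rtol * np.max(np.abs(y)):
            x = y
            break
        x = y
    x = np.abs(x)
    return {n: float(v) for n, v in zip(nodes, x / x.max())}


def eigenvector_centrality(
    network: HaploNetwork, affinity: str = "inverse", rtol: float = 1e-10
) -> dict[str, float]:
    """Max-normalised eigenvector centrality of the network's affinity
    matrix (principal eigenvector by power iteration)."""
    comps = list(nx.connected_components(network.graph))
    if len(comps) > 1:
        log.warning("network has %d components; scoring each separately", len(comps))
    scores: dict[str, float] = {}
    for comp in comps:
        scores.update(_component_scores(network.graph.subgraph(comp), affinity, rtol))
    return scores
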