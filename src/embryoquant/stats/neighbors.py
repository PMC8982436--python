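"""Immediate-cell-neighbor graph.

Primary definition: two cells are neighbors iff their labels touch across a
pixel edge in the label image (4-connectivity across the shared boundary).
Fallback when only centroids exist: Delaunay adjacency with edges longer
than twice the median edge length pruned. Border cells carry a ``border``
node attribute so downstream statistics can exclude them as focal cells
while keeping them as neighbors.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay


def label_adjacency_graph(label_image: np.ndarray,
                          border_labels=None) -> nx.Graph:
    lab = np.asarray(label_image)
    pairs = []
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        sel = (a != b) & (a > 0) & (b > 0)
        pairs.append(np.stack([a[sel], b[sel]], axis=1))
    pairs = np.concatenate(pairs) if pairs else np.empty((0, 2), int)
    pairs = np.unique(np.sort(pairs, axis=1), axis=0) if len(pairs) else pairs

    g = nx.Graph()
    labels = np.unique(lab)
    labels = labels[labels > 0]
    if border_labels is None:
        border_labels = set()
        for edge in (lab[0], lab[-1], lab[:, 0], lab[:, -1]):
            border_labels.update(int(v) for v in np.unique(edge) if v > 0)
    border_labels = set(int(v) for v in border_labels)
    for v in labels:
        g.add_node(int(v), border=int(v) in border_labels)
    g.add_edges_from((int(a), int(b)) for a, b in pairs)
    return g


def delaunay_graph(labels, centroids: np.ndarray, border_labels=None,
                   prune_factor: float = 2.0) -> nx.Graph:
    """Neighbor graph from centroids via Delaunay triangulation."""
    labels = [int(v) for v in labels]
    pts = np.asarray(centroids, dtype=float)
    if border_labels is None:
        border_labels = []
    border_labels = set(int(v) for v in border_labels)
    g = nx.Graph()
    for v in labels:
        g.add_node(v, border=v in border_labels)
    if len(labels) < 3:
        if len(labels) == 2:
            g.add_edge(labels[0], labels[1])
        return g
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = lengths <= prune_factor * np.median(lengths)
    for (a, b) in edges[keep]:
        g.add_edge(labels[a], labels[b])
    return g


def build_neighbor_graph(label_image: np.ndarray | None = None,
                         labels=None, centroids=None,
                         border_labels=None) -> nx.Graph:
    """Build the NeighborGraph from a label image (primary) or centroids."""
    if label_image is not None:
        return label_adjacency_graph(label_image, border_labels=border_labels)
    if centroids is None or labels is None:
        raise ValueError("need either a label image or labels + centroids")
    return delaunay_graph(labels, centroids, border_labels=border_labels)
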