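"""Neighbor-cluster dispersion statistics.

For each non-border focal cell, the cluster is the focal cell together with
its immediate neighbors (focal inclusion is a flag). Over the cluster's
mRNA counts we report the sample mean, sample variance (denominator n-1 by
default), Fano factor FF = variance/mean and coefficient of variation
CV = sd/mean. FF is 1 for Poisson counts and carries units of counts; CV is
unitless. Clusters with fewer than ``min_cluster`` members or zero mean are
recorded as missing (0/0 is not evidence of low variability), never as 0.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

DISPERSION_COLUMNS = ["label", "cluster_size", "cluster_mean",
                      "cluster_variance", "fano", "cv"]


def local_dispersion(
    cells: pd.DataFrame,
    graph: nx.Graph,
    include_focal: bool = True,
    ddof: int = 1,
    min_cluster: int = 3,
    value_col: str = "mrna_count",
) -> pd.DataFrame:
    """Per-focal-cell dispersion map over neighbor clusters.

    Border cells are excluded as focal cells but still contribute as
    neighbors. Every graph node must appear in ``cells``.
    """
    values = cells.set_index("label")[value_col]
    missing = [v for v in graph.nodes if v not in values.index]
    if missing:
        raise ValueError(f"graph nodes absent from cell table: {missing[:5]}")
    rows = []
    for node in sorted(graph.nodes):
        if graph.nodes[node].get("border", False):
            continue
        members = list(graph.neighbors(node))
        if include_focal:
            members = [node] + members
        v = values.loc[members].to_numpy(dtype=float)
        n = len(v)
        if n < min_cluster:
            rows.append((node, n, np.nan, np.nan, np.nan, np.nan))
            continue
        mean = v.mean()
        var = v.var(ddof=ddof)
        if mean == 0:
            rows.append((node, n, mean, var, np.nan, np.nan))
        else:
            rows.append((node, n, mean, var, var / mean, np.sqrt(var) / mean))
    return pd.DataFrame(rows, columns=DISPERSION_COLUMNS)


def pooled_fano(cells: pd.DataFrame, value_col: str = "mrna_count",
                ddof: int = 1) -> float:
    """Single FF over all cells pooled (the per-embryo reduction)."""
    v = cells[value_col].to_numpy(dtype=float)
    if len(v) < 2 or v.mean() == 0:
        return float("nan")
    return float(v.var(ddof=ddof) / v.mean())
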