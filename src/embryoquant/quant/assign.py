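"""Spot-to-cell assignment and per-cell count aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..synth.lattice import CellMap


def assign_spots_to_cells(spots: pd.DataFrame, label_image: np.ndarray) -> pd.DataFrame:
    """Set ``cell_label`` to the label-image value at the rounded position.

    Label 0 (outside the tissue) leaves the spot unassigned.
    """
    label_image = np.asarray(label_image)
    out = spots.copy()
    if len(out) == 0:
        out["cell_label"] = pd.Series(dtype=np.int32)
        return out
    x = np.rint(out["x"].to_numpy()).astype(int)
    y = np.rint(out["y"].to_numpy()).astype(int)
    h, w = label_image.shape
    if (x < 0).any() or (y < 0).any() or (x >= w).any() or (y >= h).any():
        raise ValueError("spot coordinates fall outside the label image")
    out["cell_label"] = label_image[y, x].astype(np.int32)
    return out


def build_cell_table(
    exon_spots: pd.DataFrame,
    label_image: np.ndarray,
    genotype: str = "",
    embryo_id: str = "",
    cellmap: CellMap | None = None,
) -> pd.DataFrame:
    """Aggregate assigned spots into a CellTable.

    ``exon_spots`` must carry ``cell_label`` and, if TS calling ran, the
    boolean ``is_ts`` column and a ``ts_count`` per-cell series can be merged
    afterwards; here mrna_count counts exon spots not flagged as TS.
    Conservation holds: sum(mrna_count) + n_flagged_ts + n_unassigned equals
    the number of exon spots.
    """
    label_image = np.asarray(label_image)
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    is_ts = exon_spots["is_ts"] if "is_ts" in exon_spots else pd.Series(
        False, index=exon_spots.index)
    counted = exon_spots.loc[(exon_spots["cell_label"] > 0) & (~is_ts)]
    mrna = counted.groupby("cell_label").size()

    if cellmap is not None:
        geom = cellmap.cells[["label", "cx", "cy", "area_px", "border"]].copy()
    else:
        areas = np.bincount(label_image.ravel())
        h, w = label_image.shape
        border_set = set()
        for edge in (label_image[0], label_image[-1],
                     label_image[:, 0], label_image[:, -1]):
            border_set.update(np.unique(edge).tolist())
        ys, xs = np.mgrid[0:h, 0:w]
        cy = np.bincount(label_image.ravel(), weights=ys.ravel())
        cx = np.bincount(label_image.ravel(), weights=xs.ravel())
        geom = pd.DataFrame({
            "label": labels,
            "cx": cx[labels] / areas[labels],
            "cy": cy[labels] / areas[labels],
            "area_px": areas[labels],
            "border": [lab in border_set for lab in labels],
        })
    geom["mrna_count"] = geom["label"].map(mrna).fillna(0).astype(int)
    geom["ts_count"] = 0
    geom["genotype"] = genotype
    geom["embryo_id"] = embryo_id
    return geom.reset_index(drop=True)


def check_conservation(exon_spots: pd.DataFrame, cells: pd.DataFrame) -> bool:
    """Every exon spot is counted exactly once: mRNA, TS-flagged, or unassigned."""
    is_ts = exon_spots["is_ts"] if "is_ts" in exon_spots else pd.Series(
        False, index=exon_spots.index)
    assigned_ts = int(((exon_spots["cell_label"] > 0) & is_ts).sum())
    unassigned = int((exon_spots["cell_label"] == 0).sum())
    return int(cells["mrna_count"].sum()) + assigned_ts + unassigned == len(exon_spots)
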