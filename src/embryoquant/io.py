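"""File formats: multi-page TIFF image stacks and CSV ground-truth/result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth.lattice import CellMap
from .synth.render import CHANNELS

CELLS_COLUMNS = ["label", "cx", "cy", "area_px", "dv", "genotype",
                 "true_mrna", "true_ts", "true_protein"]
SPOTS_COLUMNS = ["x", "y", "channel", "amplitude", "cell_label"]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (C, H, W) stack as a multi-page 16-bit TIFF (one page/channel)."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def channel(stack: np.ndarray, name: str) -> np.ndarray:
    return stack[CHANNELS.index(name)]


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def ground_truth_cells_table(cellmap: CellMap, gt_cells: pd.DataFrame) -> pd.DataFrame:
    """Join geometry and simulated state into the cells.csv schema."""
    geom = cellmap.cells[["label", "cx", "cy", "area_px", "dv", "border"]]
    merged = geom.merge(gt_cells, on="label", validate="one_to_one")
    return merged[CELLS_COLUMNS + ["border"]]


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, validating required columns; extras are preserved."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df
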