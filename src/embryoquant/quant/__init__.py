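"""Image quantification: segmentation, spot detection, TS calling, assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..synth.lattice import CellMap
from ..synth.render import CHANNELS
from .assign import assign_spots_to_cells, build_cell_table, check_conservation
from .detect import detect_spots, log_response
from .segment import SegmentationError, segment_cells
from .ts import call_transcription_sites

__all__ = [
    "SegmentationError",
    "assign_spots_to_cells",
    "build_cell_table",
    "call_transcription_sites",
    "check_conservation",
    "detect_spots",
    "log_response",
    "quantify_image",
    "segment_cells",
]


def quantify_image(
    stack: np.ndarray,
    psf_sigma_px: float,
    threshold_factor: float = 6.0,
    labels: np.ndarray | None = None,
    nuclei_mask: np.ndarray | None = None,
    coloc_radius_px: float | None = None,
    genotype: str = "",
    embryo_id: str = "",
    cellmap: CellMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full quantification of one multi-channel field of view.

    Runs segmentation (or accepts ground-truth ``labels``), detects exon and
    intron spots, calls transcription sites, assigns spots to cells, and
    aggregates counts. Returns (cells, spots) DataFrames; ``spots`` stacks
    both channels with ``is_ts`` flags on exon rows.
    """
    exon_img = stack[CHANNELS.index("exon")]
    intron_img = stack[CHANNELS.index("intron")]
    membrane_img = stack[CHANNELS.index("membrane")]
    nuclei_img = stack[CHANNELS.index("nuclei")]
    if coloc_radius_px is None:
        coloc_radius_px = 2.0 * psf_sigma_px

    label_image = segment_cells(membrane_img, nuclei_img, labels=labels)
    if nuclei_mask is None:
        nuc = np.asarray(nuclei_img, dtype=float)
        nuclei_mask = nuc > (np.median(nuc) + 0.5 * (nuc.max() - np.median(nuc)))

    exon = detect_spots(exon_img, psf_sigma_px, threshold_factor, channel="exon")
    intron = detect_spots(intron_img, psf_sigma_px, threshold_factor,
                          channel="intron")
    exon = assign_spots_to_cells(exon, label_image)
    intron = assign_spots_to_cells(intron, label_image)
    exon, ts, ts_counts = call_transcription_sites(
        exon, intron, nuclei_mask, coloc_radius_px)

    cells = build_cell_table(exon, label_image, genotype=genotype,
                             embryo_id=embryo_id, cellmap=cellmap)
    cells["ts_count"] = cells["label"].map(ts_counts).fillna(0).astype(int)
    spots = pd.concat([exon, ts.assign(is_ts=True)], ignore_index=True)
    return cells, spots
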