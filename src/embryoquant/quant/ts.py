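"""Transcription-site calling from the intron channel.

The intron probe only labels nascent transcripts, so an intron-channel spot
inside a nucleus is an active transcription site. Each TS is matched to its
nearest exon-channel spot within ``coloc_radius_px`` (nascent transcripts
carry exonic sequence too); the matched exon spot is excluded from the
mature-mRNA count. Unmatched intron spots still count as TSs. Per-cell TS
counts are capped at 4 (two alleles, four after replication); excess is
logged. Exon-channel intensity is deliberately not used as a TS criterion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

MAX_TS_PER_CELL = 4


def call_transcription_sites(
    exon_spots: pd.DataFrame,
    intron_spots: pd.DataFrame,
    nuclei_mask: np.ndarray,
    coloc_radius_px: float,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Flag TSs and count them per cell.

    Both spot tables must already carry ``cell_label``. Returns
    (exon_spots with boolean ``is_ts``, accepted intron TS table,
    per-cell ts_count Series indexed by cell label, capped at 4).
    """
    if coloc_radius_px <= 0:
        raise ValueError("coloc_radius_px must be > 0")
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    exon = exon_spots.copy()
    exon["is_ts"] = False
    if len(intron_spots) == 0:
        return exon, intron_spots.copy(), pd.Series(dtype=int, name="ts_count")

    xi = np.rint(intron_spots["x"].to_numpy()).astype(int)
    yi = np.rint(intron_spots["y"].to_numpy()).astype(int)
    h, w = nuclei_mask.shape
    inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    inside[inside] = nuclei_mask[yi[inside], xi[inside]]
    n_rejected = int((~inside).sum())
    if n_rejected:
        log.info("rejected %d intron spots outside nuclei", n_rejected)
    ts = intron_spots.loc[inside].copy()

    if len(exon) and len(ts):
        tree = cKDTree(exon[["x", "y"]].to_numpy())
        # greedy nearest matching, closest pairs first, each exon spot used once
        dist, idx = tree.query(ts[["x", "y"]].to_numpy(), k=1)
        order = np.argsort(dist, kind="stable")
        used: set[int] = set()
        flagged = np.zeros(len(exon), dtype=bool)
        for j in order:
            if dist[j] > coloc_radius_px:
                continue
            candidates = tree.query_ball_point(ts[["x", "y"]].to_numpy()[j],
                                               coloc_radius_px)
            candidates = sorted(
                (c for c in candidates if c not in used),
                key=lambda c: (ts["x"].to_numpy()[j] - exon["x"].to_numpy()[c]) ** 2
                + (ts["y"].to_numpy()[j] - exon["y"].to_numpy()[c]) ** 2,
            )
            if candidates:
                used.add(candidates[0])
                flagged[candidates[0]] = True
        exon["is_ts"] = flagged

    counts = ts.loc[ts["cell_label"] > 0].groupby("cell_label").size()
    over = counts[counts > MAX_TS_PER_CELL]
    if len(over):
        log.warning("capping ts_count at %d for cells %s",
                    MAX_TS_PER_CELL, list(over.index))
    counts = counts.clip(upper=MAX_TS_PER_CELL)
    counts.name = "ts_count"
    return exon, ts, counts
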