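"""Low-expression filtering and transcription-site subgrouping."""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

TS_CLASSES = ("0", "1", "2+")


def filter_low_expression(cells: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Drop cells with fewer than ``min_count`` mRNAs (strictly less; a cell
    at exactly ``min_count`` survives)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    kept = cells.loc[cells["mrna_count"] >= min_count].reset_index(drop=True)
    removed = len(cells) - len(kept)
    if removed:
        log.info("filter_low_expression: removed %d of %d cells (< %d mRNAs)",
                 removed, len(cells), min_count)
    if len(kept) == 0:
        log.warning("filter_low_expression: no cells left after filtering")
    return kept


def group_by_ts(cells: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition cells by transcription-site class: 0, 1, or 2+ active TSs."""
    ts = cells["ts_count"]
    if (ts < 0).any():
        raise ValueError("ts_count must be >= 0")
    return {
        "0": cells.loc[ts == 0].reset_index(drop=True),
        "1": cells.loc[ts == 1].reset_index(drop=True),
        "2+": cells.loc[ts >= 2].reset_index(drop=True),
    }
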