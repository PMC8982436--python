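"""Background-adjusted protein fluorescence and measurement-area sampling.

Each region-of-interest measurement is adjusted as

    adjusted = integrated_density - area * background_mean

Negative adjusted values (background overestimate) are allowed and flagged,
never clamped. The log10 transform used for reporting is applied only at
presentation: non-positive adjusted values propagate as missing there.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REGIONS = ("anterior", "central", "posterior")


def adjusted_fluorescence(integrated_density: float, area: float,
                          background_mean: float) -> float:
    for name, v in (("integrated_density", integrated_density),
                    ("area", area), ("background_mean", background_mean)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if area < 0:
        raise ValueError("area must be >= 0")
    adj = integrated_density - area * background_mean
    if adj < 0:
        log.debug("adjusted fluorescence negative (%.3g): background "
                  "overestimate", adj)
    return adj


def sample_measurement_areas(
    tissue_mask: np.ndarray,
    n_per_region: int = 5,
    regions: int = 3,
    box_px: int = 20,
    seed: int | None = None,
    max_tries: int = 2000,
) -> pd.DataFrame:
    """Sample non-overlapping square ROIs, ``n_per_region`` per region.

    The mask is split into equal thirds (or ``regions`` bands) along its
    long axis; ROIs are drawn uniformly among positions fully inside the
    mask and pairwise disjoint. Default 3 x 5 = 15 ROIs per embryo.
    """
    mask = np.asarray(tissue_mask, dtype=bool)
    h, w = mask.shape
    along_x = w >= h
    extent = w if along_x else h
    rng = np.random.default_rng(seed)
    # integral image for O(1) box-sum queries
    ii = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def box_full(y0, x0):
        s = (ii[y0 + box_px, x0 + box_px] - ii[y0, x0 + box_px]
             - ii[y0 + box_px, x0] + ii[y0, x0])
        return s == box_px * box_px

    placed: list[tuple[int, int]] = []
    rows = []
    for r in range(regions):
        lo = r * extent // regions
        hi = (r + 1) * extent // regions
        name = REGIONS[r] if regions == 3 else f"region{r}"
        n_done = 0
        for _ in range(max_tries):
            if n_done == n_per_region:
                break
            if along_x:
                x0 = int(rng.integers(lo, max(lo + 1, hi - box_px)))
                y0 = int(rng.integers(0, max(1, h - box_px)))
            else:
                y0 = int(rng.integers(lo, max(lo + 1, hi - box_px)))
                x0 = int(rng.integers(0, max(1, w - box_px)))
            if y0 + box_px > h or x0 + box_px > w or not box_full(y0, x0):
                continue
            if any(abs(x0 - px) < box_px and abs(y0 - py) < box_px
                   for py, px in placed):
                continue
            placed.append((y0, x0))
            rows.append((name, x0, y0, box_px))
            n_done += 1
        if n_done < n_per_region:
            raise ValueError(
                f"could not place {n_per_region} non-overlapping {box_px}px "
                f"boxes in region {name!r}")
    return pd.DataFrame(rows, columns=["region", "x0", "y0", "box_px"])


def measure_rois(image: np.ndarray, rois: pd.DataFrame,
                 background_mean: float, embryo_id: str = "") -> pd.DataFrame:
    """Integrated density and adjusted fluorescence for each ROI."""
    img = np.asarray(image, dtype=float)
    rows = []
    for _, roi in rois.iterrows():
        b = int(roi["box_px"])
        window = img[int(roi["y0"]):int(roi["y0"]) + b,
                     int(roi["x0"]):int(roi["x0"]) + b]
        integ = float(window.sum())
        area = float(window.size)
        adj = adjusted_fluorescence(integ, area, background_mean)
        rows.append((embryo_id, roi["region"], integ, area, background_mean,
                     adj, adj < 0))
    return pd.DataFrame(rows, columns=[
        "embryo_id", "region", "integrated_density", "area",
        "background_mean", "adjusted", "negative"])


def log10_adjusted(adjusted) -> np.ndarray:
    """Presentation-scale log10; non-positive values become NaN (and are
    dropped from plots only, never from the adjusted data)."""
    adj = np.asarray(adjusted, dtype=float)
    out = np.full(adj.shape, np.nan)
    pos = adj > 0
    out[pos] = np.log10(adj[pos])
    n_bad = int((~pos).sum())
    if n_bad:
        log.info("log10_adjusted: %d non-positive values set to NaN", n_bad)
    return out
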