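"""Render a simulated embryo into multi-channel images.

Channels (in order): exon, intron, membrane, nuclei. Mature mRNAs are
Gaussian spots at uniform-random positions inside their cell, drawn in the
exon channel only. Each active transcription site adds one spot inside the
nucleus disk to BOTH the intron and exon channels (nascent transcripts carry
both intron and exon sequence) with amplitude spot_amp * ts_amp_scale *
nascent_load. Membrane is the rasterized cell-boundary network, nuclei are
filled disks at cell centroids. Gaussian read noise around background_mean
is added to every channel.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from skimage.segmentation import find_boundaries

from ..config import SimConfig, rng_for
from .lattice import CellMap
from .telegraph import GroundTruth, _GENO_CODE

log = logging.getLogger(__name__)

CHANNELS = ("exon", "intron", "membrane", "nuclei")


def add_gaussian_spot(img: np.ndarray, x: float, y: float, amp: float,
                      sigma: float) -> None:
    """Accumulate a 2-D Gaussian of peak ``amp`` at sub-pixel (x, y)."""
    h, w = img.shape
    r = int(math.ceil(5 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))
    img[y0:y1, x0:x1] += amp * g


def nucleus_radius(config: SimConfig) -> float:
    return config.nucleus_radius_frac * config.cell_pitch_px


def nuclei_mask(cellmap: CellMap, config: SimConfig) -> np.ndarray:
    """Boolean mask of the nucleus disks (ground-truth geometry)."""
    h, w = cellmap.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    r2 = nucleus_radius(config) ** 2
    for _, c in cellmap.cells.iterrows():
        d2 = (xx - c.cx) ** 2 + (yy - c.cy) ** 2
        mask |= d2 <= r2
    return mask


def _too_close(x: float, y: float, placed: list, min_sep: float) -> bool:
    for px, py in placed:
        if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
            return True
    return False


def _min_dist2(x: float, y: float, placed: list) -> float:
    if not placed:
        return math.inf
    return min((px - x) ** 2 + (py - y) ** 2 for px, py in placed)


def _place(rng, sampler, placed: list, min_sep: float | None,
           tries: int = 1000) -> tuple[float, float]:
    """Draw a position via ``sampler``; with a separation constraint, accept
    the first candidate far enough from all placed spots, else after
    ``tries`` return the best (max-min-distance) candidate seen."""
    if min_sep is None:
        return sampler()
    best, best_d2 = None, -1.0
    for _ in range(tries):
        x, y = sampler()
        d2 = _min_dist2(x, y, placed)
        if d2 >= min_sep**2:
            return x, y
        if d2 > best_d2:
            best, best_d2 = (x, y), d2
    log.warning("min_spot_sep_px=%.1f could not be honored (closest %.2f px)",
                min_sep, math.sqrt(max(best_d2, 0.0)))
    return best


def render_channels(
    cellmap: CellMap,
    gt: GroundTruth,
    config: SimConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render ground truth into a (4, H, W) uint16 stack.

    Also fills ``gt.spots`` with the true molecule table (x, y, channel,
    amplitude, cell_label, is_ts) and returns it. With
    ``config.min_spot_sep_px`` set, spot positions are rejection-sampled to
    keep at least that separation between all spots in a cell's vicinity.
    """
    h, w = cellmap.shape
    geno = gt.cells["genotype"].iloc[0]
    exon = np.zeros((h, w), dtype=np.float64)
    intron = np.zeros_like(exon)
    sigma = config.psf_sigma_px
    nr = nucleus_radius(config)
    min_sep = config.min_spot_sep_px

    # per-cell pixel lists for uniform placement inside the cell; in
    # min-separation mode keep spots 2 px off the cell boundary so that
    # sub-pixel localization error cannot flip their cell assignment
    label_image = cellmap.label_image
    if min_sep is not None:
        from scipy import ndimage as ndi
        interior = (ndi.minimum_filter(label_image, size=5)
                    == ndi.maximum_filter(label_image, size=5))
        label_for_placement = np.where(interior, label_image, 0)
        # a cell squeezed below the margin falls back to its full footprint
        present = np.unique(label_for_placement)
        for lab in np.setdiff1d(cellmap.cells["label"].to_numpy(), present):
            label_for_placement[label_image == lab] = lab
    else:
        label_for_placement = label_image
    flat = label_for_placement.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    starts = np.searchsorted(sorted_labels, cellmap.cells["label"].to_numpy())
    ends = np.searchsorted(sorted_labels, cellmap.cells["label"].to_numpy(),
                           side="right")

    rows = []
    # min-separation is enforced against every spot in the image: collisions
    # across a cell boundary merge detections just like same-cell ones
    placed: list = []
    cells = cellmap.cells.reset_index(drop=True)
    for i in range(len(cells)):
        label = int(cells.at[i, "label"])
        rng = rng_for(config.seed, 3, _GENO_CODE[geno], label)

        # transcription sites first: inside the nucleus disk
        for a in range(gt.allele_on.shape[1]):
            if not gt.allele_on[i, a]:
                continue
            load = int(gt.nascent_load[i, a])
            amp = config.spot_amp * config.ts_amp_scale * load
            # keep TSs a couple of pixels inside the rim so that rounding and
            # sub-pixel refinement never push a detection outside the nucleus
            r_max = max(nr - 2.0, 0.3 * nr)

            def _ts_pos():
                rr = r_max * math.sqrt(rng.random())
                th = rng.random() * 2 * math.pi
                x = cells.at[i, "cx"] + rr * math.cos(th)
                y = cells.at[i, "cy"] + rr * math.sin(th)
                return (min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0))

            x, y = _place(rng, _ts_pos, placed, min_sep)
            placed.append((x, y))
            add_gaussian_spot(exon, x, y, amp, sigma)
            add_gaussian_spot(intron, x, y, amp, sigma)
            rows.append((x, y, "exon", amp, label, True))
            rows.append((x, y, "intron", amp, label, True))

        # mature mRNAs anywhere in the cell
        n_mrna = int(gt.cells.at[i, "true_mrna"])
        pix = order[starts[i]:ends[i]]
        if n_mrna and len(pix):
            if min_sep is not None:
                exp_spacing = math.sqrt(len(pix) / max(n_mrna, 1))
                if exp_spacing < 2 * sigma:
                    log.warning(
                        "cell %d: expected spot spacing %.1f px < 2*sigma; "
                        "counting may be unreliable", label, exp_spacing)
            def _mrna_pos():
                p = pix[rng.integers(len(pix))]
                y = p // w + rng.uniform(-0.5, 0.5)
                x = p % w + rng.uniform(-0.5, 0.5)
                return (min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0))

            for _ in range(n_mrna):
                x, y = _place(rng, _mrna_pos, placed, min_sep)
                placed.append((x, y))
                add_gaussian_spot(exon, x, y, config.spot_amp, sigma)
                rows.append((x, y, "exon", config.spot_amp, label, False))

    spots = pd.DataFrame(
        rows, columns=["x", "y", "channel", "amplitude", "cell_label", "is_ts"]
    )
    gt.spots = spots

    membrane = find_boundaries(cellmap.label_image, mode="thick")
    membrane = membrane.astype(np.float64) * config.membrane_amp
    nuclei = nuclei_mask(cellmap, config).astype(np.float64) * config.nuclei_amp

    stack = np.stack([exon, intron, membrane, nuclei])
    rng_noise = rng_for(config.seed, 4, _GENO_CODE[geno])
    stack += config.background_mean
    if config.noise_sd > 0:
        stack += rng_noise.normal(0.0, config.noise_sd, stack.shape)
    stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    return stack, spots


def render_protein_channel(
    cellmap: CellMap,
    protein: pd.Series,
    config: SimConfig,
    seed_key: tuple[int, ...] = (5,),
    px_scale: float = 0.1,
) -> np.ndarray:
    """Render per-cell protein levels as a flat per-cell intensity image."""
    levels = protein.reindex(cellmap.cells["label"]).to_numpy()
    lut = np.zeros(cellmap.cells["label"].max() + 1)
    lut[cellmap.cells["label"].to_numpy()] = levels * px_scale
    img = lut[cellmap.label_image] + config.background_mean
    rng = rng_for(config.seed, *seed_key)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)
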