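"""End-to-end experiments.

Two workflows mirror the study design: (1) the mRNA-count experiment —
independent replicate experiments of 3 WT + 3 KO embryos each, quantified,
filtered at 10 mRNAs, subgrouped by TS class, neighbor-cluster dispersion,
and genotype comparison; (2) the protein experiment — per genotype, embryos
imaged at two time points, 15 random measurement areas each, adjusted
fluorescence, log10 reporting, genotype comparison per time point.
Replicate experiments are modeled as independent seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .quant import quantify_image
from .stats import (
    build_neighbor_graph,
    compare_genotypes,
    filter_low_expression,
    group_by_ts,
    local_dispersion,
    log10_adjusted,
    measure_rois,
    pooled_fano,
    sample_measurement_areas,
)
from .synth import (
    assign_domains,
    build_cell_lattice,
    render_channels,
    render_protein_channel,
    simulate_protein,
    simulate_transcription,
)

log = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_embryo(config: SimConfig, genotype: str, seed: int):
    """One synthetic embryo: lattice, domain flags, transcription ground truth."""
    cfg = dataclasses.replace(config, seed=seed)
    cellmap = build_cell_lattice(cfg)
    flags = assign_domains(cellmap, cfg)
    gt = simulate_transcription(cellmap, flags, cfg, genotype=genotype)
    return cfg, cellmap, flags, gt


def _cells_from_ground_truth(cellmap, gt, embryo_id: str) -> pd.DataFrame:
    cells = cellmap.cells[["label", "cx", "cy", "area_px", "border"]].copy()
    cells["mrna_count"] = gt.cells["true_mrna"].to_numpy()
    cells["ts_count"] = gt.cells["true_ts"].to_numpy()
    cells["genotype"] = gt.cells["genotype"].to_numpy()
    cells["embryo_id"] = embryo_id
    return cells


def quantify_embryo(cfg: SimConfig, cellmap, gt, embryo_id: str,
                    threshold_factor: float = 6.0,
                    use_true_labels: bool = True) -> pd.DataFrame:
    """Render an embryo and run the imaging pipeline on it."""
    stack, _ = render_channels(cellmap, gt, cfg)
    labels = cellmap.label_image if use_true_labels else None
    cells, _ = quantify_image(
        stack, cfg.psf_sigma_px, threshold_factor=threshold_factor,
        labels=labels, genotype=gt.cells["genotype"].iloc[0],
        embryo_id=embryo_id, cellmap=cellmap if use_true_labels else None)
    return cells


def run_experiment_counts(
    config: SimConfig,
    seed: int = 0,
    n_embryos: int = 3,
    n_experiments: int = 2,
    min_count: int = 10,
    imaging: bool = False,
    include_focal: bool = True,
    out_dir: str | Path | None = None,
) -> dict:
    """The mRNA-count comparison experiment.

    With ``imaging=False`` the imaging stages are bypassed and ground-truth
    counts feed the statistics directly (the CSV-input mode); with
    ``imaging=True`` each embryo is rendered and quantified. Returns a report
    with per-experiment comparisons and per-embryo summaries.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"experiments": [], "per_embryo": []}
    for ex in range(n_experiments):
        pooled: dict[str, dict] = {}
        for gi, genotype in enumerate(GENOTYPES):
            all_cells, all_fano = [], []
            for e in range(n_embryos):
                embryo_id = f"exp{ex}_{genotype}_e{e}"
                child = derive_seed(seed, ex, gi, e)
                cfg, cellmap, flags, gt = simulate_embryo(config, genotype, child)
                if imaging:
                    cells = quantify_embryo(cfg, cellmap, gt, embryo_id)
                else:
                    cells = _cells_from_ground_truth(cellmap, gt, embryo_id)
                kept = filter_low_expression(cells, min_count=min_count)
                graph = build_neighbor_graph(cellmap.label_image)
                sub = graph.subgraph(kept["label"].tolist())
                disp = local_dispersion(kept, sub, include_focal=include_focal)
                groups = group_by_ts(kept)
                report["per_embryo"].append({
                    "experiment": ex, "genotype": genotype,
                    "embryo_id": embryo_id, "n_cells": len(cells),
                    "n_kept": len(kept),
                    "median_count": float(kept["mrna_count"].median())
                    if len(kept) else float("nan"),
                    "pooled_fano": pooled_fano(kept),
                    "ts_class_sizes": {k: len(v) for k, v in groups.items()},
                })
                if out_dir is not None:
                    recolor = kept[["label", "mrna_count", "ts_count"]].merge(
                        disp[["label", "fano", "cv"]], on="label", how="left")
                    recolor.to_csv(out_dir / f"recolor_{embryo_id}.csv",
                                   index=False)
                all_cells.append(kept)
                all_fano.append(disp["fano"].dropna())
            pooled[genotype] = {
                "counts": pd.concat(all_cells)["mrna_count"].to_numpy()
                if all_cells else np.array([]),
                "fano": pd.concat(all_fano).to_numpy()
                if all_fano else np.array([]),
            }
        exp_report = {"experiment": ex}
        for stat in ("counts", "fano"):
            try:
                res = compare_genotypes(pooled["WT"][stat], pooled["KO"][stat])
                exp_report[stat] = res.as_dict()
            except ValueError as err:
                exp_report[stat] = {"error": str(err)}
        report["experiments"].append(exp_report)
    return report


def estimate_background(image: np.ndarray, outside_mask: np.ndarray,
                        n: int = 5, box_px: int = 16,
                        seed: int | None = None) -> float:
    """Mean pixel intensity over ``n`` random boxes outside the tissue of
    interest (the per-picture background measurements)."""
    rois = sample_measurement_areas(outside_mask, n_per_region=n, regions=1,
                                   box_px=box_px, seed=seed)
    img = np.asarray(image, dtype=float)
    means = [img[r.y0:r.y0 + r.box_px, r.x0:r.x0 + r.box_px].mean()
             for r in rois.itertuples()]
    return float(np.mean(means))


def run_experiment_protein(
    config: SimConfig,
    seed: int = 0,
    n_embryos: int = 3,
    t_early: float | None = None,
    t_late: float | None = None,
    box_px: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """The protein-fluorescence comparison experiment.

    ``t_early`` defaults to the midpoint between the KO and WT onsets
    (KO-only signal); ``t_late`` to 1.5x the later onset (both expressing).
    ``box_px`` defaults to a quarter of the cell pitch so the 15 measurement
    areas fit inside the expression stripe at any tissue size.
    """
    if box_px is None:
        box_px = max(6, config.cell_pitch_px // 4)
    if t_early is None:
        t_early = 0.5 * (config.protein_onset_wt + config.protein_onset_ko)
    if t_late is None:
        t_late = 1.5 * max(config.protein_onset_wt, config.protein_onset_ko)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"time_points": {}}
    for ti, t in enumerate((t_early, t_late)):
        measurements = {}
        for gi, genotype in enumerate(GENOTYPES):
            frames = []
            for e in range(n_embryos):
                embryo_id = f"{genotype}_t{ti}_e{e}"
                child = derive_seed(seed, 100 + ti, gi, e)
                cfg = dataclasses.replace(config, seed=child)
                cellmap = build_cell_lattice(cfg)
                flags = assign_domains(cellmap, cfg)
                protein = simulate_protein(flags, cfg, genotype=genotype,
                                           t_query=t)
                img = render_protein_channel(cellmap, protein, cfg)
                active = flags.set_index("label")["rho"]
                lut = np.zeros(cellmap.cells["label"].max() + 1, dtype=bool)
                lut[active.index.to_numpy()] = active.to_numpy()
                rho_mask = lut[cellmap.label_image]
                bg = estimate_background(img, ~rho_mask, n=5, box_px=box_px,
                                         seed=derive_seed(child, 7))
                rois = sample_measurement_areas(
                    rho_mask, n_per_region=5, regions=3, box_px=box_px,
                    seed=derive_seed(child, 8))
                frames.append(measure_rois(img, rois, bg, embryo_id=embryo_id))
            table = pd.concat(frames, ignore_index=True)
            table["log10_adjusted"] = log10_adjusted(table["adjusted"])
            measurements[genotype] = table
            if out_dir is not None:
                table.to_csv(out_dir / f"protein_{genotype}_t{ti}.csv",
                             index=False)
        res = compare_genotypes(measurements["WT"]["adjusted"],
                                measurements["KO"]["adjusted"])
        report["time_points"][f"t{ti}"] = {
            "t_query": float(t),
            "n_measurements": {g: len(m) for g, m in measurements.items()},
            "median_log10_adjusted": {
                g: float(np.nanmedian(m["log10_adjusted"]))
                for g, m in measurements.items()},
            "comparison": res.as_dict(),
        }
        report.setdefault("tables", {})[f"t{ti}"] = measurements
    return report
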