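"""Allele-resolved bursty transcription under the two-state telegraph model.

Each allele switches OFF<->ON at rates k_on/k_off, transcribes at k_tx while
ON, and transcripts decay first-order at k_deg. The sampler is exact: the
promoter path is simulated event-by-event (exponential dwell times), and the
mRNA count at t_end is then drawn from its exact conditional distribution —
births along the path form a Cox process and each transcript survives to
t_end independently with probability exp(-k_deg (t_end - birth)), so the
count given the path is Poisson with mean

    k_tx * integral over ON time of exp(-k_deg (t_end - s)) ds.

Starting from zero transcripts with the promoter initialized from its
stationary law, t_end >> 1/k_deg yields stationary counts:

    mean  = n_alleles * p_on * k_tx / k_deg,          p_on = k_on/(k_on+k_off)
    var   = mean * (1 + k_tx k_off / ((k_on+k_off)(k_on+k_off+k_deg)))

Cells flagged inactive for the gene transcribe at a basal "leaky" rate
(leak_frac * k_tx) and never display an active transcription site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import ConfigError, SimConfig, rng_for
from .lattice import CellMap

_GENO_CODE = {"WT": 0, "KO": 1}


@dataclass
class GroundTruth:
    """True per-cell expression state of one simulated embryo.

    ``cells``: label, genotype, rho_active (domain flag), true_mrna,
    true_ts (number of ON alleles displayed as transcription sites),
    true_protein (filled by the protein stage, else 0).
    ``allele_on``: (n_cells, n_alleles) ON indicators at t_end.
    ``nascent_load``: same shape; nascent transcripts at each active TS
    (0 where inactive).
    ``spots``: per-molecule table, filled in by the renderer.
    """

    cells: pd.DataFrame
    allele_on: np.ndarray
    nascent_load: np.ndarray
    spots: pd.DataFrame | None = None


def _on_exposure(rng: np.random.Generator, k_on: float, k_off: float,
                 k_deg: float, t_end: float) -> tuple[float, int]:
    """Simulate one allele's promoter path on [0, t_end].

    Returns (I, on_at_end) where I = integral over ON time of
    exp(-k_deg (t_end - s)) ds, the decay-weighted ON exposure.
    """
    p_on = 0.5 if k_on + k_off == 0 else k_on / (k_on + k_off)
    state = 1 if rng.random() < p_on else 0
    if k_on + k_off == 0:
        # frozen promoter
        if state == 0:
            return 0.0, 0
        if k_deg == 0:
            return t_end, 1
        return (1.0 - np.exp(-k_deg * t_end)) / k_deg, 1

    t = 0.0
    I = 0.0
    # draw dwell times in blocks; expected event count is (k_on+k_off)*t_end
    block = max(16, int((k_on + k_off) * t_end * 1.5) + 10)
    while t < t_end:
        waits = rng.exponential(1.0, size=block)
        for u in waits:
            rate = k_off if state == 1 else k_on
            dwell = np.inf if rate == 0 else u / rate
            t1 = min(t + dwell, t_end)
            if state == 1 and t1 > t:
                if k_deg == 0:
                    I += t1 - t
                else:
                    I += (np.exp(-k_deg * (t_end - t1))
                          - np.exp(-k_deg * (t_end - t))) / k_deg
            t = t1
            if t >= t_end:
                break
            state = 1 - state
    return I, state


def simulate_transcription(
    cellmap: CellMap,
    flags: pd.DataFrame,
    config: SimConfig,
    genotype: str = "WT",
    gene: str = "rho",
) -> GroundTruth:
    """Simulate per-allele transcription for every cell of an embryo.

    ``flags`` is the output of :func:`assign_domains`; cells inactive for
    ``gene`` transcribe at the basal leak rate with no visible TS. Each
    cell draws from its own RNG stream keyed by (seed, genotype, label), so
    results for a given cell do not depend on the rest of the lattice.
    """
    genotype = genotype.upper()
    if genotype not in _GENO_CODE:
        raise ConfigError(f"genotype must be WT or KO, got {genotype!r}")
    if config.t_end <= 0:
        raise ConfigError("t_end must be > 0")
    k_deg = config.k_deg(genotype)
    active = (
        flags.set_index("label")[gene]
        .reindex(cellmap.cells["label"])
        .to_numpy()
    )
    n = cellmap.n_cells
    na = config.n_alleles
    counts = np.zeros(n, dtype=np.int64)
    allele_on = np.zeros((n, na), dtype=np.int8)
    nascent = np.zeros((n, na), dtype=np.int64)

    for i, label in enumerate(cellmap.cells["label"].to_numpy()):
        rng = rng_for(config.seed, 2, _GENO_CODE[genotype], int(label))
        k_tx = config.k_tx if active[i] else config.leak_frac * config.k_tx
        for a in range(na):
            I, on = _on_exposure(rng, config.k_on, config.k_off, k_deg,
                                 config.t_end)
            counts[i] += rng.poisson(k_tx * I)
            # a TS is visible only if the allele is ON and actually loaded
            if active[i] and on and k_tx > 0:
                allele_on[i, a] = 1
                nascent[i, a] = 1 + rng.poisson(config.nascent_mean)

    cells = pd.DataFrame(
        {
            "label": cellmap.cells["label"].to_numpy(),
            "genotype": genotype,
            "rho_active": active,
            "true_mrna": counts,
            "true_ts": allele_on.sum(axis=1),
            "true_protein": 0.0,
        }
    )
    return GroundTruth(cells=cells, allele_on=allele_on, nascent_load=nascent)
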