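"""Deterministic protein accumulation.

Protein appears in rho-active cells only, starting at a genotype-specific
onset time (earlier in the KO). After onset it follows linear birth-death
dynamics fed by the closed-form stationary mean mRNA of the genotype:

    p(t) = (k_translate * m_bar / k_pdeg) * (1 - exp(-k_pdeg (t - onset)))

so the t -> infinity limit is k_translate * m_bar / k_pdeg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ConfigError, SimConfig


def simulate_protein(
    flags: pd.DataFrame,
    config: SimConfig,
    genotype: str = "WT",
    t_query: float = 0.0,
    gene: str = "rho",
) -> pd.Series:
    """Per-cell protein level (arbitrary units) at time ``t_query`` minutes.

    Returns a Series indexed by cell label; zero outside the active domain
    and before onset.
    """
    if t_query < 0:
        raise ConfigError(f"t_query must be >= 0, got {t_query!r}")
    if config.k_translate < 0 or config.k_pdeg < 0:
        raise ConfigError("protein rates must be >= 0")
    onset = config.protein_onset(genotype)
    active = flags.set_index("label")[gene]
    levels = pd.Series(0.0, index=active.index, name="protein")
    if t_query <= onset:
        return levels
    m_bar = config.stationary_mean(genotype)
    if config.k_pdeg == 0:
        p = config.k_translate * m_bar * (t_query - onset)
    else:
        p = (config.k_translate * m_bar / config.k_pdeg) * (
            1.0 - np.exp(-config.k_pdeg * (t_query - onset))
        )
    levels[active] = p
    return levels
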