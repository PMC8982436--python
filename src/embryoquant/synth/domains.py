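"""Dorsoventral expression domains.

Each gene is active in a half-open DV interval [lo, hi). The rho stripe must
be nested inside the broader mir-9a domain, so cells in the mir-9a-only band
at the ventral edge exist whenever the intervals differ.
"""

from __future__ import annotations

import pandas as pd

from ..config import ConfigError, SimConfig
from .lattice import CellMap


def assign_domains(cellmap: CellMap, config: SimConfig) -> pd.DataFrame:
    """Flag each cell for each gene by its DV coordinate.

    Returns a DataFrame indexed like ``cellmap.cells`` with one boolean
    column per gene plus the cell label. Raises ``ConfigError`` if the rho
    interval is not a subset of the mir-9a interval.
    """
    domains = config.domains
    if "rho" in domains and "mir9a" in domains:
        (rlo, rhi), (mlo, mhi) = domains["rho"], domains["mir9a"]
        if not (mlo <= rlo and rhi <= mhi):
            raise ConfigError("rho domain must be contained in the mir9a domain")
    dv = cellmap.cells["dv"].to_numpy()
    flags = pd.DataFrame({"label": cellmap.cells["label"].to_numpy()})
    for gene, (lo, hi) in domains.items():
        flags[gene] = (dv >= lo) & (dv < hi)
    return flags
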