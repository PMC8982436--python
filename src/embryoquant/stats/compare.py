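"""Genotype comparison by the Mann-Whitney U rank-sum test.

Two-sided by default; exact enumeration when both samples have n <= 8 and
no ties, otherwise the normal approximation with tie correction and
continuity correction. The effect summary reports both medians and the
Hodges-Lehmann shift (median of all pairwise KO - WT differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ComparisonResult:
    statistic: float          # Mann-Whitney U for the first (WT) sample
    p_value: float
    method: str               # "exact" | "asymptotic"
    n_wt: int
    n_ko: int
    median_wt: float
    median_ko: float
    hl_shift: float           # median of pairwise (KO - WT) differences

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_genotypes(values_wt, values_ko, alternative: str = "two-sided",
                      method: str = "auto") -> ComparisonResult:
    """Rank-sum comparison of two samples (e.g. per-cell counts or FFs).

    NaNs are dropped; empty samples are an error. ``method`` may be
    "exact", "asymptotic" or "auto" (exact iff both n <= 8 and tie-free).
    """
    wt = np.asarray(values_wt, dtype=float)
    ko = np.asarray(values_ko, dtype=float)
    wt = wt[np.isfinite(wt)]
    ko = ko[np.isfinite(ko)]
    if len(wt) == 0 or len(ko) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([wt, ko]))) == len(wt) + len(ko)
        method = "exact" if (len(wt) <= 8 and len(ko) <= 8 and tie_free) \
            else "asymptotic"
    res = sps.mannwhitneyu(wt, ko, alternative=alternative, method=method)
    diffs = ko[None, :] - wt[:, None]
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_wt=len(wt),
        n_ko=len(ko),
        median_wt=float(np.median(wt)),
        median_ko=float(np.median(ko)),
        hl_shift=float(np.median(diffs)),
    )
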