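"""Benjamini-Hochberg step-up screening at a chosen false discovery rate.

Hypotheses are sorted by p-value; the rank-i critical value is i/m * q.
The largest rank whose p-value sits at or below its critical value sets the
rejection cut: all hypotheses with the k smallest p-values are rejected,
and tied p-values share a fate. The default family is one model contrast
within one panel (e.g. M2-vs-M1 across the blood biomarkers), the
narrowest grouping consistent with per-contrast significance columns; a
pooled all-comparisons family is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import GroupingError

__all__ = ["BHResult", "bh_screen", "screen_family"]

DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class BHResult:
    """Outcome of one Benjamini-Hochberg screen (original hypothesis order)."""

    pvalues: np.ndarray
    q: float
    rank: np.ndarray            # 1-based rank of each p-value after sorting
    critical_value: np.ndarray  # rank/m * q, aligned with the hypotheses
    rejected: np.ndarray        # boolean flags, aligned with the hypotheses

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bh_screen(pvalues: Sequence[float], q: float = DEFAULT_FDR) -> BHResult:
    """Step-up screen: reject the k smallest p-values, k the largest rank
    with p(k) <= k/m * q. Ties in p share a fate."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a one-dimensional, non-empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= crit)[0]
    rejected_sorted = np.zeros(m, dtype=bool)
    if len(passing):
        k = passing[-1]
        rejected_sorted[: k + 1] = True
    # ties share a fate: anything equal to a rejected p is rejected
    if rejected_sorted.any():
        threshold = sorted_p[rejected_sorted].max()
        rejected = p <= threshold
    else:
        rejected = np.zeros(m, dtype=bool)
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    critical = rank / m * q
    return BHResult(pvalues=p, q=q, rank=rank, critical_value=critical,
                    rejected=rejected)


def screen_family(comparisons: pd.DataFrame, q: float = DEFAULT_FDR,
                  family_mode: str = "contrast") -> pd.DataFrame:
    """Screen AUC-comparison rows with BH and attach significance flags.

    ``comparisons`` needs columns ``panel``, ``contrast`` and ``p_value``.
    With ``family_mode="contrast"`` each (panel, contrast) group is its own
    family; with ``"pooled"`` all rows form one family. Returns a copy with
    ``critical_value`` and ``rejected`` columns.
    """
    required = {"panel", "contrast", "p_value"}
    missing = required - set(comparisons.columns)
    if missing:
        raise GroupingError(f"comparison table lacks columns: {sorted(missing)}")
    if family_mode not in ("contrast", "pooled"):
        raise GroupingError(f"unknown family mode {family_mode!r}")
    out = comparisons.copy()
    out["critical_value"] = np.nan
    out["rejected"] = False
    if family_mode == "pooled":
        groups: List[pd.Index] = [out.index]
    else:
        groups = [idx for _, idx in
                  out.groupby(["panel", "contrast"], sort=False).groups.items()]
    for idx in groups:
        res = bh_screen(out.loc[idx, "p_value"].to_numpy(), q=q)
        out.loc[idx, "critical_value"] = res.critical_value
        out.loc[idx, "rejected"] = res.rejected
    return out
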