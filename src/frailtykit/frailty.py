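"""Frailty-index construction from a deficit matrix.

The frailty index (FI) of a participant is the sum of their deficit values
divided by the number of deficits with data, over a stated considered item
set — e.g. 20 deficits present out of 40 considered gives FI = 0.5. An FI
is only defined when at least 80% of the considered items are non-missing
(the completeness rule, threshold inclusive); otherwise the score is an
explicit undefined sentinel (NaN in vector output), never silently zero.

Leave-one-out variants drop the biomarker under study from the considered
set, so that an FI used alongside that biomarker in a regression does not
contain it (a 23-item blood panel yields a 22-item FI, a 47-item
examination panel a 46-item FI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FrailtyKitError

COMPLETENESS_THRESHOLD = 0.8

__all__ = ["FIScore", "compute_fi", "compute_fi_vector",
           "compute_fi_excluding", "COMPLETENESS_THRESHOLD"]


@dataclass(frozen=True)
class FIScore:
    """One participant's frailty index with its audit fields.

    ``value`` is ``None`` when fewer than 80% of the considered items are
    non-missing.
    """

    numerator: float
    denominator: int
    completeness: float
    value: Optional[float]

    @property
    def defined(self) -> bool:
        return self.value is not None


def _as_row(row, items: Sequence[str]) -> np.ndarray:
    if isinstance(row, pd.Series):
        missing = [i for i in items if i not in row.index]
        if missing:
            raise FrailtyKitError(f"row lacks items: {missing}")
        return row[list(items)].to_numpy(dtype=float)
    if isinstance(row, Mapping):
        missing = [i for i in items if i not in row]
        if missing:
            raise FrailtyKitError(f"row lacks items: {missing}")
        return np.array([np.nan if row[i] is None else float(row[i])
                         for i in items])
    arr = np.asarray(row, dtype=float)
    if arr.shape != (len(items),):
        raise FrailtyKitError("row length does not match the item set")
    return arr


def compute_fi(row, items: Sequence[str]) -> FIScore:
    """Frailty index of one participant over a considered item set.

    Parameters
    ----------
    row
        Deficit values for the participant: a Series/mapping keyed by item
        name, or a plain sequence aligned with ``items``. NaN/None = missing.
    items
        The considered item set (non-empty).
    """
    if len(items) == 0:
        raise ValueError("considered item set must be non-empty")
    if len(set(items)) != len(items):
        raise ValueError("considered item set contains duplicates")
    vals = _as_row(row, items)
    present = ~np.isnan(vals)
    denominator = int(present.sum())
    numerator = float(vals[present].sum())
    completeness = denominator / len(items)
    value = (numerator / denominator
             if completeness >= COMPLETENESS_THRESHOLD else None)
    return FIScore(numerator, denominator, completeness, value)


def compute_fi_vector(matrix: pd.DataFrame, items: Sequence[str]) -> pd.DataFrame:
    """Row-wise frailty indices over a deficit matrix.

    Returns a DataFrame indexed like ``matrix`` with columns ``numerator``,
    ``denominator``, ``completeness`` and ``value`` (NaN where undefined).
    """
    if len(items) == 0:
        raise ValueError("considered item set must be non-empty")
    if len(set(items)) != len(items):
        raise ValueError("considered item set contains duplicates")
    missing = [i for i in items if i not in matrix.columns]
    if missing:
        raise FrailtyKitError(f"deficit matrix lacks items: {missing}")
    sub = matrix[list(items)].to_numpy(dtype=float)
    present = ~np.isnan(sub)
    denominator = present.sum(axis=1)
    numerator = np.nansum(sub, axis=1)
    completeness = denominator / len(items)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(completeness >= COMPLETENESS_THRESHOLD,
                         numerator / np.maximum(denominator, 1), np.nan)
    # a zero denominator can only occur below the threshold, already NaN
    return pd.DataFrame(
        {"numerator": numerator, "denominator": denominator,
         "completeness": completeness, "value": value},
        index=matrix.index,
    )


def compute_fi_excluding(matrix: pd.DataFrame, items: Sequence[str],
                         focal_item: str) -> pd.DataFrame:
    """Leave-one-out frailty index: the considered set minus the focal item."""
    if focal_item not in items:
        raise ValueError(f"focal item {focal_item!r} not in the considered set")
    reduced = [i for i in items if i != focal_item]
    return compute_fi_vector(matrix, reduced)
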