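"""Map raw biomarker values to deficit values in [0, 1].

Scalar coders (`code_binary`, `code_ordinal`, `code_normalized`) define the
semantics for one value; `code_matrix` applies a whole dictionary to a
cohort table column-wise (vectorized, but contractually identical to the
scalar coders entry by entry). Missing raw values always propagate to
missing deficits; non-numeric raw entries are treated as missing with a
warning rather than an error.

Boundary conventions: normal-range bounds are inclusive (a value on the
bound is normal); an ordinal value equal to a cut-point belongs to the
higher deficit level; normalized values beyond the reference window are
clamped to 0 or 1.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .dictionary import CodingRule, DataDictionary
from .errors import DictionaryError, SchemaError

__all__ = ["code_binary", "code_ordinal", "code_normalized", "code_value",
           "code_matrix", "panel_of_matrix"]


def _check_kind(rule: CodingRule, kind: str) -> None:
    if rule.kind != kind:
        raise DictionaryError(
            f"{rule.item_name}: rule kind is {rule.kind!r}, not {kind!r}"
        )


def code_binary(value: Optional[float], rule: CodingRule) -> float:
    """0 if the value lies inside the normal range (inclusive), else 1."""
    _check_kind(rule, "binary_range")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    lo, hi = rule.normal_range  # type: ignore[misc]
    return 0.0 if lo <= value <= hi else 1.0


def code_ordinal(value: Optional[float], rule: CodingRule) -> float:
    """Level of the highest cut-point not exceeding the value (0 below all)."""
    _check_kind(rule, "ordinal")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    idx = int(np.searchsorted(rule.cut_points, value, side="right"))
    return float(rule.levels[idx])  # type: ignore[index]


def code_normalized(value: Optional[float], rule: CodingRule) -> float:
    """Min-max normalize onto the deficit scale, clamped to [0, 1]."""
    _check_kind(rule, "normalized")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    lo, hi = rule.reference_min, rule.reference_max  # type: ignore[assignment]
    frac = (value - lo) / (hi - lo)
    frac = min(1.0, max(0.0, frac))
    return frac if rule.direction == "higher_is_deficit" else 1.0 - frac


_CODERS = {
    "binary_range": code_binary,
    "ordinal": code_ordinal,
    "normalized": code_normalized,
}


def code_value(value: Optional[float], rule: CodingRule) -> float:
    """Apply whichever scalar coder matches the rule's kind."""
    return _CODERS[rule.kind](value, rule)


def _coerce_numeric(col: pd.Series, item: str) -> pd.Series:
    coerced = pd.to_numeric(col, errors="coerce")
    bad = coerced.isna() & col.notna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-numeric entries in {item!r} treated as missing",
            stacklevel=3,
        )
    return coerced.astype(float)


def _code_column(col: pd.Series, rule: CodingRule) -> pd.Series:
    values = _coerce_numeric(col, rule.item_name)
    arr = values.to_numpy(dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if rule.kind == "binary_range":
        lo, hi = rule.normal_range  # type: ignore[misc]
        out[ok] = np.where((arr[ok] >= lo) & (arr[ok] <= hi), 0.0, 1.0)
    elif rule.kind == "ordinal":
        idx = np.searchsorted(rule.cut_points, arr[ok], side="right")
        out[ok] = np.asarray(rule.levels, dtype=float)[idx]
    else:
        lo, hi = rule.reference_min, rule.reference_max  # type: ignore[assignment]
        frac = np.clip((arr[ok] - lo) / (hi - lo), 0.0, 1.0)
        out[ok] = frac if rule.direction == "higher_is_deficit" else 1.0 - frac
    return pd.Series(out, index=col.index, name=rule.item_name)


def code_matrix(table: pd.DataFrame, dictionary: DataDictionary) -> pd.DataFrame:
    """Code every dictionary item of a cohort table into a deficit matrix.

    The result has one column per dictionary item, in dictionary order, with
    entries in [0, 1] or NaN exactly where the raw table is missing. The
    table's index (participant id) is preserved.
    """
    missing = [name for name in dictionary.item_names if name not in table.columns]
    if missing:
        raise SchemaError(f"cohort table lacks dictionary items: {missing}")
    cols = {rule.item_name: _code_column(table[rule.item_name], rule)
            for rule in dictionary}
    return pd.DataFrame(cols, index=table.index)


def panel_of_matrix(matrix: pd.DataFrame, dictionary: DataDictionary,
                    panel: str) -> pd.DataFrame:
    """Restrict a deficit matrix to one panel's items, in dictionary order."""
    names = dictionary.panel(panel).item_names
    missing = [n for n in names if n not in matrix.columns]
    if missing:
        raise SchemaError(f"deficit matrix lacks panel items: {missing}")
    return matrix[names]
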