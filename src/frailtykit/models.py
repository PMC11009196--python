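"""Weighted logistic mortality models for one focal biomarker.

Four nested models are fitted per biomarker, all on the same common sample:

* M1: age + sex
* M2: age + sex + biomarker (raw scale, linear)
* M3: age + sex + leave-one-out FI (focal biomarker excluded from the index)
* M4: age + sex + biomarker + leave-one-out FI

Analytic weights multiply each observation's Bernoulli log-likelihood
contribution; estimation is via iteratively reweighted least squares
(statsmodels GLM with variance weights). The common sample is the
intersection of participants usable by all four models — non-missing
demographics, weight, outcome and focal biomarker, and a defined
leave-one-out FI — so the models' AUCs are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coding import code_matrix
from .dictionary import DataDictionary
from .errors import DegenerateSampleError, DesignError
from .frailty import compute_fi_excluding, compute_fi_vector

MODEL_IDS = ("M1", "M2", "M3", "M4")

__all__ = ["ModelSpec", "FittedModel", "common_sample_mask",
           "fit_weighted_logistic", "fit_model_family", "MODEL_IDS"]


@dataclass(frozen=True)
class ModelSpec:
    """One of the four nested mortality models for a focal biomarker."""

    model_id: str
    focal_biomarker: Optional[str]
    panel: str

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.model_id in ("M2", "M4") and self.focal_biomarker is None:
            raise ValueError(f"{self.model_id} requires a focal biomarker")

    @property
    def predictors(self) -> List[str]:
        base = ["age", "male"]
        if self.model_id == "M2":
            return base + ["biomarker"]
        if self.model_id == "M3":
            return base + ["fi_loo"]
        if self.model_id == "M4":
            return base + ["biomarker", "fi_loo"]
        return base


@dataclass
class FittedModel:
    """A fitted weighted logistic model with per-participant risks."""

    spec: Optional[ModelSpec]
    coefficients: Dict[str, float]
    n_used: int
    converged: bool
    log_likelihood: float
    predicted_risk: np.ndarray
    index: Optional[pd.Index] = None

    def to_report(self) -> dict:
        return {
            "model_id": self.spec.model_id if self.spec else None,
            "focal_biomarker": self.spec.focal_biomarker if self.spec else None,
            "panel": self.spec.panel if self.spec else None,
            "n_used": self.n_used,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "coefficients": self.coefficients,
        }


def fit_weighted_logistic(design: pd.DataFrame, outcome, weights) -> FittedModel:
    """Maximize the weight-multiplied Bernoulli log-likelihood.

    ``design`` holds the predictor columns (an intercept is added); fitting
    uses IRLS with a relative tolerance of 1e-8 and at most 100 iterations.
    Separation is reported through ``converged=False`` (detected by a
    diverging coefficient norm), never silently truncated.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(design) != len(y) or len(design) != len(w):
        raise DesignError("design, outcome and weights must align")
    if np.any(w <= 0):
        raise DesignError("weights must be strictly positive")
    n_events = int((y == 1).sum())
    if n_events == 0 or n_events == len(y):
        raise DegenerateSampleError("need at least one event and one non-event")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("rank-deficient design matrix")
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    coefs = dict(zip(X.columns, np.asarray(res.params, dtype=float)))
    converged = bool(res.converged) and float(np.abs(res.params).max()) < 1e3
    return FittedModel(
        spec=None,
        coefficients=coefs,
        n_used=len(y),
        converged=converged,
        log_likelihood=float(res.llf),
        predicted_risk=np.asarray(res.fittedvalues, dtype=float),
        index=design.index,
    )


def common_sample_mask(cohort: pd.DataFrame, biomarker_values: pd.Series,
                       fi_loo: pd.DataFrame,
                       fi_full: Optional[pd.DataFrame] = None) -> pd.Series:
    """Participants usable by all four models for one focal biomarker.

    Requires non-missing age, sex, weight, death indicator and focal
    biomarker value, and a defined leave-one-out FI. ``fi_full`` may be
    passed for auditing but imposes no extra restriction: only the
    leave-one-out FI enters Models 3 and 4.
    """
    for obj in (biomarker_values, fi_loo):
        if not obj.index.equals(cohort.index):
            raise DesignError("inputs must be aligned on participant id")
    mask = (
        cohort["age"].notna()
        & cohort["sex"].notna()
        & cohort["weight"].notna()
        & cohort["died"].notna()
        & pd.to_numeric(biomarker_values, errors="coerce").notna()
        & fi_loo["value"].notna()
    )
    if not mask.any():
        raise DegenerateSampleError("common sample is empty")
    return mask


def fit_model_family(cohort: pd.DataFrame, dictionary: DataDictionary,
                     focal_biomarker: str,
                     deficit_matrix: Optional[pd.DataFrame] = None
                     ) -> Dict[str, FittedModel]:
    """Fit M1-M4 for one focal biomarker on their common sample.

    The panel is the focal biomarker's panel; the FI covariate excludes the
    focal item from that panel. All four models share the same participants
    and weights. A precomputed ``deficit_matrix`` (from ``code_matrix``)
    may be supplied to avoid re-coding the cohort for every biomarker.
    """
    rule = dictionary[focal_biomarker]
    panel_dict = dictionary.panel(rule.panel)
    if deficit_matrix is None:
        deficit_matrix = code_matrix(cohort, panel_dict)
    items = panel_dict.item_names
    fi_loo = compute_fi_excluding(deficit_matrix, items, focal_biomarker)
    biomarker = pd.to_numeric(cohort[focal_biomarker], errors="coerce")
    mask = common_sample_mask(cohort, biomarker, fi_loo)

    sub = cohort.loc[mask]
    base = pd.DataFrame(
        {"age": sub["age"].astype(float),
         "male": (sub["sex"] == "male").astype(float)},
        index=sub.index,
    )
    covars = {
        "M1": base,
        "M2": base.assign(biomarker=biomarker.loc[mask].astype(float)),
        "M3": base.assign(fi_loo=fi_loo.loc[mask, "value"].astype(float)),
        "M4": base.assign(biomarker=biomarker.loc[mask].astype(float),
                          fi_loo=fi_loo.loc[mask, "value"].astype(float)),
    }
    y = sub["died"].astype(float)
    w = sub["weight"].astype(float)
    fitted: Dict[str, FittedModel] = {}
    for model_id, X in covars.items():
        fm = fit_weighted_logistic(X, y, w)
        focal = None if model_id == "M1" else focal_biomarker
        fm.spec = ModelSpec(model_id, focal, rule.panel)
        fitted[model_id] = fm
    return fitted
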