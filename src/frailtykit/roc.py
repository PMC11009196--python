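"""Weighted AUC and equality testing of correlated ROC curves.

The AUC of a risk score for a binary outcome is the probability that a
randomly chosen event outranks a randomly chosen non-event, with ties
half-credited. Under analytic weights w the estimator is

    AUC = sum_{i in events} sum_{j in non-events} w_i w_j psi(s_i, s_j)
          / (sum_i w_i)(sum_j w_j),   psi = 1 if s_i > s_j, 1/2 if equal.

Rather than the O(mn) double sum, placements are computed by sorting: an
event's placement is the weighted fraction of non-events it outranks, and
symmetrically for non-events; both placement means equal the AUC.

Equality of k correlated AUCs on the same sample is tested with structural
components in the style of DeLong, DeLong and Clarke-Pearson: the AUC
covariance is assembled from weighted covariances of the event-side and
non-event-side placements across score vectors. Weights are normalized to
mean 1 internally, so effective class sizes are weight sums on the count
scale and the whole machinery is invariant to rescaling the weights; with
unit weights it reduces exactly to the classical unweighted procedure.
A pair is compared with a 1-df chi-square on the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (AlignmentError, DegenerateComparisonError,
                     UndefinedAUCError)

__all__ = ["AUCResult", "AUCComparison", "auc_weighted",
           "placement_components", "auc_covariance", "test_auc_equality",
           "test_auc_equality_joint"]


@dataclass(frozen=True)
class AUCResult:
    """A weighted AUC with its DeLong-type standard error and Wald 95% CI."""

    auc: float
    se: float
    ci95: Tuple[float, float]
    n_events: int
    n_nonevents: int


@dataclass(frozen=True)
class AUCComparison:
    """A paired AUC-equality test between two correlated risk scores."""

    label_a: str
    label_b: str
    auc_a: float
    auc_b: float
    covariance: np.ndarray
    chi2: float
    df: int
    p_value: float
    significant: Optional[bool] = None  # set after FDR screening


def _split(scores, outcome, weights):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome)
    if weights is None:
        w = np.ones(len(s))
    else:
        w = np.asarray(weights, dtype=float)
    if not (len(s) == len(y) == len(w)):
        raise AlignmentError("scores, outcome and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    w = w / w.mean()  # mean-1 normalization: scale invariance by construction
    events = y == 1
    if events.sum() == 0 or (~events).sum() == 0:
        raise UndefinedAUCError("AUC needs at least one event and one non-event")
    return s, w, events


def _placements_against(scores: np.ndarray, opp_scores: np.ndarray,
                        opp_weights: np.ndarray) -> np.ndarray:
    """Weighted fraction of the opposite class each score outranks.

    Ties receive half credit (the midrank convention).
    """
    order = np.argsort(opp_scores, kind="mergesort")
    sorted_s = opp_scores[order]
    cum_w = np.concatenate([[0.0], np.cumsum(opp_weights[order])])
    total = cum_w[-1]
    lo = np.searchsorted(sorted_s, scores, side="left")
    hi = np.searchsorted(sorted_s, scores, side="right")
    below = cum_w[lo]
    tied = cum_w[hi] - cum_w[lo]
    return (below + 0.5 * tied) / total


def placement_components(scores, outcome, weights=None
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Event-side and non-event-side structural components of the AUC.

    Returns ``(v_events, v_nonevents)``: for each event, the weighted
    fraction of non-events its score exceeds (ties half); for each
    non-event, the weighted fraction of events exceeding it. The weighted
    mean of either vector equals the AUC.
    """
    s, w, events = _split(scores, outcome, weights)
    v10 = _placements_against(s[events], s[~events], w[~events])
    # non-event placement: fraction of events ranked above it
    v01 = 1.0 - _placements_against(s[~events], s[events], w[events])
    return v10, v01


def _auc_from_placements(v10, w_events) -> float:
    return float(np.average(v10, weights=w_events))


def auc_covariance(score_sets: Sequence, outcome, weights=None) -> np.ndarray:
    """DeLong-type covariance matrix of k correlated weighted AUCs.

    ``score_sets`` are k score vectors over the same observations. The
    covariance is S10/m + S01/n, where S10 (S01) is the weighted covariance
    of event-side (non-event-side) placements across score sets and m, n
    are the weight sums of the two classes after mean-1 normalization (so
    with unit weights this is the classical estimator).
    """
    k = len(score_sets)
    if k == 0:
        raise ValueError("need at least one score vector")
    first = np.asarray(score_sets[0], dtype=float)
    for s in score_sets[1:]:
        if len(np.asarray(s)) != len(first):
            raise AlignmentError("score vectors must have equal length")
    _, w, events = _split(first, outcome, weights)
    w_e, w_n = w[events], w[~events]
    m_w, n_w = float(w_e.sum()), float(w_n.sum())
    V10 = np.empty((k, int(events.sum())))
    V01 = np.empty((k, int((~events).sum())))
    for idx, s in enumerate(score_sets):
        v10, v01 = placement_components(s, outcome, weights)
        V10[idx], V01[idx] = v10, v01

    def _weighted_cov(V: np.ndarray, wts: np.ndarray, total: float) -> np.ndarray:
        # Bessel-type correction for reliability weights: reduces to the
        # classical 1/(m-1) with unit weights; a single-member class has no
        # estimable placement variance and yields NaN entries.
        mean = (V * wts).sum(axis=1) / total
        D = V - mean[:, None]
        denom = total - float((wts ** 2).sum()) / total
        if denom <= 0:
            return np.full((V.shape[0], V.shape[0]), np.nan)
        return (D * wts) @ D.T / denom

    S10 = _weighted_cov(V10, w_e, m_w)
    S01 = _weighted_cov(V01, w_n, n_w)
    return S10 / m_w + S01 / n_w


def auc_weighted(scores, outcome, weights=None) -> AUCResult:
    """Weighted AUC with DeLong-type SE and a truncated Wald 95% CI."""
    s, w, events = _split(scores, outcome, weights)
    v10, _ = placement_components(scores, outcome, weights)
    auc = _auc_from_placements(v10, w[events])
    var = float(auc_covariance([scores], outcome, weights)[0, 0])
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return AUCResult(auc=auc, se=se, ci95=ci,
                     n_events=int(events.sum()),
                     n_nonevents=int((~events).sum()))


def auc_ci_logit(result: AUCResult) -> Tuple[float, float]:
    """Alternative 95% CI on the logit scale (respects the [0,1] bounds)."""
    a, se = result.auc, result.se
    if a <= 0.0 or a >= 1.0 or se == 0.0:
        return result.ci95
    z = stats.norm.ppf(0.975)
    logit = np.log(a / (1 - a))
    se_logit = se / (a * (1 - a))
    lo_v = 1.0 / (1.0 + np.exp(-(logit - z * se_logit)))
    hi_v = 1.0 / (1.0 + np.exp(-(logit + z * se_logit)))
    return (float(lo_v), float(hi_v))


def test_auc_equality(score_a, score_b, outcome, weights=None,
                      label_a: str = "a", label_b: str = "b"
                      ) -> AUCComparison:
    """1-df chi-square test of AUC equality for two correlated scores.

    chi2 = (AUC_a - AUC_b)^2 / var(AUC_a - AUC_b), with the variance of the
    difference from the paired placement covariance. When the two score
    vectors are identical the variance and difference are both zero and the
    test degenerates to chi2 = 0, p = 1; a zero variance with unequal AUCs
    is an error.
    """
    cov = auc_covariance([score_a, score_b], outcome, weights)
    v10a, _ = placement_components(score_a, outcome, weights)
    v10b, _ = placement_components(score_b, outcome, weights)
    s, w, events = _split(np.asarray(score_a, dtype=float), outcome, weights)
    auc_a = _auc_from_placements(v10a, w[events])
    auc_b = _auc_from_placements(v10b, w[events])
    diff = auc_a - auc_b
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if not np.isfinite(var_diff):
        raise DegenerateComparisonError(
            "difference variance not estimable (need at least two events "
            "and two non-events)"
        )
    var_diff = max(var_diff, 0.0)
    if var_diff == 0.0:
        if abs(diff) < 1e-12:
            chi2, p = 0.0, 1.0
        else:
            raise DegenerateComparisonError(
                "zero estimated variance with unequal AUCs"
            )
    else:
        chi2 = diff * diff / var_diff
        p = float(stats.chi2.sf(chi2, df=1))
    return AUCComparison(label_a=label_a, label_b=label_b,
                         auc_a=auc_a, auc_b=auc_b, covariance=cov,
                         chi2=float(chi2), df=1, p_value=float(p))


def test_auc_equality_joint(score_sets: Sequence, outcome, weights=None
                            ) -> Tuple[float, int, float]:
    """Joint chi-square test that k correlated AUCs are all equal.

    Contrasts successive differences; the statistic is the quadratic form
    of the contrast through the pseudo-inverse of its covariance. Returns
    (chi2, df, p).
    """
    k = len(score_sets)
    if k < 2:
        raise ValueError("need at least two score vectors")
    cov = auc_covariance(score_sets, outcome, weights)
    _, w, events = _split(np.asarray(score_sets[0], dtype=float),
                          outcome, weights)
    aucs = np.array([
        _auc_from_placements(
            placement_components(s, outcome, weights)[0], w[events])
        for s in score_sets
    ])
    L = np.eye(k - 1, k) - np.eye(k - 1, k, k=1)
    d = L @ aucs
    V = L @ cov @ L.T
    Vinv = np.linalg.pinv(V)
    chi2 = float(d @ Vinv @ d)
    df = int(np.linalg.matrix_rank(V))
    if df == 0:
        return 0.0, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df=df))
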