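"""Concordance-index estimators for censored survival data.

The concordance index (C-index) of a scalar marker :math:`\\eta` for a
survival time :math:`T` is the probability that, of two randomly drawn
subjects, the one predicted to live longer actually does.  This module
provides

* :func:`harrell_c` — Harrell's pair-counting estimator, which drops
  pairs whose smaller observed time is censored and is therefore
  upward-biased under censoring;
* :func:`uno_c` — Uno's inverse-probability-of-censoring-weighted (IPCW)
  estimator, which reweights the remaining usable pairs by
  :math:`\\hat G(\\tilde T_j-)^{-2}`, where :math:`\\hat G` is the
  Kaplan-Meier estimate of the censoring survival function, and is
  consistent under independent censoring;
* :func:`smoothed_risk` / :func:`smoothed_risk_gradient` — a sigmoid-smoothed,
  differentiable surrogate of the negative IPCW concordance together with
  its analytic gradient, the optimisation objective used by
  :func:`cboost.boosting.boost_cindex`.

Orientation convention: with ``orientation="survival"`` (the default)
larger marker values predict *longer* survival; ``orientation="risk"``
flips the convention so larger values predict shorter survival, and maps
any tie-free estimate ``c`` to ``1 - c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.special import expit

from .data import SurvivalSample

Orientation = Literal["survival", "risk"]

#: Sigmoid arguments are clamped to this magnitude before exponentiation;
#: beyond it the sigmoid is numerically 0 or 1.
SIGMOID_CLAMP = 40.0


class ConcordanceUndefinedError(ValueError):
    """No usable pair exists, so no concordance estimate is defined."""


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Right-continuous Kaplan-Meier step function.

    ``survival_values[k]`` is the value of the curve on
    ``[jump_times[k], jump_times[k+1])``; the curve is 1 before the first
    jump time.  Fitting with ``indicator = 1 - event`` yields the censoring
    survival function G used for IPCW.
    """

    jump_times: np.ndarray
    survival_values: np.ndarray
    n_at_fit: int

    def evaluate(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx < 0, 1.0, self.survival_values[np.maximum(idx, 0)])

    def evaluate_left(self, t) -> np.ndarray:
        """S(t-), the left limit just before t."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="left") - 1
        return np.where(idx < 0, 1.0, self.survival_values[np.maximum(idx, 0)])


@dataclass(frozen=True)
class PairWeights:
    """IPCW weights over the usable ordered subject pairs.

    A pair ``(j, i)`` is *usable* when the smaller observed time belongs to
    ``j``, is strictly smaller than ``i``'s, and ``j``'s event was observed.
    Only usable pairs are stored: ``j_idx[k], i_idx[k], weight[k]`` describe
    the k-th usable pair; all other ordered pairs implicitly carry weight 0.
    ``n_dropped`` counts usable pairs discarded because the censoring curve
    vanished at the needed time (infinite weight).
    """

    j_idx: np.ndarray
    i_idx: np.ndarray
    weight: np.ndarray
    n_subjects: int
    n_dropped: int = 0

    @property
    def n_usable(self) -> int:
        return self.j_idx.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())


@dataclass(frozen=True)
class ConcordanceResult:
    """A concordance estimate with its provenance."""

    estimate: float
    n_usable_pairs: int
    estimator: Literal["harrell", "uno", "uno_smoothed"]


def km_fit(times, indicator) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit curve of the distribution flagged by ``indicator``.

    To estimate the censoring survival function G required by Uno's
    estimator, call with ``indicator = 1 - event``.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(indicator, dtype=float)
    if t.size == 0:
        raise ValueError("cannot fit a Kaplan-Meier curve to an empty sample")
    if t.shape != d.shape:
        raise ValueError("times and indicator must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    sf = kmf.survival_function_
    jumps = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    # lifelines prepends t=0 with S=1; keep it only if 0 is a real time point
    keep = (jumps > 0) | np.isin(jumps, t)
    return KaplanMeierCurve(jumps[keep], values[keep], n_at_fit=t.shape[0])


def _usable_pairs(sample: SurvivalSample) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (j, i) of usable ordered pairs: T_j < T_i and event_j = 1.

    Pairs with tied observed times are not usable.
    """
    t = sample.observed_time
    usable = (t[:, None] < t[None, :]) & (sample.event[:, None] == 1)
    return np.nonzero(usable)


def harrell_weights(sample: SurvivalSample) -> PairWeights:
    """Unit weight on every usable pair (Harrell's convention)."""
    j_idx, i_idx = _usable_pairs(sample)
    return PairWeights(j_idx, i_idx, np.ones(j_idx.shape[0]), sample.n)


def uno_weights(
    sample: SurvivalSample,
    g_curve: KaplanMeierCurve,
    tau: float | None = None,
) -> PairWeights:
    """IPCW weights ``G(T_j-)**-2`` for Uno's estimator.

    ``g_curve`` must be the Kaplan-Meier estimate of the *censoring*
    survival function, conventionally fitted on the learning sample.
    Pairs where ``g_curve`` has dropped to 0 at the needed time would get
    infinite weight; they are dropped with a warning naming the time.  An
    optional truncation time ``tau`` restricts usable pairs to
    ``T_j < tau`` (off by default).
    """
    j_idx, i_idx = _usable_pairs(sample)
    if tau is not None:
        keep = sample.observed_time[j_idx] < tau
        j_idx, i_idx = j_idx[keep], i_idx[keep]
    g = g_curve.evaluate_left(sample.observed_time[j_idx])
    positive = g > 0
    n_dropped = int((~positive).sum())
    if n_dropped:
        t_bad = np.unique(sample.observed_time[j_idx[~positive]])
        warnings.warn(
            f"censoring curve is 0 at time(s) {t_bad[:5].tolist()}; "
            f"dropping {n_dropped} pair(s) with infinite IPCW weight",
            RuntimeWarning,
            stacklevel=2,
        )
    j_idx, i_idx, g = j_idx[positive], i_idx[positive], g[positive]
    return PairWeights(j_idx, i_idx, g ** -2.0, sample.n, n_dropped)


def _weighted_concordance(
    pw: PairWeights, eta: np.ndarray, orientation: Orientation
) -> tuple[float, int]:
    if pw.n_usable == 0 or pw.total_weight == 0:
        raise ConcordanceUndefinedError(
            "no usable pair (all smaller observed times censored or dropped); "
            "the concordance index is undefined"
        )
    d = eta[pw.i_idx] - eta[pw.j_idx]
    if orientation == "risk":
        d = -d
    concordant = pw.weight @ (d > 0)
    ties = pw.weight @ (d == 0)
    return float((concordant + 0.5 * ties) / pw.total_weight), pw.n_usable


def _check_eta(sample: SurvivalSample, eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (sample.n,):
        raise ValueError(f"eta must have length n={sample.n}, got shape {eta.shape}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite values")
    return eta


def harrell_c(
    sample: SurvivalSample, eta, orientation: Orientation = "survival"
) -> ConcordanceResult:
    """Harrell's concordance estimator.

    Counts, among usable pairs, those whose marker ordering agrees with the
    survival-time ordering; marker ties contribute 1/2.  Pairs whose smaller
    observed time is censored are ignored, which biases the estimate upward
    under censoring.
    """
    eta = _check_eta(sample, eta)
    est, n_pairs = _weighted_concordance(harrell_weights(sample), eta, orientation)
    return ConcordanceResult(est, n_pairs, "harrell")


def uno_c(
    sample: SurvivalSample,
    eta,
    g_curve: KaplanMeierCurve,
    orientation: Orientation = "survival",
    tau: float | None = None,
) -> ConcordanceResult:
    """Uno's IPCW concordance estimator.

    The weighted fraction of concordant usable pairs with weights
    ``G(T_j-)**-2``; reduces exactly to :func:`harrell_c` when no
    observation is censored (all weights 1).
    """
    eta = _check_eta(sample, eta)
    pw = uno_weights(sample, g_curve, tau=tau)
    est, n_pairs = _weighted_concordance(pw, eta, orientation)
    return ConcordanceResult(est, n_pairs, "uno")


def _pair_diffs(
    pw: PairWeights, eta: np.ndarray, sigma: float, orientation: Orientation
) -> np.ndarray:
    d = (eta[pw.i_idx] - eta[pw.j_idx]) / sigma
    if orientation == "risk":
        d = -d
    return np.clip(d, -SIGMOID_CLAMP, SIGMOID_CLAMP)


def smoothed_risk(
    sample: SurvivalSample,
    eta,
    g_curve: KaplanMeierCurve,
    sigma: float,
    orientation: Orientation = "survival",
    pair_weights: PairWeights | None = None,
) -> float:
    """Sigmoid-smoothed negative IPCW concordance in ``[-1, 0]``.

    Each usable pair's hard ordering indicator is replaced by the sigmoid of
    the orientation-signed marker difference divided by ``sigma``; the sum is
    normalised by the total pair weight.  As ``sigma -> 0`` this converges
    to ``-uno_c`` on tie-free markers.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    eta = _check_eta(sample, eta)
    pw = pair_weights if pair_weights is not None else uno_weights(sample, g_curve)
    if pw.n_usable == 0 or pw.total_weight == 0:
        raise ConcordanceUndefinedError("no usable pair; smoothed risk undefined")
    s = expit(_pair_diffs(pw, eta, sigma, orientation))
    return float(-(pw.weight @ s) / pw.total_weight)


def smoothed_risk_gradient(
    sample: SurvivalSample,
    eta,
    g_curve: KaplanMeierCurve,
    sigma: float,
    orientation: Orientation = "survival",
    pair_weights: PairWeights | None = None,
) -> np.ndarray:
    """Analytic gradient of :func:`smoothed_risk` with respect to ``eta``.

    The negative of this vector is the pseudo-response fitted by the
    component-wise boosting base-learners.  Because the loss depends only on
    pairwise differences, the gradient components always sum to zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    eta = _check_eta(sample, eta)
    pw = pair_weights if pair_weights is not None else uno_weights(sample, g_curve)
    if pw.n_usable == 0 or pw.total_weight == 0:
        raise ConcordanceUndefinedError("no usable pair; gradient undefined")
    s = expit(_pair_diffs(pw, eta, sigma, orientation))
    c = pw.weight * s * (1.0 - s) / (sigma * pw.total_weight)
    # risk = -(1/W) sum w * sig(+-(eta_i - eta_j)/sigma)
    grad = np.bincount(pw.j_idx, weights=c, minlength=sample.n) - np.bincount(
        pw.i_idx, weights=c, minlength=sample.n
    )
    if orientation == "risk":
        grad = -grad
    return grad
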