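"""Compiled inner loops (numba) with pure-numpy fallbacks.

The pairwise kernels are the hot path of both marker pre-selection and
boosting; numba compiles them to tight machine loops.  Every kernel has a
numpy twin computing the same quantity, used when numba is unavailable.
The active implementation is chosen once at import time.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap

_CLAMP = 40.0


@njit(cache=True)
def _marker_concordance_numba(i_idx, j_idx, w, X, out):  # pragma: no cover
    for k in range(i_idx.shape[0]):
        ii = i_idx[k]
        jj = j_idx[k]
        wk = w[k]
        for m in range(X.shape[1]):
            if X[ii, m] > X[jj, m]:
                out[m] += wk
            elif X[ii, m] == X[jj, m]:
                out[m] += 0.5 * wk


def marker_concordance(i_idx, j_idx, weight, markers) -> np.ndarray:
    """Per-marker weighted concordant fraction over the usable pairs.

    Entry ``m`` is ``sum_k w_k [x(i_k, m) > x(j_k, m)] / sum_k w_k`` (ties
    counting 1/2), i.e. the survival-oriented concordance estimate of marker
    ``m`` used alone as the predictor.
    """
    total = float(weight.sum())
    if HAVE_NUMBA:
        out = np.zeros(markers.shape[1])
        _marker_concordance_numba(
            i_idx.astype(np.int64), j_idx.astype(np.int64), weight, markers, out
        )
        return out / total
    out = np.empty(markers.shape[1])
    for m in range(markers.shape[1]):
        d = markers[i_idx, m] - markers[j_idx, m]
        out[m] = weight @ ((d > 0) + 0.5 * (d == 0))
    return out / total


@njit(cache=True)
def _boost_numba(  # pragma: no cover
    i_idx, j_idx, w, X, ss_x, sign, sigma, sl, m_stop, window, tol
):
    n, p = X.shape
    n_pairs = i_idx.shape[0]
    eta = np.zeros(n)
    beta = np.zeros(p)
    u = np.empty(n)
    risk_path = np.empty(m_stop)
    selection = np.empty(m_stop, dtype=np.int64)
    n_iter = 0
    for m in range(m_stop):
        risk = 0.0
        for k in range(n):
            u[k] = 0.0
        for k in range(n_pairs):
            d = sign * (eta[i_idx[k]] - eta[j_idx[k]]) / sigma
            if d > _CLAMP:
                d = _CLAMP
            elif d < -_CLAMP:
                d = -_CLAMP
            s = 1.0 / (1.0 + np.exp(-d))
            risk -= w[k] * s
            c = sign * w[k] * s * (1.0 - s) / sigma
            u[i_idx[k]] += c
            u[j_idx[k]] -= c
        risk_path[m] = risk
        n_iter = m + 1
        if m > window and risk_path[m - window] - risk < tol:
            selection[m] = -1
            break
        uu = 0.0
        for k in range(n):
            uu += u[k] * u[k]
        best = 0
        best_rss = np.inf
        best_slope = 0.0
        for col in range(p):
            if ss_x[col] <= 0.0:
                continue
            xu = 0.0
            for k in range(n):
                xu += X[k, col] * u[k]
            slope = xu / ss_x[col]
            rss = uu - slope * slope * ss_x[col]
            if rss < best_rss:
                best_rss = rss
                best = col
                best_slope = slope
        beta[best] += sl * best_slope
        for k in range(n):
            eta[k] += sl * best_slope * X[k, best]
        selection[m] = best
    return beta, eta, risk_path[:n_iter], selection[:n_iter]


def _boost_numpy(i_idx, j_idx, w, X, ss_x, sign, sigma, sl, m_stop, window, tol):
    from scipy.special import expit

    n, p = X.shape
    eta = np.zeros(n)
    beta = np.zeros(p)
    constant = ss_x <= 0.0
    ss_safe = np.where(constant, 1.0, ss_x)
    risk_path: list[float] = []
    selection: list[int] = []
    for m in range(m_stop):
        d = np.clip(sign * (eta[i_idx] - eta[j_idx]) / sigma, -_CLAMP, _CLAMP)
        s = expit(d)
        risk = float(-(w @ s))
        risk_path.append(risk)
        if m > window and risk_path[m - window] - risk < tol:
            selection.append(-1)
            break
        c = sign * w * s * (1.0 - s) / sigma
        u = np.bincount(i_idx, weights=c, minlength=n) - np.bincount(
            j_idx, weights=c, minlength=n
        )
        slopes = np.where(constant, 0.0, (u @ X) / ss_safe)
        rss = (u @ u) - slopes * slopes * ss_x
        rss[constant] = np.inf if constant.all() else rss[constant]
        best = int(np.argmin(np.where(constant, np.inf, rss)))
        beta[best] += sl * slopes[best]
        eta = eta + sl * slopes[best] * X[:, best]
        selection.append(best)
    return beta, eta, np.asarray(risk_path), np.asarray(selection, dtype=np.int64)


def boost_loop(i_idx, j_idx, w, X, ss_x, sign, sigma, sl, m_stop, window, tol):
    """Run the component-wise boosting iterations; returns
    ``(beta, eta, risk_path, selection)`` where a trailing ``-1`` in
    ``selection`` marks an early exit (that iteration made no update)."""
    if HAVE_NUMBA:
        return _boost_numba(
            i_idx.astype(np.int64),
            j_idx.astype(np.int64),
            np.ascontiguousarray(w),
            np.asfortranarray(X),
            np.ascontiguousarray(ss_x),
            float(sign),
            float(sigma),
            float(sl),
            int(m_stop),
            int(window),
            float(tol),
        )
    return _boost_numpy(i_idx, j_idx, w, X, ss_x, sign, sigma, sl, m_stop, window, tol)
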