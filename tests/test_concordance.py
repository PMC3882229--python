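"""Concordance estimators: examples, brute-force oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cboost import (
    ConcordanceUndefinedError,
    SurvivalSample,
    harrell_c,
    km_fit,
    smoothed_risk,
    smoothed_risk_gradient,
    uno_c,
    uno_weights,
)


def brute_force_c(times, events, eta, g_curve=None, orientation="survival"):
    """Independent O(n^2) pair-sum oracle for Harrell's and Uno's estimators."""
    num = den = 0.0
    n = len(times)
    for j in range(n):
        if events[j] != 1:
            continue
        w = 1.0
        if g_curve is not None:
            g = float(g_curve.evaluate_left(times[j]))
            if g <= 0:
                continue
            w = g**-2
        for i in range(n):
            if times[j] < times[i]:
                d = eta[i] - eta[j]
                if orientation == "risk":
                    d = -d
                num += w * (1.0 if d > 0 else 0.5 if d == 0 else 0.0)
                den += w
    if den == 0:
        raise ZeroDivisionError
    return num / den


def _random_survival(seed, n=40, censor=True):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0, n) + 1e-3
    e = rng.integers(0, 2, n).astype(float) if censor else np.ones(n)
    e[np.argmin(t)] = 1
    eta = rng.normal(size=n)
    return SurvivalSample(t, e, rng.normal(size=(n, 2))), eta


# ---------------------------------------------------------------------------
# Kaplan-Meier


@pytest.mark.parametrize(
    "times, indicator, query, expected",
    [
        # no censoring: the empirical survival function
        ((1, 2, 3), (1, 1, 1), (1, 2, 3), (2 / 3, 1 / 3, 0.0)),
        # no events: the curve never drops
        ((1, 2, 3), (0, 0, 0), (0.5, 1.5, 3.5), (1.0, 1.0, 1.0)),
        # hand-computed product limit with an event/censoring tie at t=4:
        # S(2)=3/4, S(4)=3/4*(1-1/3)=1/2, S(5)=0
        ((2, 4, 4, 5), (1, 0, 1, 1), (2, 4, 5), (0.75, 0.5, 0.0)),
    ],
)
def test_km_product_limit_matches_hand_computation(times, indicator, query, expected):
    curve = km_fit(times, indicator)
    assert np.allclose(curve.evaluate(np.array(query)), expected)


def test_km_is_right_continuous_with_left_limits():
    curve = km_fit((2, 4, 4, 5), (1, 0, 1, 1))
    assert curve.evaluate(2.0) == pytest.approx(0.75)
    assert curve.evaluate_left(2.0) == pytest.approx(1.0)
    assert curve.evaluate_left(4.0) == pytest.approx(0.75)
    assert curve.evaluate(1.0) == pytest.approx(1.0)


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_fit([], [])
    with pytest.raises(ValueError):
        km_fit([-1.0, 2.0], [1, 1])
    with pytest.raises(ValueError):
        km_fit([1.0, 2.0], [1])


# ---------------------------------------------------------------------------
# Harrell's estimator


def test_harrell_perfectly_concordant_and_tied():
    s = SurvivalSample((1, 2, 3), (1, 1, 1), np.zeros((3, 1)))
    assert harrell_c(s, (-1.0, 0.0, 1.0)).estimate == 1.0
    assert harrell_c(s, (0.0, 0.0, 0.0)).estimate == 0.5
    assert harrell_c(s, (1.0, 0.0, -1.0)).estimate == 0.0


def test_harrell_excludes_pairs_with_censored_smaller_time():
    # subject 2 censored at t=2: pairs (2,3) and (2,4) are unusable
    s = SurvivalSample((1, 2, 3, 4), (1, 0, 1, 1), np.zeros((4, 1)))
    eta = np.array([0.5, -1.0, 2.0, 1.0])
    res = harrell_c(s, eta)
    assert res.n_usable_pairs == 4  # (1,·)x3 + (3,4)
    assert res.estimate == pytest.approx(brute_force_c(s.observed_time, s.event, eta))


@pytest.mark.parametrize("seed", range(8))
def test_harrell_matches_bruteforce_and_sksurv(seed):
    from sksurv.metrics import concordance_index_censored

    sample, eta = _random_survival(seed, n=50)
    mine = harrell_c(sample, eta, orientation="risk").estimate
    oracle = brute_force_c(sample.observed_time, sample.event, eta, orientation="risk")
    y_e = sample.event.astype(bool)
    ref = concordance_index_censored(y_e, sample.observed_time, eta)[0]
    assert mine == pytest.approx(oracle, abs=1e-12)
    assert mine == pytest.approx(ref, abs=1e-12)


def test_all_censored_raises_undefined_not_half():
    s = SurvivalSample((1, 2, 3), (0, 0, 0), np.zeros((3, 1)))
    with pytest.raises(ConcordanceUndefinedError):
        harrell_c(s, (1.0, 2.0, 3.0))
    g = km_fit(s.observed_time, 1 - s.event)
    with pytest.raises(ConcordanceUndefinedError):
        uno_c(s, (1.0, 2.0, 3.0), g)


# ---------------------------------------------------------------------------
# Uno's IPCW estimator


def test_uno_weights_unit_without_censoring(uncensored_sample):
    g = km_fit(uncensored_sample.observed_time, 1 - uncensored_sample.event)
    pw = uno_weights(uncensored_sample, g)
    assert np.allclose(pw.weight, 1.0)


def test_uno_weights_hand_computed_four_subjects():
    # censoring KM has a single drop at t=2 (G=2/3 afterwards); the usable
    # pair starting at t=3 therefore gets weight (3/2)^2
    s = SurvivalSample((1, 2, 3, 4), (1, 0, 1, 1), np.zeros((4, 1)))
    g = km_fit(s.observed_time, 1 - s.event)
    pw = uno_weights(s, g)
    by_pair = {(j, i): w for j, i, w in zip(pw.j_idx, pw.i_idx, pw.weight)}
    assert by_pair == pytest.approx(
        {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0, (2, 3): 2.25}
    )


def test_uno_reduces_to_harrell_without_censoring(uncensored_sample, rng):
    eta = rng.normal(size=uncensored_sample.n)
    g = km_fit(uncensored_sample.observed_time, 1 - uncensored_sample.event)
    assert uno_c(uncensored_sample, eta, g).estimate == pytest.approx(
        harrell_c(uncensored_sample, eta).estimate
    )


def test_uno_anticoncordant_is_zero():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    s = SurvivalSample(t, np.ones(4), np.zeros((4, 1)))
    g = km_fit(t, np.zeros(4))
    assert uno_c(s, -t, g).estimate == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_uno_matches_bruteforce_and_sksurv(seed):
    from sksurv.metrics import concordance_index_ipcw

    sample, eta = _random_survival(seed, n=40)
    rng = np.random.default_rng(seed + 1000)
    t_tr = rng.exponential(1.0, 80) + 1e-3
    e_tr = rng.integers(0, 2, 80).astype(float)
    # keep the training censoring curve positive over the test time range
    top = np.argmax(t_tr)
    e_tr[top] = 0
    t_tr[top] = sample.observed_time.max() * 1.01
    g = km_fit(t_tr, 1 - e_tr)
    mine = uno_c(sample, eta, g, orientation="risk").estimate
    oracle = brute_force_c(
        sample.observed_time, sample.event, eta, g_curve=g, orientation="risk"
    )
    y_tr = np.array(
        list(zip(e_tr.astype(bool), t_tr)), dtype=[("e", bool), ("t", float)]
    )
    y_te = np.array(
        list(zip(sample.event.astype(bool), sample.observed_time)),
        dtype=[("e", bool), ("t", float)],
    )
    ref = concordance_index_ipcw(y_tr, y_te, eta)[0]
    assert mine == pytest.approx(oracle, abs=1e-12)
    assert mine == pytest.approx(ref, abs=1e-10)


def test_truncation_time_restricts_usable_pairs(censored_sample):
    g = km_fit(censored_sample.observed_time, 1 - censored_sample.event)
    tau = float(np.median(censored_sample.observed_time))
    pw = uno_weights(censored_sample, g, tau=tau)
    assert np.all(censored_sample.observed_time[pw.j_idx] < tau)


@pytest.mark.parametrize("transform", [lambda x: 3.0 * x - 2.0, lambda x: x**3])
def test_estimators_invariant_under_monotone_transforms(censored_sample, rng, transform):
    eta = rng.normal(size=censored_sample.n)
    g = km_fit(censored_sample.observed_time, 1 - censored_sample.event)
    for est in (harrell_c, lambda s, e: uno_c(s, e, g)):
        assert est(censored_sample, transform(eta)).estimate == pytest.approx(
            est(censored_sample, eta).estimate
        )


def test_orientation_flip_maps_estimate_to_complement(censored_sample, rng):
    eta = rng.normal(size=censored_sample.n)  # tie-free a.s.
    g = km_fit(censored_sample.observed_time, 1 - censored_sample.event)
    c_surv = uno_c(censored_sample, eta, g, orientation="survival").estimate
    c_risk = uno_c(censored_sample, eta, g, orientation="risk").estimate
    assert c_surv + c_risk == pytest.approx(1.0)


def test_censoring_biases_harrell_upward_but_not_uno():
    """In a pure location AFT model (discrimination strongest early in
    time), rising censoring rates drive Harrell's estimator upward while
    the IPCW estimator stays near the uncensored concordance."""
    from dataclasses import replace

    from cboost import SimulationConfig, generate

    cfg0 = SimulationConfig(
        n=4000,
        p_total=4,
        correlation=0.0,
        mu_coefficients=(1.0, 1.0, -1.0, -1.0),
        sigma_coefficients=(0.0,) * 4,
        target_censoring=0.0,
        censoring_family="exponential",
    )
    rng = np.random.default_rng(5)
    d0 = generate(cfg0, rng)
    c_full = harrell_c(d0.sample, d0.true_eta).estimate

    drift = []
    for cens in (0.3, 0.5, 0.7):
        d = generate(replace(cfg0, target_censoring=cens), rng)
        g = km_fit(d.sample.observed_time, 1 - d.sample.event)
        c_h = harrell_c(d.sample, d.true_eta).estimate
        c_u = uno_c(d.sample, d.true_eta, g).estimate
        drift.append(c_h - c_full)
        assert abs(c_u - c_full) < 0.02
    assert drift[-1] > 0.03  # heavy censoring inflates Harrell's estimate
    assert drift[0] < drift[-1]


# ---------------------------------------------------------------------------
# smoothed risk and gradient


def _g(sample):
    return km_fit(sample.observed_time, 1 - sample.event)


def test_smoothed_risk_constant_eta_is_minus_half(censored_sample):
    eta = np.full(censored_sample.n, 3.7)
    assert smoothed_risk(censored_sample, eta, _g(censored_sample), 0.1) == pytest.approx(-0.5)


def test_smoothed_risk_sigma_to_zero_limit(censored_sample, rng):
    eta = rng.normal(size=censored_sample.n)
    g = _g(censored_sample)
    risk = smoothed_risk(censored_sample, eta, g, sigma=1e-4)
    assert abs(risk + uno_c(censored_sample, eta, g).estimate) < 1e-3


def test_smoothed_risk_direct_summation_oracle():
    sample, eta = _random_survival(3, n=12)
    g = _g(sample)
    sigma = 0.1
    pw = uno_weights(sample, g)
    expected = 0.0
    for j, i, w in zip(pw.j_idx, pw.i_idx, pw.weight):
        expected -= w / (1.0 + np.exp(-(eta[i] - eta[j]) / sigma))
    expected /= pw.weight.sum()
    assert smoothed_risk(sample, eta, g, sigma) == pytest.approx(expected, rel=1e-12)


def test_smoothed_risk_translation_invariant(censored_sample, rng):
    eta = rng.normal(size=censored_sample.n)
    g = _g(censored_sample)
    assert smoothed_risk(censored_sample, eta, g, 0.2) == pytest.approx(
        smoothed_risk(censored_sample, eta + 11.3, g, 0.2)
    )


def test_smoothed_risk_rejects_nonpositive_sigma(censored_sample):
    with pytest.raises(ValueError):
        smoothed_risk(censored_sample, np.zeros(censored_sample.n), _g(censored_sample), 0.0)


@given(seed=st.integers(0, 10_000), sigma=st.sampled_from([0.05, 0.1, 0.5]))
def test_gradient_matches_central_finite_differences(seed, sigma):
    sample, eta = _random_survival(seed, n=15)
    g = _g(sample)
    grad = smoothed_risk_gradient(sample, eta, g, sigma)
    h = 1e-6
    fd = np.empty(sample.n)
    for k in range(sample.n):
        ep, em = eta.copy(), eta.copy()
        ep[k] += h
        em[k] -= h
        fd[k] = (smoothed_risk(sample, ep, g, sigma) - smoothed_risk(sample, em, g, sigma)) / (2 * h)
    assert np.allclose(grad, fd, rtol=1e-5, atol=1e-9)


def test_gradient_components_sum_to_zero(censored_sample, rng):
    eta = rng.normal(size=censored_sample.n)
    grad = smoothed_risk_gradient(censored_sample, eta, _g(censored_sample), 0.1)
    assert grad.sum() == pytest.approx(0.0, abs=1e-12)


def test_single_usable_pair_closed_form_gradient():
    s = SurvivalSample((1.0, 2.0), (1, 1), np.zeros((2, 1)))
    g = km_fit(s.observed_time, 1 - s.event)
    eta = np.array([0.3, -0.2])
    sigma = 0.25
    # one pair (j=0, i=1), weight 1: risk = -sig(d/sigma), d = eta1 - eta0
    sig = 1.0 / (1.0 + np.exp(-(eta[1] - eta[0]) / sigma))
    expected = np.array([sig * (1 - sig) / sigma, -sig * (1 - sig) / sigma])
    assert np.allclose(smoothed_risk_gradient(s, eta, g, sigma), expected)


def test_extreme_eta_differences_do_not_overflow(censored_sample):
    eta = np.linspace(-1e6, 1e6, censored_sample.n)
    g = _g(censored_sample)
    risk = smoothed_risk(censored_sample, eta, g, 0.1)
    grad = smoothed_risk_gradient(censored_sample, eta, g, 0.1)
    assert np.isfinite(risk)
    assert np.all(np.isfinite(grad))
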