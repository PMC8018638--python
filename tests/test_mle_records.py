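"""Closed-form record MLE, Fisher information, delta method, asymptotic CI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recstress import (
    EGParams,
    LowerRecordSample,
    asymptotic_ci,
    delta_variance,
    estimate_mle,
    fisher_information,
    score_residuals,
    simulate_lower_records,
)
from scipy.special import psi


def test_steel_record_mle(steel_records):
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    # lam-hat = (n+m)/(n*(xbar-x_n)+m*(ybar-y_m)) = 7/240 by hand arithmetic
    assert mle.lam_hat == pytest.approx(7 / 240, rel=1e-14)
    assert mle.alpha_hat == pytest.approx(4 * math.exp(7 / 240 * 115), rel=1e-12)
    assert mle.beta_hat == pytest.approx(3 * math.exp(7 / 240 * 112), rel=1e-12)
    assert round(mle.r_hat, 4) == 0.5927
    assert mle.r_hat == mle.alpha_hat / (mle.alpha_hat + mle.beta_hat)


def test_score_equations_vanish_at_mle(steel_records):
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    assert np.all(np.abs(score_residuals(mle, xr, yr)) < 1e-8)


def test_identical_samples_give_half():
    s = LowerRecordSample(values=(10.0, 6.0, 2.0))
    mle = estimate_mle(s, s)
    assert mle.r_hat == pytest.approx(0.5, rel=1e-14)


def test_unidentifiable_lam_raises():
    a = LowerRecordSample(values=(5.0,))
    b = LowerRecordSample(values=(3.0,))
    with pytest.raises(ValueError, match="identifiable"):
        estimate_mle(a, b)


def test_exchange_symmetry_and_scaling(rng):
    px, py = EGParams(2.0, 1.0), EGParams(1.0, 1.0)
    for _ in range(20):
        xr = simulate_lower_records(5, px, seed=rng)
        yr = simulate_lower_records(4, py, seed=rng)
        fwd = estimate_mle(xr, yr)
        rev = estimate_mle(yr, xr)
        assert rev.r_hat == pytest.approx(1.0 - fwd.r_hat, rel=1e-10)
        assert rev.lam_hat == pytest.approx(fwd.lam_hat, rel=1e-12)
        # scaling data by c>0 scales lam by 1/c and leaves R alone
        c = 3.7
        xs = LowerRecordSample(values=tuple(c * v for v in xr.values))
        ys = LowerRecordSample(values=tuple(c * v for v in yr.values))
        scaled = estimate_mle(xs, ys)
        assert scaled.lam_hat == pytest.approx(fwd.lam_hat / c, rel=1e-10)
        assert scaled.r_hat == pytest.approx(fwd.r_hat, rel=1e-10)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_lam_is_weighted_harmonic_mean(seed):
    rng = np.random.default_rng(seed)
    xr = simulate_lower_records(4, EGParams(2.0, 1.0), seed=rng)
    yr = simulate_lower_records(3, EGParams(1.0, 1.0), seed=rng)
    mle = estimate_mle(xr, yr)
    x, y = xr.to_array(), yr.to_array()
    lam1 = 1.0 / (x.mean() - x[-1])
    lam2 = 1.0 / (y.mean() - y[-1])
    n, m = xr.n, yr.n
    harmonic = (n + m) / (n / lam1 + m / lam2)
    assert mle.lam_hat == pytest.approx(harmonic, rel=1e-12)


def test_fisher_cross_entry_vanishes_at_special_shape():
    n, m = 6, 4
    alpha = math.exp(float(psi(n + 1)))
    info = fisher_information(alpha, 2.0, 0.7, n, m)
    assert info.I[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert info.I[0, 1] == 0.0  # alpha-beta entries are exactly zero


def test_fisher_inverse_matches_cofactor_formulas(steel_records):
    # oracle: explicit adjugate/determinant of the 3x3 with I12 = 0
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    info = fisher_information(mle.alpha_hat, mle.beta_hat, mle.lam_hat, mle.n, mle.m)
    I = info.I
    det = I[0, 0] * I[1, 1] * I[2, 2] - I[0, 0] * I[1, 2] ** 2 - I[1, 1] * I[0, 2] ** 2
    adj = np.array(
        [
            [I[1, 1] * I[2, 2] - I[1, 2] ** 2, I[1, 2] * I[0, 2], -I[1, 1] * I[0, 2]],
            [I[1, 2] * I[0, 2], I[0, 0] * I[2, 2] - I[0, 2] ** 2, -I[0, 0] * I[1, 2]],
            [-I[1, 1] * I[0, 2], -I[0, 0] * I[1, 2], I[0, 0] * I[1, 1]],
        ]
    )
    assert np.allclose(info.U, adj / det, atol=1e-8, rtol=1e-8)
    assert np.allclose(info.U @ I, np.eye(3), atol=1e-8)


def test_fisher_validation():
    with pytest.raises(ValueError):
        fisher_information(-1.0, 1.0, 1.0, 3, 3)
    with pytest.raises(ValueError):
        fisher_information(1.0, 1.0, 1.0, 0, 3)


def test_delta_variance_steel_value(steel_records):
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    info = fisher_information(mle.alpha_hat, mle.beta_hat, mle.lam_hat, mle.n, mle.m)
    assert delta_variance(mle, info) == pytest.approx(0.0341, abs=2e-4)


def test_delta_variance_symmetric_reduction():
    # alpha = beta collapses C'UC to (U11 + U22 - 2*U12) / (16 alpha^2)
    from recstress.mle_records import RecordMLE

    alpha = 2.5
    info = fisher_information(alpha, alpha, 0.8, 5, 5)
    sym = RecordMLE(lam_hat=0.8, alpha_hat=alpha, beta_hat=alpha, r_hat=0.5, n=5, m=5)
    U = info.U
    expected = (U[0, 0] + U[1, 1] - 2 * U[0, 1]) / (16 * alpha**2)
    assert delta_variance(sym, info) == pytest.approx(expected, rel=1e-12)


def test_delta_variance_nonnegative_sweep(rng):
    from recstress.mle_records import RecordMLE

    for _ in range(500):
        a, b = rng.uniform(0.1, 50, size=2)
        lam = rng.uniform(0.01, 10)
        n, m = int(rng.integers(1, 30)), int(rng.integers(1, 30))
        info = fisher_information(a, b, lam, n, m)
        est = RecordMLE(lam_hat=lam, alpha_hat=a, beta_hat=b, r_hat=a / (a + b), n=n, m=m)
        assert delta_variance(est, info) >= 0.0


def test_asymptotic_ci_reproduces_steel_interval(steel_records):
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    info = fisher_information(mle.alpha_hat, mle.beta_hat, mle.lam_hat, mle.n, mle.m)
    ci = asymptotic_ci(mle, delta_variance(mle, info), level=0.95)
    assert round(ci.lower, 4) == 0.4117
    assert round(ci.upper, 4) == 0.7737


def test_asymptotic_ci_degenerate_and_validation(steel_records):
    xr, yr = steel_records
    mle = estimate_mle(xr, yr)
    ci = asymptotic_ci(mle, 0.0)
    assert ci.lower == ci.upper == mle.r_hat
    with pytest.raises(ValueError):
        asymptotic_ci(mle, 0.1, level=1.5)
    with pytest.raises(ValueError):
        asymptotic_ci(mle, 0.1, ci_divisor="bogus")


def _coverage(n, m, reps, seed, ci_divisor):
    rng = np.random.default_rng(seed)
    px, py = EGParams(2.0, 1.0), EGParams(1.0, 1.0)
    r_true = 2.0 / 3.0
    hits = 0
    for _ in range(reps):
        xr = simulate_lower_records(n, px, seed=rng)
        yr = simulate_lower_records(m, py, seed=rng)
        mle = estimate_mle(xr, yr)
        info = fisher_information(mle.alpha_hat, mle.beta_hat, mle.lam_hat, n, m)
        ci = asymptotic_ci(mle, delta_variance(mle, info), ci_divisor=ci_divisor)
        hits += ci.lower <= r_true <= ci.upper
    return hits / reps


def test_plain_delta_interval_coverage_near_nominal():
    # the plain (no extra divisor) delta interval is the one with sound
    # large-sample coverage; at n=m=30 it sits inside [0.90, 0.99]
    assert 0.90 <= _coverage(30, 30, 1000, 7, "none") <= 0.99


def test_coverage_improves_with_record_count():
    near = abs(_coverage(30, 30, 800, 11, "none") - 0.95)
    far = abs(_coverage(3, 3, 800, 11, "none") - 0.95)
    assert near < far
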