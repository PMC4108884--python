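"""Phase-type representations against gamma/Erlang closed forms."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma

from flowpht import (
    ErlangMixtureSpec,
    PhaseTypeRepresentation,
    make_erlang,
    make_erlang_mixture,
    mixture_cdf,
    mixture_laplace,
    ph_cdf,
    ph_hazard,
    ph_laplace,
    ph_pdf,
    ph_survival,
    sample_absorption_times,
)
from flowpht.phase_type import load_ph, save_ph

T_GRID = np.concatenate([[0.1, 0.25, 0.5], np.linspace(1.0, 20.0, 12)])
S_GRID = np.concatenate([[0.01, 0.05], np.linspace(0.1, 10.0, 12)])


@pytest.mark.parametrize("shape,rate", [(1, 0.7), (3, 2.0), (5, 1.3)])
def test_erlang_matches_gamma_closed_forms(shape, rate):
    """Erlang(r, mu) built as a chain of r states reproduces the gamma
    CDF, pdf and survival to 1e-9 across two decades of time."""
    ph = make_erlang(shape, rate)
    for t in T_GRID:
        assert ph_cdf(ph, t) == pytest.approx(
            gamma.cdf(t, a=shape, scale=1 / rate), abs=1e-9
        )
        assert ph_pdf(ph, t) == pytest.approx(
            gamma.pdf(t, a=shape, scale=1 / rate), abs=1e-9
        )
        assert ph_survival(ph, t) == pytest.approx(
            gamma.sf(t, a=shape, scale=1 / rate), abs=1e-9
        )


@pytest.mark.parametrize("shape,rate", [(1, 0.7), (3, 2.0), (5, 1.3)])
def test_erlang_laplace_closed_form(shape, rate):
    """L(s) = (mu / (s + mu))^r for the Erlang transform, and L(0) = 1."""
    ph = make_erlang(shape, rate)
    for s in S_GRID:
        assert ph_laplace(ph, s) == pytest.approx(
            (rate / (s + rate)) ** shape, abs=1e-12
        )
    assert ph_laplace(ph, 0.0) == pytest.approx(1.0, abs=1e-12)
    # complex argument as used by the Bromwich contour
    s = 0.4 + 2.1j
    assert ph_laplace(ph, s) == pytest.approx((rate / (s + rate)) ** shape, abs=1e-12)


def test_erlang_exponential_special_case():
    ph = make_erlang(1, 2.5)
    assert ph.alpha.tolist() == [1.0]
    assert ph.T.tolist() == [[-2.5]]
    assert ph.T0.tolist() == [2.5]
    t = 0.8
    assert ph_pdf(ph, t) == pytest.approx(2.5 * np.exp(-2.5 * t), rel=1e-12)
    # exponential hazard is constant
    for t in (0.2, 1.0, 4.0):
        assert ph_hazard(ph, t) == pytest.approx(2.5, rel=1e-9)


@pytest.mark.parametrize(
    "shape,rate",
    [(0, 1.0), (-2, 1.0), (1.5, 1.0), (2, 0.0), (2, -1.0)],
)
def test_make_erlang_rejects_invalid_parameters(shape, rate):
    with pytest.raises(ValueError):
        make_erlang(shape, rate)


def test_mixture_representation_structure(mixture_spec):
    """Shapes (1,3,5) give the canonical 9-state chain: alpha places the
    weights at block starts and T is block-bidiagonal."""
    p1, p2, p3 = mixture_spec.weights
    m1, m2, m3 = mixture_spec.rates
    ph = make_erlang_mixture(mixture_spec)
    assert ph.m == 9
    np.testing.assert_allclose(ph.alpha, [p1, p2, 0, 0, p3, 0, 0, 0, 0])
    expected_T = np.zeros((9, 9))
    expected_T[0, 0] = -m1
    for k in range(1, 4):
        expected_T[k, k] = -m2
        if k < 3:
            expected_T[k, k + 1] = m2
    for k in range(4, 9):
        expected_T[k, k] = -m3
        if k < 8:
            expected_T[k, k + 1] = m3
    np.testing.assert_array_equal(ph.T, expected_T)


def test_mixture_cdf_is_weighted_gamma_cdfs(mixture_spec):
    ph = make_erlang_mixture(mixture_spec)
    for t in T_GRID:
        oracle = sum(
            p * gamma.cdf(t, a=r, scale=1 / mu)
            for p, mu, r in zip(
                mixture_spec.weights, mixture_spec.rates, mixture_spec.shapes
            )
        )
        assert ph_cdf(ph, t) == pytest.approx(oracle, abs=1e-9)
        assert mixture_cdf(mixture_spec, t) == pytest.approx(oracle, abs=1e-12)


def test_mixture_laplace_linearity(mixture_spec):
    ph = make_erlang_mixture(mixture_spec)
    for s in S_GRID:
        oracle = sum(
            p * (mu / (s + mu)) ** r
            for p, mu, r in zip(
                mixture_spec.weights, mixture_spec.rates, mixture_spec.shapes
            )
        )
        assert ph_laplace(ph, s) == pytest.approx(oracle, abs=1e-10)
        assert mixture_laplace(mixture_spec, s) == pytest.approx(oracle, abs=1e-12)


def test_mixture_collapse_to_single_erlang():
    """Weights (1-2e, e, e) with e -> 0 reduce to the first Erlang."""
    eps = 1e-12
    spec = ErlangMixtureSpec(
        weights=(1 - 2 * eps, eps, eps), rates=(0.8, 1.0, 2.0), shapes=(2, 3, 5)
    )
    ph = make_erlang_mixture(spec)
    for t in (0.5, 2.0, 6.0):
        assert ph_cdf(ph, t) == pytest.approx(
            gamma.cdf(t, a=2, scale=1 / 0.8), abs=1e-9
        )


@pytest.mark.parametrize(
    "weights,rates,shapes",
    [
        ((0.5, 0.5), (1.0, 2.0, 3.0), (1, 3, 5)),  # length mismatch
        ((0.5, 0.3, 0.3), (1.0, 2.0, 3.0), (1, 3, 5)),  # sum != 1
        ((0.5, 0.5, 0.0), (1.0, 2.0, 3.0), (1, 3, 5)),  # zero weight
        ((0.5, 0.3, 0.2), (1.0, -2.0, 3.0), (1, 3, 5)),  # negative rate
        ((0.5, 0.3, 0.2), (1.0, 2.0, 3.0), (1, 0, 5)),  # zero shape
        ((0.5, 0.3, 0.2), (1.0, 2.0, 3.0), (1, 2.5, 5)),  # fractional shape
    ],
)
def test_mixture_spec_rejects_invariant_violations(weights, rates, shapes):
    with pytest.raises(ValueError):
        ErlangMixtureSpec(weights=weights, rates=rates, shapes=shapes)


@given(
    weights=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
    rates=st.lists(st.floats(0.1, 5.0), min_size=3, max_size=3),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_representation_invariants_hold_for_any_valid_mixture(weights, rates):
    """-T e = T0 entrywise, alpha mass one, CDF/survival monotone in [0,1]."""
    w = np.asarray(weights) / np.sum(weights)
    spec = ErlangMixtureSpec(weights=tuple(w), rates=tuple(rates), shapes=(1, 3, 5))
    ph = make_erlang_mixture(spec)
    np.testing.assert_allclose(-ph.T @ np.ones(ph.m), ph.T0, atol=1e-12)
    assert ph.alpha.sum() + ph.alpha_abs == pytest.approx(1.0, abs=1e-12)
    grid = np.linspace(0.0, 25.0, 40)
    F = np.asarray(ph_cdf(ph, grid))
    S = np.asarray(ph_survival(ph, grid))
    assert np.all(np.diff(F) >= -1e-10)
    assert np.all(np.diff(S) <= 1e-10)
    assert np.all((0 <= F) & (F <= 1)) and np.all((0 <= S) & (S <= 1))
    assert F[0] == pytest.approx(0.0, abs=1e-12)


def test_pdf_matches_numerical_cdf_derivative(mixture_spec):
    ph = make_erlang_mixture(mixture_spec)
    h = 1e-5
    for t in (0.5, 1.5, 4.0):
        deriv = (ph_cdf(ph, t + h) - ph_cdf(ph, t - h)) / (2 * h)
        assert ph_pdf(ph, t) == pytest.approx(deriv, abs=1e-7)


def test_pdf_integrates_to_total_transient_mass(mixture_spec):
    from scipy.integrate import quad

    ph = make_erlang_mixture(mixture_spec)
    total, _ = quad(lambda t: ph_pdf(ph, t), 0, 60, limit=200)
    assert total == pytest.approx(1.0, abs=1e-7)


def test_hazard_raises_on_survival_underflow():
    ph = make_erlang(1, 5.0)
    with pytest.raises(FloatingPointError):
        ph_hazard(ph, 50.0)  # S = e^-250 is far below the underflow floor


def test_erlang_hazard_increases_like_gamma(mixture_spec):
    ph = make_erlang(3, 1.5)
    ts = np.array([0.5, 1.0, 2.0, 4.0])
    oracle = gamma.pdf(ts, a=3, scale=1 / 1.5) / gamma.sf(ts, a=3, scale=1 / 1.5)
    np.testing.assert_allclose(np.asarray(ph_hazard(ph, ts)), oracle, atol=1e-9)
    assert np.all(np.diff(np.asarray(ph_hazard(ph, ts))) > 0)


def test_negative_time_rejected(mixture_spec):
    ph = make_erlang_mixture(mixture_spec)
    for fn in (ph_cdf, ph_pdf, ph_survival, ph_hazard):
        with pytest.raises(ValueError):
            fn(ph, -0.5)


def test_invalid_representation_rejected():
    with pytest.raises(ValueError):  # alpha mass != 1
        PhaseTypeRepresentation(alpha=np.array([0.5]), T=np.array([[-1.0]]))
    with pytest.raises(ValueError):  # positive diagonal
        PhaseTypeRepresentation(alpha=np.array([1.0]), T=np.array([[1.0]]))
    with pytest.raises(ValueError):  # negative off-diagonal
        PhaseTypeRepresentation(
            alpha=np.array([0.5, 0.5]),
            T=np.array([[-1.0, -0.5], [0.0, -1.0]]),
        )


def test_monte_carlo_chain_agrees_with_cdf(mixture_spec, rng):
    """Simulating the underlying chain to absorption reproduces the
    analytic CDF: KS distance below 0.01 at 1e5 walkers."""
    ph = make_erlang_mixture(mixture_spec)
    samples = sample_absorption_times(ph, 100_000, rng)
    grid = np.linspace(1e-3, samples.max(), 2000)
    F_emp = np.searchsorted(np.sort(samples), grid, side="right") / samples.size
    F_ana = np.asarray(ph_cdf(ph, grid))
    assert np.max(np.abs(F_emp - F_ana)) < 0.01


def test_serialization_round_trip(tmp_path, mixture_spec):
    ph = make_erlang_mixture(mixture_spec)
    p1 = tmp_path / "rep.json"
    save_ph(ph, p1)
    back = load_ph(p1)
    np.testing.assert_array_equal(back.alpha, ph.alpha)
    np.testing.assert_array_equal(back.T, ph.T)
    assert back.alpha_abs == ph.alpha_abs
    p2 = tmp_path / "spec.json"
    save_ph(mixture_spec, p2)
    spec_back = load_ph(p2)
    assert spec_back == mixture_spec
    # decimal literals survive the text round trip exactly
    assert json.loads(p2.read_text())["weights"] == list(mixture_spec.weights)
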