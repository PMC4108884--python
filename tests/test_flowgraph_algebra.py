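"""Transmittance composition rules and the first-passage transform."""

import numpy as np
import pytest

from flowpht import (
    ErlangMixtureSpec,
    FlowgraphModel,
    Transmittance,
    estimate_transition_probabilities,
    first_passage_lt,
    first_passage_phase_type,
    mixture_transmittance,
    parallel,
    series,
    simulate_cohort,
)
from flowpht import CohortConfig, ph_survival
from flowpht.synthetic_cohort import (
    DEFAULT_P01,
    DEFAULT_P02,
    DEFAULT_P12,
    default_sojourn_specs,
    sample_first_passage,
)


def expo(p, lam):
    return Transmittance(p=p, lt=lambda s: lam / (s + lam))


def test_series_is_convolution_of_exponentials():
    l1, l2 = 0.8, 1.7
    combined = series(expo(1.0, l1), expo(1.0, l2))
    for s in (0.0, 0.3, 2.0, 1.0 + 0.7j):
        oracle = l1 * l2 / ((s + l1) * (s + l2))  # hypoexponential transform
        assert combined.lt(s) == pytest.approx(oracle, abs=1e-12)
    assert combined.p == 1.0
    assert combined.lt(0.0) == pytest.approx(1.0, abs=1e-12)


def test_series_with_instantaneous_branch_is_identity():
    a = expo(0.7, 1.2)
    degenerate = Transmittance(p=1.0, lt=lambda s: 1.0 + 0j)
    combined = series(a, degenerate)
    assert combined.p == pytest.approx(a.p)
    for s in (0.1, 1.0, 5.0):
        assert combined.lt(s) == pytest.approx(a.lt(s), abs=1e-12)


def test_parallel_is_probability_weighted_mixture():
    a, b = expo(0.5, 1.0), expo(0.5, 3.0)
    combined = parallel(a, b)
    assert combined.p == pytest.approx(1.0)
    for s in (0.0, 0.5, 2.5):
        oracle = 0.5 * (1.0 / (s + 1.0)) + 0.5 * (3.0 / (s + 3.0))
        assert combined.lt(s) == pytest.approx(oracle, abs=1e-12)


def test_parallel_rejects_probability_mass_above_one():
    with pytest.raises(ValueError):
        parallel(expo(0.7, 1.0), expo(0.5, 2.0))


def test_transmittance_validates_probability_and_lt_at_zero():
    with pytest.raises(ValueError):
        Transmittance(p=0.0, lt=lambda s: 1.0)
    with pytest.raises(ValueError):
        Transmittance(p=0.5, lt=lambda s: 0.9)  # not a proper law


def test_first_passage_normalization_and_carried_probability():
    model = FlowgraphModel.illness_death(
        t01=expo(DEFAULT_P01, 1.0), t02=expo(DEFAULT_P02, 0.5), t12=expo(DEFAULT_P12, 2.0)
    )
    fp_t = first_passage_lt(model, 0, 2)
    assert fp_t.p == pytest.approx(DEFAULT_P01 * DEFAULT_P12 + DEFAULT_P02)
    assert fp_t.lt(0.0) == pytest.approx(1.0, abs=1e-12)
    # completely monotone: decreasing in real s, within (0, 1)
    svals = np.array([0.1, 0.5, 1.0, 3.0, 8.0])
    lt_vals = np.array([fp_t.lt(s).real for s in svals])
    assert np.all(np.diff(lt_vals) < 0)
    assert np.all((0 < lt_vals) & (lt_vals < 1))


def test_first_passage_collapses_to_direct_branch():
    """With no 0->1 mass the conditional law is the 0->2 sojourn law."""
    direct = expo(0.3, 0.9)
    model = FlowgraphModel(
        branches={(0, 1): expo(1e-12, 1.0), (0, 2): direct, (1, 2): expo(1e-12, 1.0)}
    )
    fp_t = first_passage_lt(model, 0, 2)
    for s in (0.2, 1.0, 4.0):
        assert fp_t.lt(s) == pytest.approx(direct.lt(s), abs=1e-9)


def test_first_passage_requires_all_branches():
    model = FlowgraphModel(branches={(0, 1): expo(0.4, 1.0), (0, 2): expo(0.1, 1.0)})
    with pytest.raises(ValueError):
        first_passage_lt(model, 0, 2)
    with pytest.raises(NotImplementedError):
        first_passage_lt(model, 1, 2)


def test_first_passage_lt_matches_empirical_transform(rng):
    """The normalised transform agrees with the empirical Laplace transform
    of simulated semi-Markov first-passage paths (exponential branches)."""
    specs = {
        "01": ErlangMixtureSpec(weights=(1.0,), rates=(1.0,), shapes=(1,)),
        "02": ErlangMixtureSpec(weights=(1.0,), rates=(0.5,), shapes=(1,)),
        "12": ErlangMixtureSpec(weights=(1.0,), rates=(2.0,), shapes=(1,)),
    }
    model = FlowgraphModel.illness_death(
        t01=mixture_transmittance(DEFAULT_P01, specs["01"]),
        t02=mixture_transmittance(DEFAULT_P02, specs["02"]),
        t12=mixture_transmittance(DEFAULT_P12, specs["12"]),
    )
    fp_t = first_passage_lt(model, 0, 2)
    samples = sample_first_passage(
        DEFAULT_P01, DEFAULT_P02, DEFAULT_P12, specs, 100_000, rng
    )
    for s in (0.3, 1.0, 2.5):
        emp = np.exp(-s * samples)
        se = emp.std(ddof=1) / np.sqrt(emp.size)
        assert fp_t.lt(s).real == pytest.approx(emp.mean(), abs=4 * se)


def test_first_passage_phase_type_equals_transform_route(sojourn_specs):
    """The explicit mixture-of-convolutions representation and the
    transform algebra describe the same law (transform-level identity)."""
    ph = first_passage_phase_type(
        sojourn_specs["01"], sojourn_specs["02"], sojourn_specs["12"],
        DEFAULT_P01, DEFAULT_P02, DEFAULT_P12,
    )
    model = FlowgraphModel.illness_death(
        t01=mixture_transmittance(DEFAULT_P01, sojourn_specs["01"]),
        t02=mixture_transmittance(DEFAULT_P02, sojourn_specs["02"]),
        t12=mixture_transmittance(DEFAULT_P12, sojourn_specs["12"]),
    )
    fp_t = first_passage_lt(model, 0, 2)
    from flowpht import ph_laplace

    for s in (0.0, 0.2, 1.0, 4.0, 0.5 + 1.5j):
        assert ph_laplace(ph, s) == pytest.approx(fp_t.lt(s), abs=1e-10)


def test_probability_estimates_match_configuration(small_cohort):
    """Plateau (Aalen-Johansen) estimates recover the configured branch
    probabilities; ratio estimates are biased low under censoring."""
    plateau = estimate_transition_probabilities(small_cohort, method="plateau")
    ratio = estimate_transition_probabilities(small_cohort, method="ratio")
    assert plateau["p01"] == pytest.approx(0.45, abs=0.06)
    assert plateau["p02"] == pytest.approx(0.20, abs=0.05)
    assert plateau["p12"] == pytest.approx(0.40, abs=0.08)
    assert ratio["p01"] <= plateau["p01"] + 1e-12
    assert ratio["p02"] <= plateau["p02"] + 1e-12
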