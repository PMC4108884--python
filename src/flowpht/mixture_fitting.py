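"""Fit Erlang mixtures to Kaplan-Meier waiting-time estimates.

The parametric family is the mixture ``G(t) = p1 F1(t) + p2 F2(t) + p3 F3(t)``
of Erlang CDFs with fixed integer shapes (default (1, 3, 5)) and free
weights and rates.  Fitting minimises the Euclidean norm of
``F_hat(t_k) - G(t_k)`` over the support of the empirical estimate — by
default its Kaplan-Meier jump times, optionally a uniform grid.

Initialisation follows a two-stage scheme: rates start at moment-style
values ``r_i / t_med`` from the KM median (restricted mean when the median
is not reached), and weights come from a non-negative least-squares solve
(Lawson-Hanson) of the stacked system

    F_hat(t_k) = p1 F1(t_k) + p2 F2(t_k) + p3 F3(t_k),   1 = p1 + p2 + p3.

The constrained minimisation is run unconstrained in a reparameterised
space (log-weights mapped through softmax, log-rates), which makes the
returned spec feasible unconditionally; the objective never exceeds its
value at the initial point because the better of {initial, optimised} is
returned.  A small deterministic multi-start over rate perturbations guards
against poor local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import gammainc

from .empirical_cdf import EmpiricalCdf
from .phase_type import ErlangMixtureSpec

__all__ = [
    "FitResult",
    "nnls_init",
    "init_rates",
    "fit_mixture",
    "fit_transition",
    "WEIGHT_FLOOR",
]

#: weights are floored here and renormalised to honour p_i > 0 strictly
WEIGHT_FLOOR = 1e-6

#: multiplicative rate perturbations used by the multi-start
RATE_MULTIPLIERS = (1.0, 0.5, 0.75, 1.5, 2.25)


@dataclass(frozen=True)
class FitResult:
    """Fitted spec plus diagnostics of one constrained minimisation."""

    spec: ErlangMixtureSpec
    objective: float
    init_objective: float
    converged: bool
    n_grid: int
    plateau: float
    n_iter: int

    @property
    def defective_plateau(self) -> bool:
        """True when the empirical estimate plateaus below 0.9: the proper
        parametric CDF will overshoot the censored tail."""
        return self.plateau < 0.9

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = {
            "weights": list(self.spec.weights),
            "rates": list(self.spec.rates),
            "shapes": list(self.spec.shapes),
        }
        d["defective_plateau"] = self.defective_plateau
        return d


def _erlang_cdf_matrix(t: np.ndarray, shapes, rates) -> np.ndarray:
    """Columns F_i(t_k) of the component Erlang CDFs."""
    return np.column_stack([gammainc(r, mu * t) for r, mu in zip(shapes, rates)])


def _project_weights(w: np.ndarray) -> tuple[float, ...]:
    w = np.clip(np.asarray(w, dtype=float), WEIGHT_FLOOR, None)
    return tuple(w / w.sum())


def nnls_init(emp: EmpiricalCdf, shapes, rates) -> tuple[float, ...]:
    """Non-negative least-squares weights for fixed shapes and rates.

    Solves the stacked system (component CDFs at the KM jump times plus the
    sum-to-one row) by Lawson-Hanson NNLS, then projects the solution onto
    the open simplex (floor ``WEIGHT_FLOOR``, renormalise).
    """
    shapes = tuple(int(r) for r in shapes)
    rates = tuple(float(mu) for mu in rates)
    if any(mu <= 0 for mu in rates):
        raise ValueError("rates must be strictly positive")
    t = emp.jump_times
    A = _erlang_cdf_matrix(t, shapes, rates)
    # degenerate design: two components indistinguishable on this grid
    for i in range(A.shape[1]):
        for j in range(i + 1, A.shape[1]):
            denom = max(np.linalg.norm(A[:, i]), np.linalg.norm(A[:, j]), 1e-30)
            if np.linalg.norm(A[:, i] - A[:, j]) / denom < 1e-10:
                raise ValueError(
                    f"degenerate design: components {i} and {j} identical on grid"
                )
    A_full = np.vstack([A, np.ones((1, A.shape[1]))])
    b_full = np.concatenate([emp.values, [1.0]])
    w, _ = nnls(A_full, b_full)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return _project_weights(w)


def init_rates(emp: EmpiricalCdf, shapes) -> tuple[float, ...]:
    """Moment-style starting rates ``r_i / t_med``.

    ``t_med`` is the KM median; when the estimate plateaus below 1/2 the
    median is not reached and the restricted mean over the observed range
    is used instead.
    """
    shapes = tuple(int(r) for r in shapes)
    t_med = emp.median()
    if t_med is None or t_med <= 0:
        t_med = emp.restricted_mean()
    if t_med <= 0:
        raise ValueError("empirical estimate carries no usable time scale")
    return tuple(r / t_med for r in shapes)


def _objective_factory(emp: EmpiricalCdf, shapes, grid, n_uniform):
    if grid == "km":
        t = emp.jump_times
    elif grid == "uniform":
        t = np.linspace(0.0, emp.jump_times[-1], n_uniform + 1)[1:]
    else:
        raise ValueError(f"unknown grid {grid!r}")
    target = emp.evaluate(t)
    k = len(shapes)

    def unpack(theta):
        w = np.exp(theta[:k] - theta[:k].max())
        w = w / w.sum()
        # clip log-rates so exp() can never underflow to an infeasible 0
        mu = np.exp(np.clip(theta[k:], -30.0, 30.0))
        return w, mu

    def fun(theta):
        w, mu = unpack(theta)
        G = _erlang_cdf_matrix(t, shapes, mu) @ w
        return float(np.linalg.norm(G - target))

    return t, fun, unpack


def fit_mixture(
    emp: EmpiricalCdf,
    shapes,
    init: ErlangMixtureSpec,
    *,
    grid: Literal["km", "uniform"] = "km",
    n_uniform: int = 200,
    maxiter: int = 500,
) -> FitResult:
    """Minimise ``||F_hat - G||`` from a given initial spec.

    The weights/rates are optimised in softmax/log space with Nelder-Mead
    (the objective is piecewise smooth but cheap), so every iterate — and
    the returned spec — satisfies the mixture constraints by construction.
    If the optimiser fails to improve on the initial point the initial spec
    is returned with its objective.
    """
    shapes = tuple(int(r) for r in shapes)
    if shapes != tuple(init.shapes):
        raise ValueError(f"init shapes {init.shapes} do not match {shapes}")
    t, fun, unpack = _objective_factory(emp, shapes, grid, n_uniform)
    theta0 = np.concatenate([np.log(init.weights), np.log(init.rates)])
    f0 = fun(theta0)
    res = minimize(
        fun,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": maxiter * len(theta0), "xatol": 1e-8, "fatol": 1e-12},
    )
    w, mu = unpack(res.x)
    spec = ErlangMixtureSpec(
        weights=_project_weights(w), rates=tuple(mu), shapes=shapes
    )
    obj = float(fun(np.concatenate([np.log(spec.weights), np.log(spec.rates)])))
    if obj > f0:  # optimiser (or the weight-floor projection) failed to improve
        spec, obj = init, f0
    return FitResult(
        spec=spec,
        objective=float(obj),
        init_objective=float(f0),
        converged=bool(res.success),
        n_grid=t.size,
        plateau=emp.plateau,
        n_iter=int(res.nit),
    )


def fit_transition(
    emp: EmpiricalCdf,
    shapes=(1, 3, 5),
    *,
    grid: Literal["km", "uniform"] = "km",
    restarts: int = 5,
    maxiter: int = 500,
) -> FitResult:
    """Full fitting pipeline for one transition: moment rates, NNLS weights,
    constrained minimisation, deterministic multi-start over rate scalings.
    Ties in the final objective go to the first start tried."""
    shapes = tuple(int(r) for r in shapes)
    base = np.asarray(init_rates(emp, shapes))
    best: FitResult | None = None
    for factor in RATE_MULTIPLIERS[: max(1, restarts)]:
        rates = tuple(base * factor)
        weights = nnls_init(emp, shapes, rates)
        init = ErlangMixtureSpec(weights=weights, rates=rates, shapes=shapes)
        result = fit_mixture(emp, shapes, init, grid=grid, maxiter=maxiter)
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best
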