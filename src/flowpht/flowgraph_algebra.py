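"""Flowgraph transmittance algebra on the illness-death graph.

A flowgraph labels each branch (i, j) of a multistate model with a
*transmittance*: the transition probability ``p_ij`` times the Laplace
transform ``LT_ij(s)`` of the sojourn-time density on that branch.
Transmittances compose by two rules:

1. branches in series multiply,
2. branches in parallel add.

For the three-state illness-death graph (0 disease-free, 1 recurrence,
2 progression; branches 0->1, 0->2, 1->2) the unnormalised 0->2 first
passage transform is ``p01 p12 LT01 LT12 + p02 LT02``.  Passage is not
certain — a patient may never progress — so the proper first-passage
waiting-time transform conditions on eventual passage by dividing by the
total path probability ``p01 p12 + p02``.

Only series/parallel composition on this acyclic graph is implemented;
graphs with feedback (repeated recurrences) would need Mason's rule and are
out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .empirical_cdf import STATES, validate_cohort
from .phase_type import (
    ErlangMixtureSpec,
    PhaseTypeRepresentation,
    make_erlang_mixture,
    mixture_laplace,
)

__all__ = [
    "Transmittance",
    "FlowgraphModel",
    "series",
    "parallel",
    "first_passage_lt",
    "mixture_transmittance",
    "estimate_transition_probabilities",
    "first_passage_phase_type",
]

_LT0_TOL = 1e-8


@dataclass(frozen=True)
class Transmittance:
    """Branch label: transition probability ``p`` paired with the Laplace
    transform ``lt(s)`` of the branch waiting-time density.

    ``lt`` must be evaluable for complex ``s`` with ``Re(s) >= 0`` and
    satisfy ``lt(0) = 1`` (a proper waiting-time law given the transition
    happens); this is checked at construction.
    """

    p: float
    lt: Callable[[complex], complex]

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0 + 1e-12:
            raise ValueError(f"transition probability must be in (0, 1], got {self.p}")
        at_zero = complex(self.lt(0.0))
        if abs(at_zero - 1.0) > _LT0_TOL:
            raise ValueError(
                f"lt(0) must equal 1 (proper waiting-time law), got {at_zero}"
            )


def mixture_transmittance(p: float, spec: ErlangMixtureSpec) -> Transmittance:
    """Transmittance of a branch with Erlang-mixture sojourn law."""
    return Transmittance(p=p, lt=lambda s: mixture_laplace(spec, s))


def series(a: Transmittance, b: Transmittance) -> Transmittance:
    """Series rule: probabilities and transforms multiply (convolution)."""
    return Transmittance(p=a.p * b.p, lt=lambda s: a.lt(s) * b.lt(s))


def parallel(a: Transmittance, b: Transmittance) -> Transmittance:
    """Parallel rule: transmittances add.

    The combined ``p . lt`` is ``a.p a.lt + b.p b.lt``; it is carried as a
    proper transmittance with ``p = a.p + b.p`` and the mixture transform
    ``(a.p a.lt + b.p b.lt) / (a.p + b.p)`` so that ``lt(0) = 1``.
    """
    total = a.p + b.p
    if total > 1.0 + 1e-12:
        raise ValueError(f"parallel branch probabilities sum to {total} > 1")
    return Transmittance(
        p=total, lt=lambda s: (a.p * a.lt(s) + b.p * b.lt(s)) / total
    )


@dataclass(frozen=True)
class FlowgraphModel:
    """Directed flowgraph: labelled states and per-branch transmittances.

    The illness-death instance has states {0, 1, 2} and branches exactly
    {(0,1), (0,2), (1,2)}.
    """

    branches: Mapping[tuple[int, int], Transmittance]
    states: Mapping[int, str] = field(default_factory=lambda: dict(STATES))

    def __post_init__(self) -> None:
        for (i, j) in self.branches:
            if i not in self.states or j not in self.states:
                raise ValueError(f"branch ({i}, {j}) references unknown states")

    @classmethod
    def illness_death(
        cls,
        t01: Transmittance,
        t02: Transmittance,
        t12: Transmittance,
    ) -> "FlowgraphModel":
        if t01.p + t02.p > 1.0 + 1e-12:
            raise ValueError("p01 + p02 must not exceed 1")
        return cls(branches={(0, 1): t01, (0, 2): t02, (1, 2): t12})


def first_passage_lt(
    model: FlowgraphModel, source: int = 0, target: int = 2
) -> Transmittance:
    """Normalised first-passage transform from ``source`` to ``target``.

    For the illness-death graph this is

        LT(s) = [p01 p12 LT01(s) LT12(s) + p02 LT02(s)] / (p01 p12 + p02),

    a proper waiting-time transform conditional on eventual passage; the
    carried ``p`` is the overall passage probability ``p01 p12 + p02``.
    """
    if (source, target) != (0, 2):
        raise NotImplementedError(
            "first passage is implemented for (source, target) = (0, 2) on the "
            "illness-death graph"
        )
    required = {(0, 1), (0, 2), (1, 2)}
    missing = required - set(model.branches)
    if missing:
        raise ValueError(f"model is missing branches {sorted(missing)}")
    t01, t02, t12 = model.branches[(0, 1)], model.branches[(0, 2)], model.branches[(1, 2)]
    via_recurrence = series(t01, t12)
    if via_recurrence.p + t02.p <= 0:
        raise ValueError("total path probability is zero")
    # parallel() already divides by the summed probability, which is exactly
    # the conditioning on eventual passage
    return parallel(via_recurrence, t02)


def estimate_transition_probabilities(
    cohort: pd.DataFrame, method: str = "plateau"
) -> dict[str, float]:
    """Estimate the branch probabilities ``p01``, ``p02``, ``p12``.

    ``method="ratio"`` is the naive estimate — observed i->j transitions
    over patients at risk in i — which is biased low under censoring
    (censored patients who would have moved are counted in the denominator
    but never in the numerator).

    ``method="plateau"`` (default) uses the plateau of the cause-specific
    cumulative incidence: Aalen-Johansen for the two competing exits from
    state 0, and the complement-Kaplan-Meier plateau for the single exit
    from state 1.  Under independent censoring with follow-up long enough
    to exhaust the sojourn law these are consistent for the latent branch
    probabilities.

    Either way the pipeline accepts user overrides for all three values.
    """
    validate_cohort(cohort)
    if method == "ratio":
        out: dict[str, float] = {}
        for (i, j) in [(0, 1), (0, 2), (1, 2)]:
            at_risk = cohort[cohort["origin"] == i]
            if at_risk.empty:
                raise ValueError(f"cohort has no patients at risk in state {i}")
            n_events = int(
                ((at_risk["status"] == "event") & (at_risk["dest"] == j)).sum()
            )
            out[f"p{i}{j}"] = n_events / at_risk.shape[0]
        return out
    if method != "plateau":
        raise ValueError(f"unknown method {method!r}")

    from .empirical_cdf import aalen_johansen_cdf, extract_competing_sample

    out = {}
    for (i, j) in [(0, 1), (0, 2), (1, 2)]:
        times, causes = extract_competing_sample(cohort, i, j)
        out[f"p{i}{j}"] = aalen_johansen_cdf(times, causes).plateau
    return out


def first_passage_phase_type(
    spec01: ErlangMixtureSpec,
    spec02: ErlangMixtureSpec,
    spec12: ErlangMixtureSpec,
    p01: float,
    p02: float,
    p12: float,
) -> PhaseTypeRepresentation:
    """Explicit phase-type representation of the conditional 0->2 first
    passage law.

    The first-passage time, given passage occurs, is a two-component
    mixture: with probability ``p01 p12 / (p01 p12 + p02)`` the convolution
    of the 0->1 and 1->2 sojourns, otherwise the direct 0->2 sojourn.  Both
    components are phase-type (convolution = chain concatenation, mixture =
    block direct sum), so the whole law is phase-type.  This matrix-analytic
    route is independent of the transform-inversion route and serves as its
    cross-check.
    """
    total = p01 * p12 + p02
    if total <= 0:
        raise ValueError("total path probability is zero")
    w_via = p01 * p12 / total
    w_direct = p02 / total
    ph01 = make_erlang_mixture(spec01)
    ph12 = make_erlang_mixture(spec12)
    ph02 = make_erlang_mixture(spec02)
    m1, m2, m3 = ph01.m, ph12.m, ph02.m
    order = m1 + m2 + m3
    T = np.zeros((order, order))
    T[:m1, :m1] = ph01.T
    # exiting the 0->1 chain feeds the 1->2 chain (convolution)
    T[:m1, m1 : m1 + m2] = np.outer(ph01.T0, ph12.alpha)
    T[m1 : m1 + m2, m1 : m1 + m2] = ph12.T
    T[m1 + m2 :, m1 + m2 :] = ph02.T
    alpha = np.concatenate([w_via * ph01.alpha, np.zeros(m2), w_direct * ph02.alpha])
    return PhaseTypeRepresentation(alpha=alpha, T=T)
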