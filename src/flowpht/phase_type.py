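"""Phase-type distributions and Erlang-mixture constructors.

A phase-type (PH) distribution is the law of the time to absorption of a
finite-state continuous-time Markov chain with ``m`` transient states and one
absorbing state.  It is parameterised by the representation ``(alpha, T)``:
``alpha`` is the initial probability row vector over the transient states
(any remaining mass ``alpha_abs`` starts in the absorbing state, i.e. an atom
at zero), and ``T`` is the m-by-m sub-generator restricted to the transient
states.  The exit-rate vector is ``T0 = -T @ e`` with ``e`` the all-ones
vector.  The basic functionals are

* CDF        ``F(t) = 1 - alpha @ expm(T t) @ e``
* density    ``f(t) = alpha @ expm(T t) @ T0``
* survival   ``S(t) = alpha @ expm(T t) @ e``
* hazard     ``h(t) = f(t) / S(t)``
* Laplace transform ``L(s) = alpha_abs + alpha @ (s I - T)^{-1} @ T0``

An Erlang distribution ``E[r, mu]`` (sum of ``r`` i.i.d. exponentials with
rate ``mu``, in 1/years throughout this package) is the PH chain of ``r``
sequential states; finite mixtures of Erlangs are therefore PH as well and
form the parametric family this package fits to censored waiting-time data.

Matrix exponentials are computed with SciPy's scaling-and-squaring ``expm``
(no eigendecomposition: Erlang blocks make ``T`` defective) and Laplace
transforms solve the linear system ``(s I - T) x = T0`` rather than forming
an inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "PhaseTypeRepresentation",
    "ErlangMixtureSpec",
    "make_erlang",
    "make_erlang_mixture",
    "ph_cdf",
    "ph_pdf",
    "ph_survival",
    "ph_hazard",
    "ph_laplace",
    "mixture_cdf",
    "mixture_pdf",
    "mixture_laplace",
    "sample_absorption_times",
    "ph_to_dict",
    "ph_from_dict",
    "save_ph",
    "load_ph",
]

#: below this survival mass the ratio f/S is numerically meaningless
#: (f and S carry independent absolute errors ~1e-16 from expm)
HAZARD_UNDERFLOW = 1e-12

_ATOL = 1e-10


@dataclass(frozen=True)
class PhaseTypeRepresentation:
    """Representation ``(alpha, T)`` of a phase-type distribution.

    Parameters
    ----------
    alpha
        Initial probability row vector over the ``m`` transient states.
    T
        ``m x m`` sub-generator: strictly negative diagonal, non-negative
        off-diagonal, non-singular.  Units 1/years.
    alpha_abs
        Probability of starting in the absorbing state (atom at t = 0).

    Invariants are checked at construction; operations assume them.
    """

    alpha: np.ndarray
    T: np.ndarray
    alpha_abs: float = 0.0

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        T = np.atleast_2d(np.asarray(self.T, dtype=float))
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "T", T)
        m = alpha.shape[0]
        if T.shape != (m, m):
            raise ValueError(f"T must be {m}x{m}, got {T.shape}")
        if np.any(alpha < -_ATOL):
            raise ValueError("alpha entries must be non-negative")
        total = alpha.sum() + self.alpha_abs
        if not np.isclose(total, 1.0, atol=_ATOL):
            raise ValueError(f"alpha mass + alpha_abs must be 1, got {total}")
        if np.any(np.diag(T) >= 0):
            raise ValueError("T diagonal entries must be strictly negative")
        off = T - np.diag(np.diag(T))
        if np.any(off < -_ATOL):
            raise ValueError("T off-diagonal entries must be non-negative")
        T0 = -T @ np.ones(m)
        if np.any(T0 < -1e-8):
            raise ValueError("exit rates -T e must be non-negative")
        # non-singularity: a sub-generator of an absorbing chain is invertible
        if np.linalg.matrix_rank(T) < m:
            raise ValueError("T must be non-singular")
        alpha.setflags(write=False)
        T.setflags(write=False)

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def T0(self) -> np.ndarray:
        """Exit-rate (absorption) vector ``-T @ e``, clipped at zero."""
        return np.clip(-self.T @ np.ones(self.m), 0.0, None)


@dataclass(frozen=True)
class ErlangMixtureSpec:
    """Mixture of Erlang distributions ``G = sum_i p_i Erlang(r_i, mu_i)``.

    ``weights`` must be strictly positive and sum to one, ``rates`` strictly
    positive (1/years), ``shapes`` positive integers.  The default family
    used by the fitting pipeline has shapes ``(1, 3, 5)``.
    """

    weights: tuple[float, ...]
    rates: tuple[float, ...]
    shapes: tuple[int, ...]

    def __post_init__(self) -> None:
        weights = tuple(float(w) for w in self.weights)
        rates = tuple(float(r) for r in self.rates)
        shapes = tuple(self.shapes)
        if not len(weights) == len(rates) == len(shapes):
            raise ValueError("weights, rates and shapes must have equal length")
        if len(weights) == 0:
            raise ValueError("mixture must have at least one component")
        for r in shapes:
            if not (isinstance(r, (int, np.integer)) and r >= 1):
                raise ValueError(f"shapes must be positive integers, got {r!r}")
        if any(w <= 0 for w in weights):
            raise ValueError("weights must be strictly positive")
        if not np.isclose(sum(weights), 1.0, atol=1e-8):
            raise ValueError(f"weights must sum to 1, got {sum(weights)}")
        if any(mu <= 0 for mu in rates):
            raise ValueError("rates must be strictly positive")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "shapes", tuple(int(r) for r in shapes))

    @property
    def order(self) -> int:
        return int(sum(self.shapes))


def make_erlang(shape: int, rate: float) -> PhaseTypeRepresentation:
    """Phase-type representation of ``Erlang(shape, rate)``.

    ``alpha = (1, 0, ..., 0)``; ``T`` is bidiagonal with ``-rate`` on the
    diagonal and ``+rate`` on the superdiagonal (states traversed in order).
    """
    if not (isinstance(shape, (int, np.integer)) and shape >= 1):
        raise ValueError(f"shape must be a positive integer, got {shape!r}")
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate}")
    r, lam = int(shape), float(rate)
    T = np.diag(np.full(r, -lam)) + np.diag(np.full(r - 1, lam), k=1)
    alpha = np.zeros(r)
    alpha[0] = 1.0
    return PhaseTypeRepresentation(alpha=alpha, T=T)


def make_erlang_mixture(spec: ErlangMixtureSpec) -> PhaseTypeRepresentation:
    """Phase-type representation of an Erlang mixture.

    Block-diagonal ``T`` of order ``sum(shapes)`` with one bidiagonal Erlang
    block per component; ``alpha`` places each weight on the first state of
    its block.  For shapes ``(1, 3, 5)`` this is the canonical 9-state chain
    with ``alpha = (p1, p2, 0, 0, p3, 0, 0, 0, 0)``.
    """
    order = spec.order
    T = np.zeros((order, order))
    alpha = np.zeros(order)
    pos = 0
    for p, mu, r in zip(spec.weights, spec.rates, spec.shapes):
        block = make_erlang(r, mu)
        T[pos : pos + r, pos : pos + r] = block.T
        alpha[pos] = p
        pos += r
    return PhaseTypeRepresentation(alpha=alpha, T=T)


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def ph_cdf(ph: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """CDF ``F(t) = 1 - alpha @ expm(T t) @ e``; ``F(0) = alpha_abs``."""
    t = _check_time(t)
    e = np.ones(ph.m)

    def one(ti: float) -> float:
        return float(np.clip(1.0 - ph.alpha @ expm(ph.T * ti) @ e, 0.0, 1.0))

    if t.ndim == 0:
        return one(float(t))
    return np.array([one(ti) for ti in t])


def ph_survival(ph: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """Survival ``S(t) = alpha @ expm(T t) @ e = 1 - F(t)``."""
    t = _check_time(t)
    e = np.ones(ph.m)

    def one(ti: float) -> float:
        return float(np.clip(ph.alpha @ expm(ph.T * ti) @ e, 0.0, 1.0))

    if t.ndim == 0:
        return one(float(t))
    return np.array([one(ti) for ti in t])


def ph_pdf(ph: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """Density ``f(t) = alpha @ expm(T t) @ T0`` (units 1/years)."""
    t = _check_time(t)
    T0 = ph.T0

    def one(ti: float) -> float:
        return float(max(ph.alpha @ expm(ph.T * ti) @ T0, 0.0))

    if t.ndim == 0:
        return one(float(t))
    return np.array([one(ti) for ti in t])


def ph_hazard(ph: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """Hazard ``h(t) = f(t) / S(t)``.

    Raises
    ------
    FloatingPointError
        If the survival mass has underflowed below ``HAZARD_UNDERFLOW``,
        where the ratio would be numerical noise rather than a hazard.
    """
    t = _check_time(t)

    def one(ti: float) -> float:
        s = ph_survival(ph, ti)
        if s < HAZARD_UNDERFLOW:
            raise FloatingPointError(
                f"survival underflow at t={ti}: S(t)={s:g} < {HAZARD_UNDERFLOW:g}"
            )
        return ph_pdf(ph, ti) / s

    if t.ndim == 0:
        return one(float(t))
    return np.array([one(ti) for ti in t])


def ph_laplace(ph: PhaseTypeRepresentation, s) -> complex:
    """Laplace transform ``L(s) = alpha_abs + alpha @ (s I - T)^{-1} @ T0``.

    Valid for ``Re(s) > 0``; ``s = 0`` is accepted (the system is solvable
    because ``T`` is non-singular) and returns the total mass, 1 for a
    proper distribution.  The linear system is solved per evaluation point.
    """
    s_arr = np.asarray(s)
    I = np.eye(ph.m)
    T0 = ph.T0

    def one(si: complex) -> complex:
        if si.real < 0:
            raise ValueError(f"Laplace transform requires Re(s) >= 0, got {si}")
        A = si * I - ph.T
        try:
            x = np.linalg.solve(A, T0.astype(complex))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular system at s={si}") from exc
        return complex(ph.alpha_abs + ph.alpha @ x)

    if s_arr.ndim == 0:
        return one(complex(s_arr))
    return np.array([one(complex(si)) for si in s_arr])


# ---------------------------------------------------------------------------
# Closed-form Erlang-mixture functionals.  These evaluate the mixture law
# directly (gamma CDFs / rational Laplace transforms) and are the cheap path
# used by fitting and transform composition; the (alpha, T) route above is
# the matrix-analytic equivalent.

def mixture_cdf(spec: ErlangMixtureSpec, t) -> np.ndarray | float:
    """``G(t) = sum_i p_i F_i(t)`` with ``F_i`` the Erlang(r_i, mu_i) CDF."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for p, mu, r in zip(spec.weights, spec.rates, spec.shapes):
        out = out + p * gammainc(r, mu * t)
    return out if out.ndim else float(out)


def mixture_pdf(spec: ErlangMixtureSpec, t) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for p, mu, r in zip(spec.weights, spec.rates, spec.shapes):
        out = out + p * _gamma_dist.pdf(t, a=r, scale=1.0 / mu)
    return out if out.ndim else float(out)


def mixture_laplace(spec: ErlangMixtureSpec, s):
    """``L(s) = sum_i p_i (mu_i / (s + mu_i))^{r_i}``; accepts complex s."""
    s = np.asarray(s, dtype=complex)
    out = np.zeros_like(s)
    for p, mu, r in zip(spec.weights, spec.rates, spec.shapes):
        out = out + p * (mu / (s + mu)) ** r
    return out if out.ndim else complex(out)


def sample_absorption_times(
    ph: PhaseTypeRepresentation, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` absorption times by simulating the underlying Markov chain.

    Vectorised over walkers: each step draws exponential holding times from
    the diagonal rates and jumps according to the embedded chain (absorbing
    state included).  Used as a Monte-Carlo cross-check of the analytic
    functionals.
    """
    m = ph.m
    rates = -np.diag(ph.T)
    # embedded jump chain over m transient states + absorbing state m
    P = np.zeros((m, m + 1))
    off = ph.T - np.diag(np.diag(ph.T))
    P[:, :m] = off / rates[:, None]
    P[:, m] = ph.T0 / rates
    Pcum = np.cumsum(P, axis=1)

    start_probs = np.concatenate([ph.alpha, [ph.alpha_abs]])
    state = rng.choice(m + 1, size=n, p=start_probs)
    times = np.zeros(n)
    active = state < m
    while np.any(active):
        idx = np.nonzero(active)[0]
        cur = state[idx]
        times[idx] += rng.exponential(1.0 / rates[cur])
        u = rng.random(idx.size)
        nxt = (u[:, None] <= Pcum[cur]).argmax(axis=1)
        state[idx] = nxt
        active[idx] = nxt < m
    return times


# ---------------------------------------------------------------------------
# Plain-text (JSON) serialization

def ph_to_dict(ph: PhaseTypeRepresentation) -> dict:
    return {
        "kind": "phase_type",
        "alpha": ph.alpha.tolist(),
        "alpha_abs": ph.alpha_abs,
        "T": ph.T.tolist(),
    }


def ph_from_dict(d: dict) -> PhaseTypeRepresentation:
    return PhaseTypeRepresentation(
        alpha=np.asarray(d["alpha"], dtype=float),
        T=np.asarray(d["T"], dtype=float),
        alpha_abs=float(d.get("alpha_abs", 0.0)),
    )


def spec_to_dict(spec: ErlangMixtureSpec) -> dict:
    return {
        "kind": "erlang_mixture",
        "weights": list(spec.weights),
        "rates": list(spec.rates),
        "shapes": list(spec.shapes),
    }


def spec_from_dict(d: dict) -> ErlangMixtureSpec:
    return ErlangMixtureSpec(
        weights=tuple(d["weights"]),
        rates=tuple(d["rates"]),
        shapes=tuple(int(r) for r in d["shapes"]),
    )


def save_ph(obj, path: str | Path) -> None:
    """Write a representation or mixture spec to a JSON file (round-trip
    exact: JSON preserves the shortest-repr decimal of each float)."""
    if isinstance(obj, PhaseTypeRepresentation):
        d = ph_to_dict(obj)
    elif isinstance(obj, ErlangMixtureSpec):
        d = spec_to_dict(obj)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    Path(path).write_text(json.dumps(d, indent=1))


def load_ph(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d.get("kind") == "phase_type":
        return ph_from_dict(d)
    if d.get("kind") == "erlang_mixture":
        return spec_from_dict(d)
    raise ValueError(f"unrecognized kind {d.get('kind')!r} in {path}")
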