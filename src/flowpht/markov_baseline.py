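"""Homogeneous continuous-time Markov illness-death baseline.

The comparison model replaces the semi-Markov sojourn laws with a
time-homogeneous Markov chain on {0, 1, 2} (state 2 absorbing) whose
intensities are the occurrence/exposure maximum-likelihood estimates

    q_ij = (# observed i -> j transitions) / (total time at risk in i),

valid because transition times are exactly observed in the event-history
table (censored sojourns contribute exposure but no event).  The 0 -> 2
first-passage survival is then the phase-type survival with initial vector
(1, 0) and sub-generator equal to the {0, 1} block of Q.  Note this is the
*unconditional* non-absorption probability: in the Markov chain absorption
in state 2 is certain, so no conditioning on eventual passage applies —
one of the structural differences from the flowgraph model, whose
first-passage law conditions on progression occurring at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .empirical_cdf import validate_cohort
from .phase_type import PhaseTypeRepresentation, ph_survival

__all__ = ["IntensityMatrix", "estimate_intensities", "markov_first_passage_survival"]


@dataclass(frozen=True)
class IntensityMatrix:
    """3x3 generator with free intensities q01, q02, q12 (1/years)."""

    q01: float
    q02: float
    q12: float

    def __post_init__(self) -> None:
        for name in ("q01", "q02", "q12"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def Q(self) -> np.ndarray:
        return np.array(
            [
                [-(self.q01 + self.q02), self.q01, self.q02],
                [0.0, -self.q12, self.q12],
                [0.0, 0.0, 0.0],
            ]
        )

    @property
    def transient_block(self) -> np.ndarray:
        """Sub-generator restricted to the transient states {0, 1}."""
        return self.Q[:2, :2]


def estimate_intensities(cohort: pd.DataFrame) -> IntensityMatrix:
    """Occurrence/exposure MLE of the intensities from exact transition data."""
    validate_cohort(cohort)
    if cohort.empty:
        raise ValueError("cohort is empty")
    q = {}
    for (i, j) in [(0, 1), (0, 2), (1, 2)]:
        rows = cohort[cohort["origin"] == i]
        exposure = float(rows["duration_years"].sum())
        n_ij = int(((rows["status"] == "event") & (rows["dest"] == j)).sum())
        if exposure <= 0:
            if n_ij > 0:
                raise ValueError(
                    f"observed {i}->{j} transitions with zero exposure in state {i}"
                )
            q[f"q{i}{j}"] = 0.0
        else:
            q[f"q{i}{j}"] = n_ij / exposure
    return IntensityMatrix(**q)


def markov_first_passage_survival(Q: IntensityMatrix, grid) -> np.ndarray:
    """P(not yet in state 2 by t | start in state 0) on a time grid.

    Computed as the phase-type survival with alpha = (1, 0) and sub-
    generator the {0, 1} block of Q, i.e. the row-0 transient mass of
    ``expm(Q_sub t)``.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("grid times must be non-negative")
    Tsub = Q.transient_block
    if Q.q01 + Q.q02 <= 0 or Q.q12 <= 0:
        raise ValueError(
            "degenerate generator: both exit rates from 0 and the 1->2 rate "
            "must be positive for a proper first-passage law"
        )
    ph = PhaseTypeRepresentation(alpha=np.array([1.0, 0.0]), T=Tsub)
    return np.asarray(ph_survival(ph, grid))
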