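"""Per-transition empirical waiting-time distributions under right censoring.

The cohort is an event-history table: one row per observed transition or
censoring interval, with a semi-Markov clock that restarts on every state
entry.  For each branch (i, j) of the multistate graph we build a censored
sample of sojourn times in state i — the time to j when that transition was
observed, and the time to exit by any other cause (competing transition or
end of follow-up) recorded as censored — and estimate the waiting-time CDF
with the Kaplan-Meier product-limit estimator (``F = 1 - S_KM``, ties
between events and censorings at the same time resolved events-first).

Treating the competing transition as censoring gives the cause-specific
(latent waiting time) estimate standard in semi-Markov flowgraph practice;
it assumes independence between the competing sojourn clocks.  When the
largest observation is censored the estimate plateaus below one; the
defective plateau is kept as-is and handed to the fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "CensoredSample",
    "EmpiricalCdf",
    "km_cdf",
    "extract_transition_samples",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "CENSORED_DEST",
    "STATES",
]

#: destination marker used for censored rows in the cohort table
CENSORED_DEST = -1

#: state labels of the illness-death instance
STATES = {0: "disease-free", 1: "recurrence", 2: "progression"}

COHORT_COLUMNS = ["id", "origin", "dest", "duration_years", "status"]


@dataclass(frozen=True)
class CensoredSample:
    """Right-censored durations: ``events[k] = 1`` iff the transition was
    observed at ``times[k]``, 0 for censoring."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if times.size == 0:
            raise ValueError("sample is empty")
        if np.any(times < 0):
            raise ValueError("durations must be non-negative")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0/1 indicators")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass(frozen=True)
class EmpiricalCdf:
    """Right-continuous step CDF estimate with jumps at event times.

    ``values[k]`` is the estimate at and after ``jump_times[k]``; the
    estimate is 0 before the first jump.  ``plateau`` (the last value) may
    be below 1 when the largest observation is censored.
    """

    jump_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if jt.ndim != 1 or jt.shape != vals.shape or jt.size == 0:
            raise ValueError("jump_times and values must be equal-length 1-d arrays")
        if np.any(np.diff(jt) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(np.diff(vals) < -1e-12) or vals[0] < 0 or vals[-1] > 1 + 1e-12:
            raise ValueError("values must be non-decreasing within [0, 1]")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    @property
    def plateau(self) -> float:
        return float(self.values[-1])

    def evaluate(self, t) -> np.ndarray | float:
        """Step-function value at ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        padded = np.concatenate([[0.0], self.values])
        out = padded[idx]
        return out if out.ndim else float(out)

    def median(self) -> float | None:
        """Smallest jump time with mass >= 1/2, or None if not reached."""
        hit = np.nonzero(self.values >= 0.5)[0]
        if hit.size == 0:
            return None
        return float(self.jump_times[hit[0]])

    def restricted_mean(self) -> float:
        """Mean of the estimate restricted to [0, last jump]: integral of
        ``1 - F`` over the observed range."""
        t = np.concatenate([[0.0], self.jump_times])
        surv_left = np.concatenate([[1.0], 1.0 - self.values[:-1]])
        return float(np.sum(surv_left * np.diff(t)))


def renormalized(emp: EmpiricalCdf) -> EmpiricalCdf:
    """Rescale a defective estimate so its plateau is 1.

    A cause-specific Kaplan-Meier curve on a branch with latent
    never-take-this-branch mass plateaus near the branch probability; the
    conditional sojourn law given the transition is recovered (to good
    approximation when the at-risk pool is dominated by patients who never
    leave) by dividing out the plateau.  The fitting pipeline applies this
    before matching a proper parametric CDF.
    """
    if emp.plateau <= 0:
        raise ValueError("cannot renormalize an all-zero estimate")
    return EmpiricalCdf(jump_times=emp.jump_times, values=emp.values / emp.plateau)


def km_cdf(sample: CensoredSample) -> EmpiricalCdf:
    """Kaplan-Meier estimate ``F = 1 - S_KM`` of a censored sample."""
    if sample.n_events == 0:
        raise ValueError("all observations censored: no estimable distribution")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    event_times = np.unique(sample.times[sample.events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return EmpiricalCdf(jump_times=event_times, values=1.0 - surv)


def aalen_johansen_cdf(times, causes) -> EmpiricalCdf:
    """Cause-specific cumulative incidence (Aalen-Johansen) step function.

    ``causes[k]`` is 1 for the cause of interest, 2 for a competing exit,
    0 for censoring.  The estimator accumulates, at each cause-1 event
    time, the overall at-risk survival times the cause-1 event fraction:

        CIF(t) = sum_{t_k <= t} S_any(t_k-) d_1(t_k) / Y(t_k),

    with ``S_any`` the Kaplan-Meier survival treating *any* exit as an
    event.  Unlike the cause-specific Kaplan-Meier complement, this is
    consistent for ``P(sojourn <= t, exit by cause 1)`` whatever the size
    of the competing branch; its plateau estimates the branch probability.
    With no competing cause it reduces to ``1 - KM`` exactly.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=int)
    if times.shape != causes.shape or times.ndim != 1:
        raise ValueError("times and causes must be 1-d arrays of equal length")
    if not np.isin(causes, (0, 1, 2)).all():
        raise ValueError("causes must take values 0 (censored), 1, or 2")
    if not (causes == 1).any():
        raise ValueError("no events of the cause of interest")
    order = np.argsort(times, kind="stable")
    times, causes = times[order], causes[order]
    n = times.size
    jump_times, values = [], []
    cif, s_any = 0.0, 1.0
    i = 0
    while i < n:
        t = times[i]
        j = i
        d_any = d_cause = 0
        while j < n and times[j] == t:
            d_any += int(causes[j] > 0)
            d_cause += int(causes[j] == 1)
            j += 1
        at_risk = n - i
        if d_cause:
            cif += s_any * d_cause / at_risk
            jump_times.append(t)
            values.append(cif)
        if d_any:
            s_any *= 1.0 - d_any / at_risk
        i = j
    return EmpiricalCdf(jump_times=np.asarray(jump_times), values=np.asarray(values))


def extract_competing_sample(
    cohort: pd.DataFrame, origin: int, dest: int
) -> tuple[np.ndarray, np.ndarray]:
    """Durations and cause codes (1 = ``origin -> dest``, 2 = competing
    transition, 0 = censored) for all sojourns in ``origin``."""
    validate_cohort(cohort)
    if origin not in STATES or dest not in STATES:
        raise ValueError(f"unknown state labels ({origin}, {dest})")
    rows = cohort[cohort["origin"] == origin]
    if rows.empty:
        raise ValueError(f"cohort has no sojourns in state {origin}")
    times = rows["duration_years"].to_numpy(dtype=float)
    is_event = (rows["status"] == "event").to_numpy()
    is_cause = is_event & (rows["dest"] == dest).to_numpy()
    causes = np.where(is_cause, 1, np.where(is_event, 2, 0))
    return times, causes


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check schema and state labels of an event-history table."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if not cohort["status"].isin(["event", "censored"]).all():
        bad = sorted(set(cohort["status"]) - {"event", "censored"})
        raise ValueError(f"unknown status values {bad}")
    states = set(STATES)
    if not cohort["origin"].isin(states).all():
        bad = sorted(set(cohort["origin"]) - states)
        raise ValueError(f"unknown origin states {bad}")
    ev = cohort["status"] == "event"
    if not cohort.loc[ev, "dest"].isin(states).all():
        bad = sorted(set(cohort.loc[ev, "dest"]) - states)
        raise ValueError(f"unknown destination states {bad}")
    if (cohort["duration_years"] < 0).any():
        raise ValueError("durations must be non-negative")
    return cohort


def extract_transition_samples(
    cohort: pd.DataFrame, origin: int, dest: int
) -> CensoredSample:
    """Censored sojourn-time sample for the branch ``origin -> dest``.

    Every patient observed in ``origin`` contributes one duration: an event
    if they moved to ``dest``, censored if they exited any other way
    (competing transition or end of follow-up).
    """
    validate_cohort(cohort)
    if origin not in STATES or dest not in STATES:
        raise ValueError(f"unknown state labels ({origin}, {dest})")
    rows = cohort[cohort["origin"] == origin]
    if rows.empty:
        raise ValueError(f"cohort has no sojourns in state {origin}")
    times = rows["duration_years"].to_numpy(dtype=float)
    events = ((rows["status"] == "event") & (rows["dest"] == dest)).to_numpy()
    return CensoredSample(times=times, events=events.astype(int))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read an event-history CSV (columns id, origin, dest, duration_years,
    status; censored rows carry dest = -1)."""
    df = pd.read_csv(path)
    df["origin"] = df["origin"].astype(int)
    df["dest"] = df["dest"].astype(int)
    df["duration_years"] = df["duration_years"].astype(float)
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort)
    cohort.to_csv(path, index=False)
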