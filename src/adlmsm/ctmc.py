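"""Continuous-time Markov chain machinery for the three-state disability model.

A time-homogeneous CTMC on states ``1..k`` is specified by its generator
(intensity) matrix ``Q``: off-diagonal entry ``q[r][s]`` is the instantaneous
per-year rate of moving from state ``r`` to state ``s``, and each diagonal
entry is the negative sum of the off-diagonal entries in its row, so rows sum
to zero.  The transition probability matrix over an interval of length ``t``
is the matrix exponential ``P(t) = expm(Q t)``.

Covariates act multiplicatively on intensities (proportional intensities):
``q_rs(z) = q_rs0 * exp(beta_rs' z)``, the intensity-scale analogue of a
proportional hazards model.  ``exp(beta)`` is reported as a hazard ratio.

The simulator produces right-continuous piecewise-constant sample paths:
sojourn times are exponential with rate ``-q[r][r]`` and the next state is
drawn from the embedded jump chain ``q[r][s] / (-q[r][r])``.  Piecewise
time-variation of ``Q`` (covariates held constant within assessment
intervals) is handled exactly via the memorylessness of the exponential.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TRANSITIONS",
    "CovariateModel",
    "Trajectory",
    "build_intensity_matrix",
    "covariate_intensity",
    "transition_probability",
    "simulate_path",
    "observe_at",
]

#: Ordered transitions of the full three-state generator, in the conventional
#: reporting order 1-2, 1-3, 2-1, 2-3, 3-1, 3-2.
TRANSITIONS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2))


def build_intensity_matrix(
    rates: Mapping[tuple[int, int], float], n_states: int | None = None
) -> np.ndarray:
    """Assemble a generator matrix from off-diagonal transition rates.

    Parameters
    ----------
    rates
        Mapping ``(r, s) -> q_rs`` with 1-based states, ``r != s`` and every
        rate non-negative.  Unspecified off-diagonal entries are zero
        (disallowed transitions).
    n_states
        Number of states; inferred from the largest state index if omitted.

    Returns
    -------
    numpy.ndarray
        ``(k, k)`` generator with diagonal set to the negative off-diagonal
        row sum, so rows sum to zero exactly.
    """
    if n_states is None:
        n_states = max(max(r, s) for r, s in rates)
    Q = np.zeros((n_states, n_states))
    for (r, s), q in rates.items():
        if r == s:
            raise ValueError(f"rate key ({r}, {s}) is diagonal; only r != s allowed")
        if not (1 <= r <= n_states and 1 <= s <= n_states):
            raise ValueError(f"state index out of range in key ({r}, {s})")
        if not np.isfinite(q) or q < 0:
            raise ValueError(f"intensity q[{r}][{s}] = {q} must be finite and >= 0")
        Q[r - 1, s - 1] = q
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class CovariateModel:
    """Proportional-intensity model: baseline log-intensities plus covariate effects.

    ``log_baseline[(r, s)]`` holds ``log q_rs0`` and ``coefficients[(r, s)]``
    maps covariate names to the log hazard-ratio ``beta`` for that transition.
    ``covariates`` fixes the schema; every coefficient key must belong to it.
    """

    log_baseline: Mapping[tuple[int, int], float]
    coefficients: Mapping[tuple[int, int], Mapping[str, float]] = field(default_factory=dict)
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for trans, coefs in self.coefficients.items():
            if trans not in self.log_baseline:
                raise ValueError(f"coefficients given for unmodelled transition {trans}")
            unknown = set(coefs) - set(self.covariates)
            if unknown:
                raise ValueError(f"coefficients for covariates outside the schema: {sorted(unknown)}")
        for trans, theta in self.log_baseline.items():
            if not np.isfinite(theta):
                raise ValueError(f"log baseline intensity for {trans} is not finite")


def covariate_intensity(model: CovariateModel, z: Mapping[str, float]) -> np.ndarray:
    """Evaluate the generator at covariate vector ``z``.

    ``q[r][s] = exp(theta_rs + beta_rs' z)`` for each modelled transition;
    the diagonal is rebuilt as the negative row sum.
    """
    missing = set(model.covariates) - set(z)
    if missing:
        raise ValueError(f"covariate vector missing values for: {sorted(missing)}")
    rates: dict[tuple[int, int], float] = {}
    for trans, theta in model.log_baseline.items():
        eta = theta
        for name, beta in model.coefficients.get(trans, {}).items():
            eta += beta * float(z[name])
        rates[trans] = float(np.exp(eta))
    n = max(max(r, s) for r, s in model.log_baseline)
    return build_intensity_matrix(rates, n_states=n)


def transition_probability(Q: np.ndarray, delta: float) -> np.ndarray:
    """Transition probability matrix over an interval of ``delta`` years.

    Computed as ``expm(Q * delta)`` (scaling-and-squaring Pade).  Rows sum to
    one; tiny negative round-off is clipped to zero.
    """
    Q = np.asarray(Q, dtype=float)
    if delta < 0:
        raise ValueError(f"interval length must be >= 0, got {delta}")
    P = expm(Q * float(delta))
    return np.clip(P, 0.0, 1.0)


@dataclass(frozen=True)
class Trajectory:
    """Right-continuous piecewise-constant path: ``entries[i] = (entry_time, state)``."""

    entries: tuple[tuple[float, int], ...]
    t_max: float

    def state_at(self, t: float) -> int:
        if t < 0 or t > self.t_max:
            raise ValueError(f"time {t} outside the simulated horizon [0, {self.t_max}]")
        times = [e[0] for e in self.entries]
        return self.entries[bisect_right(times, t) - 1][1]


def simulate_path(
    Q_of_time: Callable[[float], np.ndarray] | np.ndarray,
    start_state: int,
    t_max: float,
    rng: np.random.Generator,
    change_times: Sequence[float] = (),
) -> Trajectory:
    """Simulate one CTMC sample path on ``[0, t_max]``.

    Parameters
    ----------
    Q_of_time
        Either a constant generator matrix or a callable ``t -> Q`` returning
        the generator in force from time ``t``.  ``Q`` must be constant
        between consecutive ``change_times``; at each change time the clock
        is restarted, which is exact by memorylessness of the exponential
        sojourn.
    start_state
        1-based initial state.
    change_times
        Sorted times (within ``(0, t_max)``) at which ``Q_of_time`` may change.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    q_fun = Q_of_time if callable(Q_of_time) else (lambda _t, _Q=np.asarray(Q_of_time): _Q)
    breaks = [float(b) for b in change_times if 0.0 < float(b) < t_max]

    t = 0.0
    state = int(start_state)
    entries = [(0.0, state)]
    k = None
    while t < t_max:
        Q = np.asarray(q_fun(t), dtype=float)
        if k is None:
            k = Q.shape[0]
            if not (1 <= state <= k):
                raise ValueError(f"start state {state} outside 1..{k}")
        out_rate = -Q[state - 1, state - 1]
        next_break = next((b for b in breaks if b > t), t_max)
        if out_rate <= 0.0:
            t = next_break  # no exit possible under the current generator
            continue
        wait = rng.exponential(1.0 / out_rate)
        if t + wait >= next_break:
            t = next_break  # generator may change; redraw (memoryless)
            continue
        t = t + wait
        probs = Q[state - 1].copy()
        probs[state - 1] = 0.0
        probs = probs / out_rate
        state = int(rng.choice(k, p=probs)) + 1
        entries.append((t, state))
    return Trajectory(tuple(entries), float(t_max))


def observe_at(path: Trajectory, times: Sequence[float]) -> list[int]:
    """Read the state occupied at each requested time (right-continuous).

    A state entered exactly at time ``t`` is the state observed at ``t``.
    Times outside ``[0, t_max]`` raise; transitions between requested times
    are invisible (interval censoring by construction).
    """
    return [path.state_at(float(t)) for t in times]
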