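"""Trial-by-trial delta-rule learning of the three visuomotor gains.

After every saccade the squared driving error |E|^2 is reduced by gradient
descent on the gains:

    omega(n+1) = omega(n) - 2 * alpha * E(n) * g(n)

where ``alpha`` is a diagonal matrix of per-gain learning rates (units
1/deg^2) and ``g`` is the learner's internal estimate of dE/domega. The
gradient treats the trans-saccadic displacement Pd as an external given —
in CVE it is not differentiated through the landing-point contingency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ErrorMode,
    GainState,
    Observables,
    Paradigm,
    compute_observables,
    prediction_error,
    postdiction_error,
)

__all__ = [
    "LearningRates",
    "Trajectory",
    "SimulationDiverged",
    "error_gradient",
    "delta_update",
    "simulate",
    "DIVERGENCE_CAP",
]

#: abort threshold on |gain|; the fitting bound on alpha exists to keep the
#: saccade vector from taking a strong exponential shape, and runaway gains
#: past this cap never return.
DIVERGENCE_CAP = 10.0


@dataclass(frozen=True)
class LearningRates:
    """Per-gain learning rates, units 1/deg^2 (multiply error x gradient)."""

    alpha_v: float
    alpha_m: float
    alpha_cd: float

    def __post_init__(self) -> None:
        for name in ("alpha_v", "alpha_m", "alpha_cd"):
            a = getattr(self, name)
            if not math.isfinite(a) or a < 0:
                raise ValueError(f"learning rate {name}={a!r} must be finite and >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_v, self.alpha_m, self.alpha_cd)


class SimulationDiverged(RuntimeError):
    """A gain left the plausible region during simulation."""

    def __init__(self, trial: int, state: tuple[float, float, float], cap: float):
        self.trial = trial
        self.state = state
        self.cap = cap
        super().__init__(
            f"gain state {state} exceeded cap {cap} at trial {trial}"
        )


def error_gradient(
    state: GainState, paradigm: Paradigm, mode: ErrorMode | str
) -> tuple[float, float, float]:
    """Learner's gradient of the driving error wrt (omega_v, omega_m, omega_cd).

    Pd is clamped: the printed update vectors contain no terms from the CVE
    landing-point contingency.
    """
    mode = ErrorMode(mode)
    wv, wm, wcd = state.as_tuple()
    P1 = paradigm.P1
    if mode is ErrorMode.PREDICTION:
        return (
            P1 * (wm * (wcd - 1.0) - 1.0),
            P1 * wv * (wcd - 1.0),
            P1 * wv * wm,
        )
    if mode is ErrorMode.POSTDICTION:
        return (
            P1 * wm * (wcd - 2.0),
            P1 * wv * (wcd - 2.0),
            P1 * wv * wm,
        )
    # visual mode: E = V2 = P1(1 - wv*wm) + Pd, Pd clamped
    return (-P1 * wm, -P1 * wv, 0.0)


def _error(obs: Observables, mode: ErrorMode) -> float:
    if mode is ErrorMode.PREDICTION:
        return prediction_error(obs)
    if mode is ErrorMode.POSTDICTION:
        return postdiction_error(obs)
    return obs.V2


def delta_update(
    state: GainState,
    rates: LearningRates,
    paradigm: Paradigm,
    mode: ErrorMode | str,
) -> GainState:
    """One delta-rule step: omega - 2*alpha*E*g, evaluated on the pre-update state."""
    mode = ErrorMode(mode)
    E = _error(compute_observables(state, paradigm), mode)
    gv, gm, gcd = error_gradient(state, paradigm, mode)
    av, am, acd = rates.as_tuple()
    return GainState(
        state.omega_v - 2.0 * av * E * gv,
        state.omega_m - 2.0 * am * E * gm,
        state.omega_cd - 2.0 * acd * E * gcd,
    )


@dataclass
class Trajectory:
    """Per-trial record of a simulated learning session.

    Trial 1 holds the initial state before any update; ``error[n-1]`` is the
    driving error evaluated on the state of trial n.
    """

    mode: ErrorMode
    paradigm: Paradigm
    rates: LearningRates
    omega: np.ndarray  # (N, 3)
    error: np.ndarray  # (N,)
    observables: pd.DataFrame = field(repr=False)  # (N, 8) columns as Observables

    def __len__(self) -> int:
        return self.omega.shape[0]

    def state(self, trial: int) -> GainState:
        """Gain state at 1-based trial index."""
        wv, wm, wcd = self.omega[trial - 1]
        return GainState(wv, wm, wcd)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table (trial, gains, observables, error, tags)."""
        df = self.observables.copy()
        df.insert(0, "trial", np.arange(1, len(self) + 1))
        df.insert(1, "omega_v", self.omega[:, 0])
        df.insert(2, "omega_m", self.omega[:, 1])
        df.insert(3, "omega_cd", self.omega[:, 2])
        df["error"] = self.error
        df["mode"] = self.mode.value
        df["paradigm"] = self.paradigm.kind.value
        return df


_OBS_COLUMNS = ["V1", "M", "CDM", "CDV", "V2_hat", "Pd", "V2", "V1_hat"]


def simulate(
    state0: GainState,
    rates: LearningRates,
    paradigm: Paradigm,
    n_trials: int,
    mode: ErrorMode | str,
    cap: float = DIVERGENCE_CAP,
) -> Trajectory:
    """Iterate the delta rule for ``n_trials`` trials (n_trials - 1 updates).

    Raises
    ------
    SimulationDiverged
        if any |gain| exceeds ``cap`` at any trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mode = ErrorMode(mode)
    omega = np.empty((n_trials, 3))
    errors = np.empty(n_trials)
    obs_rows = np.empty((n_trials, len(_OBS_COLUMNS)))
    state = state0
    for n in range(n_trials):
        if max(abs(x) for x in state.as_tuple()) > cap:
            raise SimulationDiverged(n + 1, state.as_tuple(), cap)
        obs = compute_observables(state, paradigm)
        omega[n] = state.as_tuple()
        errors[n] = _error(obs, mode)
        obs_rows[n] = (obs.V1, obs.M, obs.CDM, obs.CDV, obs.V2_hat, obs.Pd, obs.V2, obs.V1_hat)
        if n < n_trials - 1:
            state = delta_update(state, rates, paradigm, mode)
    return Trajectory(
        mode=mode,
        paradigm=paradigm,
        rates=rates,
        omega=omega,
        error=errors,
        observables=pd.DataFrame(obs_rows, columns=_OBS_COLUMNS),
    )
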