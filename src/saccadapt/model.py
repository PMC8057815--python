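"""Closed-form forward model of a single double-step saccade trial.

The visuomotor system is reduced to three scalar gains: a visual gain
``omega_v`` mapping physical target eccentricity onto the perceived
pre-saccadic target position, a motor gain ``omega_m`` mapping the percept
onto the saccadic motor command (inverse model), and a corollary-discharge
gain ``omega_cd`` mapping the copy of the motor command onto the computed
displacement of visual space CDV (forward dynamics model).

Given a gain state and a paradigm (constant target step CTS, constant
visual error CVE, or a step-free baseline) the forward model produces every
trial observable in closed form, together with the two candidate error
signals that can drive learning:

* the visual prediction error ``E_pre = V2 - V2_hat``, the mismatch between
  the post-saccadic retinal target position and its CD-based prediction;
* the postdictive motor error ``E_post = V1_hat - M``, the mismatch between
  the motor command and the pre-saccadic target position postdicted from
  post-saccadic vision via CDV.

All quantities are horizontal degrees of visual angle, rightward/outward
positive. The module is fully deterministic; execution noise lives in
:mod:`saccadapt.synth`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "ParadigmKind",
    "ErrorMode",
    "GainState",
    "Paradigm",
    "Observables",
    "NoiseSpec",
    "compute_observables",
    "prediction_error",
    "postdiction_error",
    "error_value",
    "error_from_displacement",
]


class ParadigmKind(str, enum.Enum):
    """Double-step paradigm family."""

    CTS = "CTS"  # target steps by Ps relative to its pre-saccadic position
    CVE = "CVE"  # target reappears Ps away from the saccade landing point
    BASELINE = "BASELINE"  # no step; behaves as CTS with Ps = 0


class ErrorMode(str, enum.Enum):
    """Which error signal drives learning."""

    PREDICTION = "prediction"
    POSTDICTION = "postdiction"
    VISUAL = "visual"  # raw post-saccadic retinal error V2 (comparison mode)


@dataclass(frozen=True)
class GainState:
    """The three visuomotor gains (dimensionless)."""

    omega_v: float
    omega_m: float
    omega_cd: float

    def __post_init__(self) -> None:
        for name in ("omega_v", "omega_m", "omega_cd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite gain {name}={getattr(self, name)!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.omega_v, self.omega_m, self.omega_cd)


@dataclass(frozen=True)
class Paradigm:
    """Condition descriptor: paradigm kind, target eccentricity and step.

    Parameters
    ----------
    kind:
        CTS, CVE or BASELINE.
    P1:
        Physical eccentricity of the pre-saccadic target, degrees, > 0.
    Ps:
        Signed target step in degrees; negative = inward (against saccade
        direction), positive = outward. Must be 0 for BASELINE.
    """

    kind: ParadigmKind
    P1: float = 13.0
    Ps: float = 0.0

    def __post_init__(self) -> None:
        kind = ParadigmKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not (self.P1 > 0):
            raise ValueError(f"P1 must be positive, got {self.P1}")
        if kind is ParadigmKind.BASELINE and self.Ps != 0:
            raise ValueError("BASELINE paradigm requires Ps = 0")

    @property
    def steps_with_landing(self) -> bool:
        return self.kind is ParadigmKind.CVE

    def baseline(self) -> "Paradigm":
        """The matching step-free condition (CTS with Ps = 0)."""
        return Paradigm(ParadigmKind.BASELINE, P1=self.P1, Ps=0.0)


# Named constructors for the four study conditions (P1 = 13 deg, |Ps| = 3 deg).
def condition(name: str, P1: float = 13.0, step: float = 3.0) -> Paradigm:
    """Build one of the canonical conditions: CTS_in/CTS_out/CVE_in/CVE_out/baseline."""
    name = name.lower()
    if name == "baseline":
        return Paradigm(ParadigmKind.BASELINE, P1=P1, Ps=0.0)
    try:
        kind_s, direction = name.split("_")
        kind = ParadigmKind(kind_s.upper())
        sign = {"in": -1.0, "out": +1.0}[direction]
    except (ValueError, KeyError):
        raise ValueError(f"unknown condition name {name!r}") from None
    return Paradigm(kind, P1=P1, Ps=sign * abs(step))


CONDITION_NAMES = ("CTS_in", "CTS_out", "CVE_in", "CVE_out")


@dataclass(frozen=True)
class Observables:
    """All deterministic per-trial quantities, degrees of visual angle.

    ``V1``     perceived pre-saccadic target position,
    ``M``      motor command / saccade vector,
    ``CDM``    corollary discharge of the motor command (= M),
    ``CDV``    computed displacement of visual space,
    ``V2_hat`` predicted post-saccadic retinal target position (V1 - CDV),
    ``Pd``     trans-saccadic target displacement,
    ``V2``     actual post-saccadic retinal target position,
    ``V1_hat`` postdicted pre-saccadic target position (V2 + CDV).
    """

    V1: float
    M: float
    CDM: float
    CDV: float
    V2_hat: float
    Pd: float
    V2: float
    V1_hat: float


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise SDs (degrees). The deterministic pipeline uses zeros."""

    sigma_motor: float = 0.0
    sigma_report: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_motor < 0 or self.sigma_report < 0:
            raise ValueError("noise SDs must be >= 0")


def trans_saccadic_displacement(state: GainState, paradigm: Paradigm) -> float:
    """Pd: the step relative to the pre-saccadic retinal frame (noise-free).

    CTS/BASELINE: Pd = Ps. CVE: the target reappears Ps away from the
    landing point, so Pd = P1(omega_v*omega_m - 1) + Ps.
    """
    if paradigm.steps_with_landing:
        return paradigm.P1 * (state.omega_v * state.omega_m - 1.0) + paradigm.Ps
    return paradigm.Ps


def compute_observables(state: GainState, paradigm: Paradigm) -> Observables:
    """Evaluate the noise-free forward model for one trial."""
    wv, wm, wcd = state.as_tuple()
    P1 = paradigm.P1
    V1 = P1 * wv
    M = V1 * wm
    CDM = M
    CDV = CDM * wcd
    V2_hat = V1 - CDV
    Pd = trans_saccadic_displacement(state, paradigm)
    V2 = P1 * (1.0 - wv * wm) + Pd
    V1_hat = V2 + CDV
    return Observables(V1=V1, M=M, CDM=CDM, CDV=CDV, V2_hat=V2_hat, Pd=Pd, V2=V2, V1_hat=V1_hat)


def prediction_error(obs: Observables) -> float:
    """Visual prediction error E_pre = V2 - V2_hat."""
    return obs.V2 - obs.V2_hat


def postdiction_error(obs: Observables) -> float:
    """Postdictive motor error E_post = V1_hat - M."""
    return obs.V1_hat - obs.M


def error_value(state: GainState, paradigm: Paradigm, mode: ErrorMode | str) -> float:
    """The driving error of the given mode, evaluated in closed form."""
    mode = ErrorMode(mode)
    obs = compute_observables(state, paradigm)
    if mode is ErrorMode.PREDICTION:
        return prediction_error(obs)
    if mode is ErrorMode.POSTDICTION:
        return postdiction_error(obs)
    return obs.V2


def error_from_displacement(
    state: GainState, P1: float, Pd: float, mode: ErrorMode | str
) -> float:
    """Error with the trans-saccadic displacement Pd held fixed.

    This is the function the learner's gradient actually differentiates: in
    CVE the displacement depends on the gains through the landing point, but
    the delta rule treats it as an external quantity of the trial.
    """
    mode = ErrorMode(mode)
    wv, wm, wcd = state.as_tuple()
    if mode is ErrorMode.PREDICTION:
        return P1 * (1.0 + wv * (wm * (wcd - 1.0) - 1.0)) + Pd
    if mode is ErrorMode.POSTDICTION:
        return P1 * (1.0 + wv * wm * (wcd - 2.0)) + Pd
    return P1 * (1.0 - wv * wm) + Pd
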