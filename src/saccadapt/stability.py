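"""Fixed points and stability of the postdiction learning dynamics.

Setting the trial-by-trial gain change Delta omega = -2 alpha E g to zero
yields non-isolated fixed points wherever the postdictive motor error
vanishes. Solving E_post = 0 for the motor gain (omega_v != 0 assumed):

    CTS:  omega_m = -(P1 + Ps) / (P1 * omega_v * (omega_cd - 2))
    CVE:  omega_m = -Ps / (P1 * omega_v * (omega_cd - 1))

so the steady states form a surface in gain space whose position is set by
the target eccentricity and the step. Stability is read off the Jacobian of
the per-trial gain change; at an exact fixed point the Jacobian collapses
to the rank-1 matrix -2 diag(alpha) g gradE^T, whose single nonzero
eigenvalue (for CTS, where gradE = g) is -2 sum_i alpha_i g_i^2 < 0: the
surface attracts transversally and is neutral along itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learning import LearningRates, error_gradient
from .model import ErrorMode, GainState, Paradigm, ParadigmKind, error_value

__all__ = [
    "SingularSlice",
    "StabilityLabel",
    "StabilityReport",
    "fixed_point_omega_m",
    "delta_omega",
    "jacobian",
    "jacobian_fd",
    "classify",
    "vector_field",
]


class SingularSlice(ValueError):
    """Fixed-point formula evaluated at a singular gain combination."""


class StabilityLabel(str, enum.Enum):
    STABLE = "stable"  # all nonzero eigenvalues have negative real part
    UNSTABLE = "unstable"  # some eigenvalue with positive real part
    MARGINAL = "marginal"  # all eigenvalues (numerically) zero


@dataclass
class StabilityReport:
    """Eigenstructure of the 3x3 Jacobian plus the 2-D slice summary.

    ``tau``, ``det`` and ``discriminant`` (tau^2 - 4 det) refer to the 2x2
    sub-Jacobian on the (omega_m, omega_cd) plane at fixed omega_v — the
    plane in which the vector fields are drawn.
    """

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    label: StabilityLabel
    tau: float
    det: float
    discriminant: float


def fixed_point_omega_m(
    omega_v: float, omega_cd: float, paradigm: Paradigm
) -> float:
    """Motor gain on the zero-error surface at given (omega_v, omega_cd)."""
    if omega_v == 0:
        raise SingularSlice("omega_v = 0")
    P1, Ps = paradigm.P1, paradigm.Ps
    if paradigm.kind is ParadigmKind.CVE:
        denom = P1 * omega_v * (omega_cd - 1.0)
        if denom == 0:
            raise SingularSlice("omega_cd = 1 is singular for CVE")
        return -Ps / denom
    denom = P1 * omega_v * (omega_cd - 2.0)
    if denom == 0:
        raise SingularSlice("omega_cd = 2 is singular for CTS")
    return -(P1 + Ps) / denom


def delta_omega(
    state: GainState, rates: LearningRates, paradigm: Paradigm
) -> np.ndarray:
    """Per-trial gain change -2 alpha E g of the postdiction rule."""
    E = error_value(state, paradigm, ErrorMode.POSTDICTION)
    g = np.asarray(error_gradient(state, paradigm, ErrorMode.POSTDICTION))
    return -2.0 * np.asarray(rates.as_tuple()) * E * g


def _grad_of_gradient(state: GainState, P1: float) -> np.ndarray:
    """d g_i / d omega_j for the postdiction gradient vector g."""
    wv, wm, wcd = state.as_tuple()
    return np.array(
        [
            [0.0, P1 * (wcd - 2.0), P1 * wm],
            [P1 * (wcd - 2.0), 0.0, P1 * wv],
            [P1 * wm, P1 * wv, 0.0],
        ]
    )


def jacobian(
    state: GainState,
    rates: LearningRates,
    paradigm: Paradigm,
    differentiate_through_step: bool = False,
) -> np.ndarray:
    """Analytic Jacobian of delta_omega wrt the gains.

    By default the error's gradient follows the learner convention (Pd
    clamped, matching the update rule). With
    ``differentiate_through_step=True`` the CVE landing-point contingency is
    differentiated as well (exploratory; for CTS the two coincide).
    """
    P1 = paradigm.P1
    wv, wm, wcd = state.as_tuple()
    E = error_value(state, paradigm, ErrorMode.POSTDICTION)
    g = np.asarray(error_gradient(state, paradigm, ErrorMode.POSTDICTION))
    if differentiate_through_step and paradigm.kind is ParadigmKind.CVE:
        # full E_post = P1*wv*wm*(wcd-1) + Ps
        grad_e = np.array(
            [P1 * wm * (wcd - 1.0), P1 * wv * (wcd - 1.0), P1 * wv * wm]
        )
    else:
        grad_e = g
    dg = _grad_of_gradient(state, P1)
    alpha = np.asarray(rates.as_tuple())
    return -2.0 * alpha[:, None] * (np.outer(g, grad_e) + E * dg)


def jacobian_fd(
    state: GainState,
    rates: LearningRates,
    paradigm: Paradigm,
    h: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian of delta_omega (oracle variant)."""
    base = np.asarray(state.as_tuple())
    J = np.empty((3, 3))
    for j in range(3):
        up, dn = base.copy(), base.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (
            delta_omega(GainState(*up), rates, paradigm)
            - delta_omega(GainState(*dn), rates, paradigm)
        ) / (2.0 * h)
    return J


def classify(J: np.ndarray, zero_tol: float = 1e-9) -> StabilityReport:
    """Eigenvalue classification of a gain-change Jacobian.

    Eigenvalues with |lambda| <= zero_tol count as zero (neutral directions
    along the fixed-point surface are expected and tolerated).
    """
    J = np.asarray(J, dtype=float)
    if J.shape[0] != J.shape[1]:
        raise ValueError("Jacobian must be square")
    eig = np.linalg.eigvals(J)
    nonzero = eig[np.abs(eig) > zero_tol]
    if nonzero.size == 0:
        label = StabilityLabel.MARGINAL
    elif np.all(nonzero.real < 0):
        label = StabilityLabel.STABLE
    else:
        label = StabilityLabel.UNSTABLE
    if J.shape[0] >= 3:
        sub = J[np.ix_([1, 2], [1, 2])]  # (omega_m, omega_cd) slice
    else:
        sub = J
    tau = float(np.trace(sub))
    det = float(np.linalg.det(sub))
    return StabilityReport(
        jacobian=J,
        eigenvalues=eig,
        label=label,
        tau=tau,
        det=det,
        discriminant=tau * tau - 4.0 * det,
    )


def vector_field(
    paradigm: Paradigm,
    rates: LearningRates,
    omega_v: float,
    omega_m_grid,
    omega_cd_grid,
) -> pd.DataFrame:
    """Gain-change field on an (omega_m, omega_cd) grid at fixed omega_v.

    Returns a tidy table with columns omega_m, omega_cd, d_omega_m,
    d_omega_cd and epost; arrows vanish exactly on the fixed-point curve.
    """
    rows = []
    for wm in np.asarray(omega_m_grid, dtype=float):
        for wcd in np.asarray(omega_cd_grid, dtype=float):
            state = GainState(omega_v, wm, wcd)
            d = delta_omega(state, rates, paradigm)
            rows.append(
                {
                    "omega_m": wm,
                    "omega_cd": wcd,
                    "d_omega_m": d[1],
                    "d_omega_cd": d[2],
                    "epost": error_value(state, paradigm, ErrorMode.POSTDICTION),
                }
            )
    return pd.DataFrame(rows)
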