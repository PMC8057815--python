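"""Gain estimation from measured probe-block observables.

Each probe block yields three medians: the pre-saccadic target localization
V1, the saccade vector M, and the post-saccadic target localization
relative to the saccade landing point, V2_hat. The basic model rationale
inverts the forward equations:

    CDV      = V1 - V2_hat
    omega_v  = V1 / P1
    omega_m  = M / V1
    omega_cd = CDV / CDM          (CDM identified with the measured M)

Gain changes across learning are the block-5 minus block-1 differences, and
plasticity of each gain is assessed cohort-wise with a two-sided one-sample
t-test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GainState

__all__ = [
    "PROBE_TRIALS",
    "ProbeBlockMeasure",
    "DegenerateMeasurement",
    "derive_gains",
    "gain_changes",
    "cohort_tests",
    "sign_align",
]

#: model-trial indices of the five probe blocks (281 primary-task trials).
PROBE_TRIALS = (1, 71, 141, 211, 281)


class DegenerateMeasurement(ValueError):
    """A probe measurement with a zero denominator (V1 or M = 0)."""


@dataclass(frozen=True)
class ProbeBlockMeasure:
    """Measured medians of one probe block, degrees of visual angle."""

    V1: float
    M: float
    V2_hat: float
    block_index: int = 1  # 1..5

    def __post_init__(self) -> None:
        if not 1 <= self.block_index <= 5:
            raise ValueError(f"block_index must be 1..5, got {self.block_index}")

    @property
    def trial_index(self) -> int:
        return PROBE_TRIALS[self.block_index - 1]


def derive_gains(m: ProbeBlockMeasure, P1: float) -> tuple[GainState, float]:
    """Invert the forward model for one probe block; returns (gains, CDV)."""
    if m.V1 == 0 or m.M == 0:
        raise DegenerateMeasurement(
            f"cannot derive gains from V1={m.V1}, M={m.M} (zero denominator)"
        )
    cdv = m.V1 - m.V2_hat
    state = GainState(m.V1 / P1, m.M / m.V1, cdv / m.M)
    return state, cdv


def gain_changes(blocks: Sequence[ProbeBlockMeasure], P1: float) -> pd.Series:
    """Block 5 minus block 1 change of each gain and of CDV.

    Returns a Series with entries d_omega_v, d_omega_m, d_omega_cd, d_CDV.
    """
    if len(blocks) != 5:
        raise ValueError(f"need 5 probe blocks, got {len(blocks)}")
    state1, cdv1 = derive_gains(blocks[0], P1)
    state5, cdv5 = derive_gains(blocks[4], P1)
    return pd.Series(
        {
            "d_omega_v": state5.omega_v - state1.omega_v,
            "d_omega_m": state5.omega_m - state1.omega_m,
            "d_omega_cd": state5.omega_cd - state1.omega_cd,
            "d_CDV": cdv5 - cdv1,
        }
    )


def sign_align(deltas: pd.DataFrame, inward: Iterable[bool]) -> pd.DataFrame:
    """Flip the sign of inward-condition gain changes.

    Inward and outward steps drive learning in opposite directions; aligning
    signs lets gain-change magnitudes be compared across directions.
    """
    flip = np.where(np.asarray(list(inward), dtype=bool), -1.0, 1.0)
    return deltas.mul(flip, axis=0)


def cohort_tests(deltas: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-tests of per-subject gain changes against zero.

    Parameters
    ----------
    deltas:
        One row per subject; columns are gain-change variables (e.g. the
        output of :func:`gain_changes` stacked over subjects).

    Returns
    -------
    DataFrame indexed by variable with columns mean, sd, t, df, p.
    """
    n = len(deltas)
    if n < 2:
        raise ValueError("need at least 2 subjects for a t-test")
    rows = {}
    for col in deltas.columns:
        x = np.asarray(deltas[col], dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            # degenerate: identical subjects; t undefined unless mean is 0 too
            t = 0.0 if np.allclose(x.mean(), 0) else np.inf * np.sign(x.mean())
            p = 1.0 if t == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(x, 0.0)
        rows[col] = {"mean": x.mean(), "sd": sd, "t": float(t), "df": n - 1, "p": float(p)}
    return pd.DataFrame(rows).T
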