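"""Fit learning rates to probe-series data and compare error models.

A session yields five probe blocks of (V1, M, V2_hat) medians located at
trials n = [1, 71, 141, 211, 281] of the 281 primary-task trials. Starting
from the gain state derived from probe block 1, the model is simulated for
281 trials under the chosen error mode and the three learning rates are
chosen to minimize the weighted sum of squared errors

    SSE = sum_n eta(n) * [(V1-V1_pred)^2 + (M-M_pred)^2 + (V2h-V2h_pred)^2]

with block weights eta = 1.52 for the long probe blocks (trials 1 and 281;
21 localizations each) and 0.65 for the short ones (trials 71, 141, 211;
nine localizations each). Rates are bounded to [0, 9e-5] 1/deg^2: the lower
bound enforces learning in gradient direction, the upper bound keeps the
saccade vector from taking a strong exponential shape. Model comparison
uses the residual standard error RSE = sqrt(SSE / (lambda - 1)) with
lambda = 15 data points, compared between modes by paired t-test — both
modes have identical degrees of freedom, so RSE compares them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gains import PROBE_TRIALS, ProbeBlockMeasure, derive_gains
from .learning import LearningRates, SimulationDiverged, Trajectory, simulate
from .model import ErrorMode, GainState, Paradigm, error_value

__all__ = [
    "ETA_WEIGHTS",
    "LAMBDA_POINTS",
    "ALPHA_UPPER",
    "ProbeSeries",
    "FitConfig",
    "FitResult",
    "initial_state",
    "probe_predictions",
    "objective",
    "fit",
    "fit_shared",
    "error_metrics",
    "compare_models",
]

#: per-block SSE weights, long blocks (1, 281) then short (71, 141, 211)
ETA_WEIGHTS = (1.52, 0.65, 0.65, 0.65, 1.52)
LAMBDA_POINTS = 15  # 5 blocks x 3 observables
ALPHA_LOWER = 0.0
ALPHA_UPPER = 9e-5
N_TRIALS = PROBE_TRIALS[-1]  # 281
DIVERGENCE_PENALTY = 1e6  # deg^2, returned when a simulation leaves the cap


@dataclass(frozen=True)
class ProbeSeries:
    """Five probe-block measurements plus their condition."""

    blocks: tuple[ProbeBlockMeasure, ...]
    paradigm: Paradigm
    subject: str | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) != 5:
            raise ValueError(f"need 5 probe blocks, got {len(self.blocks)}")
        if tuple(b.block_index for b in self.blocks) != (1, 2, 3, 4, 5):
            raise ValueError("blocks must be ordered with block_index 1..5")

    @property
    def data_matrix(self) -> np.ndarray:
        """(5, 3) array of measured (V1, M, V2_hat)."""
        return np.array([[b.V1, b.M, b.V2_hat] for b in self.blocks])

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(ETA_WEIGHTS)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the bounded least-squares rate fit."""

    mode: ErrorMode = ErrorMode.POSTDICTION
    alpha_lower: float = ALPHA_LOWER
    alpha_upper: float = ALPHA_UPPER
    lambda_points: int = LAMBDA_POINTS
    n_grid_starts: int = 8
    n_random_starts: int = 4
    seed: int = 0
    divergence_cap: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ErrorMode(self.mode))


@dataclass
class FitResult:
    """Fitted rates, trajectory and derived error metrics for one series."""

    alpha: LearningRates
    sse: float
    rse: float
    trajectory: Trajectory = field(repr=False)
    initial_state: GainState
    mode: ErrorMode
    metrics: dict[str, float] = field(default_factory=dict)


def initial_state(series: ProbeSeries) -> GainState:
    """Gain state at trial 1, derived from the block-1 medians."""
    state, _ = derive_gains(series.blocks[0], series.paradigm.P1)
    return state


def probe_predictions(
    state0: GainState,
    rates: LearningRates,
    paradigm: Paradigm,
    mode: ErrorMode | str,
    cap: float = 10.0,
) -> np.ndarray:
    """(5, 3) predicted (V1, M, V2_hat) at the probe trials.

    Fast scalar recursion of the delta rule; raises
    :class:`SimulationDiverged` when a gain leaves [-cap, cap].
    """
    mode = ErrorMode(mode)
    wv, wm, wcd = state0.as_tuple()
    av, am, acd = rates.as_tuple()
    P1, Ps = paradigm.P1, paradigm.Ps
    cve = paradigm.steps_with_landing
    probe = set(PROBE_TRIALS)
    preds = []
    for n in range(1, N_TRIALS + 1):
        if abs(wv) > cap or abs(wm) > cap or abs(wcd) > cap:
            raise SimulationDiverged(n, (wv, wm, wcd), cap)
        V1 = P1 * wv
        M = V1 * wm
        CDV = M * wcd
        if n in probe:
            preds.append((V1, M, V1 - CDV))
        if n == N_TRIALS:
            break
        Pd = P1 * (wv * wm - 1.0) + Ps if cve else Ps
        V2 = P1 * (1.0 - wv * wm) + Pd
        if mode is ErrorMode.POSTDICTION:
            E = V2 + CDV - M
            gv = P1 * wm * (wcd - 2.0)
            gm = P1 * wv * (wcd - 2.0)
            gcd = P1 * wv * wm
        elif mode is ErrorMode.PREDICTION:
            E = V2 - (V1 - CDV)
            gv = P1 * (wm * (wcd - 1.0) - 1.0)
            gm = P1 * wv * (wcd - 1.0)
            gcd = P1 * wv * wm
        else:
            E = V2
            gv = -P1 * wm
            gm = -P1 * wv
            gcd = 0.0
        wv -= 2.0 * av * E * gv
        wm -= 2.0 * am * E * gm
        wcd -= 2.0 * acd * E * gcd
    return np.asarray(preds)


def _residuals(
    alpha: np.ndarray, series: ProbeSeries, state0: GainState, config: FitConfig
) -> np.ndarray:
    """sqrt(eta)-weighted residual 15-vector; large finite on divergence."""
    rates = LearningRates(*np.clip(alpha, 0.0, None))
    try:
        pred = probe_predictions(
            state0, rates, series.paradigm, config.mode, cap=config.divergence_cap
        )
    except SimulationDiverged:
        return np.full(15, math.sqrt(DIVERGENCE_PENALTY / 15.0))
    resid = (series.data_matrix - pred) * np.sqrt(series.weights)[:, None]
    return resid.ravel()


def objective(alpha: LearningRates, series: ProbeSeries, config: FitConfig) -> float:
    """Weighted SSE (deg^2) of the simulated probe trajectory vs the data."""
    r = _residuals(np.asarray(alpha.as_tuple()), series, initial_state(series), config)
    return float(r @ r)


def _starts(config: FitConfig) -> list[np.ndarray]:
    lo, hi = 1e-8, config.alpha_upper
    starts = [np.full(3, a) for a in np.geomspace(lo, hi, config.n_grid_starts)]
    starts.append(np.full(3, 1e-12))  # the zero corner (nudged inside the box)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_random_starts):
        starts.append(10 ** rng.uniform(np.log10(lo), np.log10(hi), size=3))
    return starts


def _minimize(
    residual_fn, config: FitConfig
) -> tuple[np.ndarray, float]:
    best_x, best_cost = None, np.inf
    for x0 in _starts(config):
        sol = optimize.least_squares(
            residual_fn,
            np.clip(x0, 1e-12, config.alpha_upper - 1e-12),
            bounds=(config.alpha_lower, config.alpha_upper),
            method="trf",
            x_scale="jac",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=400,
        )
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x
    if best_x is None:
        raise RuntimeError("all optimizer starts failed")
    return best_x, 2.0 * best_cost  # least_squares cost = SSE / 2


def _finish(series: ProbeSeries, alpha: np.ndarray, config: FitConfig) -> FitResult:
    state0 = initial_state(series)
    rates = LearningRates(*alpha)
    sse = objective(rates, series, config)
    if sse >= DIVERGENCE_PENALTY:
        raise RuntimeError("fitted rates diverge; no stable optimum found")
    rse = math.sqrt(sse / (config.lambda_points - 1))
    traj = simulate(
        state0, rates, series.paradigm, N_TRIALS, config.mode, cap=config.divergence_cap
    )
    result = FitResult(
        alpha=rates,
        sse=sse,
        rse=rse,
        trajectory=traj,
        initial_state=state0,
        mode=config.mode,
    )
    result.metrics = error_metrics(result)
    return result


def fit(series: ProbeSeries, config: FitConfig | None = None) -> FitResult:
    """Bounded multistart least-squares fit of the three learning rates."""
    config = config or FitConfig()
    state0 = initial_state(series)
    alpha, _ = _minimize(lambda a: _residuals(a, series, state0, config), config)
    return _finish(series, alpha, config)


def fit_shared(
    series_cts: ProbeSeries, series_cve: ProbeSeries, config: FitConfig | None = None
) -> tuple[FitResult, FitResult]:
    """One shared rate vector minimizing the summed SSE of both conditions."""
    config = config or FitConfig()
    s_cts, s_cve = initial_state(series_cts), initial_state(series_cve)

    def residual_fn(a: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [
                _residuals(a, series_cts, s_cts, config),
                _residuals(a, series_cve, s_cve, config),
            ]
        )

    alpha, _ = _minimize(residual_fn, config)
    return _finish(series_cts, alpha, config), _finish(series_cve, alpha, config)


def error_metrics(result: FitResult) -> dict[str, float]:
    """Steady-state diagnostics of a fitted trajectory.

    ``baseline_error`` evaluates the driving error at the trial-1 gains in
    the step-free condition (CTS with Ps = 0); ``final_error`` is the error
    at trial 281 (step included); ``pct_decline`` is the percentage drop of
    |E| from trial 1 (step included) to trial 281. ``cdv_error_*`` is
    CDV - M, the dissociation of the internal saccade estimate from the
    actual saccade, and ``V2_*`` the visual endpoint error.
    """
    traj = result.trajectory
    obs = traj.observables
    e1, e_end = float(traj.error[0]), float(traj.error[-1])
    pct = 100.0 * (1.0 - abs(e_end) / abs(e1)) if e1 != 0 else float("nan")
    baseline = error_value(
        traj.state(1), traj.paradigm.baseline(), traj.mode
    )
    return {
        "baseline_error": float(baseline),
        "final_error": e_end,
        "pct_decline": pct,
        "cdv_error_first": float(obs["CDV"].iloc[0] - obs["M"].iloc[0]),
        "cdv_error_last": float(obs["CDV"].iloc[-1] - obs["M"].iloc[-1]),
        "V2_first": float(obs["V2"].iloc[0]),
        "V2_last": float(obs["V2"].iloc[-1]),
    }


def compare_models(
    fits_a: list[FitResult], fits_b: list[FitResult]
) -> dict[str, float]:
    """Paired two-sided t-test on per-subject RSE between two model fits.

    Returns mean_diff = mean(RSE_a - RSE_b); positive means model b fits
    better (smaller residual error).
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("cohorts must be matched subject-for-subject")
    if len(fits_a) < 2:
        raise ValueError("need at least 2 subjects")
    a = np.array([f.rse for f in fits_a])
    b = np.array([f.rse for f in fits_b])
    if np.allclose(a, b):
        return {"t": 0.0, "df": len(a) - 1, "p": 1.0, "mean_diff": float(np.mean(a - b))}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": len(a) - 1, "p": float(p), "mean_diff": float(np.mean(a - b))}
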