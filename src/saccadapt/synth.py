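"""Synthetic trial-level sessions with the structure the analysis assumes.

A session mirrors the double-step study design: nine blocks, alternating
five probe blocks (pre-saccadic localization / refresh saccade /
post-saccadic localization / refresh sequences; 21 localization pairs in
the long first and last blocks, nine in the short middle ones, last refresh
dropped) with four learning blocks of 70 saccade trials — 551 trials in
total. Probe block 1 is a baseline without target step; the step is applied
from block 2 onward. Gains evolve by the delta rule (postdiction by
default) on the primary-task trial axis n = 1..281, so the probe blocks sit
at n = [1, 71, 141, 211, 281]. Saccade execution carries Gaussian motor
noise, localization clicks Gaussian report noise, and a configurable
fraction of trials violates each acceptance rule so the filtering stage has
something to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learning import LearningRates, delta_update
from .model import (
    ErrorMode,
    GainState,
    NoiseSpec,
    Paradigm,
    compute_observables,
    condition,
)

__all__ = [
    "ViolationRates",
    "SubjectSpec",
    "CohortSpec",
    "DEFAULT_RATES",
    "DEFAULT_BASELINE_GAINS",
    "make_schedule",
    "simulate_subject",
    "simulate_cohort",
]

#: per-condition generating learning rates (postdiction-rule fits scale)
DEFAULT_RATES: dict[str, LearningRates] = {
    "CTS_in": LearningRates(5.2e-6, 3.5e-5, 1.8e-5),
    "CVE_in": LearningRates(1.9e-6, 1.3e-5, 5.4e-6),
    "CTS_out": LearningRates(8.4e-8, 1.5e-5, 6.3e-6),
    "CVE_out": LearningRates(2.0e-6, 9.9e-6, 8.0e-6),
}

#: accurate vision, mildly hypometric saccades and slightly hypometric CDV
DEFAULT_BASELINE_GAINS = GainState(1.0, 0.95, 0.985)


@dataclass(frozen=True)
class ViolationRates:
    """Fraction of trials violating each acceptance rule (independent draws).

    Defaults land the acceptance rates near the study's observed ones
    (~89% of pre-saccadic, ~77% of post-saccadic localization trials kept).
    """

    latency: float = 0.05
    amplitude: float = 0.03
    flash_timing: float = 0.05
    landing_hold: float = 0.07
    fixation_hold: float = 0.03
    click_region: float = 0.035
    pre_saccade: float = 0.04  # saccade within 400 ms of the pre-loc flash

    def zero(self) -> "ViolationRates":
        return ViolationRates(0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to generate one reproducible synthetic session."""

    condition: Paradigm
    baseline_gains: GainState = DEFAULT_BASELINE_GAINS
    true_rates: LearningRates = DEFAULT_RATES["CTS_in"]
    noise: NoiseSpec = NoiseSpec(sigma_motor=0.5, sigma_report=0.5)
    seed: int = 0
    mode: ErrorMode = ErrorMode.POSTDICTION
    learn_during_probe: bool = False
    violations: ViolationRates = field(default_factory=ViolationRates)
    subject: str = "S00"


_PROBE_BLOCKS = {1: 1, 3: 2, 5: 3, 7: 4, 9: 5}  # session block -> probe index
_PROBE_REPS = {1: 21, 2: 9, 3: 9, 4: 9, 5: 21}


def make_schedule() -> pd.DataFrame:
    """The deterministic 551-trial session schedule.

    Columns: session_trial (1..551), block (1..9), probe_block (1..5, 0 in
    learning blocks), trial_type.
    """
    rows: list[tuple[int, int, str]] = []
    for block in range(1, 10):
        if block in _PROBE_BLOCKS:
            probe = _PROBE_BLOCKS[block]
            seq: list[str] = []
            for _ in range(_PROBE_REPS[probe]):
                seq += ["pre_loc", "refresh", "post_loc", "refresh"]
            seq = seq[:-1]  # last refresh dropped
            rows += [(block, probe, t) for t in seq]
        else:
            rows += [(block, 0, "saccade")] * 70
    df = pd.DataFrame(rows, columns=["block", "probe_block", "trial_type"])
    df.insert(0, "session_trial", np.arange(1, len(df) + 1))
    return df


def _latency(rng: np.random.Generator, violated: bool) -> float:
    if violated:
        return float(rng.uniform(20, 95) if rng.random() < 0.5 else rng.uniform(405, 520))
    return float(np.clip(rng.normal(219.0, 24.0), 105.0, 395.0))


def _click_y(rng: np.random.Generator, violated: bool) -> float:
    return float(rng.uniform(0.0, 0.295) if violated else rng.uniform(0.35, 0.9))


def _fix_break(rng: np.random.Generator, violated: bool) -> float:
    return float(rng.uniform(1450, 3000) if violated else rng.uniform(0, 1300))


def simulate_subject(spec: SubjectSpec) -> pd.DataFrame:
    """Generate one trial-level session table.

    Learning updates are computed from the noise-free internal state and
    applied on every learning-block saccade trial (advancing the model
    trial counter n); with ``learn_during_probe`` they are additionally
    applied on probe-block refresh and localization saccades without
    advancing n. The table is reproducible from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = make_schedule()
    state = spec.baseline_gains
    v = spec.violations
    n_model = 1
    records: list[dict] = []
    for row in schedule.itertuples(index=False):
        paradigm = spec.condition.baseline() if row.block == 1 else spec.condition
        obs = compute_observables(state, paradigm)
        rec: dict = {
            "session_trial": row.session_trial,
            "block": row.block,
            "probe_block": row.probe_block,
            "model_trial": n_model,
            "trial_type": row.trial_type,
            "latency_ms": np.nan,
            "saccade_vector": np.nan,
            "flash_to_saccade_ms": np.nan,
            "click_x": np.nan,
            "click_y_fraction": np.nan,
            "fixation_break_ms": np.nan,
            "saccade_within_400ms": False,
            "held_landing": True,
        }
        saccadic = row.trial_type in ("saccade", "refresh", "post_loc")
        if saccadic:
            executed = obs.M + rng.normal(0.0, spec.noise.sigma_motor) if spec.noise.sigma_motor else obs.M
            if rng.random() < v.amplitude:
                executed = float(rng.uniform(1.0, 4.5))
            rec["latency_ms"] = _latency(rng, rng.random() < v.latency)
            rec["saccade_vector"] = float(executed)
        if row.trial_type == "pre_loc":
            noise = rng.normal(0.0, spec.noise.sigma_report) if spec.noise.sigma_report else 0.0
            rec["click_x"] = obs.V1 + noise
            rec["saccade_within_400ms"] = bool(rng.random() < v.pre_saccade)
            rec["click_y_fraction"] = _click_y(rng, rng.random() < v.click_region)
            rec["fixation_break_ms"] = _fix_break(rng, rng.random() < v.fixation_hold)
        elif row.trial_type == "post_loc":
            noise = rng.normal(0.0, spec.noise.sigma_report) if spec.noise.sigma_report else 0.0
            # click is screen-referenced: landing point plus the localization
            # of the flash relative to landing
            rec["click_x"] = rec["saccade_vector"] + obs.V2_hat + noise
            rec["flash_to_saccade_ms"] = (
                float(rng.uniform(10, 95))
                if rng.random() < v.flash_timing
                else float(rng.uniform(110, 320))
            )
            rec["held_landing"] = not (rng.random() < v.landing_hold)
            rec["click_y_fraction"] = _click_y(rng, rng.random() < v.click_region)
            rec["fixation_break_ms"] = _fix_break(rng, rng.random() < v.fixation_hold)
        records.append(rec)
        # learning
        if row.trial_type == "saccade":
            state = delta_update(state, spec.true_rates, paradigm, spec.mode)
            n_model += 1
        elif saccadic and spec.learn_during_probe:
            state = delta_update(state, spec.true_rates, paradigm, spec.mode)
    df = pd.DataFrame.from_records(records)
    df["subject"] = spec.subject
    df["condition"] = condition_label(spec.condition)
    return df


def condition_label(paradigm: Paradigm) -> str:
    """Canonical condition name (CTS_in, CVE_out, baseline, ...)."""
    if paradigm.Ps == 0:
        return "baseline"
    return f"{paradigm.kind.value}_{'in' if paradigm.Ps < 0 else 'out'}"


@dataclass(frozen=True)
class CohortSpec:
    """Distribution of subject specs for a simulated sample.

    Baseline gains are drawn per subject from independent Gaussians around
    ``gain_mean`` with SDs ``gain_sd``; learning rates are shared across the
    cohort (``true_rates``; defaults to the condition-typical values).
    """

    condition_name: str = "CTS_in"
    n_subjects: int = 17
    gain_mean: tuple[float, float, float] = (1.0, 0.95, 0.985)
    gain_sd: tuple[float, float, float] = (0.015, 0.02, 0.01)
    true_rates: LearningRates | None = None
    noise: NoiseSpec = NoiseSpec(sigma_motor=0.5, sigma_report=0.5)
    mode: ErrorMode = ErrorMode.POSTDICTION
    learn_during_probe: bool = False
    violations: ViolationRates = field(default_factory=ViolationRates)

    def rates(self) -> LearningRates:
        return self.true_rates or DEFAULT_RATES[self.condition_name]


def simulate_cohort(cohort: CohortSpec, master_seed: int) -> list[pd.DataFrame]:
    """Independent synthetic subjects; per-subject seeds derive from master_seed."""
    if cohort.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(master_seed)
    paradigm = condition(cohort.condition_name)
    tables = []
    for i in range(cohort.n_subjects):
        gains = GainState(
            *(rng.normal(m, s) for m, s in zip(cohort.gain_mean, cohort.gain_sd))
        )
        spec = SubjectSpec(
            condition=paradigm,
            baseline_gains=gains,
            true_rates=cohort.rates(),
            noise=cohort.noise,
            seed=int(rng.integers(0, 2**31 - 1)),
            mode=cohort.mode,
            learn_during_probe=cohort.learn_during_probe,
            violations=cohort.violations,
            subject=f"S{i:02d}",
        )
        tables.append(simulate_subject(spec))
    return tables
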