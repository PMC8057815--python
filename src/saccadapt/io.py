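"""CSV/JSON interchange and the end-to-end analysis pipeline.

The canonical interchange format is a probe-series CSV with one row per
subject x condition x probe block and columns
``subject, condition, block, V1, M, V2hat`` (degrees). A column-mapping
dict adapts externally produced tables (e.g. a published deposit with
different headers) without code changes. All artifacts are plain text.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitConfig, FitResult, ProbeSeries, compare_models, fit
from .gains import ProbeBlockMeasure, cohort_tests, derive_gains, gain_changes
from .learning import LearningRates
from .model import ErrorMode, NoiseSpec, Paradigm, condition
from .stability import classify, fixed_point_omega_m, jacobian
from .synth import CohortSpec, ViolationRates, condition_label, simulate_cohort
from .trials import filter_trials, probe_summary

__all__ = [
    "CANONICAL_COLUMNS",
    "RunConfig",
    "load_probe_series",
    "save_probe_series",
    "series_from_session",
    "fit_result_record",
    "run_pipeline",
]

log = logging.getLogger("saccadapt")

CANONICAL_COLUMNS = ("subject", "condition", "block", "V1", "M", "V2hat")
MAX_ABS_DEG = 40.0  # unit sanity bound for any degree-valued column


def load_probe_series(
    path: str | Path,
    mapping: dict[str, str] | None = None,
    P1: float = 13.0,
    step: float = 3.0,
) -> list[ProbeSeries]:
    """Read probe-series CSV into validated ProbeSeries objects.

    ``mapping`` translates canonical column names to the file's actual
    headers, e.g. ``{"V2hat": "post_loc_rel"}``.
    """
    df = pd.read_csv(path)
    mapping = mapping or {}
    rename = {mapping.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    df = df.rename(columns=rename)
    for col in ("V1", "M", "V2hat"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals.abs() >= MAX_ABS_DEG).any():
            raise ValueError(f"column {col} has values outside +-{MAX_ABS_DEG} deg")
    out: list[ProbeSeries] = []
    for (subject, cond), grp in df.groupby(["subject", "condition"], sort=True):
        grp = grp.sort_values("block")
        if list(grp["block"]) != [1, 2, 3, 4, 5]:
            raise ValueError(
                f"incomplete series for {subject}/{cond}: blocks {list(grp['block'])}"
            )
        blocks = tuple(
            ProbeBlockMeasure(V1=r.V1, M=r.M, V2_hat=r.V2hat, block_index=int(r.block))
            for r in grp.itertuples()
        )
        out.append(
            ProbeSeries(
                blocks=blocks,
                paradigm=condition(str(cond), P1=P1, step=step),
                subject=str(subject),
            )
        )
    return out


def save_probe_series(series: list[ProbeSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for b in s.blocks:
            rows.append(
                {
                    "subject": s.subject,
                    "condition": condition_label(s.paradigm),
                    "block": b.block_index,
                    "V1": b.V1,
                    "M": b.M,
                    "V2hat": b.V2_hat,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def series_from_session(
    session: pd.DataFrame, paradigm: Paradigm, subject: str | None = None
) -> tuple[ProbeSeries, dict[str, int]]:
    """filter -> robust probe medians -> ProbeSeries for one trial table."""
    accepted, rejections = filter_trials(session)
    blocks = probe_summary(accepted, paradigm.P1)
    return (
        ProbeSeries(blocks=tuple(blocks), paradigm=paradigm, subject=subject),
        rejections,
    )


def fit_result_record(result: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "alpha": list(result.alpha.as_tuple()),
        "sse": result.sse,
        "rse": result.rse,
        "mode": result.mode.value,
        "initial_state": list(result.initial_state.as_tuple()),
        "metrics": result.metrics,
    }


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    conditions: tuple[str, ...] = ("CTS_in", "CTS_out", "CVE_in", "CVE_out")
    n_subjects: int = 17
    P1: float = 13.0
    step: float = 3.0
    sigma_motor: float = 0.5
    sigma_report: float = 0.5
    seed: int = 0
    out_dir: str | None = None
    fit: FitConfig = field(default_factory=FitConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit_raw = raw.pop("fit", {})
        cfg = cls(**{k: v for k, v in raw.items()})
        if fit_raw:
            cfg.fit = FitConfig(**fit_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"]["mode"] = self.fit.mode.value
        d["conditions"] = list(self.conditions)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Synthesize cohorts, estimate gains, fit both error models, compare.

    Returns a results bundle (plain dict); when ``config.out_dir`` is set,
    probe series, gain changes, fits and the bundle JSON are also written
    there.
    """
    bundle: dict = {"config": config.to_dict(), "conditions": {}}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    noise = NoiseSpec(sigma_motor=config.sigma_motor, sigma_report=config.sigma_report)
    for i, cond_name in enumerate(config.conditions):
        log.info("pipeline: condition %s", cond_name)
        cohort = CohortSpec(condition_name=cond_name, n_subjects=config.n_subjects, noise=noise)
        # distinct, reproducible sub-seed per condition
        tables = simulate_cohort(cohort, master_seed=config.seed * 1000 + i)
        paradigm = condition(cond_name, P1=config.P1, step=config.step)
        series, deltas = [], []
        for tab in tables:
            s, _ = series_from_session(tab, paradigm, subject=tab["subject"].iloc[0])
            series.append(s)
            deltas.append(gain_changes(list(s.blocks), config.P1))
        deltas_df = pd.DataFrame(deltas, index=[s.subject for s in series])
        tests = cohort_tests(deltas_df)
        cfg_post = dataclasses.replace(config.fit, mode=ErrorMode.POSTDICTION)
        cfg_pre = dataclasses.replace(config.fit, mode=ErrorMode.PREDICTION)
        fits_post = [fit(s, cfg_post) for s in series]
        fits_pre = [fit(s, cfg_pre) for s in series]
        comparison = compare_models(fits_pre, fits_post)
        # stability snapshot at the cohort-median fitted end state
        end_states = np.array([f.trajectory.omega[-1] for f in fits_post])
        med = np.median(end_states, axis=0)
        med_alpha = LearningRates(
            *np.median([f.alpha.as_tuple() for f in fits_post], axis=0)
        )
        from .model import GainState  # local import to avoid cycle noise

        report = classify(jacobian(GainState(*med), med_alpha, paradigm))
        cond_result = {
            "gain_changes_mean": deltas_df.mean().to_dict(),
            "gain_change_tests": tests.to_dict(orient="index"),
            "fits_postdiction": [fit_result_record(f) for f in fits_post],
            "fits_prediction": [fit_result_record(f) for f in fits_pre],
            "rse_postdiction_mean": float(np.mean([f.rse for f in fits_post])),
            "rse_prediction_mean": float(np.mean([f.rse for f in fits_pre])),
            "model_comparison": comparison,
            "stability": {
                "median_end_state": med.tolist(),
                "eigenvalues": [complex(x).real for x in report.eigenvalues],
                "label": report.label.value,
                "tau": report.tau,
                "det": report.det,
                "discriminant": report.discriminant,
                "fixed_point_omega_m_at_end": fixed_point_omega_m(
                    med[0], med[2], paradigm
                ),
            },
        }
        bundle["conditions"][cond_name] = cond_result
        if out_dir:
            save_probe_series(series, out_dir / f"probe_series_{cond_name}.csv")
            deltas_df.to_csv(out_dir / f"gain_changes_{cond_name}.csv")
    if out_dir:
        (out_dir / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle
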