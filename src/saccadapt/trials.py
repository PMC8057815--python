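"""Trial-acceptance filters and robust probe-block summaries.

Trial tables are pandas DataFrames with one row per trial. Saccadic trials
(learning-block saccades, probe-block refresh saccades, post-saccadic
localization trials) are accepted only if they are reactive rightward
saccades: latency between 100 and 400 ms and a horizontal vector of at
least 5 deg. Post-saccadic localizations additionally require that the
saccade started no earlier than 100 ms after flash offset (peri-saccadic
compression guard), that gaze was held at the landing point, that the click
was not in the lower 30% of the display (the "did not see the flash"
response), and that fixation was not broken for more than 1400 ms.
Pre-saccadic localizations require no saccade within 400 ms of flash onset
plus the same click-region and fixation-hold rules.

Block summaries are medians after excluding points more than three scaled
median absolute deviations from the median (scaled MAD = 1.4826 x MAD,
the normal-consistency constant; single pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gains import PROBE_TRIALS, ProbeBlockMeasure

__all__ = [
    "TRIAL_TYPES",
    "REJECTION_RULES",
    "filter_trials",
    "robust_median",
    "probe_summary",
    "IncompleteBlock",
]

TRIAL_TYPES = ("saccade", "refresh", "pre_loc", "post_loc")

#: attribution order when a trial violates several rules
REJECTION_RULES = ("latency", "amplitude", "flash_timing", "fixation_hold", "click_region")

LATENCY_MIN_MS = 100.0
LATENCY_MAX_MS = 400.0
MIN_VECTOR_DEG = 5.0
MIN_FLASH_TO_SACCADE_MS = 100.0
MAX_FIXATION_BREAK_MS = 1400.0
MIN_CLICK_Y_FRACTION = 0.30
MAD_SCALE = 1.4826


class IncompleteBlock(ValueError):
    """A probe block with no accepted trials of a required type."""


def _first_violation(flags: dict[str, bool]) -> str | None:
    for rule in REJECTION_RULES:
        if flags.get(rule, False):
            return rule
    return None


def _violations(row: pd.Series) -> dict[str, bool]:
    t = row["trial_type"]
    if t in ("saccade", "refresh", "post_loc"):
        flags = {
            "latency": not (LATENCY_MIN_MS <= row["latency_ms"] <= LATENCY_MAX_MS),
            "amplitude": not (row["saccade_vector"] >= MIN_VECTOR_DEG),
        }
        if t == "post_loc":
            flags["flash_timing"] = not (
                row["flash_to_saccade_ms"] >= MIN_FLASH_TO_SACCADE_MS
            )
            flags["fixation_hold"] = (not bool(row["held_landing"])) or (
                row["fixation_break_ms"] > MAX_FIXATION_BREAK_MS
            )
            flags["click_region"] = not (row["click_y_fraction"] > MIN_CLICK_Y_FRACTION)
        return flags
    if t == "pre_loc":
        return {
            "flash_timing": bool(row["saccade_within_400ms"]),
            "fixation_hold": row["fixation_break_ms"] > MAX_FIXATION_BREAK_MS,
            "click_region": not (row["click_y_fraction"] > MIN_CLICK_Y_FRACTION),
        }
    raise ValueError(f"unknown trial_type {t!r}")


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the acceptance rules; return (accepted table, rejection counts).

    Rejection counts attribute each rejected trial to the first violated
    rule in :data:`REJECTION_RULES` order. Filtering is idempotent.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    unknown = set(table["trial_type"].unique()) - set(TRIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown trial_type values {sorted(unknown)}")
    keep = np.ones(len(table), dtype=bool)
    counts: dict[str, int] = {rule: 0 for rule in REJECTION_RULES}
    for i, (_, row) in enumerate(table.iterrows()):
        rule = _first_violation(_violations(row))
        if rule is not None:
            keep[i] = False
            counts[rule] += 1
    return table.loc[keep].copy(), counts


def robust_median(values) -> float:
    """Median after a single pass of 3-scaled-MAD outlier exclusion.

    When the scaled MAD is zero but non-median values exist (e.g.
    [1, 1, 1, 1, 100]), only values exactly equal to the median are kept.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("robust_median of empty input")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    if mad == 0:
        kept = x[x == med]
        return float(np.median(kept)) if kept.size else float(med)
    return float(np.median(x[np.abs(x - med) <= 3.0 * mad]))


def probe_summary(session: pd.DataFrame, P1: float) -> list[ProbeBlockMeasure]:
    """Robust per-probe-block medians of (V1, M, V2_hat) from accepted trials.

    Expects the session table to carry a ``probe_block`` column (1..5, 0 for
    learning-block trials). V1 is the median pre-saccadic localization click,
    M the median saccade vector of post-saccadic localization trials, and
    V2_hat the median click re-expressed relative to the saccade landing
    point (click_x - saccade_vector, both measured from the fixation point).
    """
    blocks: list[ProbeBlockMeasure] = []
    for b in range(1, 6):
        sub = session[session["probe_block"] == b]
        pre = sub[sub["trial_type"] == "pre_loc"]
        post = sub[sub["trial_type"] == "post_loc"]
        if len(pre) == 0 or len(post) == 0:
            raise IncompleteBlock(
                f"probe block {b}: {len(pre)} pre-loc / {len(post)} post-loc accepted trials"
            )
        V1 = robust_median(pre["click_x"])
        M = robust_median(post["saccade_vector"])
        V2_hat = robust_median(post["click_x"] - post["saccade_vector"])
        blocks.append(ProbeBlockMeasure(V1=V1, M=M, V2_hat=V2_hat, block_index=b))
    assert tuple(m.trial_index for m in blocks) == PROBE_TRIALS
    return blocks
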