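"""Responder classification from daily ReQuest-GI scores.

A patient is a *responder* at a horizon (day 28 for Week 4, day 56 for
Week 8) if their daily GI sub-score is below 1.6 on 3 consecutive calendar
days, the run lying entirely within treatment days (day >= 1) and ending on
or before the horizon.  The 1.6 threshold is the 95% upper confidence limit
of scores observed in healthy subjects.  Day 0 is the pre-treatment day and
never counts toward a run; a missing day breaks consecutiveness
(conservative default; a skip-missing variant is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ResponderRule",
    "ResponderStatus",
    "first_qualifying_run_end",
    "classify_responder",
    "classify_cohort",
    "cohort_response_rate",
]

MAX_DAY = 56


@dataclass(frozen=True)
class ResponderRule:
    """Parameters of the responder definition.

    threshold : score cut (default 1.6, healthy-subject upper limit)
    run_length : required consecutive qualifying days (default 3)
    strict : True -> score < threshold ("below"); False -> score <= threshold
    window_start_day : first day that may start a run (default 1: treatment
        days only, day 0 is pre-treatment)
    horizon_day : last day a qualifying run may end (28 = Week 4, 56 = Week 8)
    skip_missing : if True, missing days are skipped rather than breaking a
        run (runs still need ``run_length`` observed qualifying days)
    """

    threshold: float = 1.6
    run_length: int = 3
    strict: bool = True
    window_start_day: int = 1
    horizon_day: int = 56
    skip_missing: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.window_start_day > self.horizon_day:
            raise ValueError("window_start_day must be <= horizon_day")

    def at_horizon(self, horizon_day: int) -> "ResponderRule":
        return replace(self, horizon_day=horizon_day)


@dataclass(frozen=True)
class ResponderStatus:
    patient_id: object
    horizon_day: int
    is_responder: bool
    first_qualifying_run_end_day: int | None


def first_qualifying_run_end(
    days: np.ndarray, scores: np.ndarray, rule: ResponderRule
) -> int | None:
    """Day on which the first qualifying run ends, or None.

    ``days``/``scores`` are aligned 1-d arrays for one patient; days with a
    missing score may either be absent from ``days`` or carry NaN.
    """
    days = np.asarray(days, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if days.size == 0:
        raise ValueError("empty daily score series")
    present = ~np.isnan(scores)
    days, scores = days[present], scores[present]
    order = np.argsort(days)
    days, scores = days[order], scores[order]
    in_window = (days >= rule.window_start_day) & (days <= rule.horizon_day)
    days, scores = days[in_window], scores[in_window]
    if rule.strict:
        ok = scores < rule.threshold
    else:
        ok = scores <= rule.threshold
    run = 0
    prev_day = None
    for day, good in zip(days, ok):
        consecutive = prev_day is not None and (
            day == prev_day + 1 or (rule.skip_missing and day > prev_day)
        )
        if good:
            run = run + 1 if consecutive and run > 0 else 1
            if run >= rule.run_length:
                return int(day)
        else:
            run = 0
        prev_day = day
    return None


def classify_responder(series: pd.DataFrame, rule: ResponderRule) -> ResponderStatus:
    """Classify one patient's series (columns ``patient_id``, ``day``, ``gi``)."""
    if series.empty:
        raise ValueError("empty daily score series")
    ids = series["patient_id"].unique()
    if len(ids) != 1:
        raise ValueError("classify_responder expects a single patient's series")
    end = first_qualifying_run_end(
        series["day"].to_numpy(), series["gi"].to_numpy(), rule
    )
    return ResponderStatus(
        patient_id=ids[0],
        horizon_day=rule.horizon_day,
        is_responder=end is not None,
        first_qualifying_run_end_day=end,
    )


def classify_cohort(daily_scores: pd.DataFrame, rule: ResponderRule) -> pd.DataFrame:
    """Classify every patient in a long-format daily-score table.

    Returns a DataFrame with columns ``patient_id``, ``horizon_day``,
    ``is_responder``, ``run_end_day`` (nullable integer).

    The scan is vectorised: scores are pivoted to a patient x day matrix and
    qualifying runs located with a rolling all-of-``run_length`` window.
    """
    if daily_scores.empty:
        raise ValueError("empty daily score table")
    if rule.skip_missing:
        # Irregular day spacing: fall back to the per-patient scan.
        rows = [
            (pid, rule.horizon_day, end is not None, end)
            for pid, grp in daily_scores.groupby("patient_id", sort=True)
            for end in [
                first_qualifying_run_end(
                    grp["day"].to_numpy(), grp["gi"].to_numpy(), rule
                )
            ]
        ]
    else:
        wide = daily_scores.pivot_table(
            index="patient_id", columns="day", values="gi", aggfunc="first"
        )
        days = np.arange(rule.window_start_day, rule.horizon_day + 1)
        wide = wide.reindex(columns=days)
        vals = wide.to_numpy(dtype=float)
        if rule.strict:
            ok = vals < rule.threshold
        else:
            ok = vals <= rule.threshold
        ok &= ~np.isnan(vals)
        L = rule.run_length
        if ok.shape[1] >= L:
            csum = np.cumsum(ok, axis=1, dtype=int)
            window = csum[:, L - 1 :].copy()
            window[:, 1:] -= csum[:, :-L]
            hit = window >= L  # all L days qualify
            first = np.argmax(hit, axis=1)
            any_hit = hit.any(axis=1)
            end_days = days[L - 1 :][first]
        else:
            any_hit = np.zeros(ok.shape[0], dtype=bool)
            end_days = np.zeros(ok.shape[0], dtype=int)
        rows = [
            (pid, rule.horizon_day, bool(h), int(d) if h else None)
            for pid, h, d in zip(wide.index, any_hit, end_days)
        ]
    out = pd.DataFrame(
        rows, columns=["patient_id", "horizon_day", "is_responder", "run_end_day"]
    )
    out["run_end_day"] = out["run_end_day"].astype("Int64")
    return out


def cohort_response_rate(statuses: pd.DataFrame) -> float:
    """Proportion of responders among classified patients (one horizon)."""
    if len(statuses) == 0:
        raise ValueError("no responder statuses supplied")
    horizons = statuses["horizon_day"].unique()
    if len(horizons) != 1:
        raise ValueError(f"mixed horizons in status table: {sorted(horizons)}")
    return float(statuses["is_responder"].mean())
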