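"""Dual prediction-level ("grey zone") search over early-treatment scores.

For each of the 11 candidate days (day 0 = pre-treatment baseline and
treatment days 1-10) and each ReQuest score kind (total, GI, WSO), score
levels are swept in steps of 0.01 from 0 to the score maximum.  At each
level L the cohort splits into a predicted-response group (score <= L) and
a predicted-non-response group (score > L); the *prediction rates* are the
proportions of those groups whose Week-8 responder classification matches
the prediction (i.e. positive/negative predictive values).

Per day, the response level is the level maximising the response prediction
rate and the non-response level the one maximising the non-response
prediction rate, each subject to a minimum group size (the search is
degenerate without one: a single-patient group trivially attains rate 1).
The best prediction day is the one whose indeterminate zone — the score
interval between the two levels, where no prediction is made — is
narrowest.

Grid levels are handled as integer multiples of the step to avoid
floating-point drift at cell boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scores import GI_MAX, TOTAL_MAX, WSO_MAX

__all__ = [
    "SCORE_MAXIMA",
    "LevelSweep",
    "DayPredictionResult",
    "PredictionSummary",
    "prediction_rates_at_level",
    "sweep_day",
    "optimize_day",
    "select_best_day",
    "predict_cohort",
]

SCORE_MAXIMA: Mapping[str, float] = {"total": TOTAL_MAX, "gi": GI_MAX, "wso": WSO_MAX}

#: Comparison tolerance when testing ``score <= level`` on grid levels.
_EPS = 1e-9


@dataclass(frozen=True)
class LevelSweep:
    """Per-level predicted-group sizes and prediction rates for one day."""

    day: int
    score_kind: str
    step: float
    levels: np.ndarray  # ascending grid, 0 .. score_max
    n_low: np.ndarray  # |{score <= level}|
    n_resp_low: np.ndarray  # responders within the low group
    response_rate: np.ndarray  # NaN where n_low == 0
    n_high: np.ndarray  # |{score > level}|
    n_nonresp_high: np.ndarray  # non-responders within the high group
    nonresponse_rate: np.ndarray  # NaN where n_high == 0
    n_patients: int
    n_responders: int


@dataclass(frozen=True)
class DayPredictionResult:
    """Optimal dual levels for one candidate day and score kind."""

    day: int
    score_kind: str
    admissible: bool
    response_level: float | None = None
    nonresponse_level: float | None = None
    response_rate: float | None = None
    nonresponse_rate: float | None = None
    n_low: int | None = None
    n_high: int | None = None
    reason: str | None = None

    @property
    def indeterminate_width(self) -> float | None:
        if self.response_level is None or self.nonresponse_level is None:
            return None
        return self.nonresponse_level - self.response_level

    def as_dict(self) -> dict:
        d = {
            "day": self.day,
            "score_kind": self.score_kind,
            "admissible": self.admissible,
            "response_level": self.response_level,
            "nonresponse_level": self.nonresponse_level,
            "response_rate": self.response_rate,
            "nonresponse_rate": self.nonresponse_rate,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "indeterminate_width": self.indeterminate_width,
        }
        if self.reason:
            d["reason"] = self.reason
        return d


@dataclass(frozen=True)
class PredictionSummary:
    """Best early-treatment day per score kind, plus the baseline result."""

    best: dict[str, DayPredictionResult] = field(default_factory=dict)
    baseline: dict[str, DayPredictionResult] = field(default_factory=dict)
    all_days: dict[str, list[DayPredictionResult]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "best": {k: r.as_dict() for k, r in self.best.items()},
            "baseline": {k: r.as_dict() for k, r in self.baseline.items()},
        }


def _clean(day_scores, responder_flags) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(pd.Series(day_scores), dtype=float)
    flags = np.asarray(pd.Series(responder_flags), dtype=bool)
    if scores.size == 0:
        raise ValueError("empty score map")
    if scores.size != flags.size:
        raise ValueError("scores and responder flags must align")
    present = ~np.isnan(scores)
    return scores[present], flags[present]


def prediction_rates_at_level(
    day_scores, responder_flags, level: float
) -> tuple[float, float, int, int]:
    """Prediction rates at one level.

    Returns ``(response_rate, nonresponse_rate, n_low, n_high)`` where the
    low group is {score <= level} and the high group {score > level}.  A
    rate over an empty group is NaN, never fabricated.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    scores, flags = _clean(day_scores, responder_flags)
    low = scores <= level + _EPS
    n_low = int(low.sum())
    n_high = int((~low).sum())
    response_rate = float(flags[low].mean()) if n_low else math.nan
    nonresponse_rate = float((~flags[~low]).mean()) if n_high else math.nan
    return response_rate, nonresponse_rate, n_low, n_high


def sweep_day(
    day_scores,
    responder_flags,
    step: float = 0.01,
    score_max: float = GI_MAX,
    day: int = 0,
    score_kind: str = "gi",
) -> LevelSweep:
    """Sweep levels 0, step, 2*step, ... up to ``score_max`` (inclusive).

    Patients with a missing score that day are excluded from both groups.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    scores, flags = _clean(day_scores, responder_flags)
    n = scores.size
    n_resp = int(flags.sum())

    k_max = int(math.floor(score_max / step + _EPS))
    levels = np.arange(k_max + 1) * step
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_resp = np.concatenate([[0], np.cumsum(flags[order])])

    idx = np.searchsorted(sorted_scores, levels + _EPS, side="right")
    n_low = idx.astype(int)
    n_resp_low = sorted_resp[idx].astype(int)
    n_high = n - n_low
    n_nonresp_high = (n - n_resp) - (n_low - n_resp_low)

    with np.errstate(invalid="ignore", divide="ignore"):
        response_rate = np.where(n_low > 0, n_resp_low / np.maximum(n_low, 1), np.nan)
        nonresponse_rate = np.where(
            n_high > 0, n_nonresp_high / np.maximum(n_high, 1), np.nan
        )
    return LevelSweep(
        day=day,
        score_kind=score_kind,
        step=step,
        levels=levels,
        n_low=n_low,
        n_resp_low=n_resp_low,
        response_rate=response_rate,
        n_high=n_high,
        n_nonresp_high=n_nonresp_high,
        nonresponse_rate=nonresponse_rate,
        n_patients=n,
        n_responders=n_resp,
    )


def optimize_day(sweep: LevelSweep, min_group: int = 30) -> DayPredictionResult:
    """Pick the optimal dual levels from a sweep.

    The response level L maximises, in order: the response rate among
    levels with ``n_low >= min_group``; the low-group size (coverage);
    and finally hugs the class boundary (smallest level among remaining
    ties).  The non-response level U is symmetric: maximal non-response
    rate, then maximal high-group size, then the *largest* tied level.
    Within a (rate, coverage) tie the low/high groups are identical, so the
    final tie-break only fixes where inside the empty score gap the levels
    sit; the boundary-hugging convention keeps L <= U whenever the groups
    themselves are orderable.  A day with no qualifying level on either
    side, or with L > U, is flagged inadmissible rather than raising.
    """
    if sweep.levels.size == 0:
        raise ValueError("empty level sweep")
    low_ok = sweep.n_low >= max(min_group, 1)
    high_ok = sweep.n_high >= max(min_group, 1)
    if not low_ok.any() or not high_ok.any():
        side = "response" if not low_ok.any() else "non-response"
        return DayPredictionResult(
            day=sweep.day,
            score_kind=sweep.score_kind,
            admissible=False,
            reason=f"no level with >= {min_group} patients on the {side} side",
        )
    resp = np.where(low_ok, sweep.response_rate, -np.inf)
    nonresp = np.where(high_ok, sweep.nonresponse_rate, -np.inf)
    tie_low = np.flatnonzero(resp >= resp.max() - _EPS)
    tie_low = tie_low[sweep.n_low[tie_low] == sweep.n_low[tie_low].max()]
    i_low = int(tie_low.min())  # smallest level among (rate, coverage) ties
    tie_high = np.flatnonzero(nonresp >= nonresp.max() - _EPS)
    tie_high = tie_high[sweep.n_high[tie_high] == sweep.n_high[tie_high].max()]
    i_high = int(tie_high.max())  # largest level among (rate, coverage) ties
    L = float(sweep.levels[i_low])
    U = float(sweep.levels[i_high])
    result = DayPredictionResult(
        day=sweep.day,
        score_kind=sweep.score_kind,
        admissible=L <= U,
        response_level=L,
        nonresponse_level=U,
        response_rate=float(sweep.response_rate[i_low]),
        nonresponse_rate=float(sweep.nonresponse_rate[i_high]),
        n_low=int(sweep.n_low[i_low]),
        n_high=int(sweep.n_high[i_high]),
        reason=None if L <= U else "response level exceeds non-response level",
    )
    return result


def select_best_day(results: Iterable[DayPredictionResult]) -> PredictionSummary:
    """Select, per score kind, the admissible day 1-10 with the narrowest
    indeterminate zone (ties -> earliest day); day 0 is reported separately
    as the baseline prediction."""
    by_kind: dict[str, list[DayPredictionResult]] = {}
    for r in results:
        by_kind.setdefault(r.score_kind, []).append(r)
    best: dict[str, DayPredictionResult] = {}
    baseline: dict[str, DayPredictionResult] = {}
    for kind, rs in by_kind.items():
        rs.sort(key=lambda r: r.day)
        for r in rs:
            if r.day == 0:
                baseline[kind] = r
        candidates = [r for r in rs if 1 <= r.day <= 10 and r.admissible]
        if candidates:
            best[kind] = min(
                candidates, key=lambda r: (r.indeterminate_width, r.day)
            )
    return PredictionSummary(best=best, baseline=baseline, all_days=by_kind)


def predict_cohort(
    daily_scores: pd.DataFrame,
    statuses: pd.DataFrame,
    days: Sequence[int] = tuple(range(11)),
    score_kinds: Sequence[str] = ("total", "gi", "wso"),
    step: float = 0.01,
    min_group: int = 30,
) -> PredictionSummary:
    """Run the full sweep over candidate days and score kinds.

    ``daily_scores`` is the long-format table (patient_id, day, gi, wso,
    total); ``statuses`` the Week-8 responder classification.
    """
    flag_by_patient = statuses.set_index("patient_id")["is_responder"]
    results = []
    for day in days:
        day_rows = daily_scores[daily_scores["day"] == day]
        if day_rows.empty:
            continue
        for kind in score_kinds:
            scores = day_rows.set_index("patient_id")[kind]
            flags = flag_by_patient.reindex(scores.index)
            if flags.isna().any():
                raise ValueError(
                    "responder status missing for patients scored on day "
                    f"{day}: {list(scores.index[flags.isna()])[:5]} ..."
                )
            sweep = sweep_day(
                scores,
                flags,
                step=step,
                score_max=SCORE_MAXIMA[kind],
                day=day,
                score_kind=kind,
            )
            results.append(optimize_day(sweep, min_group=min_group))
    return select_best_day(results)


def summary_table(summary: PredictionSummary) -> pd.DataFrame:
    """Flatten a summary into the reporting table (rates as 1-dp percents)."""
    rows = []
    for label, group in (("best", summary.best), ("baseline", summary.baseline)):
        for kind, r in group.items():
            rows.append(
                {
                    "score_kind": kind,
                    "selection": label,
                    "day": r.day,
                    "response_level": r.response_level,
                    "n_low": r.n_low,
                    "nonresponse_level": r.nonresponse_level,
                    "n_high": r.n_high,
                    "response_rate_pct": None
                    if r.response_rate is None
                    else round(100 * r.response_rate, 1),
                    "nonresponse_rate_pct": None
                    if r.nonresponse_rate is None
                    else round(100 * r.nonresponse_rate, 1),
                    "admissible": r.admissible,
                }
            )
    return pd.DataFrame(rows)
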