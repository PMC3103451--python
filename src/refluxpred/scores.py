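"""Instrument scoring: ReQuest (short form), HADS and GERDyzer.

ReQuest assesses seven GORD symptom dimensions, each by a 100 mm intensity
VAS and (except general well-being) a 7-point frequency Likert scale.  The
dimensions group into two sub-scales:

* GI  (acid, upper abdominal, lower abdominal, nausea), range 0-30.77
* WSO (well-being, sleep, other complaints),            range 0-15.51

so the total score ranges 0-46.28.  The proprietary item-to-score algorithm
is not public; this module uses a documented stand-in: each dimension
contributes ``weight * (intensity/100) * (frequency/6)`` (intensity only for
well-being), with per-dimension weights that default to an equal split of
the published sub-scale maxima.  The sub-scale and total maxima — the
quantities every downstream analysis depends on — are exact.

HADS is scored per the published instrument: two 7-item sub-scales
(anxiety, depression), items 0-3, with bands normal (0-7), suggestive
(8-10) and probable (>=11).  GERDyzer is aggregated as the mean of its ten
0-100 VAS dimensions (higher = greater quality-of-life impairment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GI_MAX",
    "WSO_MAX",
    "TOTAL_MAX",
    "GI_DIMENSIONS",
    "WSO_DIMENSIONS",
    "DIMENSIONS",
    "RequestItemResponse",
    "RequestDayScore",
    "HadsScore",
    "default_request_weights",
    "score_request_day",
    "hads_band",
    "score_hads",
    "score_gerdyzer",
]

#: Published score ranges of the short-form ReQuest.
GI_MAX = 30.77
WSO_MAX = 15.51
TOTAL_MAX = 46.28

GI_DIMENSIONS = ("acid", "upper_abdominal", "lower_abdominal", "nausea")
WSO_DIMENSIONS = ("wellbeing", "sleep", "other")
DIMENSIONS = GI_DIMENSIONS + WSO_DIMENSIONS

#: The well-being dimension carries no frequency item.
_INTENSITY_ONLY = frozenset({"wellbeing"})


class ScoringError(ValueError):
    """Raised for invalid item-level input."""


@dataclass(frozen=True)
class RequestItemResponse:
    """One dimension's response: intensity 0-100 mm, frequency 0-6 (or None)."""

    dimension: str
    intensity: float
    frequency: int | None = None

    def validate(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ScoringError(f"unknown ReQuest dimension {self.dimension!r}")
        if not 0.0 <= self.intensity <= 100.0:
            raise ScoringError(
                f"intensity {self.intensity} outside [0, 100] for {self.dimension}"
            )
        if self.dimension in _INTENSITY_ONLY:
            if self.frequency is not None:
                raise ScoringError("wellbeing has no frequency item")
        else:
            if self.frequency is None or self.frequency not in range(7):
                raise ScoringError(
                    f"frequency must be an integer 0-6 for {self.dimension}, "
                    f"got {self.frequency!r}"
                )


@dataclass(frozen=True)
class RequestDayScore:
    """One day's ReQuest scores: per-dimension, sub-scales and total."""

    gi: float
    wso: float
    total: float
    dimension_scores: Mapping[str, float]


def default_request_weights() -> dict[str, float]:
    """Per-dimension maxima: sub-scale maxima split equally within sub-scale."""
    weights = {d: GI_MAX / len(GI_DIMENSIONS) for d in GI_DIMENSIONS}
    weights.update({d: WSO_MAX / len(WSO_DIMENSIONS) for d in WSO_DIMENSIONS})
    return weights


def score_request_day(
    items: Iterable[RequestItemResponse],
    weights: Mapping[str, float] | None = None,
) -> RequestDayScore:
    """Score one day's ReQuest responses.

    Parameters
    ----------
    items
        Exactly one :class:`RequestItemResponse` per dimension.
    weights
        Per-dimension maxima; defaults to an equal split of the sub-scale
        maxima.  Must be nonnegative and sum to the published maxima within
        each sub-scale for the scale interpretation to hold (not enforced,
        so alternative splits remain usable).
    """
    if weights is None:
        weights = default_request_weights()
    seen: dict[str, RequestItemResponse] = {}
    for item in items:
        item.validate()
        if item.dimension in seen:
            raise ScoringError(f"duplicate dimension {item.dimension!r}")
        seen[item.dimension] = item
    missing = set(DIMENSIONS) - set(seen)
    if missing:
        raise ScoringError(f"missing dimensions: {sorted(missing)}")

    dim_scores: dict[str, float] = {}
    for dim, item in seen.items():
        w = weights[dim]
        score = w * item.intensity / 100.0
        if dim not in _INTENSITY_ONLY:
            score *= item.frequency / 6.0
        dim_scores[dim] = score
    gi = sum(dim_scores[d] for d in GI_DIMENSIONS)
    wso = sum(dim_scores[d] for d in WSO_DIMENSIONS)
    return RequestDayScore(gi=gi, wso=wso, total=gi + wso, dimension_scores=dim_scores)


# ---------------------------------------------------------------------------
# HADS

#: Default item-to-subscale layout: odd-numbered items (1-based) -> anxiety.
DEFAULT_HADS_MAP = tuple("anxiety" if i % 2 == 0 else "depression" for i in range(14))

_BANDS = ("normal", "suggestive", "probable")


@dataclass(frozen=True)
class HadsScore:
    anxiety: int
    depression: int
    total: int
    anxiety_band: str
    depression_band: str


def hads_band(score: int) -> str:
    """Band a HADS sub-score: 0-7 normal, 8-10 suggestive, >=11 probable."""
    if not 0 <= score <= 21:
        raise ScoringError(f"HADS sub-score {score} outside [0, 21]")
    if score <= 7:
        return "normal"
    if score <= 10:
        return "suggestive"
    return "probable"


def score_hads(
    item_scores: Sequence[int],
    subscale_map: Sequence[str] = DEFAULT_HADS_MAP,
) -> HadsScore:
    """Score the 14-item HADS into anxiety/depression sub-scores and bands."""
    if len(item_scores) != 14 or len(subscale_map) != 14:
        raise ScoringError("HADS requires exactly 14 items and 14 map entries")
    for v in item_scores:
        if v not in (0, 1, 2, 3):
            raise ScoringError(f"HADS item score {v!r} outside 0-3")
    if sorted(subscale_map.count(s) for s in ("anxiety", "depression")) != [7, 7]:
        raise ScoringError("subscale_map must assign 7 items to each subscale")
    anxiety = sum(v for v, s in zip(item_scores, subscale_map) if s == "anxiety")
    depression = sum(v for v, s in zip(item_scores, subscale_map) if s == "depression")
    return HadsScore(
        anxiety=anxiety,
        depression=depression,
        total=anxiety + depression,
        anxiety_band=hads_band(anxiety),
        depression_band=hads_band(depression),
    )


# ---------------------------------------------------------------------------
# GERDyzer

N_GERDYZER_DIMENSIONS = 10


def score_gerdyzer(dimension_vas: Sequence[float]) -> float:
    """Aggregate the ten GERDyzer VAS dimensions as their mean (0-100).

    Higher scores indicate greater quality-of-life impairment.  The mean is
    used (rather than the sum) so the aggregate keeps the 0-100 mm VAS
    interpretation.
    """
    if len(dimension_vas) != N_GERDYZER_DIMENSIONS:
        raise ScoringError(
            f"GERDyzer requires exactly {N_GERDYZER_DIMENSIONS} dimension values"
        )
    for v in dimension_vas:
        if not 0.0 <= v <= 100.0:
            raise ScoringError(f"GERDyzer VAS value {v} outside [0, 100]")
    return float(sum(dimension_vas)) / N_GERDYZER_DIMENSIONS
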