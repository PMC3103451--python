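"""Concordance of score-defined response with patient satisfaction and
investigator assessment, and quality-of-life summaries by responder group.

The responder rule is a daily-questionnaire construct; patients and
investigators judge symptom control more coarsely.  These summaries
quantify the disagreement: the share of patients in the most favourable
assessment category ('very satisfied' / 'well-controlled') who are
nevertheless non-responders, and the share of responders who still declare
themselves 'not satisfied' (or are judged 'not controlled').

GERDyzer quality-of-life scores are compared between responder groups at
baseline and both visits; the baseline-to-visit falls are compared with an
unpaired large-sample (Welch) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceTable",
    "crosstab_assessment",
    "discordance_summary",
    "qol_summary",
]

_CATEGORIES = {
    "satisfaction": ("very", "fairly", "not"),
    "investigator": ("well", "fairly", "not"),
}
_VISIT_DAY = {"week4": 28, "week8": 56}


@dataclass(frozen=True)
class ConcordanceTable:
    """3x2 cross-tabulation of assessment category by responder status."""

    assessment_kind: str
    visit: str
    counts: pd.DataFrame  # index: category; columns: [responder, nonresponder]
    n_assessed: int
    n_missing: int

    @property
    def proportions(self) -> pd.DataFrame:
        """Within-category (row) proportions."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0), axis=0)


def crosstab_assessment(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    assessment_kind: str,
    visit: str,
) -> ConcordanceTable:
    """Cross-tabulate an assessment against responder status at its visit.

    Patients lacking the assessment are excluded from the table and
    counted in ``n_missing``.
    """
    if assessment_kind not in _CATEGORIES:
        raise ValueError(f"unknown assessment kind {assessment_kind!r}")
    if visit not in _VISIT_DAY:
        raise ValueError(f"unknown visit {visit!r}")
    col = f"{assessment_kind}_{'w4' if visit == 'week4' else 'w8'}"
    if col not in cohort:
        raise ValueError(f"cohort lacks assessment column {col!r}")
    horizons = statuses["horizon_day"].unique()
    if len(horizons) != 1 or horizons[0] != _VISIT_DAY[visit]:
        raise ValueError(
            f"statuses must be classified at day {_VISIT_DAY[visit]} for {visit}"
        )
    flags = statuses.set_index("patient_id")["is_responder"]
    assessed = cohort[["patient_id", col]].dropna(subset=[col])
    n_missing = len(cohort) - len(assessed)
    resp = flags.reindex(assessed["patient_id"])
    if resp.isna().any():
        raise ValueError("responder status missing for assessed patients")
    categories = _CATEGORIES[assessment_kind]
    counts = pd.DataFrame(
        0,
        index=pd.Index(categories, name="category"),
        columns=["responder", "nonresponder"],
    )
    tab = pd.crosstab(assessed[col].to_numpy(), resp.to_numpy())
    for cat in tab.index:
        if cat not in categories:
            raise ValueError(f"unexpected {assessment_kind} category {cat!r}")
        for is_resp in tab.columns:
            counts.loc[cat, "responder" if is_resp else "nonresponder"] = tab.loc[
                cat, is_resp
            ]
    return ConcordanceTable(
        assessment_kind=assessment_kind,
        visit=visit,
        counts=counts,
        n_assessed=int(counts.to_numpy().sum()),
        n_missing=n_missing,
    )


def discordance_summary(table: ConcordanceTable) -> dict:
    """Headline discordance proportions from a concordance table.

    * ``top_category_nonresponder_share``: fraction of patients in the most
      favourable category ('very' / 'well') who are non-responders;
    * ``responder_worst_category_share``: fraction of responders who fall
      in the least favourable category ('not').

    Undefined proportions (zero denominators) are returned as NaN and
    flagged.
    """
    top = table.counts.index[0]
    worst = table.counts.index[-1]
    top_total = int(table.counts.loc[top].sum())
    resp_total = int(table.counts["responder"].sum())
    top_share = (
        table.counts.loc[top, "nonresponder"] / top_total if top_total else math.nan
    )
    worst_share = (
        table.counts.loc[worst, "responder"] / resp_total if resp_total else math.nan
    )
    return {
        "assessment_kind": table.assessment_kind,
        "visit": table.visit,
        "top_category": top,
        "top_category_n": top_total,
        "top_category_nonresponder_n": int(table.counts.loc[top, "nonresponder"]),
        "top_category_nonresponder_share": float(top_share),
        "top_category_nonresponder_pct": None
        if math.isnan(top_share)
        else round(100.0 * top_share, 1),
        "responder_n": resp_total,
        "responder_worst_category_share": float(worst_share),
        "responder_worst_category_pct": None
        if math.isnan(worst_share)
        else round(100.0 * worst_share, 1),
        "undefined": bool(math.isnan(top_share) or math.isnan(worst_share)),
    }


def qol_summary(cohort: pd.DataFrame, statuses: pd.DataFrame) -> dict:
    """GERDyzer group means at day 0 / week 4 / week 8 and the falls.

    The baseline-to-visit falls are compared between responders and
    non-responders with an unpaired Welch test (large-sample; the
    underlying analysis reports only a p-value, not a named test).
    """
    needed = {"gerdyzer_day0", "gerdyzer_w4", "gerdyzer_w8"}
    if not needed <= set(cohort.columns):
        raise ValueError("cohort lacks GERDyzer columns")
    horizons = statuses["horizon_day"].unique()
    if len(horizons) != 1:
        raise ValueError("mixed horizons in status table")
    flags = (
        statuses.set_index("patient_id")["is_responder"]
        .reindex(cohort["patient_id"])
        .to_numpy(bool)
    )
    out: dict = {"groups": {}, "comparisons": {}}
    for label, mask in (("responder", flags), ("nonresponder", ~flags)):
        sub = cohort[mask]
        if len(sub) == 0:
            out["groups"][label] = {"n": 0, "flagged": "empty group"}
            continue
        entry = {"n": int(len(sub))}
        for when in ("day0", "w4", "w8"):
            entry[f"mean_{when}"] = float(sub[f"gerdyzer_{when}"].mean())
        entry["fall_w4"] = entry["mean_day0"] - entry["mean_w4"]
        entry["fall_w8"] = entry["mean_day0"] - entry["mean_w8"]
        out["groups"][label] = entry
    for visit in ("w4", "w8"):
        r = cohort.loc[flags, "gerdyzer_day0"] - cohort.loc[flags, f"gerdyzer_{visit}"]
        n = cohort.loc[~flags, "gerdyzer_day0"] - cohort.loc[~flags, f"gerdyzer_{visit}"]
        if len(r) < 2 or len(n) < 2:
            out["comparisons"][visit] = {"flagged": "group too small"}
            continue
        t, p = stats.ttest_ind(r, n, equal_var=False)
        out["comparisons"][visit] = {
            "mean_fall_responder": float(np.mean(r)),
            "mean_fall_nonresponder": float(np.mean(n)),
            "difference": float(np.mean(r) - np.mean(n)),
            "statistic": float(t),
            "p_value": float(p),
        }
    return out
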