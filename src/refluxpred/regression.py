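"""Logistic factor screening of week-8 treatment response.

Univariate screening fits one logistic regression per baseline factor
(erosive vs non-erosive disease, HADS total and sub-scores, IBS symptoms,
BMI, gender, geography, H. pylori serology, age, and — within the erosive
subgroup only — oesophagitis grade) with week-8 responder status as the
outcome.  A global multivariate model then adjusts for confounding; it
enters HADS only as the total score and erosive disease only by its
presence (not by grade).

Fits are maximum likelihood (Newton iterations via statsmodels) with Wald
standard errors; each factor additionally gets a likelihood-ratio p-value
(null vs factor model), which is the single per-factor p-value the
screening table reports.  No multiple-testing adjustment is applied: the
screen is explorative and p-values are interpreted as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FactorSpec",
    "RegressionResult",
    "TABLE_FACTORS",
    "MULTIVARIATE_FACTORS",
    "encode_factors",
    "fit_logistic",
    "univariate_screen",
    "multivariate_fit",
    "results_table",
]

_CONVERGENCE_TOL = 1e-8


@dataclass(frozen=True)
class FactorSpec:
    """How one cohort field enters a design matrix."""

    name: str
    kind: str  # 'binary' | 'continuous' | 'categorical'
    source: str  # cohort column (or derived quantity)
    reference_level: str | None = None
    levels: tuple[str, ...] | None = None
    subgroup: str | None = None  # e.g. 'erd': fit within ERD patients only
    drop_values: tuple[str, ...] = ()


def _default_specs() -> dict[str, FactorSpec]:
    return {
        "erd_nerd": FactorSpec("erd_nerd", "binary", "oesophagitis"),
        "hads_total": FactorSpec("hads_total", "continuous", "hads_total"),
        "hads_anxiety": FactorSpec(
            "hads_anxiety", "continuous", "hads_anxiety_baseline"
        ),
        "hads_depression": FactorSpec(
            "hads_depression", "continuous", "hads_depression_baseline"
        ),
        "ibs": FactorSpec(
            "ibs", "categorical", "ibs_flag", reference_level="no",
            levels=("no", "yes", "unknown"),
        ),
        "bmi": FactorSpec("bmi", "continuous", "bmi"),
        "gender": FactorSpec(
            "gender", "categorical", "gender", reference_level="female",
            levels=("female", "male"),
        ),
        "geography": FactorSpec(
            "geography", "categorical", "geography",
            reference_level="Western Europe",
            levels=(
                "Western Europe", "South America", "Asia", "Canada",
                "South Africa", "Australia",
            ),
        ),
        "h_pylori": FactorSpec(
            "h_pylori", "categorical", "h_pylori", reference_level="negative",
            levels=("negative", "positive", "intermediate"),
            drop_values=("missing",),
        ),
        "age": FactorSpec("age", "continuous", "age"),
        "oesophagitis_grade": FactorSpec(
            "oesophagitis_grade", "categorical", "oesophagitis",
            reference_level="A", levels=("A", "B", "C", "D"), subgroup="erd",
        ),
    }


#: Factor screening order of the published table.
TABLE_FACTORS = (
    "erd_nerd",
    "hads_total",
    "hads_anxiety",
    "hads_depression",
    "ibs",
    "bmi",
    "gender",
    "geography",
    "h_pylori",
    "age",
    "oesophagitis_grade",
)

#: The global model uses HADS as total score and erosive disease by
#: presence only; grades and HADS sub-scores are excluded.
MULTIVARIATE_FACTORS = (
    "erd_nerd",
    "hads_total",
    "ibs",
    "bmi",
    "gender",
    "geography",
    "h_pylori",
    "age",
)


@dataclass
class RegressionResult:
    """One fitted logistic model."""

    model: str  # 'univariate' | 'multivariate'
    factors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    llnull: float
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool = False
    lr_pvalues: dict[str, float] = field(default_factory=dict)
    degenerate_columns: tuple[str, ...] = ()

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)


def _prepare(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "hads_total" not in df and {
        "hads_anxiety_baseline",
        "hads_depression_baseline",
    } <= set(df.columns):
        df["hads_total"] = (
            df["hads_anxiety_baseline"] + df["hads_depression_baseline"]
        )
    return df


def encode_factors(
    cohort: pd.DataFrame, factor_names: Sequence[str]
) -> tuple[pd.DataFrame, int, tuple[str, ...]]:
    """Build a design matrix (without outcome) for the named factors.

    Returns ``(design, n_dropped, degenerate_columns)``.  Dummy coding is
    against the stated reference levels; rows with a missing or dropped
    value in any required factor are removed (complete-case), and
    zero-variance columns are reported rather than silently kept.
    """
    specs = _default_specs()
    unknown = [f for f in factor_names if f not in specs]
    if unknown:
        raise ValueError(f"unknown factor(s): {unknown}")
    if not factor_names:
        raise ValueError("no factors supplied")
    df = _prepare(cohort)

    keep = pd.Series(True, index=df.index)
    for name in factor_names:
        spec = specs[name]
        if spec.source not in df:
            raise ValueError(f"cohort lacks column {spec.source!r} for {name}")
        col = df[spec.source]
        keep &= col.notna()
        if spec.kind == "categorical":
            keep &= ~col.isin(spec.drop_values)
            keep &= col.isin(spec.levels) | col.isna()
        if name == "erd_nerd":
            keep &= col.isin(["NERD", "A", "B", "C", "D"])
        if spec.subgroup == "erd":
            keep &= col.isin(["A", "B", "C", "D"])
    sub = df[keep]

    cols: dict[str, np.ndarray] = {}
    for name in factor_names:
        spec = specs[name]
        col = sub[spec.source]
        if name == "erd_nerd":
            cols["erd_nerd[ERD]"] = col.isin(["A", "B", "C", "D"]).to_numpy(float)
        elif spec.kind == "continuous":
            cols[name] = col.to_numpy(float)
        elif spec.kind == "categorical":
            for level in spec.levels:
                if level == spec.reference_level:
                    continue
                cols[f"{name}[{level}]"] = (col == level).to_numpy(float)
        else:  # pragma: no cover - no plain-binary spec besides erd_nerd
            cols[name] = col.to_numpy(float)
    design = pd.DataFrame(cols, index=sub.index)
    degenerate = tuple(c for c in design.columns if design[c].nunique() <= 1)
    return design, int((~keep).sum()), degenerate


def fit_logistic(
    design: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    model: str = "univariate",
    factors: tuple[str, ...] = (),
    n_dropped: int = 0,
    degenerate: tuple[str, ...] = (),
) -> RegressionResult:
    """Maximum-likelihood logistic fit with Wald inference.

    Complete or quasi-complete separation is flagged on the result rather
    than returning a silently divergent estimate.
    """
    y = np.asarray(outcome, dtype=float)
    if design.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    if design.shape[0] == 0:
        raise ValueError("empty design matrix")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot fit")
    X = sm.add_constant(design.astype(float), has_constant="add")

    separation = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(
                disp=0, method="newton", tol=_CONVERGENCE_TOL, maxiter=100
            )
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception:
            # Newton failing outright on a separable design: refit with a
            # bounded step so coefficients/SEs are at least finite, and flag.
            fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
            separation = True
    # Quasi-separation shows up as huge coefficients with huge SEs.
    if np.any(np.abs(fit.params) > 15) or not np.all(np.isfinite(fit.bse)):
        separation = True
    p1 = y.mean()
    llnull = y.size * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    return RegressionResult(
        model=model,
        factors=factors or tuple(design.columns),
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        llf=float(fit.llf),
        llnull=float(llnull),
        n_used=int(y.size),
        n_dropped=n_dropped,
        converged=converged and not separation,
        separation=separation,
        degenerate_columns=degenerate,
    )


def _lr_pvalue(full: RegressionResult, reduced_llf: float, df: int) -> float:
    lr = 2.0 * (full.llf - reduced_llf)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def _fit_named(
    cohort: pd.DataFrame,
    outcome_by_patient: pd.Series,
    factor_names: tuple[str, ...],
    model: str,
) -> RegressionResult:
    design, n_dropped, degenerate = encode_factors(cohort, factor_names)
    y = outcome_by_patient.reindex(cohort.loc[design.index, "patient_id"]).to_numpy()
    if np.isnan(np.asarray(y, dtype=float)).any():
        raise ValueError("responder status missing for some cohort patients")
    result = fit_logistic(
        design,
        y,
        model=model,
        factors=factor_names,
        n_dropped=n_dropped,
        degenerate=degenerate,
    )
    # Likelihood-ratio p per factor: drop the factor's columns and refit.
    for name in factor_names:
        cols = [c for c in design.columns if c == name or c.startswith(f"{name}[")]
        reduced_cols = [c for c in design.columns if c not in cols]
        if reduced_cols:
            reduced = fit_logistic(design[reduced_cols], y, model=model)
            reduced_llf = reduced.llf
        else:
            reduced_llf = result.llnull
        result.lr_pvalues[name] = _lr_pvalue(result, reduced_llf, df=len(cols))
    return result


def _check_statuses(cohort: pd.DataFrame, statuses: pd.DataFrame) -> pd.Series:
    if len(cohort) < 2:
        raise ValueError("cohort too small for regression")
    horizons = statuses["horizon_day"].unique()
    if len(horizons) != 1 or horizons[0] != 56:
        raise ValueError("factor screening expects week-8 (day 56) statuses")
    return statuses.set_index("patient_id")["is_responder"].astype(float)


def univariate_screen(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    factor_names: Iterable[str] = TABLE_FACTORS,
) -> list[RegressionResult]:
    """One single-factor logistic fit per screened factor.

    Oesophagitis grade is fitted within the erosive subgroup only.
    """
    outcome = _check_statuses(cohort, statuses)
    return [
        _fit_named(cohort, outcome, (name,), model="univariate")
        for name in factor_names
    ]


def multivariate_fit(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    factor_names: tuple[str, ...] = MULTIVARIATE_FACTORS,
) -> RegressionResult:
    """The global confounding-adjusted model."""
    if not factor_names:
        raise ValueError("no factors supplied")
    outcome = _check_statuses(cohort, statuses)
    return _fit_named(cohort, outcome, tuple(factor_names), model="multivariate")


def results_table(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Flatten fit results to the reporting table."""
    rows = []
    for res in results:
        for term in res.params.index:
            if term == "const":
                continue
            factor = next(
                (f for f in res.factors if term == f or term.startswith(f"{f}[")),
                term,
            )
            rows.append(
                {
                    "model": res.model,
                    "factor": factor,
                    "term": term,
                    "coefficient": res.params[term],
                    "se": res.bse[term],
                    "odds_ratio": float(np.exp(res.params[term])),
                    "wald_p": res.pvalues[term],
                    "lr_p": res.lr_pvalues.get(factor),
                    "n_used": res.n_used,
                    "converged": res.converged,
                    "separation": res.separation,
                }
            )
    return pd.DataFrame(rows)
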