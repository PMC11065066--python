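"""Covariate coding and logistic association of trajectory types with a binary outcome.

Per-trajectory odds ratios versus a reference trajectory are estimated by
maximum-likelihood logistic regression with indicator variables for each
non-reference trajectory plus the baseline adjustment set: age at baseline,
birth cohort (no crisis / war period / Great Depression), BMI, smoking,
two-or-more chronic conditions, low physical activity, and cohort attrition
(no dropout / dropout / deceased). 95% confidence intervals are Wald
intervals on the log-odds scale, exp(beta +/- 1.96 * SE).

The birth-cohort categories follow the historical-crisis windows: a war
period is 1914-1918 or 1939-1945, the Great Depression 1929-1938, and all
other birth years count as no crisis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_95 = 1.96  # Wald multiplier for 95% CIs
SEPARATION_COEF = 15.0  # |log-odds| beyond this flags quasi-complete separation
CONDITION_WARN = 1e6

BIRTH_COHORTS = ("no_crisis", "war", "great_depression")
ATTRITION_LEVELS = ("no_dropout", "dropout", "deceased")

#: Answer code meaning "more than once a week" on the 4-point activity scale
#: (1 more than once a week; 2 once a week; 3 one to three times a month;
#: 4 hardly ever or never).
ACTIVE_ANSWER = 1

COVARIATE_COLUMNS = [
    "subject_id",
    "age_baseline",
    "birth_cohort",
    "bmi",
    "smoker",
    "chronic_2plus",
    "low_activity",
    "attrition",
]


def code_birth_cohort(birth_year: int) -> str:
    """Map a birth year to its crisis category (total function on integers)."""
    y = int(birth_year)
    if 1914 <= y <= 1918 or 1939 <= y <= 1945:
        return "war"
    if 1929 <= y <= 1938:
        return "great_depression"
    return "no_crisis"


@dataclass
class CovariateRecord:
    """One subject's baseline adjustment set."""

    subject_id: str
    age_baseline: float
    birth_cohort: str
    bmi: float
    smoker: int
    chronic_2plus: int
    low_activity: int
    attrition: str

    def __post_init__(self) -> None:
        if self.birth_cohort not in BIRTH_COHORTS:
            raise ValueError(f"unknown birth_cohort {self.birth_cohort!r}")
        if self.attrition not in ATTRITION_LEVELS:
            raise ValueError(f"unknown attrition {self.attrition!r}")


RAW_FIELDS = [
    "subject_id",
    "birth_year",
    "age_baseline",
    "weight_kg",
    "height_m",
    "smoker",
    "n_chronic",
    "vigorous_activity",
    "moderate_activity",
    "attrition",
]


def code_covariates(raw: Mapping[str, object]) -> CovariateRecord:
    """Derive the model covariates from raw baseline survey fields.

    BMI = weight / height^2; chronic_2plus indicates two or more chronic
    conditions; low_activity means neither the vigorous nor the moderate
    activity item was answered "more than once a week". A missing field
    raises KeyError/ValueError — table-level coding turns that into a
    complete-case exclusion.
    """
    missing = [f for f in RAW_FIELDS if f not in raw or pd.isna(raw[f])]
    if missing:
        raise ValueError(f"missing raw fields: {missing}")
    height = float(raw["height_m"])
    if height <= 0:
        raise ValueError("height must be positive")
    return CovariateRecord(
        subject_id=str(raw["subject_id"]),
        age_baseline=float(raw["age_baseline"]),
        birth_cohort=code_birth_cohort(int(raw["birth_year"])),
        bmi=float(raw["weight_kg"]) / height**2,
        smoker=int(bool(raw["smoker"])),
        chronic_2plus=int(int(raw["n_chronic"]) >= 2),
        low_activity=int(
            int(raw["vigorous_activity"]) != ACTIVE_ANSWER
            and int(raw["moderate_activity"]) != ACTIVE_ANSWER
        ),
        attrition=str(raw["attrition"]),
    )


def code_covariate_table(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Complete-case covariate coding; returns the coded table and excluded ids."""
    records, excluded = [], []
    for _, row in raw.iterrows():
        try:
            records.append(code_covariates(row.to_dict()))
        except (ValueError, KeyError):
            excluded.append(str(row.get("subject_id", "?")))
    coded = pd.DataFrame([r.__dict__ for r in records], columns=COVARIATE_COLUMNS)
    return coded, excluded


@dataclass
class AssociationResult:
    """Per-trajectory odds ratios versus the reference, with model metadata."""

    reference: object
    odds_ratios: pd.DataFrame  # index = trajectory label; OR, ci_low, ci_high, coef, se
    n: int
    covariates_used: list[str]
    converged: bool
    message: str = ""
    coefficients: pd.Series = field(default_factory=pd.Series)
    standard_errors: pd.Series = field(default_factory=pd.Series)


def _design_matrix(
    labels: pd.Series,
    covariates: pd.DataFrame | None,
    reference: object,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    parts = [pd.Series(1.0, index=labels.index, name="intercept")]
    traj_terms = []
    for lab in sorted((set(labels.unique()) - {reference}), key=str):
        name = f"traj[{lab}]"
        parts.append((labels == lab).astype(float).rename(name))
        traj_terms.append(name)
    cov_terms: list[str] = []
    if covariates is not None:
        cov = covariates
        for col in ("age_baseline", "bmi", "smoker", "chronic_2plus", "low_activity"):
            if col in cov.columns:
                parts.append(cov[col].astype(float))
                cov_terms.append(col)
        if "birth_cohort" in cov.columns:
            for level in BIRTH_COHORTS[1:]:  # no_crisis is the reference level
                name = f"birth_cohort[{level}]"
                parts.append((cov["birth_cohort"] == level).astype(float).rename(name))
                cov_terms.append(name)
        if "attrition" in cov.columns:
            for level in ATTRITION_LEVELS[1:]:  # no_dropout is the reference level
                name = f"attrition[{level}]"
                parts.append((cov["attrition"] == level).astype(float).rename(name))
                cov_terms.append(name)
    X = pd.concat(parts, axis=1)
    return X, traj_terms, cov_terms


def fit_trajectory_outcome_model(
    outcome: Sequence[int] | pd.Series,
    labels: Sequence[object] | pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: object | None = None,
) -> AssociationResult:
    """Logistic model of a binary outcome on trajectory type plus covariates.

    Parameters
    ----------
    outcome, labels
        Equal-length binary outcome and trajectory assignment, aligned by
        position (or by ``subject_id`` if ``covariates`` carries one).
    covariates
        Optional coded covariate table (columns as in ``COVARIATE_COLUMNS``);
        ``None`` fits the crude (unadjusted) model.
    reference
        Trajectory whose odds are the denominator; defaults to the largest
        cluster. Must contain both outcome values.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    labs = pd.Series(np.asarray(labels, dtype=object), index=y.index)
    if len(y) != len(labs):
        raise ValueError("outcome and labels differ in length")
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        if len(covariates) != len(y):
            raise ValueError("covariates table length mismatch")

    if reference is None:
        reference = labs.value_counts().idxmax()
    if reference not in set(labs):
        raise ValueError(f"reference trajectory {reference!r} not present")
    ref_outcomes = set(y[labs == reference].unique())
    if ref_outcomes != {0.0, 1.0}:
        raise ValueError(
            f"reference trajectory {reference!r} must contain both outcome values"
        )

    X, traj_terms, cov_terms = _design_matrix(labs, covariates, reference)
    cond = np.linalg.cond(X.to_numpy())
    if cond > CONDITION_WARN:
        warnings.warn(
            f"design matrix condition number {cond:.3g} exceeds {CONDITION_WARN:.0e}; "
            "estimates may be unstable (age and birth cohort are partially collinear)",
            UserWarning,
            stacklevel=2,
        )

    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse = fit.params, fit.bse
            if not fit.mle_retvals.get("converged", True):
                converged, message = False, "maximum-likelihood fit did not converge"
        except Exception as exc:  # e.g. PerfectSeparationError
            converged, message = False, f"fit failed: {exc}"
            params = pd.Series(np.nan, index=X.columns)
            bse = pd.Series(np.nan, index=X.columns)

    if converged and np.any(np.abs(params[traj_terms]) > SEPARATION_COEF):
        converged = False
        message = (
            "quasi-complete separation suspected: a trajectory coefficient "
            f"exceeds |{SEPARATION_COEF}| on the log-odds scale"
        )

    rows = []
    for term in traj_terms:
        lab = term[len("traj[") : -1]
        coef, se = float(params[term]), float(bse[term])
        # clip the log-scale bounds so diverged (separated) fits yield inf, not overflow
        lo = np.clip(coef - Z_95 * se, -700, 700)
        hi = np.clip(coef + Z_95 * se, -700, 700)
        rows.append(
            {
                "trajectory": lab,
                "odds_ratio": float(np.exp(np.clip(coef, -700, 700))),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "coef": coef,
                "se": se,
            }
        )
    or_table = pd.DataFrame(rows).set_index("trajectory")

    return AssociationResult(
        reference=reference,
        odds_ratios=or_table,
        n=int(len(y)),
        covariates_used=cov_terms,
        converged=converged,
        message=message,
        coefficients=params,
        standard_errors=bse,
    )


def make_association_table(result: AssociationResult) -> pd.DataFrame:
    """Human-readable OR table: "label, OR (lo–hi)", reference marked "Ref."."""
    rows = [{"trajectory": str(result.reference), "OR (95%CI)": "Ref."}]
    for lab, r in result.odds_ratios.iterrows():
        rows.append(
            {
                "trajectory": str(lab),
                "OR (95%CI)": (
                    f"{r['odds_ratio']:.2f} ({r['ci_low']:.2f}–{r['ci_high']:.2f})"
                ),
            }
        )
    return pd.DataFrame(rows)


def filter_outcome_site(
    outcomes: pd.DataFrame,
    site: str | None = None,
    known_sites: Sequence[str] | None = None,
) -> pd.Series:
    """Binary outcome restricted to one cancer site.

    ``outcomes`` needs columns ``cancer`` (0/1) and ``site`` (text, empty or
    NA for none). With ``site=None`` the overall outcome is returned, a
    superset of every site-specific one.
    """
    if "cancer" not in outcomes.columns:
        raise ValueError("outcomes table needs a 'cancer' column")
    overall = outcomes["cancer"].astype(int)
    if site is None:
        return overall
    if "site" not in outcomes.columns:
        raise ValueError("outcomes table needs a 'site' column for site filters")
    sites_present = set(
        outcomes.loc[outcomes["site"].notna(), "site"].astype(str).str.lower()
    ) - {""}
    known = set(s.lower() for s in known_sites) if known_sites is not None else sites_present
    if site.lower() not in known:
        raise ValueError(f"unknown cancer site {site!r}; known: {sorted(known)}")
    hit = outcomes["site"].fillna("").astype(str).str.lower() == site.lower()
    return (overall.astype(bool) & hit).astype(int)
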