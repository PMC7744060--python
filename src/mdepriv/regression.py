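"""Count regressions of the number of deprivations on covariates.

The outcome is each respondent's unweighted deprivation count
``d_i = sum_j b_ij`` (an integer in 0..m).  Two families are fit: OLS, and a
Poisson model appropriate for a count outcome; both report
heteroskedasticity-robust (sandwich) standard errors.  For the Poisson
model, a coefficient ``beta`` translates to a percent change in the expected
number of deprivations via ``(e^beta - 1) x 100``.

Household income arrives as a 1..21 category; :func:`impute_income` assigns
the category midpoint (the open-ended top category gets 1.5x its lower
bound) and the design uses its natural log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survey import DeprivationMatrix, SurveyDataset

__all__ = [
    "INCOME_CATEGORY_BOUNDS",
    "RegressionSpec",
    "RegressionResult",
    "impute_income",
    "build_design",
    "fit_count_model",
    "percent_change",
]

logger = logging.getLogger("mdepriv")

# 21-category household income bands (dollars/year). The survey reports only
# the category number; these bounds define the midpoint imputation. The top
# category is open-ended (upper bound None).
INCOME_CATEGORY_BOUNDS: list[tuple[float, Optional[float]]] = [
    (0, 5_000),
    (5_000, 7_500),
    (7_500, 10_000),
    (10_000, 12_500),
    (12_500, 15_000),
    (15_000, 20_000),
    (20_000, 25_000),
    (25_000, 30_000),
    (30_000, 35_000),
    (35_000, 40_000),
    (40_000, 50_000),
    (50_000, 60_000),
    (60_000, 75_000),
    (75_000, 85_000),
    (85_000, 100_000),
    (100_000, 125_000),
    (125_000, 150_000),
    (150_000, 175_000),
    (175_000, 200_000),
    (200_000, 250_000),
    (250_000, None),
]

# design terms in presentation order; 'basic' subset mirrors race-only models
FULL_TERMS = [
    "white",
    "black",
    "hispanic",
    "log_income",
    "hh_size",
    "age",
    "educ",
    "female",
    "married",
    "metro",
    "stay_home",
]
BASIC_TERMS = ["white", "black", "hispanic"]

RACE_DUMMY_LEVELS = {"white": "white", "black": "black", "hispanic": "hispanic"}
# reference: other non-Hispanic and 2+ races non-Hispanic


@dataclass(frozen=True)
class RegressionSpec:
    """What to fit: family, covariate terms, weighting and SE options."""

    family: Literal["ols", "poisson"] = "ols"
    terms: Sequence[str] = field(default_factory=lambda: list(FULL_TERMS))
    use_sample_weights: bool = False
    robust_se: bool = True
    income_bounds: Sequence[tuple[float, Optional[float]]] = field(
        default_factory=lambda: list(INCOME_CATEGORY_BOUNDS)
    )

    def __post_init__(self):
        if self.family not in ("ols", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.terms:
            raise ValueError("design must contain at least one term")


@dataclass(frozen=True)
class RegressionResult:
    """Coefficients and robust SEs for one fitted count model."""

    family: str
    coefficients: dict[str, float]
    robust_ses: dict[str, float]
    fit_stats: dict[str, float]
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        """term, estimate, robust SE and significance stars (10/5/1 percent)."""
        from scipy import stats

        rows = []
        for term, beta in self.coefficients.items():
            se = self.robust_ses[term]
            z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
            p = 2 * (1 - stats.norm.cdf(abs(z)))
            stars = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""
            rows.append(
                {"term": term, "estimate": beta, "robust_se": se, "p_value": p, "stars": stars}
            )
        return pd.DataFrame(rows)


def impute_income(
    income_category: int,
    bounds_table: Sequence[tuple[float, Optional[float]]] = INCOME_CATEGORY_BOUNDS,
) -> float:
    """Dollar income imputed for a 1-based income category.

    Midpoint of the category's bounds; the open-ended top category gets
    1.5x its lower bound.
    """
    n_cat = len(bounds_table)
    if not 1 <= int(income_category) <= n_cat:
        raise ValueError(f"income category must be in 1..{n_cat}, got {income_category}")
    lo, hi = bounds_table[int(income_category) - 1]
    if hi is None:
        return lo * 1.5
    return (lo + hi) / 2


def build_design(
    dataset: SurveyDataset,
    matrix: DeprivationMatrix,
    spec: RegressionSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Design matrix, deprivation-count outcome, and bookkeeping info.

    Expected covariate columns (as produced by the synthetic generator):
    race_ethnicity (white/black/other/hispanic/two_plus), age,
    education (1..4 ordered), gender (male/female), marital
    (married/partner/other), household_size, income_category (1..21),
    metro (0/1), stay_home (0/1). Rows with any missing required covariate
    are dropped (and logged); constant columns are flagged as collinear in
    ``info['collinear']``.
    """
    data = dataset.data.set_index(dataset.data["respondent_id"].astype(str))
    data = data.loc[matrix.row_ids]
    count = pd.Series(matrix.b.sum(axis=1), index=data.index, name="n_deprivations")

    cols = {}
    if "white" in spec.terms or "black" in spec.terms or "hispanic" in spec.terms:
        race = data["race_ethnicity"].astype("string").str.lower()
        for term, level in RACE_DUMMY_LEVELS.items():
            if term in spec.terms:
                cols[term] = (race == level).astype(float).where(~race.isna())
    if "log_income" in spec.terms:
        cat = pd.to_numeric(data["income_category"], errors="coerce")
        cols["log_income"] = cat.map(
            lambda c: math.log(impute_income(int(c), spec.income_bounds))
            if pd.notna(c)
            else np.nan
        )
    if "hh_size" in spec.terms:
        cols["hh_size"] = pd.to_numeric(data["household_size"], errors="coerce")
    if "age" in spec.terms:
        cols["age"] = pd.to_numeric(data["age"], errors="coerce")
    if "educ" in spec.terms:
        cols["educ"] = pd.to_numeric(data["education"], errors="coerce")
    if "female" in spec.terms:
        g = data["gender"].astype("string").str.lower()
        cols["female"] = (g == "female").astype(float).where(~g.isna())
    if "married" in spec.terms:
        mar = data["marital"].astype("string").str.lower()
        cols["married"] = (mar == "married").astype(float).where(~mar.isna())
    if "metro" in spec.terms:
        cols["metro"] = pd.to_numeric(data["metro"], errors="coerce")
    if "stay_home" in spec.terms:
        cols["stay_home"] = pd.to_numeric(data["stay_home"], errors="coerce")

    X = pd.DataFrame(cols, index=data.index)[list(spec.terms)]
    complete = ~X.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing covariates", n_dropped)
    X = X.loc[complete].astype(float)
    y = count.loc[complete]
    if len(X) == 0:
        raise ValueError("no usable rows after dropping missing covariates")

    X = sm.add_constant(X, prepend=True, has_constant="add")
    collinear = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    rank = np.linalg.matrix_rank(X.to_numpy())
    info = {
        "n_dropped": n_dropped,
        "n_obs": int(len(X)),
        "collinear": collinear,
        "full_rank": bool(rank == X.shape[1]),
        "weights": data.loc[complete, dataset.weight_column].to_numpy(dtype=float),
    }
    if collinear:
        logger.warning("build_design: constant column(s) collinear with intercept: %s", collinear)
    return X, y, info


def fit_count_model(
    design: pd.DataFrame,
    outcome: pd.Series,
    spec: RegressionSpec,
    sample_weights: Optional[np.ndarray] = None,
) -> RegressionResult:
    """Fit OLS or Poisson with sandwich standard errors.

    OLS uses HC1 robust SEs; Poisson is fit by maximum likelihood with the
    standard robust sandwich covariance (HC0).  With
    ``spec.use_sample_weights`` the fits become survey-weighted
    pseudo-likelihood estimates.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design terms")
    names = list(design.columns)
    cov_ols = "HC1" if spec.robust_se else "nonrobust"
    cov_pois = "HC0" if spec.robust_se else "nonrobust"

    if spec.family == "ols":
        if spec.use_sample_weights and sample_weights is not None:
            model = sm.WLS(y, X, weights=sample_weights)
        else:
            model = sm.OLS(y, X)
        res = model.fit(cov_type=cov_ols)
        stats = {"r_squared": float(res.rsquared), "n_obs": int(res.nobs)}
        converged = True
    else:
        if y.max() == 0:
            raise ValueError("outcome is identically zero: Poisson fit is degenerate")
        if spec.use_sample_weights and sample_weights is not None:
            model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=sample_weights)
            res = model.fit(cov_type=cov_pois)
            llnull = sm.GLM(
                y, np.ones((len(y), 1)), family=sm.families.Poisson(),
                var_weights=sample_weights,
            ).fit().llf
            pseudo = 1 - res.llf / llnull
            converged = bool(res.converged)
        else:
            model = sm.Poisson(y, X)
            res = model.fit(disp=0, maxiter=200, cov_type=cov_pois)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError(
                    f"Poisson fit did not converge: {res.mle_retvals}"
                )
            pseudo = float(res.prsquared)
            converged = True
        stats = {"pseudo_r_squared": float(pseudo), "n_obs": int(res.nobs)}

    return RegressionResult(
        family=spec.family,
        coefficients=dict(zip(names, np.asarray(res.params, dtype=float))),
        robust_ses=dict(zip(names, np.asarray(res.bse, dtype=float))),
        fit_stats=stats,
        converged=converged,
    )


def percent_change(beta: float) -> float:
    """Percent change in the expected count implied by a Poisson coefficient."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    return (math.exp(beta) - 1.0) * 100.0
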