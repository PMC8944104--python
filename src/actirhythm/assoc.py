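"""Survey-weighted association analyses for component scores.

Three analyses: multiple linear regression of a component's scores on all
sociodemographic covariates simultaneously; quintile-based weighted logistic
regression of dichotomized self-rated health adjusted for the same
covariates; and weekday-weekend Pearson correlations between score tables.

Weights are treated as analytic (precision-type) weights: point estimates
come from weighted least squares / weighted maximum likelihood, and standard
errors from the HC0 robust sandwich, so rescaling all weights by a positive
constant changes nothing.  No design strata or PSUs are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import IntegrityError, NumericalError

#: covariates in fixed design order, with their reference levels (youngest
#: age group; larger-sample gender and race/ethnicity; highest-SES education,
#: income and work groups)
REFERENCE_LEVELS: dict[str, str] = {
    "age_group": "25-29",
    "gender": "male",
    "race_ethnicity": "NH White",
    "education": "college grad+",
    "income": ">=$75k",
    "work_status": "40+ h",
}

_DESIGN_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("25-29", "30-39", "40-49", "50-59", "60-69", "70+"),
    "gender": ("male", "female"),
    "race_ethnicity": ("NH White", "NH Black", "Mexican American",
                       "Other Hispanic", "NH Asian", "other"),
    "education": ("<HS", "HS grad", "some college", "college grad+"),
    "income": ("<$20k", "$20k-$44.9k", "$45k-$74.9k", ">=$75k"),
    "work_status": ("did not work", "<40 h", "40+ h"),
}

Z95 = 1.96  # normal 95% quantile; no degrees-of-freedom correction applied


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy columns for every non-reference covariate level.

    Column order is deterministic: covariates in the fixed order above, and
    within each, the enum's level order with the reference level dropped.
    Unseen or missing levels are errors — the exclusion cascade guarantees
    complete covariates.
    """
    idx = (
        covariates["participant_id"]
        if "participant_id" in covariates.columns
        else covariates.index.to_series()
    )
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(covariates))}
    for cov, levels in _DESIGN_LEVELS.items():
        vals = covariates[cov]
        bad = ~vals.isin(levels)
        if bad.any():
            raise IntegrityError(
                f"unexpected {cov} level(s) {sorted(set(vals[bad].astype(str)))} "
                "in the design; apply exclusions first"
            )
        for level in levels:
            if level == REFERENCE_LEVELS[cov]:
                continue
            cols[f"{cov}[{level}]"] = (vals == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=pd.Index(idx, name="participant_id"))


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved via the small-diagonal part of a pivoted QR
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise NumericalError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class RegressionResult:
    """Per-level effect estimates from one weighted linear model."""

    component: int
    stratum: str
    n: int
    table: pd.DataFrame            # term, beta, se, ci_low, ci_high, reference
    params: pd.Series
    fit: object


def weighted_linear(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    weights: np.ndarray | pd.Series,
    component: int = 0,
    stratum: str = "overall",
) -> RegressionResult:
    """WLS of a score on the full covariate design, HC0 robust intervals.

    beta_hat = (X'WX)^-1 X'Wy; reference levels appear in the output table
    with beta = 0 by construction.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise IntegrityError("weights must be positive")
    _check_full_rank(X)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    rows = []
    for cov, levels in _DESIGN_LEVELS.items():
        for level in levels:
            term = f"{cov}[{level}]"
            if level == REFERENCE_LEVELS[cov]:
                rows.append({"term": f"{cov}[{level}]", "beta": 0.0, "se": 0.0,
                             "ci_low": 0.0, "ci_high": 0.0, "reference": True})
            elif term in X.columns:
                b, se = fit.params[term], fit.bse[term]
                rows.append({"term": term, "beta": b, "se": se,
                             "ci_low": b - Z95 * se, "ci_high": b + Z95 * se,
                             "reference": False})
    return RegressionResult(component, stratum, len(y), pd.DataFrame(rows),
                            fit.params, fit)


def assign_quintiles(scores: pd.Series) -> pd.Series:
    """Rank-based quintile labels Q1 (lowest) .. Q5 (highest).

    Cutpoints are unweighted sample quintiles; ties are broken by stable
    participant-id order so the split is reproducible.  Group sizes differ by
    at most one, larger groups first.
    """
    if len(scores) < 5:
        raise ValueError("need at least 5 scores to form quintiles")
    s = scores.sort_index(kind="stable")
    order = np.argsort(s.to_numpy(), kind="stable")
    labels = np.empty(len(s), dtype=object)
    for q, chunk in enumerate(np.array_split(order, 5), start=1):
        labels[chunk] = f"Q{q}"
    return pd.Series(labels, index=s.index, name="quintile").reindex(scores.index)


@dataclass
class ORResult:
    """Quintile odds ratios for poor/fair health from one weighted logistic fit."""

    component: int
    stratum: str
    n: int
    table: pd.DataFrame            # quintile, n_cases, or, ci_low, ci_high
    p_trend: float
    fit: object


def weighted_logistic(
    y: np.ndarray | pd.Series,
    quintiles: pd.Series,
    X: pd.DataFrame | None,
    weights: np.ndarray | pd.Series,
    component: int = 0,
    stratum: str = "overall",
    max_iter: int = 200,
) -> ORResult:
    """Weighted logistic regression of a binary outcome on score quintiles.

    Q5 (highest scores) is the reference; Q1..Q4 enter as indicators, with
    the covariate design (if given) added.  Fitting is weighted maximum
    likelihood by IRLS; CIs use HC0 robust standard errors.  The trend test
    refits with the quintile index 1..5 as a single ordinal term and reports
    its Wald p-value.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise IntegrityError("weights must be positive")
    if not np.isin(y, [0.0, 1.0]).all():
        raise IntegrityError("outcome must be binary (drop missing-health rows first)")
    q = quintiles.to_numpy()
    # separation diagnostic: a quintile whose outcome is constant cannot
    # identify its odds ratio
    for lab in ("Q1", "Q2", "Q3", "Q4", "Q5"):
        sub = y[q == lab]
        if sub.size == 0 or sub.min() == sub.max():
            raise NumericalError(
                f"quintile {lab} has a constant outcome (empty cell); "
                "the odds ratio is not identifiable"
            )
    dummies = pd.DataFrame(
        {f"quintile[{lab}]": (q == lab).astype(float) for lab in ("Q1", "Q2", "Q3", "Q4")},
        index=quintiles.index,
    )
    if X is not None:
        if X.index.equals(dummies.index):
            design = pd.concat([dummies, X], axis=1)
        else:  # same length, positional alignment
            design = pd.concat(
                [dummies, X.reset_index(drop=True).set_index(dummies.index)], axis=1
            )
    else:
        design = dummies.copy()
        design["intercept"] = 1.0
    _check_full_rank(design)
    fit = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w).fit(
        cov_type="HC0", maxiter=max_iter
    )
    if not fit.converged:
        raise NumericalError(
            f"weighted logistic IRLS did not converge in {max_iter} iterations; "
            f"deviance trace tail: {fit.fit_history['deviance'][-5:]}"
        )
    rows = []
    for lab in ("Q1", "Q2", "Q3", "Q4"):
        b = fit.params[f"quintile[{lab}]"]
        se = fit.bse[f"quintile[{lab}]"]
        rows.append({"quintile": lab, "n_cases": int(y[q == lab].sum()),
                     "odds_ratio": float(np.exp(b)),
                     "ci_low": float(np.exp(b - Z95 * se)),
                     "ci_high": float(np.exp(b + Z95 * se)),
                     "reference": False})
    rows.append({"quintile": "Q5", "n_cases": int(y[q == "Q5"].sum()),
                 "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                 "reference": True})
    # trend: ordinal quintile index replaces the four indicators
    trend_design = design.drop(columns=[f"quintile[{lab}]" for lab in ("Q1", "Q2", "Q3", "Q4")])
    trend_design.insert(0, "quintile_index",
                        pd.Series(q, index=quintiles.index).str[1].astype(float))
    tfit = sm.GLM(y, trend_design, family=sm.families.Binomial(), var_weights=w).fit(
        cov_type="HC0", maxiter=max_iter
    )
    if not tfit.converged:
        raise NumericalError("trend-model IRLS did not converge")
    p_trend = float(tfit.pvalues["quintile_index"])
    return ORResult(component, stratum, len(y), pd.DataFrame(rows), p_trend, fit)


def score_correlations(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> pd.Series:
    """Unweighted Pearson r per matched component across two score tables.

    Both tables are restricted to their common participant ids; raw score
    columns (``score_m``) are matched by component index.
    """
    common = scores_a.index.intersection(scores_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common participants for a correlation")
    cols = [c for c in scores_a.columns if c.startswith("score_")]
    out = {}
    for c in cols:
        if c in scores_b.columns:
            out[c] = float(
                np.corrcoef(scores_a.loc[common, c], scores_b.loc[common, c])[0, 1]
            )
    return pd.Series(out, name="pearson_r")
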