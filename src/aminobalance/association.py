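"""Determinant and fatigue-association models.

Two model families are exposed:

* linear regression with standardized betas for the determinants of total
  daily amino-acid losses (univariable screen at p < 0.05, then one joint
  multivariable fit);
* logistic regression for severe fatigue (subjective fatigue score ≥ 35),
  with predictors entered either per SD increment (approximately normal
  analytes) or per log2 doubling (right-skewed analytes), and two a-priori
  covariate sets: model 1 = {age, sex, BMI, dialysis vintage}; model 2 adds
  {hemoglobin, C-reactive protein, cardiovascular disease, diabetes}.

Fits are maximum likelihood via iteratively reweighted least squares
(statsmodels GLM, tolerance 1e-8, max 100 iterations); non-convergence or
quasi-separation is flagged rather than reported as an estimate.  Robustness
is probed with five exclusion rules: predictor outliers (|z| > 2),
twice-weekly dialysis, vintage > 60 months, BMI < 18.5 kg/m², and
hemoglobin below the within-sex 5th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort_stats import assess_distribution

__all__ = [
    "AssociationResult",
    "severe_fatigue",
    "transform_policy",
    "PRESET_LOG2",
    "fit_linear_stdbeta",
    "select_multivariable",
    "MODEL_COVARIATES",
    "fit_logistic",
    "sensitivity_suite",
    "probability_curve",
]

SEVERE_FATIGUE_THRESHOLD = 35.0

# analytes entered per log2 doubling rather than per SD, by compartment
PRESET_LOG2: dict[str, frozenset[str]] = {
    "plasma": frozenset({"taurine"}),
    "losses": frozenset({"taurine", "tryptophan"}),
}

MODEL_COVARIATES: dict[int, list[str]] = {
    0: [],
    1: ["age", "male", "bmi", "vintage_months"],
    2: ["age", "male", "bmi", "vintage_months", "hemoglobin", "crp", "cvd", "diabetes"],
}


@dataclass
class AssociationResult:
    """One predictor's estimate: std-beta or OR with Wald 95% CI and p-value."""

    predictor: str
    estimate: float | None
    ci95: tuple[float, float] | None
    p: float | None
    increment: str  # "per-SD" | "per-log2" | "raw"
    model: str
    n: int
    vif_max: float | None = None
    converged: bool = True
    note: str | None = None
    n_excluded: int = 0
    _fit: object = field(default=None, repr=False, compare=False)


def severe_fatigue(score: float) -> bool:
    """Severe fatigue: subjective fatigue score ≥ 35."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        raise ValueError("fatigue score missing; subject must be excluded upstream")
    return float(score) >= SEVERE_FATIGUE_THRESHOLD


def transform_policy(analyte: str, values=None, compartment: str = "plasma") -> str:
    """Decide the increment convention for a predictor: "identity" or "log2".

    Right-skewed analytes are log2-transformed (odds ratios per doubling);
    the preset pins the conventional choices (plasma taurine; taurine and
    tryptophan losses).  Without a preset entry the sample distribution
    decides.
    """
    if analyte in PRESET_LOG2.get(compartment, frozenset()):
        return "log2"
    if values is not None and len(values) >= 3:
        return "log2" if assess_distribution(values) != "normal" else "identity"
    return "identity"


def _log2_checked(x: np.ndarray, name: str) -> np.ndarray:
    if np.any(x <= 0):
        raise ValueError(f"non-positive value in {name}: log2 transform undefined")
    return np.log2(x)


def _vif_max(X: np.ndarray) -> float | None:
    """Largest variance inflation factor among predictors (None if single column)."""
    if X.shape[1] < 2:
        return None
    vifs = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
        vifs.append(1.0 / max(1.0 - r2, 1e-12))
    return float(max(vifs))


# ---------------------------------------------------------------------------
# linear determinants

def fit_linear_stdbeta(y, X: pd.DataFrame, model: str = "univariable") -> list[AssociationResult]:
    """OLS on z-scored outcome and predictors; betas are standardized.

    In the univariable case the standardized beta equals the Pearson
    correlation between predictor and outcome.
    """
    y = np.asarray(y, dtype=float)
    X = X.astype(float)
    keep = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
    y, X = y[keep], X.loc[keep]
    n = len(y)
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1]} predictors")
    sy = np.std(y, ddof=1)
    if sy == 0:
        raise ValueError("outcome has zero variance")
    Z = np.empty((n, X.shape[1]))
    for j, col in enumerate(X.columns):
        s = np.std(X[col].to_numpy(), ddof=1)
        if s == 0:
            raise ValueError(f"zero-variance predictor {col!r}")
        Z[:, j] = (X[col].to_numpy() - X[col].mean()) / s
    yz = (y - y.mean()) / sy
    fit = sm.OLS(yz, sm.add_constant(Z)).fit()
    vif = _vif_max(Z)
    out = []
    for j, col in enumerate(X.columns):
        lo, hi = fit.conf_int()[j + 1]
        out.append(
            AssociationResult(
                predictor=col,
                estimate=float(fit.params[j + 1]),
                ci95=(float(lo), float(hi)),
                p=float(fit.pvalues[j + 1]),
                increment="per-SD",
                model=model,
                n=n,
                vif_max=vif,
                _fit=fit,
            )
        )
    return out


def univariable_screen(y, X: pd.DataFrame) -> list[AssociationResult]:
    """One univariable standardized-beta fit per candidate determinant."""
    return [
        fit_linear_stdbeta(y, X[[col]], model="univariable")[0] for col in X.columns
    ]


def select_multivariable(
    univariable: list[AssociationResult], alpha: float = 0.05
) -> list[str]:
    """Predictors carried into the joint model: univariable p < alpha."""
    return [r.predictor for r in univariable if r.p is not None and r.p < alpha]


def determinant_analysis(y, X: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Univariable screen, p < alpha selection, then one joint standardized fit.

    Returns {"univariable": [...], "selected": [names], "multivariable": [...]};
    an empty selection yields a documented no-multivariable-model result.
    """
    uni = univariable_screen(y, X)
    selected = select_multivariable(uni, alpha)
    multi = (
        fit_linear_stdbeta(y, X[selected], model="multivariable") if selected else []
    )
    return {"univariable": uni, "selected": selected, "multivariable": multi}


# ---------------------------------------------------------------------------
# logistic fatigue models

def _design(
    df: pd.DataFrame,
    predictor: str,
    model: int,
    transform: str,
) -> tuple[np.ndarray, np.ndarray, int, str]:
    cols = [predictor] + MODEL_COVARIATES[model]
    sub = df[cols + ["severe_fatigue"]].dropna()
    y = sub["severe_fatigue"].astype(float).to_numpy()
    x = sub[predictor].astype(float).to_numpy()
    if transform == "log2":
        x = _log2_checked(x, predictor)
        increment = "per-log2"
    else:
        s = np.std(x, ddof=1)  # sample SD of the analysis dataset after exclusions
        if s == 0:
            raise ValueError(f"zero-variance predictor {predictor!r}")
        x = (x - x.mean()) / s
        increment = "per-SD"
    Xmat = np.column_stack(
        [x] + [sub[c].astype(float).to_numpy() for c in MODEL_COVARIATES[model]]
    )
    return y, Xmat, len(sub), increment


def fit_logistic(
    df: pd.DataFrame,
    predictor: str,
    model: int = 1,
    transform: str | None = None,
    compartment: str = "plasma",
) -> AssociationResult:
    """Adjusted odds ratio of severe fatigue for one predictor.

    ``df`` holds one row per subject with ``severe_fatigue`` (0/1), the
    predictor column, and the model covariates.  The OR is per 1-SD increment
    (identity transform) or per doubling (log2 transform); the transform
    defaults to :func:`transform_policy`.
    """
    if transform is None:
        transform = transform_policy(predictor, df[predictor].dropna(), compartment)
    y, Xmat, n, increment = _design(df, predictor, model, transform)
    model_label = f"model-{model}" if model else "unadjusted"
    if y.min() == y.max():
        return AssociationResult(
            predictor, None, None, None, increment, model_label, n,
            converged=False, note="outcome is constant in the analysis set",
        )
    X = sm.add_constant(Xmat)
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-8, maxiter=100)
    except Exception as err:  # e.g. perfect separation detected by statsmodels
        return AssociationResult(
            predictor, None, None, None, increment, model_label, n,
            converged=False, note=f"fit failed: {err}",
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        return AssociationResult(
            predictor, None, None, None, increment, model_label, n,
            converged=False, note="non-convergence or separation (unstable Wald SE)",
        )
    z = 1.959963984540054
    return AssociationResult(
        predictor=predictor,
        estimate=float(np.exp(beta)),
        ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        p=float(fit.pvalues[1]),
        increment=increment,
        model=model_label,
        n=n,
        vif_max=_vif_max(Xmat),
        _fit=fit,
    )


# ---------------------------------------------------------------------------
# sensitivity analyses

def _sensitivity_masks(df: pd.DataFrame, predictor: str) -> dict[str, pd.Series]:
    x = df[predictor].astype(float)
    z = (x - x.mean()) / x.std(ddof=1)
    masks = {"outliers_2sd": z.abs() <= 2}
    masks["exclude_twice_weekly"] = (
        df["thrice_weekly"].astype(bool)
        if "thrice_weekly" in df
        else pd.Series(True, index=df.index)
    )
    masks["vintage_le_60mo"] = (
        df["vintage_months"] <= 60 if "vintage_months" in df else pd.Series(True, index=df.index)
    )
    masks["bmi_ge_18.5"] = df["bmi"] >= 18.5 if "bmi" in df else pd.Series(True, index=df.index)
    if "hemoglobin" in df and "male" in df:
        thr = df.groupby("male")["hemoglobin"].transform(lambda s: s.quantile(0.05))
        masks["hemoglobin_ge_p5"] = df["hemoglobin"] >= thr
    else:
        masks["hemoglobin_ge_p5"] = pd.Series(True, index=df.index)
    return masks


def sensitivity_suite(
    df: pd.DataFrame,
    predictor: str,
    model: int = 2,
    transform: str | None = None,
    compartment: str = "plasma",
) -> dict[str, AssociationResult]:
    """Refit one association under the five exclusion rules.

    Rules: (1) drop predictor outliers (|z| > 2 within the analysis set);
    (2) drop twice-weekly dialysis; (3) drop vintage > 60 months; (4) drop
    BMI < 18.5; (5) drop hemoglobin below the within-sex 5th percentile.
    Per-SD scaling is recomputed within each subset.
    """
    out: dict[str, AssociationResult] = {}
    for rule, mask in _sensitivity_masks(df, predictor).items():
        sub = df[mask]
        n_excl = int((~mask).sum())
        if len(sub) == 0 or sub["severe_fatigue"].nunique() < 2:
            out[rule] = AssociationResult(
                predictor, None, None, None, "n/a", f"model-{model}", 0,
                converged=False, note="rule left no analyzable data", n_excluded=n_excl,
            )
            continue
        res = fit_logistic(sub, predictor, model, transform, compartment)
        res.n_excluded = n_excl
        out[rule] = res
    return out


def probability_curve(result: AssociationResult, grid) -> pd.DataFrame:
    """Predicted probability of severe fatigue along a predictor grid.

    The grid is on the fitted predictor scale (z or log2 units); all
    covariates are held at their analysis-set means.  Inverse-logit of the
    linear predictor.
    """
    if result._fit is None:
        raise ValueError("result carries no fitted model")
    fit = result._fit
    grid = np.asarray(grid, dtype=float)
    exog = np.asarray(fit.model.exog)
    means = exog.mean(axis=0)  # col 0 is the constant
    eta = (
        fit.params[0]
        + fit.params[1] * grid
        + (means[2:] @ fit.params[2:] if exog.shape[1] > 2 else 0.0)
    )
    return pd.DataFrame({"predictor": grid, "probability": expit(eta)})
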