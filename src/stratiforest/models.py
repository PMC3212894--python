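"""Predictive stand models: Lasso screening, post-selection refits, prediction.

Basal area and stem density are modelled log-linearly (OLS on the
log-transformed response after Lasso variable screening); conifer share is a
logistic model on the proportion.  Back-transformation of log models offers
an optional multiplicative bias correction exp(sigma^2 / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "lasso_screen",
    "fit_model",
    "predict_cells",
    "sample_efficiency",
    "pearson_normality_test",
]


@dataclass
class ModelSpec:
    response: str
    transform: str  # "ln", "logit" or "identity"
    predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    lam: float = 0.0
    cv_folds: int = 10
    mse: float = float("nan")
    r_squared: float = float("nan")
    r_squared_natural: float = float("nan")
    residual_sd: float = float("nan")
    ln_offset: float = 0.0
    bias_correction: bool = False
    normality_stat: float = float("nan")
    normality_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.transform not in ("ln", "logit", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not np.isnan(self.r_squared) and not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("R^2 out of [0, 1]")
        if self.lam < 0:
            raise ValueError("penalty must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def lasso_screen(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    rule: str = "1se",
) -> tuple[list[str], float]:
    """Cross-validated Lasso variable screen on standardized predictors.

    The penalty is chosen over a log-spaced path by K-fold cross-validation.
    ``rule="1se"`` (default) takes the largest penalty whose mean CV error is
    within one standard error of the minimum — the standard screening choice,
    which keeps the selection sparse and recovers a true support reliably;
    ``rule="min"`` takes the pure CV minimum.  Returns the names with
    nonzero coefficients at the chosen penalty and the penalty itself.
    """
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds or folds < 2:
        raise ValueError("need n >= folds >= 2")
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ValueError("missing values in screen inputs")
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xm - mu) / sd

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(alphas=n_lambdas, cv=cv, max_iter=50_000).fit(Z, y)
    if rule == "min":
        lam = float(model.alpha_)
    else:
        mean_err = model.mse_path_.mean(axis=1)
        se_err = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        i_min = int(np.argmin(mean_err))
        threshold = mean_err[i_min] + se_err[i_min]
        # alphas_ descend, so the first qualifying index is the largest penalty
        lam = float(model.alphas_[int(np.where(mean_err <= threshold)[0][0])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = Lasso(alpha=lam, max_iter=50_000).fit(Z, y)
    selected = [names[j] for j in np.flatnonzero(np.abs(final.coef_) > 1e-12)]
    if not selected:
        warnings.warn("Lasso selected no predictors; intercept-only model")
    return selected, lam


def _prepare_ln(y_raw: np.ndarray, ln_offset: float | None) -> tuple[np.ndarray, float]:
    if ln_offset is None:
        ln_offset = 0.0 if np.min(y_raw) > 0 else 1.0
    shifted = y_raw + ln_offset
    if np.any(shifted <= 0):
        raise ValueError("response not positive after offset; increase ln_offset")
    return np.log(shifted), ln_offset


def fit_model(
    X_selected: pd.DataFrame,
    y_raw: np.ndarray,
    transform: str = "ln",
    response: str = "y",
    ln_offset: float | None = None,
    weights: np.ndarray | None = None,
    lam: float = 0.0,
    bias_correction: bool = False,
) -> ModelSpec:
    """Post-selection refit of the screened model by OLS / quasi-binomial ML.

    ``ln``: OLS on ln(y + offset); the offset defaults to 0 when all
    responses are positive, else 1.  ``logit``: GLM with binomial family on
    the proportion (0..1 or 0..100 input), optionally weighted by tally
    counts.  Fit statistics are reported on the transformed scale.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    names = list(X_selected.columns)
    Xm = X_selected.to_numpy(dtype=float)
    n = len(y_raw)
    if Xm.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if names:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xm]))
        if rank < len(names) + 1:
            corr = np.corrcoef(Xm, rowvar=False)
            pairs = [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
                if abs(np.atleast_2d(corr)[i, j]) > 0.9999
            ]
            raise ValueError(f"singular design matrix; collinear columns: {pairs}")

    design = sm.add_constant(Xm, has_constant="add") if names else np.ones((n, 1))

    if transform == "logit":
        prop = y_raw / 100.0 if np.nanmax(y_raw) > 1.0 else y_raw.copy()
        eps = 1e-6
        prop = np.clip(prop, eps, 1 - eps)
        glm = sm.GLM(
            prop,
            design,
            family=sm.families.Binomial(),
            var_weights=weights if weights is not None else np.ones(n),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit()
        eta = design @ res.params
        z = np.log(prop / (1 - prop))
        resid = z - eta
        mse = float(np.mean(resid**2))
        ss_tot = float(np.sum((z - z.mean()) ** 2))
        r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
        nstat, npval = pearson_normality_test(resid)
        return ModelSpec(
            response=response,
            transform="logit",
            predictors=names,
            intercept=float(res.params[0]),
            coefficients={nm: float(b) for nm, b in zip(names, res.params[1:])},
            lam=lam,
            mse=mse,
            r_squared=max(0.0, min(1.0, r2)),
            residual_sd=float(np.std(resid, ddof=len(names) + 1)) if n > len(names) + 1 else 0.0,
            normality_stat=nstat,
            normality_p=npval,
        )

    if transform == "ln":
        y_t, off = _prepare_ln(y_raw, ln_offset)
    else:
        y_t, off = y_raw.copy(), 0.0

    ols = sm.OLS(y_t, design).fit()
    resid = ols.resid
    dof = max(n - len(names) - 1, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((y_t - y_t.mean()) ** 2))
    r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    nstat, npval = pearson_normality_test(resid)
    spec = ModelSpec(
        response=response,
        transform=transform,
        predictors=names,
        intercept=float(ols.params[0]),
        coefficients={nm: float(b) for nm, b in zip(names, ols.params[1:])},
        lam=lam,
        mse=float(np.mean(resid**2)),
        r_squared=max(0.0, min(1.0, r2)),
        residual_sd=sigma,
        ln_offset=off,
        bias_correction=bias_correction,
        normality_stat=nstat,
        normality_p=npval,
    )
    if transform == "ln":
        pred_nat = np.exp(ols.fittedvalues) - off
        y_nat = y_raw
        sst = float(np.sum((y_nat - y_nat.mean()) ** 2))
        spec.r_squared_natural = (
            max(0.0, min(1.0, 1 - float(np.sum((y_nat - pred_nat) ** 2)) / sst)) if sst > 0 else 1.0
        )
    return spec


def predict_cells(model: ModelSpec, cells: pd.DataFrame) -> np.ndarray:
    """Per-cell predictions in natural units (m2/ha, stems/ha or percent)."""
    for p in model.predictors:
        if p not in cells.columns:
            raise KeyError(f"missing predictor column: {p!r}")
    eta = np.full(len(cells), model.intercept, dtype=float)
    for p in model.predictors:
        eta += model.coefficients[p] * cells[p].to_numpy(dtype=float)
    if model.transform == "ln":
        out = np.exp(eta)
        if model.bias_correction:
            out *= np.exp(model.residual_sd**2 / 2.0)
        return out - model.ln_offset
    if model.transform == "logit":
        return 100.0 / (1.0 + np.exp(-eta))
    return eta


def sample_efficiency(r_squared: float) -> float:
    """Relative plots needed with a correlated auxiliary: 2(1 - sqrt(R^2))."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("r_squared must lie in [0, 1]")
    return 2.0 * (1.0 - np.sqrt(r_squared))


def pearson_normality_test(residuals: np.ndarray, n_bins: int | None = None) -> tuple[float, float]:
    """Pearson chi-square goodness-of-fit of residuals against a normal.

    Residuals are standardized and binned at equiprobable normal quantiles;
    the statistic is chi-square with ``n_bins - 3`` degrees of freedom
    (mean and sd estimated).
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 8:
        return float("nan"), float("nan")
    if n_bins is None:
        n_bins = max(4, int(np.ceil(2 * n**0.4)))
    sd = r.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan")
    z = (r - r.mean()) / sd
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1))
    observed, _ = np.histogram(z, bins=edges)
    expected = n / n_bins
    chi2 = float(np.sum((observed - expected) ** 2) / expected)
    dof = max(n_bins - 3, 1)
    return chi2, float(stats.chi2.sf(chi2, dof))
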