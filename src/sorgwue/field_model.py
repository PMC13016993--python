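"""Plot-level linear mixed model with a random accession intercept.

The field design confounds genetics with space and sampling date, so
plot-level trait values are adjusted with

    y = intercept + row + column + beta_T AveT + beta_H AveH + u_a + e,
    u_a ~ N(0, sigma2_accession),   e ~ N(0, sigma2_residual),

fit by restricted maximum likelihood.  Because the only random term is
the accession intercept, the covariance is block diagonal per accession
(H_i = I + gamma J with gamma = sigma2_a / sigma2_e), so REML reduces to
a one-dimensional profile over log gamma solved by bounded scalar
optimization; fixed effects come from GLS at the optimum and accession
BLUPs are shrunken group residual sums:

    u_i = gamma * S_i / (1 + gamma * n_i)

with S_i the residual sum of group i.  Row and column enter as
categorical fixed effects by default (absorbing arbitrary spatial
gradients); a numeric option is available.  Aliased design columns are
dropped with a logged warning rather than raising, since field layouts
routinely alias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import FitError, InputError
from .io_formats import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class MixedModelResult:
    """REML fit of the random-intercept field model for one trait."""

    trait: str
    fixed_names: list[str]
    fixed_coefficients: np.ndarray
    sigma2_accession: float
    sigma2_residual: float
    blups: pd.Series  # accession -> shrunken random intercept
    loglik: float
    converged: bool
    boundary: bool  # sigma2_accession estimated at 0
    dropped_columns: list[str]
    method: str = "reml"
    n_obs: int = 0
    # internal pieces needed for prediction
    _design_means: np.ndarray | None = None
    _group_design_means: pd.DataFrame | None = None  # accession x fixed term

    @property
    def variance_ratio(self) -> float:
        if self.sigma2_accession == 0:
            return math.inf
        return self.sigma2_residual / self.sigma2_accession


def build_design(
    data: pd.DataFrame,
    *,
    categorical_spatial: bool = True,
    include_weather: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept, row, column, AveT, AveH.

    Row/column are dummy-coded (first level dropped) when
    ``categorical_spatial``; otherwise they enter as numeric gradients.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    for term in ("row", "column"):
        if categorical_spatial:
            d = pd.get_dummies(data[term].astype("category"), prefix=term,
                               drop_first=True, dtype=float)
            cols.extend(d[c].to_numpy() for c in d.columns)
            names.extend(d.columns)
        else:
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
    if include_weather:
        for term in ("AveT", "AveH"):
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns via pivoted QR (keeps the first
    independent set, intercept always retained)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if 0 not in keep:  # never drop the intercept
        keep = sorted(set(keep) | {0})[: rank]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _profile_criterion(
    log_gamma: float,
    X: np.ndarray, y: np.ndarray,
    group_X: np.ndarray, group_y: np.ndarray, group_n: np.ndarray,
    group_idx: np.ndarray,
    restricted: bool,
) -> tuple[float, np.ndarray, float]:
    """-2 x (restricted) profile log-likelihood up to a constant, plus the
    GLS coefficients and weighted RSS at this variance ratio.

    Works on explicitly whitened data: for a random-intercept model
    H_i^(-1/2) = I - (1 - (1 + gamma n_i)^(-1/2)) J / n_i per group, so
    GLS reduces to OLS on H^(-1/2) X, H^(-1/2) y.  Solving by SVD keeps
    the estimate stable even as gamma -> infinity, where between-group
    columns shrink toward zero.
    """
    gamma = math.exp(log_gamma)
    shrink = 1.0 - 1.0 / np.sqrt(1.0 + gamma * group_n)  # per group
    a = (shrink / group_n)[group_idx]
    Xw = X - a[:, None] * group_X[group_idx]
    yw = y - a * group_y[group_idx]
    n, p = X.shape
    beta, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(((yw - Xw @ beta) ** 2).sum())
    rss = max(rss, 1e-300)
    logdet_H = float(np.log1p(gamma * group_n).sum())
    if restricted:
        if rank < p:
            return np.inf, beta, rss
        logdet_A = 2.0 * float(np.log(sv[:p]).sum())  # A = Xw'Xw
        crit = (n - p) * math.log(rss) + logdet_H + logdet_A
    else:
        crit = n * math.log(rss) + logdet_H
    return crit, beta, rss


def fit_random_intercept_reml(
    pheno: PhenotypeTable | pd.DataFrame,
    trait: str,
    *,
    categorical_spatial: bool = True,
    include_weather: bool = True,
    method: str = "reml",
    log_gamma_bounds: tuple[float, float] = (-25.0, 25.0),
) -> MixedModelResult:
    """Fit the random-accession-intercept model for one trait by REML.

    The variance ratio gamma = sigma2_accession / sigma2_residual is
    profiled out and optimized on the log scale to tolerance 1e-8; fixed
    effects are GLS at the optimum.  Non-convergence or a boundary
    estimate (sigma2_accession -> 0) is flagged on the result, not
    raised.
    """
    data = pheno.data if isinstance(pheno, PhenotypeTable) else pheno
    data = data.dropna(subset=[trait]).reset_index(drop=True)
    counts = data["accession"].value_counts()
    if (counts >= 2).sum() < 2:
        raise InputError("need >= 2 plots for >= 2 accessions to separate variances")

    X, names = build_design(
        data, categorical_spatial=categorical_spatial, include_weather=include_weather
    )
    X, names, dropped = _drop_aliased(X, names)
    y = data[trait].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise FitError(f"design with {p} columns leaves no residual df at n={n}")

    groups, group_idx = np.unique(data["accession"].to_numpy(), return_inverse=True)
    q = len(groups)
    group_n = np.bincount(group_idx, minlength=q).astype(float)
    group_X = np.zeros((q, p))
    for j in range(p):
        group_X[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=q)
    group_y = np.bincount(group_idx, weights=y, minlength=q)

    restricted = method == "reml"
    args = (X, y, group_X, group_y, group_n, group_idx, restricted)

    res = minimize_scalar(
        lambda lg: _profile_criterion(lg, *args)[0],
        bounds=log_gamma_bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    log_gamma = float(res.x)
    crit_lower = _profile_criterion(log_gamma_bounds[0], *args)[0]
    boundary = (log_gamma <= log_gamma_bounds[0] + 1e-3) or (
        crit_lower <= float(res.fun) + 1e-10
    )
    crit, beta, rss = _profile_criterion(log_gamma, *args)
    gamma = 0.0 if boundary else math.exp(log_gamma)
    if boundary:
        crit, beta, rss = _profile_criterion(log_gamma_bounds[0], *args)

    df_denom = (n - p) if restricted else n
    sigma2_e = rss / df_denom
    sigma2_a = gamma * sigma2_e
    if boundary:
        logger.warning("trait %s: sigma2_accession at boundary 0", trait)

    # BLUPs: shrunken group residual sums
    resid_sum = group_y - group_X @ beta
    blup = gamma * resid_sum / (1.0 + gamma * group_n)
    blups = pd.Series(blup, index=groups, name="blup")

    # full (restricted) log-likelihood including constants
    logdet_H = float(np.log1p(gamma * group_n).sum())
    ll = -0.5 * (df_denom * math.log(2 * math.pi * sigma2_e) + logdet_H
                 + rss / sigma2_e)
    if restricted:
        shrink = 1.0 - 1.0 / np.sqrt(1.0 + gamma * group_n)
        a = (shrink / group_n)[group_idx]
        Xw = X - a[:, None] * group_X[group_idx]
        sign, logdet_A = np.linalg.slogdet((Xw.T @ Xw) / sigma2_e)
        ll -= 0.5 * logdet_A

    return MixedModelResult(
        trait=trait, fixed_names=names, fixed_coefficients=beta,
        sigma2_accession=sigma2_a, sigma2_residual=sigma2_e,
        blups=blups, loglik=ll, converged=converged, boundary=boundary,
        dropped_columns=dropped, method=method, n_obs=n,
        _design_means=X.mean(axis=0),
        _group_design_means=pd.DataFrame(
            group_X / group_n[:, None], index=groups, columns=names
        ),
    )


def predict_accession_values(
    result: MixedModelResult,
    accessions: list[str] | None = None,
    reference_covariates: dict[str, float] | None = None,
    mode: str = "reference",
) -> pd.Series:
    """Adjusted accession-level predictions for downstream association.

    ``mode='reference'`` (default): prediction_i = fixed part evaluated
    at reference covariates + BLUP_i, with the reference being the
    design mean (row/column effects averaged out, AveT/AveH at their
    observed means, optionally overridden via ``reference_covariates``).
    ``mode='observed'``: the fixed part uses each accession's own mean
    design row instead, i.e. the fitted value at its observed plots;
    with batch-constant covariates this is the mode that reproduces
    accession values exactly in the noiseless limit.
    """
    if not result.converged:
        raise FitError(f"cannot predict from non-converged fit for {result.trait}")
    if accessions is None:
        accessions = list(result.blups.index)
    unknown = [a for a in accessions if a not in result.blups.index]
    if unknown:
        raise KeyError(f"accessions not in fit: {unknown[:5]}")
    logger.info(
        "predictions for %s: fixed effects at %s covariates + BLUP",
        result.trait, mode,
    )
    if mode == "observed":
        fixed_part = (
            result._group_design_means.loc[accessions].to_numpy()
            @ result.fixed_coefficients
        )
    elif mode == "reference":
        ref = np.array(result._design_means, dtype=float)
        if reference_covariates:
            for k, v in reference_covariates.items():
                if k not in result.fixed_names:
                    raise KeyError(f"unknown covariate {k!r}")
                ref[result.fixed_names.index(k)] = v
        fixed_part = float(ref @ result.fixed_coefficients)
    else:
        raise FitError(f"unknown prediction mode {mode!r}")
    return pd.Series(
        fixed_part + result.blups.loc[accessions].to_numpy(),
        index=accessions, name=result.trait,
    )


def compare_weather_models_aic(
    pheno: PhenotypeTable | pd.DataFrame,
    trait: str,
    *,
    categorical_spatial: bool = True,
) -> dict:
    """AIC comparison (ML fits) of the model with vs without AveT/AveH.

    REML likelihoods are not comparable across fixed-effect sets, so both
    candidates are refit by ML.  Returns AICs and the preferred variant.
    """
    out = {}
    for label, include in (("with_weather", True), ("without_weather", False)):
        fit = fit_random_intercept_reml(
            pheno, trait, categorical_spatial=categorical_spatial,
            include_weather=include, method="ml",
        )
        k = len(fit.fixed_names) + 2  # + two variance components
        out[label] = {"aic": 2 * k - 2 * fit.loglik, "loglik": fit.loglik, "k": k}
    out["preferred"] = min(
        ("with_weather", "without_weather"), key=lambda s: out[s]["aic"]
    )
    return out


def fit_all_traits(
    pheno: PhenotypeTable, **kwargs
) -> tuple[dict[str, MixedModelResult], pd.DataFrame]:
    """Fit every trait column and return the adjusted-value table
    (accessions x traits) used by the association scan."""
    fits = {}
    preds = {}
    for trait in pheno.trait_columns:
        fit = fit_random_intercept_reml(pheno, trait, **kwargs)
        fits[trait] = fit
        preds[trait] = predict_accession_values(fit)
    return fits, pd.DataFrame(preds)
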