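"""Trial-level brain-behavior models with pair random intercepts.

Behavioral outcomes (adaptation z, early-phrase asynchrony, entry asynchrony,
phrase-2 IKI difference) are predicted from the PLV averaged over a
significant window x ROI x band, with participant pair as random intercept:

    behavior ~ PLV + (1 | pair)

Model significance is a likelihood-ratio test against the intercept-only
null with the same random structure (df = 1).  Skewed outcomes
(|skewness| > 1) are log-transformed when strictly positive, square-root
transformed otherwise.  Bimodal outcomes (phrase-2 IKI differences split by
congruency) are binarized by median split (ties to the lower bin) and fitted
with a random-intercept logistic model, estimated by adaptive Gauss-Hermite
quadrature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sstats
import statsmodels.api as sm


def choose_transform(y: np.ndarray) -> str:
    """Pick a variance-stabilizing transform for a skewed outcome.

    ``'log'`` for strictly positive data with |skew| > 1, ``'sqrt'`` for
    nonnegative skewed data, ``'none'`` otherwise.
    """
    y = np.asarray(y, float)
    if abs(sstats.skew(y)) <= 1:
        return "none"
    if np.all(y > 0):
        return "log"
    if np.all(y >= 0):
        return "sqrt"
    return "none"


def apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log":
        return np.log(y)
    if transform == "sqrt":
        return np.sqrt(y)
    if transform == "none":
        return np.asarray(y, float)
    raise ValueError(f"unknown transform {transform!r}")


def median_split(y: np.ndarray) -> np.ndarray:
    """Binarize by median; ties go to the lower bin (deterministic)."""
    y = np.asarray(y, float)
    return (y > np.median(y)).astype(int)


def _clean(table: pd.DataFrame, outcome: str, predictor: str, group: str):
    df = table[[group, predictor, outcome]].dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 trials with finite outcome/predictor")
    if not np.isfinite(df[predictor]).all():
        raise ValueError("predictor must be finite")
    return df


def fit_linear_mixed(
    table: pd.DataFrame,
    outcome: str,
    predictor: str = "plv",
    group: str = "pair",
    transform: str | None = None,
) -> dict:
    """Linear mixed model outcome ~ predictor + (1 | group), fitted by ML.

    Returns a report dict: slope estimate, standard error, Wald p,
    likelihood-ratio chi-square and p against the intercept-only null with
    the same random structure, the transform used, and convergence flags.
    A single group degenerates to ordinary regression (with a warning).
    """
    df = _clean(table, outcome, predictor, group)
    y = df[outcome].to_numpy(float)
    if transform is None:
        transform = choose_transform(y)
    y = apply_transform(y, transform)
    x = df[predictor].to_numpy(float)
    groups = df[group].to_numpy()
    n_groups = len(np.unique(groups))

    report = {"outcome": outcome, "predictor": predictor, "model": "linear",
              "transform": transform, "n_trials": len(df),
              "n_groups": int(n_groups), "df": 1}

    if n_groups < 2:
        warnings.warn("single group: mixed model degenerates to ordinary "
                      "least squares", stacklevel=2)
        full = sm.OLS(y, sm.add_constant(x)).fit()
        null = sm.OLS(y, np.ones((len(y), 1))).fit()
        lr = 2 * (full.llf - null.llf)
        report.update(
            estimate=float(full.params[1]), se=float(full.bse[1]),
            p=float(full.pvalues[1]), lr_chi2=float(max(lr, 0.0)),
            lr_p=float(sstats.chi2.sf(max(lr, 0.0), 1)),
            converged=True, singular=False,
        )
        return report

    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, exog, groups=groups).fit(reml=False)
        null = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=False)
    lr = max(2 * (full.llf - null.llf), 0.0)
    singular = bool(np.asarray(full.cov_re).min() < 1e-8)
    if singular:
        warnings.warn("singular fit: random-intercept variance estimated at "
                      "the boundary (~0)", stacklevel=2)
    report.update(
        estimate=float(full.params[1]), se=float(full.bse[1]),
        p=float(full.pvalues[1]), lr_chi2=float(lr),
        lr_p=float(sstats.chi2.sf(lr, 1)),
        converged=bool(full.converged and null.converged),
        singular=singular,
    )
    return report


# ---------------------------------------------------------------------------
# random-intercept logistic model via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


def _group_loglik(beta_eta: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Marginal log-likelihood of one group, integrating out the intercept.

    ``beta_eta`` are the fixed-effect linear predictors of the group's
    trials.  Uses adaptive Gauss-Hermite quadrature: the integrand is
    recentred at its mode (found by Newton steps on the concave log
    integrand) and rescaled by its curvature.
    """
    def h_parts(u):
        eta = beta_eta + sigma * u
        # log p(y | u) summed, stable logistic log-likelihood
        ll = -np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta)))
        return ll - 0.5 * u * u

    # Newton on h(u); derivatives of the Bernoulli log-likelihood
    u = 0.0
    for _ in range(50):
        eta = np.clip(beta_eta + sigma * u, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = sigma * np.sum(y - mu) - u
        hess = -sigma ** 2 * np.sum(mu * (1 - mu)) - 1.0
        step = grad / hess
        u -= step
        if abs(step) < 1e-10:
            break
    tau = -hess                       # curvature at the mode, > 0
    scale = np.sqrt(2.0 / tau)
    vals = np.array([h_parts(u + scale * t) + t * t for t in _GH_NODES])
    m = vals.max()
    integral = scale * np.sum(_GH_WEIGHTS * np.exp(vals - m))
    return m + np.log(integral) - 0.5 * np.log(2 * np.pi)


def _logistic_mixed_loglik(params, x_by_group, y_by_group, slope: bool):
    if slope:
        b0, b1, log_sigma = params
    else:
        b0, log_sigma = params
        b1 = 0.0
    sigma = np.exp(log_sigma)
    total = 0.0
    for xg, yg in zip(x_by_group, y_by_group):
        total += _group_loglik(b0 + b1 * xg, yg, sigma)
    return total


def _fit_logistic(x_by_group, y_by_group, slope: bool):
    x0 = np.array([0.0, 0.0, np.log(0.5)]) if slope else np.array([0.0, np.log(0.5)])

    def neg(params):
        return -_logistic_mixed_loglik(params, x_by_group, y_by_group, slope)

    bounds = ([(-30, 30)] * (2 if slope else 1)) + [(-8, 4)]
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    return res


def _numerical_se(fun, params: np.ndarray) -> np.ndarray:
    """Standard errors from a central-difference Hessian of a log-likelihood."""
    k = len(params)
    h = 1e-4 * np.maximum(np.abs(params), 1.0)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (
                4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


def fit_logistic_mixed(
    table: pd.DataFrame,
    outcome: str,
    predictor: str = "plv",
    group: str = "pair",
    binarize: bool = True,
) -> dict:
    """Random-intercept logistic model for a (median-split) binary outcome.

    Same contract as :func:`fit_linear_mixed` on the logit scale: slope
    estimate, SE, Wald p, and an LR test against the intercept-only null
    with the same random structure.  Complete separation drives the slope
    toward the optimizer bounds; this is reported via ``separation=True``
    rather than an error.
    """
    df = _clean(table, outcome, predictor, group)
    y = df[outcome].to_numpy(float)
    if binarize:
        y = median_split(y)
    else:
        y = y.astype(int)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("outcome must be binary when binarize=False")
    x = df[predictor].to_numpy(float)
    groups = df[group].to_numpy()
    uniq = np.unique(groups)
    x_by_group = [x[groups == g] for g in uniq]
    y_by_group = [y[groups == g] for g in uniq]
    if len(uniq) < 2:
        warnings.warn("single group: random intercept not identifiable",
                      stacklevel=2)

    res_full = _fit_logistic(x_by_group, y_by_group, slope=True)
    res_null = _fit_logistic(x_by_group, y_by_group, slope=False)
    llf_full = -res_full.fun
    llf_null = -res_null.fun
    lr = max(2 * (llf_full - llf_null), 0.0)

    se = _numerical_se(
        lambda p: _logistic_mixed_loglik(p, x_by_group, y_by_group, True),
        res_full.x)
    estimate = float(res_full.x[1])
    slope_se = float(se[1])
    z = estimate / slope_se if slope_se > 0 else np.nan
    separation = bool(abs(estimate) >= 29.0)

    return {
        "outcome": outcome, "predictor": predictor, "model": "logistic",
        "transform": "median_split" if binarize else "none",
        "n_trials": len(df), "n_groups": int(len(uniq)), "df": 1,
        "estimate": estimate, "se": slope_se,
        "p": float(2 * sstats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        "lr_chi2": float(lr), "lr_p": float(sstats.chi2.sf(lr, 1)),
        "sigma_intercept": float(np.exp(res_full.x[2])),
        "converged": bool(res_full.success and res_null.success),
        "separation": separation,
    }
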