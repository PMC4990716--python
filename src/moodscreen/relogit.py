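"""Random-intercept logistic regression for short binary panels.

The screening model treats the biweekly depressed label of patient *i* at
window *t* as

    y_it ~ Bernoulli(p_it),   logit(p_it) = x_it' beta + b_i,
    b_i ~ Normal(0, sigma_b^2),

where x_it holds the sleep / mood / anxiety indicators.  The patient-level
intercept absorbs stable unobserved severity differences; a random (rather
than fixed) effect keeps patients with a single observation in the sample
and avoids one dummy per patient in a short panel.

The marginal likelihood integrates b_i out by Gauss–Hermite quadrature
(default 15 nodes, change of variable ``b = sqrt(2) * sigma_b * node``) and
is maximized by BFGS with an analytic gradient; ``sigma_b`` is optimized on
the log scale so nonnegativity is automatic, and a boundary solution is
reported as ``sigma_b = 0``.  The coefficient covariance comes from the
observed information (numerical Hessian at the optimum).

Predicted probabilities are population-level — ``logistic(x' beta)`` with
the random intercept at zero — because screening a new patient provides no
posterior for their b_i.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

DEFAULT_QUAD_POINTS = 15
_SIGMA_FLOOR = 1e-3   # below this the random intercept is reported as absent
_BETA_BLOWUP = 30.0   # |beta| beyond this flags (quasi-)complete separation


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PanelDesign:
    """Outcome, predictor matrix (with intercept) and patient index."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if not (len(self.y) == len(self.X) == len(self.groups)):
            raise ValueError("y, X and groups must have equal length")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        if np.isnan(self.X).any():
            raise ValueError("predictors contain missing values; drop those rows upstream")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names must match predictor columns")

    @classmethod
    def from_indicators(cls, table: pd.DataFrame,
                        predictors=("sleep", "mood", "anxiety")) -> "PanelDesign":
        """Design from an indicator table: intercept + the named columns."""
        predictors = list(predictors)
        X = np.column_stack([np.ones(len(table)),
                             table[predictors].to_numpy(dtype=float)])
        return cls(y=table["depressed"].to_numpy(dtype=float), X=X,
                   groups=table["patient_id"].to_numpy(),
                   names=["const"] + predictors)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.groups))


@dataclass
class ReLogitFit:
    """ML estimates of the random-intercept logistic panel model."""

    beta: np.ndarray
    sigma_b: float
    loglik: float
    vcov: np.ndarray
    names: list[str]
    n_obs: int
    n_patients: int
    quad_points: int
    converged: bool
    n_iter: int = 0
    sigma_b_se: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        if name not in self.names:
            raise KeyError(f"unknown predictor {name!r}; have {self.names}")
        return float(self.beta[self.names.index(name)])

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        se = self.se()
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "beta": [float(b) for b in self.beta],
            "sigma_b": float(self.sigma_b),
            "loglik": float(self.loglik),
            "vcov": [[float(v) for v in row] for row in self.vcov],
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "quad_points": self.quad_points,
            "sigma_b_se": float(self.sigma_b_se),
            "converged": bool(self.converged),
            "notes": self.notes,
        }


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(groups, sort=True)
    return codes, len(uniques)


def _nll_grad_nodes(beta, y, X, codes, n_groups, b, logw, *, want_wr=False):
    """Negative marginal log-likelihood and beta-gradient at fixed intercept
    nodes ``b`` (already scaled by sqrt(2)*sigma)."""
    eta = X @ beta                                          # (N,)
    etab = eta[:, None] + b[None, :]                        # (N,K)
    sgn = 2.0 * y - 1.0
    ll_obs = -np.logaddexp(0.0, -sgn[:, None] * etab)       # log Bernoulli terms
    ll_grp = np.zeros((n_groups, etab.shape[1]))
    np.add.at(ll_grp, codes, ll_obs)
    a = ll_grp + logw[None, :]
    amax = a.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    nll = -float(lse.sum())

    w_post = np.exp(a - lse[:, None])                       # node posteriors per patient
    resid = y[:, None] - expit(etab)                        # (N,K)
    wr = w_post[codes] * resid
    g_beta = -(X.T @ wr.sum(axis=1))
    if want_wr:
        return nll, g_beta, wr
    return nll, g_beta


def _nll_grad(params, y, X, codes, n_groups, nodes, logw):
    """Negative marginal log-likelihood and gradient in (beta, log sigma_b)."""
    beta, theta = params[:-1], params[-1]
    b = math.sqrt(2.0) * math.exp(theta) * nodes            # (K,)
    nll, g_beta, wr = _nll_grad_nodes(beta, y, X, codes, n_groups, b, logw,
                                      want_wr=True)
    g_theta = -float((wr * b[None, :]).sum())               # d b_k / d theta = b_k
    return nll, np.concatenate([g_beta, [g_theta]])


def marginal_loglik(beta, sigma_b: float, design: PanelDesign,
                    quad_points: int = DEFAULT_QUAD_POINTS) -> float:
    """Gauss–Hermite marginal log-likelihood at given parameters."""
    codes, n_groups = _group_index(design.groups)
    nodes, weights = hermgauss(quad_points)
    logw = np.log(weights) - 0.5 * math.log(math.pi)
    theta = math.log(max(sigma_b, 1e-12))
    nll, _ = _nll_grad(np.concatenate([np.asarray(beta, float), [theta]]),
                       design.y, design.X, codes, n_groups, nodes, logw)
    return -nll


def _numeric_hessian(f, x0, step=1e-4):
    n = len(x0)
    H = np.empty((n, n))
    h = step * (1.0 + np.abs(x0))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_relogit(design: PanelDesign,
                quad_points: int = DEFAULT_QUAD_POINTS,
                start: np.ndarray | None = None,
                sigma_start: float = 0.5,
                fixed_sigma: float | None = None) -> ReLogitFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Raises on a single-patient panel (sigma_b unidentifiable) or a
    one-class outcome.  Complete separation does not raise: the fit is
    returned with ``converged=False`` and a warning.

    ``fixed_sigma`` profiles the likelihood at a known random-intercept SD
    instead of estimating it; ``fixed_sigma=0`` is exactly the pooled
    (ordinary) logistic ML fit, which the model nests.
    """
    if fixed_sigma is None and design.n_patients < 2:
        raise ValueError("need at least 2 patients to identify sigma_b")
    if len(np.unique(design.y)) < 2:
        raise ValueError("outcome must contain both classes")

    codes, n_groups = _group_index(design.groups)
    nodes, weights = hermgauss(quad_points)
    logw = np.log(weights) - 0.5 * math.log(math.pi)

    if start is None:
        pooled = LogisticRegression(penalty=None, fit_intercept=False,
                                    solver="lbfgs", max_iter=1000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled.fit(design.X, design.y)
        start = pooled.coef_.ravel()
    notes: list[str] = []
    if fixed_sigma is not None:
        if fixed_sigma < 0:
            raise ValueError("fixed_sigma must be nonnegative")
        b_fixed = math.sqrt(2.0) * fixed_sigma * nodes

        def nll_grad_beta(beta):
            nll, g = _nll_grad_nodes(beta, design.y, design.X, codes,
                                     n_groups, b_fixed, logw)
            return nll, g

        res = minimize(nll_grad_beta, np.asarray(start, float), jac=True,
                       method="BFGS", options={"maxiter": 500, "gtol": 1e-9})
        beta = res.x
        sigma = float(fixed_sigma)
        notes.append(f"sigma_b held fixed at {fixed_sigma}")
    else:
        x0 = np.concatenate([np.asarray(start, float), [math.log(sigma_start)]])
        res = minimize(_nll_grad, x0, jac=True, method="BFGS",
                       args=(design.y, design.X, codes, n_groups, nodes, logw),
                       options={"maxiter": 500, "gtol": 1e-7})
        beta = res.x[:-1]
        sigma = math.exp(res.x[-1])
    converged = bool(res.success)

    if np.abs(beta).max() > _BETA_BLOWUP:
        converged = False
        notes.append("possible complete separation: coefficient escaping to infinity")
        warnings.warn(notes[-1], ConvergenceWarning)
    if fixed_sigma is None and sigma < _SIGMA_FLOOR:
        notes.append("sigma_b at boundary; reported as 0 (no patient-level heterogeneity)")
        sigma = 0.0

    # observed information on the (beta, sigma) scale; at a boundary,
    # fixed-sigma or separated fit use the beta block alone
    p = len(beta)
    estimate_sigma = fixed_sigma is None and sigma > 0.0

    def nll_at(q):
        if estimate_sigma:
            b_vec, sig = q[:p], max(q[p], 1e-12)
        else:
            b_vec, sig = q, sigma
        val, _ = _nll_grad_nodes(b_vec, design.y, design.X, codes, n_groups,
                                 math.sqrt(2.0) * sig * nodes, logw)
        return val

    sigma_se = float("nan")
    try:
        if estimate_sigma:
            H = _numeric_hessian(nll_at, np.concatenate([beta, [sigma]]))
            vcov_full = np.linalg.inv(H)
            vcov = vcov_full[:p, :p]
            if vcov_full[p, p] > 0:
                sigma_se = math.sqrt(vcov_full[p, p])
        else:
            H = _numeric_hessian(nll_at, beta)
            vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.full((p, p), np.nan)
        notes.append("observed information singular; covariance unavailable")

    return ReLogitFit(beta=beta, sigma_b=float(sigma), loglik=-float(res.fun),
                      vcov=vcov, names=list(design.names),
                      n_obs=design.n_obs, n_patients=design.n_patients,
                      quad_points=quad_points, converged=converged,
                      n_iter=int(res.nit), sigma_b_se=sigma_se, notes=notes)


def predict_prob(fit: ReLogitFit, predictors) -> np.ndarray:
    """Population-level probabilities ``logistic(x' beta)`` (b_i = 0).

    ``predictors`` may be an indicator-style DataFrame carrying the fit's
    named columns (an intercept is added) or a ready design matrix.
    """
    if isinstance(predictors, pd.DataFrame):
        cols = [n for n in fit.names if n != "const"]
        X = np.column_stack([np.ones(len(predictors)),
                             predictors[cols].to_numpy(dtype=float)]) \
            if "const" in fit.names else predictors[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(fit.beta):
        raise ValueError(
            f"predictor matrix has shape {X.shape}; fit expects "
            f"{len(fit.beta)} columns ({fit.names})")
    return expit(X @ fit.beta)


def odds_multiplier(fit: ReLogitFit, predictor_name: str, delta: float) -> float:
    """Multiplicative change in the odds for a ``delta`` change in one
    predictor: ``exp(delta * beta)``."""
    return math.exp(delta * fit.coef(predictor_name))
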