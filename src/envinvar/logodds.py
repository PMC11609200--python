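"""Log-odds transform of binary child variables.

A binary child Z is replaced by the fitted linear predictor of a logistic
regression, log(p/(1-p)) = b0 + x.b with p = P(Z=1 | X=x).  The score is
exactly linear in the predictors, which is the property the downstream linear
invariance methods need; no sigmoid is applied and no probabilities are
propagated.  In training environments the fit may include the target among
the predictors; in the test environment the target is unavailable, so the
fit uses the predictors alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from envinvar.scm import Cohort, ROLE_CHILD_SCORE, ROLE_BINARY_CHILD

logger = logging.getLogger(__name__)

#: ridge penalty applied to slopes (never the intercept) when the ML fit
#: separates or fails to converge
RIDGE_FALLBACK = 1e-4


class DegenerateChildError(ValueError):
    """The binary variable has a single class in some fit context."""


class FitError(RuntimeError):
    """Logistic fit failed even after the ridge fallback."""


@dataclass
class LogOddsModel:
    """A fitted logistic model used as a linear scoring map."""

    intercept: float
    coef: dict[str, float]
    predictor_set: list[str]
    fit_context: str
    n_iter: int
    grad_norm: float
    used_ridge: bool = False

    def __post_init__(self) -> None:
        if list(self.coef) != list(self.predictor_set):
            raise ValueError("coefficient keys must match predictor_set")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": self.coef,
            "predictor_set": self.predictor_set,
            "fit_context": self.fit_context,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "used_ridge": self.used_ridge,
        }


def _neg_loglik_ridge(params: np.ndarray, X: np.ndarray, z: np.ndarray, lam: float):
    eta = params[0] + X @ params[1:]
    # log(1+exp(eta)) - z*eta, numerically stable
    nll = np.logaddexp(0.0, eta).sum() - float(z @ eta)
    nll += 0.5 * lam * float(params[1:] @ params[1:])
    p = expit(eta)
    grad = np.empty_like(params)
    grad[0] = float((p - z).sum())
    grad[1:] = X.T @ (p - z) + lam * params[1:]
    return nll, grad


def _ridge_fit(X: np.ndarray, z: np.ndarray, lam: float) -> tuple[np.ndarray, int, float]:
    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        _neg_loglik_ridge, x0, args=(X, z, lam), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "gtol": 1e-9},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise FitError(f"ridge fallback did not converge: {res.message}")
    return res.x, int(res.nit), float(np.linalg.norm(res.jac))


def fit_logistic(
    z: np.ndarray, X: pd.DataFrame, fit_context: str = "pooled"
) -> LogOddsModel:
    """Maximum-likelihood logistic fit with a ridge fallback on separation.

    Quasi-separated data (or any non-convergent ML path) is refit with a small
    L2 penalty on the slopes so the returned coefficients are always finite;
    a warning is emitted and the model is flagged.
    """
    z = np.asarray(z, dtype=float)
    if not set(np.unique(z)) <= {0.0, 1.0}:
        raise ValueError("z must be binary in {0,1}")
    if len(np.unique(z)) < 2:
        raise DegenerateChildError(
            f"single-class binary variable in context {fit_context!r}"
        )
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if len(z) <= Xv.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")

    used_ridge = False
    params = n_iter = grad_norm = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> fallback
            model = sm.Logit(z, sm.add_constant(Xv, has_constant="add"))
            res = model.fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.all(
            np.abs(res.params) < 1e3
        ):
            params = np.asarray(res.params)
            n_iter = int(res.mle_retvals.get("iterations", -1))
            grad_norm = float(np.linalg.norm(model.score(res.params)))
    except Exception:
        params = None
    if params is None:
        warnings.warn(
            f"logistic fit in context {fit_context!r} separated or failed to "
            f"converge; refitting with ridge penalty {RIDGE_FALLBACK:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        params, n_iter, grad_norm = _ridge_fit(Xv, z, RIDGE_FALLBACK)
        used_ridge = True
    return LogOddsModel(
        intercept=float(params[0]),
        coef={name: float(b) for name, b in zip(names, params[1:])},
        predictor_set=names,
        fit_context=fit_context,
        n_iter=n_iter,
        grad_norm=grad_norm,
        used_ridge=used_ridge,
    )


def transform(model: LogOddsModel, X: pd.DataFrame) -> np.ndarray:
    """Exact linear score b0 + X.b (no link inversion, no clipping)."""
    missing = [p for p in model.predictor_set if p not in X.columns]
    if missing:
        raise KeyError(f"predictor columns missing from data: {missing}")
    beta = np.array([model.coef[p] for p in model.predictor_set])
    return model.intercept + X[model.predictor_set].to_numpy(dtype=float) @ beta


def apply_child_transform(
    train: Cohort,
    test: Cohort,
    child: str,
    train_predictors: list[str],
    test_predictors: list[str],
) -> tuple[Cohort, Cohort, dict[str, LogOddsModel]]:
    """Replace a binary child column by per-context log-odds scores.

    One logistic fit per training environment cell (the per-environment
    heterogeneity of the child regression is what the matching construction
    exploits) and one fit on the test environment, which excludes the target.
    The original binary column is preserved under ``<child>__binary``.
    """
    for cohort, where in ((train, "train"), (test, "test")):
        vals = set(np.unique(cohort.data[child].to_numpy()))
        if not vals <= {0.0, 1.0}:
            raise ValueError(
                f"child {child!r} is not binary in the {where} cohort "
                "(already transformed?)"
            )
    train, test = train.copy(), test.copy()
    models: dict[str, LogOddsModel] = {}

    for cohort, contexts, preds in (
        (train, train.env_labels(), train_predictors),
        (test, ["test"], test_predictors),
    ):
        raw = cohort.data[child].to_numpy()
        scores = np.empty(cohort.n, dtype=float)
        for ctx in contexts:
            mask = (
                cohort.env == ctx if ctx != "test" else np.ones(cohort.n, dtype=bool)
            )
            try:
                model = fit_logistic(raw[mask], cohort.data.loc[mask, preds], ctx)
            except DegenerateChildError as err:
                raise DegenerateChildError(
                    f"child {child!r} single-class in fit context {ctx!r}"
                ) from err
            models[ctx] = model
            scores[mask] = transform(model, cohort.data.loc[mask, preds])
        cohort.data[child + "__binary"] = raw
        cohort.roles[child + "__binary"] = ROLE_BINARY_CHILD
        cohort.data[child] = scores
        cohort.roles[child] = ROLE_CHILD_SCORE
        logger.info(
            "apply_child_transform: %r scored in contexts %s", child, list(contexts)
        )
    return train, test, models
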