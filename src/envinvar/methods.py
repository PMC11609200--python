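"""Invariance-based regression estimators over enumerated predictor subsets.

Five estimators of a continuous target from multi-environment training data,
evaluated by mean squared error in a held-out test environment:

* **OLS** -- pooled least squares on the full selected-predictor set; the
  baseline that ignores environment structure.
* **ICP** (invariant causal prediction) -- accepts every subset whose pooled
  residual distribution is invariant across training environments and
  predicts from the *intersection* of accepted subsets, which controls the
  family-wise probability of including a non-parent but is conservative
  (frequently no invariant subset is found, reported as NA).
* **SR** (stable regression) -- screens subsets by coefficient equality
  across environments (a weaker, conditional-expectation form of invariance)
  and among the survivors picks the one with the best cross-validated
  prediction error: the "stable blanket".
* **IMP** (invariant matching property) -- a two-stage construction that uses
  a causal *child* of the target: per-environment regressions of the child on
  all candidate predictors give matching scores eta_e(x) that absorb
  environment-specific shifts of the target's own mechanism, so regressing
  the target on (X_S, eta_e) yields environment-invariant coefficients even
  under interventions on the target.  Subsets are accepted when the
  SE-scaled distance between per-environment coefficient vectors is small
  and the training prediction error is competitive; accepted models are
  averaged for prediction.
* **IMP_inv** -- IMP with the coefficient-distance score replaced by the
  residual-invariance test applied to the stage-two residuals.

IMP additionally yields a causal-parent voting procedure: each accepted
model votes for the predictors in its subset.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from envinvar.scm import Cohort

logger = logging.getLogger(__name__)

OLS, ICP, SR, IMP, IMP_INV = "OLS", "ICP", "SR", "IMP", "IMP_inv"
METHOD_NAMES = (IMP, IMP_INV, SR, ICP, OLS)  # publication column order

SUBSET_GUARD = 16  # 2**16 enumerated subsets at most, unless max_size caps it


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# OLS primitive
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    """Least-squares fit with intercept; names exclude the intercept term."""

    names: list[str]
    coef: np.ndarray  # [intercept, slopes...]
    se: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.coef[0] + X @ self.coef[1:]


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> OLSFit:
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} samples for {k} predictors, have {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < k + 1:
        raise CollinearityError(f"rank-deficient design for subset {list(names)}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    sigma2 = float(resid @ resid) / (n - k - 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return OLSFit(list(names), coef, np.sqrt(np.diag(cov)), resid, fitted)


def fit_ols(cohort: Cohort, target: str, subset: Sequence[str]) -> OLSFit:
    """Ordinary least squares of the target on a predictor subset."""
    X = cohort.data[list(subset)].to_numpy(dtype=float)
    y = cohort.data[target].to_numpy(dtype=float)
    return _ols(X, y, subset)


# ---------------------------------------------------------------------------
# Invariance tests
# ---------------------------------------------------------------------------


def residual_invariance_test(
    residuals: np.ndarray, env_labels: np.ndarray, alpha: float = 0.05
) -> float:
    """Combined p-value for residual invariance across environments.

    Means are compared by a one-way ANOVA F test, variances by Levene's test
    (median-centred); the two p-values are Bonferroni-combined as
    min(1, 2 * min(p_mean, p_var)).  With a single environment the test is
    vacuous and returns 1 with a warning.  ``alpha`` is carried for callers'
    reject/accept decisions; the return value is the p-value itself.
    """
    residuals = np.asarray(residuals, dtype=float)
    env_labels = np.asarray(env_labels)
    groups = [residuals[env_labels == lab] for lab in np.unique(env_labels)]
    if len(groups) < 2:
        warnings.warn(
            "single training environment: invariance test is vacuous (p=1)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    if any(len(g) < 3 for g in groups):
        raise ValueError("each environment needs at least 3 residuals")
    if np.ptp(residuals) == 0:
        return 1.0  # identical residuals everywhere: trivially invariant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_mean = stats.f_oneway(*groups).pvalue
        p_var = stats.levene(*groups, center="median").pvalue
    # degenerate groups (zero within-group variance) make the F statistics nan
    if np.isnan(p_mean):
        means = [g.mean() for g in groups]
        p_mean = 1.0 if np.ptp(means) == 0 else 0.0
    if np.isnan(p_var):
        p_var = 1.0
    return float(min(1.0, 2.0 * min(p_mean, p_var)))


# ---------------------------------------------------------------------------
# Candidate / result containers
# ---------------------------------------------------------------------------


@dataclass
class CandidateModel:
    """One predictor subset with its fit, scores and acceptance status."""

    subset: tuple[str, ...]
    coef_pooled: np.ndarray | None = None
    coef_by_env: dict[str, np.ndarray] = field(default_factory=dict)
    invariance_pvalue: float | None = None
    invariance_score: float | None = None
    prediction_score: float | None = None
    accepted: bool = False


@dataclass
class MethodResult:
    """Per-method output: accepted models, final set, test predictions, MSE.

    ``final_predictor_set`` and the test fields are None when the method
    identified no invariance (rendered as "NA" in tables).
    """

    method: str
    accepted_models: list[CandidateModel] = field(default_factory=list)
    final_predictor_set: tuple[str, ...] | None = None
    pooled_coef: np.ndarray | None = None  # aligned to final set, with intercept
    test_predictions: np.ndarray | None = None
    test_mse: float | None = None
    empty_intersection: bool = False
    child: str | None = None
    candidate_predictors: tuple[str, ...] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_na(self) -> bool:
        if self.method in (IMP, IMP_INV):
            return not self.accepted_models
        return self.final_predictor_set is None and not self.empty_intersection


@dataclass
class VoteTally:
    """Nonnegative per-variable vote counts from accepted models."""

    counts: dict[str, int]
    n_accepted: int

    def total_votes(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Subset enumeration
# ---------------------------------------------------------------------------


def enumerate_subsets(
    predictors: Sequence[str],
    max_size: int | None = None,
    allow_large: bool = False,
) -> list[tuple[str, ...]]:
    """All nonempty predictor subsets up to ``max_size``, ordered by size
    then lexicographically in the given predictor order."""
    predictors = list(predictors)
    if max_size is None and len(predictors) > SUBSET_GUARD and not allow_large:
        raise ValueError(
            f"{len(predictors)} predictors would enumerate "
            f"2**{len(predictors)} subsets; set max_size or allow_large"
        )
    cap = len(predictors) if max_size is None else min(max_size, len(predictors))
    out: list[tuple[str, ...]] = []
    for size in range(1, cap + 1):
        out.extend(itertools.combinations(predictors, size))
    return out


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def icp(
    train: Cohort,
    target: str,
    subsets: Sequence[tuple[str, ...]],
    alpha: float = 0.05,
) -> MethodResult:
    """Invariant causal prediction over enumerated subsets.

    A subset is accepted when the residuals of its pooled fit pass the
    residual-invariance test at level ``alpha``.  The final predictor set is
    the intersection of all accepted subsets.  Zero accepted subsets -> NA;
    a nonempty accepted family with empty intersection falls back to an
    intercept-only model, flagged ``empty_intersection``.
    """
    y = train.data[target].to_numpy(dtype=float)
    models: list[CandidateModel] = []
    for subset in subsets:
        fit = fit_ols(train, target, subset)
        p = residual_invariance_test(fit.residuals, train.env, alpha)
        models.append(
            CandidateModel(
                subset=tuple(subset),
                coef_pooled=fit.coef,
                invariance_pvalue=p,
                accepted=p >= alpha,
            )
        )
    accepted = [m for m in models if m.accepted]
    diagnostics = {"n_tested": len(models), "n_accepted": len(accepted)}
    if not accepted:
        logger.info("ICP: no invariant subset found (NA)")
        return MethodResult(ICP, [], None, diagnostics=diagnostics)
    final: set[str] = set(accepted[0].subset)
    for m in accepted[1:]:
        final &= set(m.subset)
    if not final:
        logger.info("ICP: empty intersection of %d accepted subsets", len(accepted))
        coef = np.array([float(y.mean())])
        return MethodResult(
            ICP,
            accepted,
            final_predictor_set=(),
            pooled_coef=coef,
            empty_intersection=True,
            diagnostics=diagnostics,
        )
    final_tuple = tuple(p for p in train.predictors if p in final)
    fit = fit_ols(train, target, final_tuple)
    return MethodResult(
        ICP, accepted, final_tuple, pooled_coef=fit.coef, diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# Stable regression
# ---------------------------------------------------------------------------


def _chow_pvalue(train: Cohort, target: str, subset: tuple[str, ...]) -> float:
    """Coefficient-equality (Chow-type) F test across environments."""
    y = train.data[target].to_numpy(dtype=float)
    X = train.data[list(subset)].to_numpy(dtype=float)
    labels = train.env
    envs = list(dict.fromkeys(labels))
    if len(envs) < 2:
        warnings.warn(
            "single training environment: coefficient-equality test is vacuous",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    k = len(subset) + 1
    rss_pooled = float(np.sum(_ols(X, y, subset).residuals ** 2))
    rss_env = 0.0
    for lab in envs:
        mask = labels == lab
        rss_env += float(np.sum(_ols(X[mask], y[mask], subset).residuals ** 2))
    n = len(y)
    df1 = k * (len(envs) - 1)
    df2 = n - len(envs) * k
    if df2 <= 0:
        raise ValueError("too few samples per environment for the Chow test")
    if rss_env <= 0:
        return 1.0 if rss_pooled <= 0 else 0.0
    f = ((rss_pooled - rss_env) / df1) / (rss_env / df2)
    return float(stats.f.sf(f, df1, df2))


def stable_regression(
    train: Cohort,
    target: str,
    subsets: Sequence[tuple[str, ...]],
    alpha: float = 0.05,
    cv_folds: int = 5,
    seed: int = 0,
) -> MethodResult:
    """Stable-blanket selection: invariance screen then prediction power.

    Subsets surviving the coefficient-equality screen at ``alpha`` compete on
    seeded ``cv_folds``-fold pooled CV mean squared error; ties go to the
    smaller subset, then lexicographic order.  No survivor -> NA.
    """
    y = train.data[target].to_numpy(dtype=float)
    survivors: list[CandidateModel] = []
    n_tested = 0
    for subset in subsets:
        n_tested += 1
        p = _chow_pvalue(train, target, tuple(subset))
        if p >= alpha:
            survivors.append(
                CandidateModel(subset=tuple(subset), invariance_pvalue=p, accepted=True)
            )
    diagnostics = {"n_tested": n_tested, "n_accepted": len(survivors)}
    if not survivors:
        logger.info("SR: no subset passed the invariance screen (NA)")
        return MethodResult(SR, [], None, diagnostics=diagnostics)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(y))
    for m in survivors:
        X = train.data[list(m.subset)].to_numpy(dtype=float)
        sse = 0.0
        for tr, val in splits:
            fit = _ols(X[tr], y[tr], m.subset)
            sse += float(np.sum((fit.predict(X[val]) - y[val]) ** 2))
        m.prediction_score = sse / len(y)
    best = min(
        survivors,
        key=lambda m: (round(m.prediction_score, 12), len(m.subset), m.subset),
    )
    fit = fit_ols(train, target, best.subset)
    best.coef_pooled = fit.coef
    return MethodResult(
        SR,
        survivors,
        final_predictor_set=best.subset,
        pooled_coef=fit.coef,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# IMP / IMP_inv
# ---------------------------------------------------------------------------


def _matching_scores(
    cohort: Cohort, child: str, candidates: Sequence[str]
) -> np.ndarray:
    """Stage one: per-environment OLS of the child score on all candidate
    predictors; returns the fitted values eta_e(x) aligned to the cohort."""
    eta = np.empty(cohort.n, dtype=float)
    Xc = cohort.data[list(candidates)].to_numpy(dtype=float)
    c = cohort.data[child].to_numpy(dtype=float)
    for lab in cohort.env_labels():
        mask = cohort.env == lab
        fit = _ols(Xc[mask], c[mask], candidates)
        eta[mask] = fit.fitted
    return eta


def _stage2_design(
    cohort: Cohort, subset: tuple[str, ...], eta: np.ndarray
) -> np.ndarray:
    return np.column_stack(
        [cohort.data[list(subset)].to_numpy(dtype=float), eta]
    )


def _imp_common(
    train: Cohort,
    child: str,
    target: str,
    subsets: Sequence[tuple[str, ...]],
    candidates: Sequence[str],
) -> tuple[list[CandidateModel], np.ndarray, np.ndarray, dict[tuple, dict]]:
    """Shared stage-one/stage-two machinery for IMP and IMP_inv."""
    y = train.data[target].to_numpy(dtype=float)
    eta = _matching_scores(train, child, candidates)
    envs = train.env_labels()
    models: list[CandidateModel] = []
    per_subset: dict[tuple, dict] = {}
    for subset in subsets:
        subset = tuple(subset)
        names = list(subset) + ["eta"]
        X2 = _stage2_design(train, subset, eta)
        coef_by_env: dict[str, np.ndarray] = {}
        se_by_env: dict[str, np.ndarray] = {}
        resid_own = np.empty(train.n, dtype=float)
        try:
            for lab in envs:
                mask = train.env == lab
                fit = _ols(X2[mask], y[mask], names)
                coef_by_env[lab] = fit.coef
                se_by_env[lab] = fit.se
                resid_own[mask] = fit.residuals
        except CollinearityError:
            # structural when S spans the candidate set: eta is then an exact
            # linear combination of X_S and the subset carries no matching
            # information; recorded as rejected rather than propagated
            models.append(
                CandidateModel(
                    subset=subset,
                    invariance_score=np.inf,
                    prediction_score=np.inf,
                )
            )
            per_subset[subset] = {"pooled_resid": None}
            continue
        # SE-scaled coefficient distance, max over environment pairs
        score = 0.0
        for a, b in itertools.combinations(envs, 2):
            d = coef_by_env[a] - coef_by_env[b]
            s2 = se_by_env[a] ** 2 + se_by_env[b] ** 2
            score = max(score, float(np.sqrt(np.mean(d * d / s2))))
        pooled = _ols(X2, y, names)
        models.append(
            CandidateModel(
                subset=subset,
                coef_pooled=pooled.coef,
                coef_by_env=coef_by_env,
                invariance_score=score,
                prediction_score=float(np.mean(resid_own**2)),
            )
        )
        per_subset[subset] = {"pooled_resid": pooled.residuals}
    return models, y, eta, per_subset


def imp_fit(
    train: Cohort,
    child: str,
    target: str,
    subsets: Sequence[tuple[str, ...]],
    candidate_predictors: Sequence[str] | None = None,
    tau_inv: float = 3.0,
    c_pred: float = 1.5,
) -> MethodResult:
    """Invariant-matching estimator with the coefficient-distance acceptance.

    Stage one regresses the (log-odds-transformed) child on *all* candidate
    predictors within each environment; stage two regresses the target on
    (X_S, eta_e).  A subset is accepted when the maximum pairwise SE-scaled
    distance between per-environment stage-two coefficient vectors is at most
    ``tau_inv`` and its pooled training MSE is within ``c_pred`` times the
    best over subsets.  Accepted models are averaged at prediction time.
    """
    candidates = tuple(candidate_predictors or train.predictors)
    models, _, _, _ = _imp_common(train, child, target, subsets, candidates)
    best_pred = min(m.prediction_score for m in models)
    for m in models:
        m.accepted = bool(
            np.isfinite(m.invariance_score)
            and m.invariance_score <= tau_inv
            and m.prediction_score <= c_pred * best_pred
        )
    accepted = [m for m in models if m.accepted]
    diagnostics = {
        "n_tested": len(models),
        "n_accepted": len(accepted),
        "tau_inv": tau_inv,
        "c_pred": c_pred,
    }
    if not accepted:
        logger.info("IMP: all subsets rejected (NA)")
    return MethodResult(
        IMP,
        accepted,
        child=child,
        candidate_predictors=candidates,
        diagnostics=diagnostics,
    )


def imp_inv_fit(
    train: Cohort,
    child: str,
    target: str,
    subsets: Sequence[tuple[str, ...]],
    candidate_predictors: Sequence[str] | None = None,
    alpha: float = 0.05,
    c_pred: float = 1.5,
) -> MethodResult:
    """IMP variant scored by residual invariance of the stage-two model.

    Identical construction to :func:`imp_fit`; acceptance replaces the
    coefficient-distance threshold by the residual-invariance test applied to
    the pooled stage-two residuals at level ``alpha``.
    """
    candidates = tuple(candidate_predictors or train.predictors)
    models, _, _, per_subset = _imp_common(train, child, target, subsets, candidates)
    best_pred = min(m.prediction_score for m in models)
    for m in models:
        resid = per_subset[m.subset]["pooled_resid"]
        if resid is None:  # collinear stage-two design, rejected in _imp_common
            m.invariance_pvalue = 0.0
            continue
        p = residual_invariance_test(resid, train.env, alpha)
        m.invariance_pvalue = p
        m.accepted = bool(p >= alpha and m.prediction_score <= c_pred * best_pred)
    accepted = [m for m in models if m.accepted]
    diagnostics = {
        "n_tested": len(models),
        "n_accepted": len(accepted),
        "alpha": alpha,
        "c_pred": c_pred,
    }
    if not accepted:
        logger.info("IMP_inv: all subsets rejected (NA)")
    return MethodResult(
        IMP_INV,
        accepted,
        child=child,
        candidate_predictors=candidates,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Baseline, scoring, voting
# ---------------------------------------------------------------------------


def ols_baseline(
    train: Cohort, target: str, predictors: Sequence[str]
) -> MethodResult:
    """Pooled OLS on the full selected-predictor set (never NA)."""
    fit = fit_ols(train, target, predictors)
    return MethodResult(
        OLS,
        [CandidateModel(tuple(predictors), coef_pooled=fit.coef, accepted=True)],
        final_predictor_set=tuple(predictors),
        pooled_coef=fit.coef,
        diagnostics={"n_tested": 1, "n_accepted": 1},
    )


def predict_and_score(
    result: MethodResult, test: Cohort, target: str
) -> MethodResult:
    """Attach test-environment predictions and MSE to a method result.

    NA results propagate (no predictions, no MSE).  The invariant-matching
    methods recompute the matching score inside the test environment from the
    child-on-predictors regression, then average the accepted models'
    pooled stage-two predictions.
    """
    y = test.data[target].to_numpy(dtype=float)
    if result.is_na:
        return replace(result, test_predictions=None, test_mse=None)
    if result.method in (IMP, IMP_INV):
        eta_f = _matching_scores(test, result.child, result.candidate_predictors)
        preds = np.zeros(test.n)
        for m in result.accepted_models:
            X2 = _stage2_design(test, m.subset, eta_f)
            preds += m.coef_pooled[0] + X2 @ m.coef_pooled[1:]
        preds /= len(result.accepted_models)
    elif result.empty_intersection:
        preds = np.full(test.n, result.pooled_coef[0])
    else:
        X = test.data[list(result.final_predictor_set)].to_numpy(dtype=float)
        preds = result.pooled_coef[0] + X @ result.pooled_coef[1:]
    if len(preds) != len(y):
        raise ValueError("prediction/target length mismatch")
    mse = float(np.mean((preds - y) ** 2))
    return replace(result, test_predictions=preds, test_mse=mse)


def vote_parents(
    results: Iterable[MethodResult], variables: Sequence[str] | None = None
) -> VoteTally:
    """Causal-parent voting: each accepted model votes for its subset.

    votes(v) = number of accepted models (across the supplied results) whose
    predictor subset contains v.  Variables with more votes are more likely
    to be causal parents of the target.
    """
    counter: Counter[str] = Counter()
    n_accepted = 0
    universe: list[str] = list(variables) if variables is not None else []
    for res in results:
        for m in res.accepted_models:
            n_accepted += 1
            counter.update(m.subset)
            if variables is None:
                for v in m.subset:
                    if v not in universe:
                        universe.append(v)
    return VoteTally(
        counts={v: counter.get(v, 0) for v in universe}, n_accepted=n_accepted
    )
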