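"""Cohort preprocessing: complete-case filtering, lasso pre-selection, and
construction of the test environment and training-environment partitions.

The analysis keeps only participants with every analysis variable observed,
pre-selects predictors by an L1-penalised linear fit with cross-validated
penalty, reserves the prior-flag == 1 stratum as the held-out test
environment, and splits the remaining training sample into two environments
along a demographic variable (continuous variables at a threshold, binary
variables by category).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from envinvar.scm import Cohort, ROLE_DEMOGRAPHIC

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """Filtering removed every sample."""


class SplitError(ValueError):
    """A requested split produced an empty side."""


@dataclass
class SelectionResult:
    """Outcome of the lasso pre-selection step."""

    selected: list[str]
    regularization_path: list[tuple[float, float]]  # (penalty, cv error)
    chosen_penalty: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema_version": "1",
                    "selected": self.selected,
                    "regularization_path": [
                        [float(a), float(e)] for a, e in self.regularization_path
                    ],
                    "chosen_penalty": float(self.chosen_penalty),
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


@dataclass
class EnvironmentSplit:
    """Assignment of retained samples to the test environment and to
    training environments (two demographic cells)."""

    test_mask: np.ndarray
    train_env_labels: np.ndarray  # labels for samples with test_mask == False
    partition_variable: str
    partition_rule: str

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.train_env_labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def complete_case_filter(cohort: Cohort) -> Cohort:
    """Drop every sample with any missing analysis value (order preserved)."""
    mask = cohort.data.notna().all(axis=1).to_numpy()
    removed = int((~mask).sum())
    if not mask.any():
        raise EmptyCohortError("complete-case filter removed every sample")
    if removed:
        logger.info("complete_case_filter: removed %d of %d samples", removed, cohort.n)
    return cohort.subset(mask)


def _cv_fold_slices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random permutation cut into contiguous blocks."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, n_folds)]


def lasso_select(
    cohort: Cohort, target: str, n_folds: int = 10, seed: int = 0
) -> SelectionResult:
    """L1 variable selection with cross-validated penalty.

    Predictors are z-standardised inside each training fold (statistics from
    the fold only); the returned selection refers to the original columns.
    Penalty ties on CV error resolve to the smallest penalty among the
    minimisers, i.e. the more inclusive selection.
    """
    predictors = cohort.predictors
    X = cohort.data[predictors].to_numpy(dtype=float)
    y = cohort.data[target].to_numpy(dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, have {n}")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; selection is degenerate")

    def standardize(A: np.ndarray, mu=None, sd=None):
        if mu is None:
            mu = A.mean(axis=0)
            sd = A.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        return (A - mu) / sd, mu, sd

    Xs_full, mu_full, sd_full = standardize(X)
    alphas, _, _ = lasso_path(Xs_full, y - y.mean(), alphas=100, eps=1e-3)

    folds = _cv_fold_slices(n, n_folds, seed)
    cv_err = np.zeros(len(alphas))
    for val_idx in folds:
        tr = np.setdiff1d(np.arange(n), val_idx)
        Xtr, mu, sd = standardize(X[tr])
        ytr = y[tr]
        ybar = ytr.mean()
        _, coefs, _ = lasso_path(Xtr, ytr - ybar, alphas=alphas)
        Xval = (X[val_idx] - mu) / sd
        preds = Xval @ coefs + ybar  # (n_val, n_alphas)
        cv_err += ((preds - y[val_idx][:, None]) ** 2).sum(axis=0)
    cv_err /= n

    best = cv_err.min()
    minimizers = alphas[cv_err <= best + 1e-12]
    chosen = float(minimizers.min())
    final = Lasso(alpha=chosen, fit_intercept=True, max_iter=50_000)
    final.fit(Xs_full, y)
    selected = [p for p, c in zip(predictors, final.coef_) if c != 0.0]
    logger.info(
        "lasso_select: chose penalty %.6g (%d/%d predictors)",
        chosen,
        len(selected),
        len(predictors),
    )
    return SelectionResult(
        selected=selected,
        regularization_path=list(zip(alphas.tolist(), cv_err.tolist())),
        chosen_penalty=chosen,
        seed=seed,
    )


def split_train_test(cohort: Cohort, flag: str) -> tuple[Cohort, Cohort]:
    """Partition by a binary flag: flag==1 is the held-out test environment."""
    values = cohort.data[flag].to_numpy()
    uniq = set(np.unique(values[~pd.isna(values)]))
    if not uniq <= {0, 1, 0.0, 1.0}:
        raise ValueError(f"flag column {flag!r} is not binary: values {sorted(uniq)}")
    test_mask = values == 1
    if test_mask.all() or not test_mask.any():
        raise SplitError(f"flag {flag!r} puts every sample on one side")
    train, test = cohort.subset(~test_mask), cohort.subset(test_mask)
    logger.info(
        "split_train_test: %d train / %d test on flag %r", train.n, test.n, flag
    )
    return train, test


def partition_training(
    train: Cohort, variable: str, threshold: float | None = None
) -> EnvironmentSplit:
    """Split the training sample into two environments along a demographic.

    Continuous variables split at ``threshold`` (default: training median, an
    even split); binary variables split by category and need no threshold.
    """
    if train.roles.get(variable) != ROLE_DEMOGRAPHIC:
        raise ValueError(f"{variable!r} is not a demographic variable")
    values = train.data[variable].to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise SplitError(f"partition variable {variable!r} is constant")
    uniq = set(np.unique(values))
    if uniq <= {0.0, 1.0}:
        labels = np.where(values == 1, f"{variable}=1", f"{variable}=0").astype(object)
        rule = "binary category"
    else:
        thr = float(np.median(values)) if threshold is None else float(threshold)
        labels = np.where(
            values <= thr, f"{variable}<={thr:g}", f"{variable}>{thr:g}"
        ).astype(object)
        rule = f"threshold {thr:g}" + (" (median)" if threshold is None else "")
    uniq_labels = np.unique(labels)
    if len(uniq_labels) < 2:
        raise SplitError(
            f"partition on {variable!r} ({rule}) left one environment empty"
        )
    counts = {lab: int((labels == lab).sum()) for lab in uniq_labels}
    logger.info("partition_training: %r -> %s (%s)", variable, counts, rule)
    return EnvironmentSplit(
        test_mask=np.zeros(train.n, dtype=bool),
        train_env_labels=labels,
        partition_variable=variable,
        partition_rule=rule,
    )


def with_environments(train: Cohort, split: EnvironmentSplit) -> Cohort:
    """Return the training cohort with environment labels from a partition."""
    out = train.copy()
    out.env = split.train_env_labels.copy()
    return out
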