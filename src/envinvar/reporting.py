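"""End-to-end seeded pipeline and publication-shaped output tables.

``run_pipeline`` chains: complete-case filter -> (optional) lasso
pre-selection -> test/train split on the prior flag -> demographic training
partitions -> log-odds transform of each binary child -> the five estimators
-> test-environment MSE -> causal-parent voting.  Outputs are an MSE table
per child (partitions x methods, NA-capable) and a vote table per
(child, matching method), all reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from envinvar import methods as M
from envinvar.logodds import apply_child_transform
from envinvar.prep import (
    complete_case_filter,
    lasso_select,
    partition_training,
    split_train_test,
    with_environments,
)
from envinvar.scm import (
    Cohort,
    OBSERVATIONAL,
    build_scm,
    prism_preset,
    sample_environment,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
NA = "NA"


def _sigfig(x: float, digits: int = 6) -> str:
    """Fixed 6-significant-digit rendering for byte-stable CSV output."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return np.format_float_positional(
        float(x), precision=digits, unique=False, fractional=False, trim="-"
    )


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (seeds are mandatory)."""

    target: str
    children: list[str]
    test_flag: str
    partition_variables: list[str]
    methods: list[str] = field(default_factory=lambda: list(M.METHOD_NAMES))
    preset: str | None = "prism"  # or None with input_csv set
    input_csv: str | None = None
    n_samples: int = 2744
    use_lasso: bool = True
    predictors: list[str] | None = None  # explicit pool; overrides the lasso
    lasso_folds: int = 10
    alpha: float = 0.05
    tau_inv: float = 3.0
    c_pred: float = 1.5
    cv_folds: int = 5
    max_subset_size: int | None = None
    age_threshold: float | None = None
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(M.METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.preset is None and self.input_csv is None:
            raise ValueError("either a preset or an input CSV is required")
        if self.seed is None:
            raise ValueError("a seed is mandatory; unseeded runs are not supported")

    def config_hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=False)


@dataclass
class ResultsBundle:
    """All tables of one run plus provenance."""

    mse_tables: dict[str, pd.DataFrame]  # child -> partitions x methods
    vote_tables: dict[tuple[str, str], pd.DataFrame]  # (child, method) -> votes
    models: dict  # nested summary of every MethodResult
    provenance: dict


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_csv:
        return Cohort.from_csv(config.input_csv)
    if config.preset != "prism":
        raise ValueError(f"unknown preset {config.preset!r}")
    scm = build_scm(prism_preset())
    return sample_environment(scm, OBSERVATIONAL, config.n_samples, config.seed)


def _validate_columns(cohort: Cohort, config: RunConfig) -> None:
    referenced = (
        [config.target, config.test_flag]
        + config.children
        + config.partition_variables
    )
    missing = [c for c in referenced if c not in cohort.data.columns]
    if missing:
        raise ValueError(f"configured columns missing from cohort: {missing}")


def _method_summary(res: M.MethodResult) -> dict:
    return {
        "method": res.method,
        "na": res.is_na,
        "final_predictor_set": list(res.final_predictor_set)
        if res.final_predictor_set is not None
        else None,
        "empty_intersection": res.empty_intersection,
        "test_mse": res.test_mse,
        "n_tested": res.diagnostics.get("n_tested"),
        "n_accepted": res.diagnostics.get("n_accepted"),
        "accepted_subsets": [list(m.subset) for m in res.accepted_models],
    }


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> ResultsBundle:
    """Execute the full analysis; deterministic given the config's seed."""
    if cohort is None:
        cohort = _load_cohort(config)
    _validate_columns(cohort, config)
    cohort = complete_case_filter(cohort)

    if config.predictors is not None:
        # fixed predictor pool, the analogue of working from a published
        # variable list rather than re-running the selector
        missing = [p for p in config.predictors if p not in cohort.data.columns]
        if missing:
            raise ValueError(f"configured predictors missing: {missing}")
        selection = None
        selected = list(config.predictors)
    elif config.use_lasso:
        # selection on the full sample precedes the environment work,
        # mirroring the published order of operations (a leakage caveat)
        selection = lasso_select(
            cohort, config.target, n_folds=config.lasso_folds, seed=config.seed
        )
        selected = selection.selected
        logger.warning(
            "variable selection ran on the full sample before the "
            "train/test split (published order; leakage caveat)"
        )
    else:
        selection = None
        selected = cohort.predictors
    if not selected:
        raise ValueError("variable selection returned an empty predictor set")

    train, test = split_train_test(cohort, config.test_flag)
    subsets = M.enumerate_subsets(selected, max_size=config.max_subset_size)

    mse_cells: dict[str, dict[str, dict[str, object]]] = {
        child: {} for child in config.children
    }
    vote_frames: dict[tuple[str, str], dict[str, dict[str, int]]] = {}
    models_log: dict = {}

    for part_var in config.partition_variables:
        threshold = (
            config.age_threshold if part_var.upper().startswith("AGE") else None
        )
        split = partition_training(train, part_var, threshold)
        train_env = with_environments(train, split)
        for child in config.children:
            t_train, t_test, lo_models = apply_child_transform(
                train_env,
                test,
                child,
                train_predictors=selected + [config.target],
                test_predictors=list(selected),
            )
            row: dict[str, object] = {}
            for method in config.methods:
                if method == M.OLS:
                    res = M.ols_baseline(t_train, config.target, selected)
                elif method == M.ICP:
                    res = M.icp(t_train, config.target, subsets, config.alpha)
                elif method == M.SR:
                    res = M.stable_regression(
                        t_train,
                        config.target,
                        subsets,
                        config.alpha,
                        config.cv_folds,
                        config.seed,
                    )
                elif method == M.IMP:
                    res = M.imp_fit(
                        t_train,
                        child,
                        config.target,
                        subsets,
                        candidate_predictors=selected,
                        tau_inv=config.tau_inv,
                        c_pred=config.c_pred,
                    )
                else:  # IMP_inv
                    res = M.imp_inv_fit(
                        t_train,
                        child,
                        config.target,
                        subsets,
                        candidate_predictors=selected,
                        alpha=config.alpha,
                        c_pred=config.c_pred,
                    )
                res = M.predict_and_score(res, t_test, config.target)
                row[method] = NA if res.test_mse is None else res.test_mse
                logger.info(
                    "method=%s partition=%s child=%s tested=%s accepted=%s mse=%s",
                    method,
                    part_var,
                    child,
                    res.diagnostics.get("n_tested"),
                    res.diagnostics.get("n_accepted"),
                    row[method],
                )
                models_log.setdefault(part_var, {}).setdefault(child, {})[
                    method
                ] = _method_summary(res)
                if method in (M.IMP, M.IMP_INV):
                    tally = M.vote_parents([res], variables=selected)
                    vote_frames.setdefault((child, method), {})[
                        part_var
                    ] = tally.counts
            mse_cells[child][part_var] = row

    mse_tables = {
        child: pd.DataFrame.from_dict(cells, orient="index", dtype=object)[
            config.methods
        ].rename_axis("Training Environments")
        for child, cells in mse_cells.items()
    }
    vote_tables = {
        key: pd.DataFrame(cols).rename_axis("Variable")
        for key, cols in vote_frames.items()
    }
    provenance = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "package_version": __import__("envinvar").__version__,
        "seed": config.seed,
        "n_after_filter": cohort.n,
        "selected_predictors": list(selected),
        "chosen_penalty": None if selection is None else selection.chosen_penalty,
    }
    return ResultsBundle(mse_tables, vote_tables, models_log, provenance)


def write_tables(bundle: ResultsBundle, outdir) -> list[Path]:
    """Write every table as CSV (header comment carries the config hash),
    plus a JSON summary; floats fixed at 6 significant digits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# envinvar schema={SCHEMA_VERSION} config={bundle.provenance['config_hash']}\n"
    paths: list[Path] = []

    def write_df(df: pd.DataFrame, path: Path) -> None:
        rendered = df.map(lambda v: v if isinstance(v, str) else _sigfig(v))
        with open(path, "w") as fh:
            fh.write(header)
            rendered.to_csv(fh, lineterminator="\n")
        paths.append(path)

    for child, table in bundle.mse_tables.items():
        write_df(table, outdir / f"mse_table_{child}.csv")
    for (child, method), table in bundle.vote_tables.items():
        write_df(table, outdir / f"votes_{child}_{method}.csv")
    summary = outdir / "models.json"
    with open(summary, "w") as fh:
        json.dump(
            {"provenance": bundle.provenance, "models": bundle.models},
            fh,
            indent=1,
            default=float,
        )
        fh.write("\n")
    paths.append(summary)
    return paths


def read_table(path) -> pd.DataFrame:
    """Round-trip reader for tables written by :func:`write_tables`."""
    return pd.read_csv(path, comment="#", index_col=0, dtype=object)
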