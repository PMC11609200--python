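"""Linear-Gaussian structural causal models with environment-wise interventions.

Data are generated from a DAG over demographic variables, continuous predictor
scores, a continuous target, and binary child variables of the target.  Every
continuous variable is a linear function of its parents plus Gaussian noise;
binary children follow a logistic (Bernoulli) mechanism in the target and
optional covariates.  Environments are realised by intervening on mechanisms:
mean shifts, noise rescaling, coefficient replacement, or a do-style override
of the target's equation.  Child mechanisms can never be intervened on -- the
conditional law of a child given its parents is invariant by construction,
which is the modularity assumption all downstream invariance methods rest on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

SCHEMA_VERSION = "1"

ROLE_PREDICTOR = "predictor"
ROLE_TARGET = "target"
ROLE_BINARY_CHILD = "binary_child"
ROLE_CHILD_SCORE = "child_score"  # binary child after the log-odds transform
ROLE_DEMOGRAPHIC = "demographic"
ROLE_ENV_FLAG = "env_flag"

_ROLES = {
    ROLE_PREDICTOR,
    ROLE_TARGET,
    ROLE_BINARY_CHILD,
    ROLE_CHILD_SCORE,
    ROLE_DEMOGRAPHIC,
    ROLE_ENV_FLAG,
}

OBSERVATIONAL = "observational"

_INTERVENTION_KINDS = {"mean_shift", "noise_scale", "coef_replace", "target_do"}


class GraphError(ValueError):
    """The edge set is not a DAG."""


class SpecError(ValueError):
    """An SCM specification violates its invariants."""


def subseed(seed: int, label: str) -> int:
    """Deterministic per-environment sub-seed.

    Hash-derived so that adding an environment to a plan never perturbs the
    draws of existing ones.  Result is always below 2**31.
    """
    digest = hashlib.blake2s(f"{seed}|{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass(frozen=True)
class InterventionSpec:
    """One mechanism change applied in a given environment.

    kind:
        ``mean_shift``   -- add ``magnitude`` to the variable's equation
        ``noise_scale``  -- replace the variable's noise scale by ``magnitude``
        ``coef_replace`` -- replace incoming edge weights; ``magnitude`` is a
                            mapping ``source -> new weight``
        ``target_do``    -- replace the target's equation by
                            ``magnitude + noise`` (do-style shift)
    """

    variable: str
    kind: str
    magnitude: float | Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in _INTERVENTION_KINDS:
            raise SpecError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "noise_scale" and not float(self.magnitude) > 0:
            raise SpecError("noise_scale intervention requires magnitude > 0")
        if self.kind == "coef_replace" and not isinstance(self.magnitude, Mapping):
            raise SpecError("coef_replace magnitude must map source -> weight")


@dataclass(frozen=True)
class ChildSpec:
    """A binary causal child of the target with a logistic mechanism.

    C ~ Bernoulli(expit(intercept + coef_target * Y + sum_j coef_j * X_j)).
    """

    name: str
    intercept: float
    coef_target: float
    coef_covariates: Mapping[str, float] = field(default_factory=dict)
    link: str = "logistic"

    def __post_init__(self) -> None:
        if self.coef_target == 0:
            raise SpecError(f"child {self.name!r}: coef_target must be nonzero")
        if self.link != "logistic":
            raise SpecError("only the logistic link is supported")


@dataclass(frozen=True)
class DemographicSpec:
    """An exogenous demographic variable (continuous Gaussian or Bernoulli)."""

    name: str
    kind: str  # "continuous" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "binary"}:
            raise SpecError(f"demographic {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous" and not self.sd > 0:
            raise SpecError(f"demographic {self.name!r}: sd must be > 0")
        if self.kind == "binary" and not 0 < self.p < 1:
            raise SpecError(f"demographic {self.name!r}: p must lie in (0,1)")


@dataclass(frozen=True)
class SCMSpec:
    """Full description of a multi-environment linear-Gaussian SCM.

    ``edges`` carries weights between non-child continuous variables
    (demographics, predictors, and optionally target -> predictor edges for
    descendants of the target).  The target's own equation is given by
    ``target_parents``.  ``env_interventions`` maps an environment label to
    the interventions active there; the label ``"observational"`` (no
    interventions) is always available.
    """

    n_predictors: int
    target_name: str
    target_parents: Mapping[str, float]
    noise_scales: Mapping[str, float]
    children: tuple[ChildSpec, ...] = ()
    edges: tuple[tuple[str, str, float], ...] = ()
    demographics: tuple[DemographicSpec, ...] = ()
    env_interventions: Mapping[str, tuple[InterventionSpec, ...]] = field(
        default_factory=dict
    )
    predictor_names: tuple[str, ...] = ()
    env_flag: tuple[str, str] | None = None  # (flag name, source child name)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.predictor_names:
            object.__setattr__(
                self,
                "predictor_names",
                tuple(f"X{i + 1}" for i in range(self.n_predictors)),
            )
        if len(self.predictor_names) != self.n_predictors:
            raise SpecError("predictor_names length must equal n_predictors")
        self.validate()

    # -- naming helpers -------------------------------------------------
    @property
    def demographic_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.demographics)

    @property
    def child_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.children)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return self.demographic_names + self.predictor_names + (self.target_name,)

    def validate(self) -> None:
        known = set(self.continuous_names)
        child_names = set(self.child_names)
        if self.target_name in self.predictor_names:
            raise SpecError("target cannot also be a predictor")
        for name, scale in self.noise_scales.items():
            if not scale > 0:
                raise SpecError(f"noise scale for {name!r} must be > 0")
        for src, dst, _ in self.edges:
            if src not in known or dst not in known:
                raise SpecError(f"edge {src!r}->{dst!r} names unknown variable")
            if dst in self.demographic_names:
                raise SpecError("demographic variables are exogenous")
            if dst == self.target_name:
                raise SpecError("use target_parents for the target's equation")
        for parent in self.target_parents:
            if parent not in self.predictor_names:
                raise SpecError(f"target parent {parent!r} is not a predictor")
        for child in self.children:
            for cov in child.coef_covariates:
                if cov not in known:
                    raise SpecError(
                        f"child {child.name!r} covariate {cov!r} unknown"
                    )
        for label, ivs in self.env_interventions.items():
            for iv in ivs:
                if iv.variable in child_names:
                    raise SpecError(
                        f"environment {label!r}: interventions on child "
                        f"mechanisms are forbidden ({iv.variable!r})"
                    )
                if iv.variable not in known:
                    raise SpecError(
                        f"environment {label!r}: intervention names unknown "
                        f"variable {iv.variable!r}"
                    )
                if iv.kind == "target_do" and iv.variable != self.target_name:
                    raise SpecError("target_do is only legal on the target")
        if self.env_flag is not None:
            flag, source = self.env_flag
            if source not in child_names:
                raise SpecError(f"env_flag source {source!r} is not a child")
        # acyclicity over the full continuous-variable graph
        g = nx.DiGraph()
        g.add_nodes_from(self.continuous_names)
        g.add_edges_from((s, d) for s, d, _ in self.edges)
        g.add_edges_from((p, self.target_name) for p in self.target_parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphError(f"edge set contains a cycle: {cycle}")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "n_predictors": self.n_predictors,
            "predictor_names": list(self.predictor_names),
            "target_name": self.target_name,
            "target_parents": dict(self.target_parents),
            "noise_scales": dict(self.noise_scales),
            "edges": [list(e) for e in self.edges],
            "demographics": [vars(d).copy() for d in self.demographics],
            "children": [
                {
                    "name": c.name,
                    "intercept": c.intercept,
                    "coef_target": c.coef_target,
                    "coef_covariates": dict(c.coef_covariates),
                    "link": c.link,
                }
                for c in self.children
            ],
            "env_interventions": {
                label: [
                    {
                        "variable": iv.variable,
                        "kind": iv.kind,
                        "magnitude": dict(iv.magnitude)
                        if isinstance(iv.magnitude, Mapping)
                        else iv.magnitude,
                    }
                    for iv in ivs
                ]
                for label, ivs in self.env_interventions.items()
            },
            "env_flag": list(self.env_flag) if self.env_flag else None,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SCMSpec":
        return cls(
            n_predictors=d["n_predictors"],
            predictor_names=tuple(d.get("predictor_names") or ()),
            target_name=d["target_name"],
            target_parents=dict(d["target_parents"]),
            noise_scales=dict(d["noise_scales"]),
            edges=tuple(tuple(e) for e in d.get("edges", ())),
            demographics=tuple(
                DemographicSpec(**dd) for dd in d.get("demographics", ())
            ),
            children=tuple(ChildSpec(**cd) for cd in d.get("children", ())),
            env_interventions={
                label: tuple(InterventionSpec(**ivd) for ivd in ivs)
                for label, ivs in d.get("env_interventions", {}).items()
            },
            env_flag=tuple(d["env_flag"]) if d.get("env_flag") else None,
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "SCMSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """Samples-by-variables table with variable roles and environment labels."""

    data: pd.DataFrame
    roles: dict[str, str]
    env: np.ndarray  # per-sample environment label

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if set(self.roles) != set(cols):
            raise SpecError("role map must cover every column exactly once")
        bad = {c: r for c, r in self.roles.items() if r not in _ROLES}
        if bad:
            raise SpecError(f"unknown roles: {bad}")
        self.env = np.asarray(self.env)
        if len(self.env) != len(self.data):
            raise SpecError("env labels must align with samples")

    @property
    def n(self) -> int:
        return len(self.data)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]

    @property
    def predictors(self) -> list[str]:
        return self.columns_with_role(ROLE_PREDICTOR)

    @property
    def target(self) -> str:
        t = self.columns_with_role(ROLE_TARGET)
        if len(t) != 1:
            raise SpecError(f"cohort must have exactly one target, found {t}")
        return t[0]

    def env_labels(self) -> list[str]:
        seen: list[str] = []
        for label in self.env:
            if label not in seen:
                seen.append(label)
        return seen

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(
            self.data.loc[mask].reset_index(drop=True),
            dict(self.roles),
            self.env[mask],
        )

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), dict(self.roles), self.env.copy())

    # -- CSV + JSON sidecar round trip ----------------------------------
    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["env_label"] = self.env
        out.to_csv(path, index=False)
        sidecar = str(path) + ".roles.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"schema_version": SCHEMA_VERSION, "roles": self.roles}, fh, indent=1
            )

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        with open(str(path) + ".roles.json") as fh:
            sidecar = json.load(fh)
        env = df.pop("env_label").to_numpy(dtype=object)
        return cls(df, sidecar["roles"], env)


class SCM:
    """A sampling-ready structural causal model built from an :class:`SCMSpec`."""

    def __init__(self, spec: SCMSpec):
        self.spec = spec
        g = nx.DiGraph()
        g.add_nodes_from(spec.continuous_names)
        g.add_edges_from((s, d) for s, d, _ in spec.edges)
        g.add_edges_from((p, spec.target_name) for p in spec.target_parents)
        # lexicographic tie-break keeps the order reproducible across runs
        self.topo_order: list[str] = list(nx.lexicographical_topological_sort(g))
        self._graph = g
        # base equations: variable -> (parent weights, noise scale, shift)
        eqs: dict[str, dict] = {}
        for d in spec.demographics:
            eqs[d.name] = {"demo": d}
        for name in spec.predictor_names:
            eqs[name] = {
                "parents": {},
                "scale": spec.noise_scales.get(name, 1.0),
                "shift": 0.0,
                "do": None,
            }
        eqs[spec.target_name] = {
            "parents": dict(spec.target_parents),
            "scale": spec.noise_scales.get(spec.target_name, 1.0),
            "shift": 0.0,
            "do": None,
        }
        for src, dst, w in spec.edges:
            eqs[dst]["parents"][src] = w
        self._base_eqs = eqs

    def environment_equations(self, env_label: str) -> dict[str, dict]:
        """Equations with the environment's interventions applied."""
        if env_label != OBSERVATIONAL and env_label not in self.spec.env_interventions:
            raise SpecError(f"unknown environment {env_label!r}")
        eqs = {
            name: (eq if "demo" in eq else {**eq, "parents": dict(eq["parents"])})
            for name, eq in self._base_eqs.items()
        }
        for iv in self.spec.env_interventions.get(env_label, ()):
            eq = eqs[iv.variable]
            if "demo" in eq:
                raise SpecError("interventions on demographics are not supported")
            if iv.kind == "mean_shift":
                eq["shift"] += float(iv.magnitude)
            elif iv.kind == "noise_scale":
                eq["scale"] = float(iv.magnitude)
            elif iv.kind == "coef_replace":
                eq["parents"].update(
                    {s: float(w) for s, w in iv.magnitude.items()}
                )
            elif iv.kind == "target_do":
                eq["do"] = float(iv.magnitude)
        return eqs

    def child_linear_predictor(
        self, child: ChildSpec, values: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        eta = child.intercept + child.coef_target * values[self.spec.target_name]
        for cov, w in child.coef_covariates.items():
            eta = eta + w * values[cov]
        return eta


def build_scm(spec: SCMSpec) -> SCM:
    """Validate a spec and return a sampling-ready model."""
    spec.validate()
    return SCM(spec)


def sample_environment(scm: SCM, env_label: str, n: int, seed: int) -> Cohort:
    """Draw ``n`` i.i.d. samples from one environment.

    Unintervened mechanisms are identical in distribution across environments;
    children are Bernoulli draws through the logistic link.  Fully
    deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = scm.spec
    rng = np.random.default_rng(seed)
    eqs = scm.environment_equations(env_label)
    values: dict[str, np.ndarray] = {}
    for name in scm.topo_order:
        eq = eqs[name]
        if "demo" in eq:
            d: DemographicSpec = eq["demo"]
            if d.kind == "continuous":
                values[name] = d.mean + d.sd * rng.standard_normal(n)
            else:
                values[name] = rng.binomial(1, d.p, n).astype(float)
            continue
        noise = eq["scale"] * rng.standard_normal(n)
        if eq["do"] is not None:
            values[name] = eq["do"] + noise
        else:
            v = np.full(n, eq["shift"], dtype=float)
            for parent, w in eq["parents"].items():
                v = v + w * values[parent]
            values[name] = v + noise
    roles: dict[str, str] = {}
    for d in spec.demographics:
        roles[d.name] = ROLE_DEMOGRAPHIC
    for name in spec.predictor_names:
        roles[name] = ROLE_PREDICTOR
    roles[spec.target_name] = ROLE_TARGET
    for child in spec.children:
        eta = scm.child_linear_predictor(child, values)
        values[child.name] = rng.binomial(1, expit(eta)).astype(float)
        roles[child.name] = ROLE_BINARY_CHILD
    if spec.env_flag is not None:
        flag, source = spec.env_flag
        child = next(c for c in spec.children if c.name == source)
        eta = scm.child_linear_predictor(child, values)
        values[flag] = rng.binomial(1, expit(eta)).astype(float)
        roles[flag] = ROLE_ENV_FLAG
    order = [c for c in scm.topo_order] + [c.name for c in spec.children]
    if spec.env_flag is not None:
        order.append(spec.env_flag[0])
    df = pd.DataFrame({name: values[name] for name in order})
    return Cohort(df, roles, np.full(n, env_label, dtype=object))


def sample_multi_env(
    scm: SCM, env_plan: Mapping[str, int], seed: int
) -> Cohort:
    """Concatenate per-environment samples; sub-seeds derived from ``seed``."""
    if not env_plan:
        raise ValueError("environment plan is empty")
    parts = [
        sample_environment(scm, label, n, subseed(seed, label))
        for label, n in env_plan.items()
    ]
    df = pd.concat([p.data for p in parts], ignore_index=True)
    env = np.concatenate([p.env for p in parts])
    return Cohort(df, parts[0].roles, env)


def true_parents(scm: SCM, variable: str) -> set[str]:
    """Ground-truth parent set of ``variable`` (test oracle)."""
    spec = scm.spec
    if variable == spec.target_name:
        return set(spec.target_parents)
    for child in spec.children:
        if child.name == variable:
            return {spec.target_name} | set(child.coef_covariates)
    if variable in spec.continuous_names:
        return {s for s, d, _ in spec.edges if d == variable}
    if spec.env_flag is not None and variable == spec.env_flag[0]:
        _, source = spec.env_flag
        return true_parents(scm, source)
    raise ValueError(f"unknown variable {variable!r}")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Instrument-scale predictor names; the first seven are the active set that
#: influences the target and/or the children.
PRISM_PREDICTORS = (
    "I-PANAS-SF negative affect",
    "PHQ-9 suicide ideation item",
    "PHQ-9",
    "ISEL appraisal",
    "ES external",
    "ES internal",
    "DES-IV inward hostility",
    "DES-IV guilt",
    "DES-IV shame",
    "ES total latent",
    "ISEL belonging",
    "ISEL tangible",
    "I-PANAS-SF positive affect",
    "PC-PTSD",
    "ACSS-FAD",
    "BRFLI",
    "ISI",
)

#: the seven-variable active pool (the analogue of the published selection)
PRISM_ACTIVE = PRISM_PREDICTORS[:7]

PRISM_TARGET = "SCS-R"
PRISM_SI_PREVALENCE = 0.288
PRISM_SB_PREVALENCE = 0.088
PRISM_DEFAULT_N = 2744


def _calibrate_intercept(eta_no_intercept: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == prevalence (monotone in b0)."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta_no_intercept))) - prevalence

    return brentq(gap, -30.0, 30.0, xtol=1e-10)


@lru_cache(maxsize=1)
def prism_preset() -> SCMSpec:
    """SCM emulating the primary-care cohort's variable layout.

    Seventeen correlated continuous risk/protective scores, a continuous
    suicidal-belief target driven by a subset of them, binary suicidal-ideation
    (SI, prevalence ~0.288) and suicidal-behavior (SB, prevalence ~0.088)
    children of the target, demographic columns AGE (continuous, median 28),
    GENDER and RACE (binary), and a prior-SI environment flag drawn from the
    SI mechanism's latent propensity.  Child intercepts are calibrated
    numerically (fixed internal seed) so the marginal prevalences hit their
    targets; the predictors' correlation structure is a modelling choice, not
    an estimate of any real cohort.
    """
    names = PRISM_PREDICTORS
    demographics = (
        DemographicSpec("AGE", "continuous", mean=28.0, sd=8.0),
        DemographicSpec("GENDER", "binary", p=0.49),
        DemographicSpec("RACE", "binary", p=0.67),
    )
    # hub-and-spoke correlation: general-distress scales feed related scales;
    # demographics induce mild covariate shift across partition environments
    edges = [
        ("PHQ-9", "I-PANAS-SF negative affect", 0.50),
        ("PHQ-9", "ISI", 0.45),
        ("PHQ-9", "ES internal", 0.40),
        ("PHQ-9", "PHQ-9 suicide ideation item", 0.55),
        ("PHQ-9", "PC-PTSD", 0.40),
        ("ES external", "ES internal", 0.35),
        ("ES external", "ES total latent", 0.60),
        ("ES internal", "ES total latent", 0.40),
        ("I-PANAS-SF negative affect", "DES-IV guilt", 0.45),
        ("DES-IV guilt", "DES-IV shame", 0.55),
        ("DES-IV guilt", "DES-IV inward hostility", 0.45),
        ("ISEL appraisal", "ISEL belonging", 0.50),
        ("ISEL appraisal", "ISEL tangible", 0.40),
        ("ISEL belonging", "I-PANAS-SF positive affect", 0.35),
        ("ISEL appraisal", "BRFLI", 0.35),
        ("AGE", "PHQ-9", -0.02),
        ("AGE", "ACSS-FAD", 0.015),
        ("GENDER", "ES external", 0.25),
        ("GENDER", "ACSS-FAD", 0.30),
        ("RACE", "ISEL tangible", 0.20),
        ("RACE", "PC-PTSD", -0.15),
    ]
    target_parents = {
        "I-PANAS-SF negative affect": 0.60,
        "PHQ-9": 0.80,
        "ES internal": 0.55,
        "ES external": 0.35,
        "ISEL appraisal": -0.50,
    }
    noise_scales = {name: 1.0 for name in names}
    noise_scales[PRISM_TARGET] = 1.0
    base = SCMSpec(
        n_predictors=len(names),
        predictor_names=names,
        target_name=PRISM_TARGET,
        target_parents=target_parents,
        noise_scales=noise_scales,
        edges=tuple(edges),
        demographics=demographics,
        children=(),
        env_interventions={},
        seed=0,
    )
    # calibrate child intercepts against the continuous system's actual
    # distribution (deterministic internal Monte Carlo)
    probe = sample_environment(build_scm(base), OBSERVATIONAL, 200_000, seed=987_654)
    si_covs = {"PHQ-9 suicide ideation item": 0.45, "DES-IV inward hostility": 0.25}
    sb_covs = {"PHQ-9 suicide ideation item": 0.35, "ACSS-FAD": 0.20}
    children = []
    for name, coef_target, covs, prev in (
        ("SI", 0.55, si_covs, PRISM_SI_PREVALENCE),
        ("SB", 0.70, sb_covs, PRISM_SB_PREVALENCE),
    ):
        eta = coef_target * probe.data[PRISM_TARGET].to_numpy()
        for cov, w in covs.items():
            eta = eta + w * probe.data[cov].to_numpy()
        b0 = _calibrate_intercept(eta, prev)
        children.append(
            ChildSpec(name, intercept=b0, coef_target=coef_target, coef_covariates=covs)
        )
    return replace(base, children=tuple(children), env_flag=("prior_SI", "SI"))


def parent_recovery_preset(seed: int = 0) -> SCMSpec:
    """Small benchmark where parent-based invariance holds across training.

    Y = 1.0*X1 + 0.8*X2 + N(0,1); X3 is a non-parent correlated with X1;
    Z is a weak proxy (descendant) of Y that is highly predictive in
    training.  Environment ``e2`` intervenes on X1, X2 and Z but never on
    Y's mechanism, so exactly the parent supersets without Z stay invariant
    across training.  Environment ``test`` intervenes on the target (mean
    shift) and decouples the proxy from it (its edge weight replaced by 0,
    plus a mean shift): a pooled regression that leans on the proxy transfers
    badly, parent-only models carry only the target-shift bias, and
    child-matching models absorb the target shift itself.
    """
    return SCMSpec(
        n_predictors=4,
        predictor_names=("X1", "X2", "X3", "Z"),
        target_name="Y",
        target_parents={"X1": 1.0, "X2": 0.8},
        noise_scales={"X1": 1.0, "X2": 1.0, "X3": 1.0, "Z": 1.0, "Y": 1.0},
        edges=(("X1", "X3", 0.5), ("Y", "Z", 0.5)),
        children=(ChildSpec("C", intercept=-0.4, coef_target=1.5),),
        env_interventions={
            "e1": (),
            "e2": (
                InterventionSpec("X1", "mean_shift", 1.0),
                InterventionSpec("X2", "mean_shift", -1.0),
                InterventionSpec("X2", "noise_scale", 1.5),
                InterventionSpec("Z", "mean_shift", 2.0),
            ),
            "test": (
                InterventionSpec("Y", "mean_shift", 2.0),
                InterventionSpec("Z", "coef_replace", {"Y": 0.0}),
                InterventionSpec("Z", "mean_shift", -3.0),
            ),
        },
        seed=seed,
    )


def target_shift_preset(seed: int = 0) -> SCMSpec:
    """Benchmark with interventions on the target across all environments.

    Parent-based invariance fails (Y's own mechanism shifts between training
    environments), the regime the invariant-matching construction is built
    for; the child mechanism stays invariant by construction.  The test
    environment applies a do-style override of the target.
    """
    return SCMSpec(
        n_predictors=3,
        predictor_names=("X1", "X2", "X3"),
        target_name="Y",
        target_parents={"X1": 1.0, "X2": 0.8},
        noise_scales={"X1": 1.0, "X2": 1.0, "X3": 1.0, "Y": 1.0},
        edges=(("X1", "X3", 0.5),),
        children=(ChildSpec("C", intercept=-0.4, coef_target=1.5),),
        env_interventions={
            "e1": (),
            "e2": (
                InterventionSpec("Y", "mean_shift", 2.0),
                InterventionSpec("X1", "mean_shift", 0.8),
            ),
            "test": (InterventionSpec("Y", "target_do", 3.0),),
        },
        seed=seed,
    )


def voting_preset(seed: int = 0) -> SCMSpec:
    """Single-parent benchmark for the causal-parent voting procedure.

    Y = 1.5*X1 + N(0, 0.8); X2 (correlated with X1) and X3 are inert; the
    binary child C depends on Y alone.  The two training environments differ
    by a mean shift and a noise rescaling of the target, which changes the
    slope of the child's predictor-only log-odds score between environments.
    Subsets containing the parent can represent the target directly and stay
    matched; subsets without it must lean on the matching score, whose
    environment-specific scale breaks stage-two coefficient invariance, so
    the parent dominates the vote.  Intended to be run with the child scored
    from the predictors alone in every context.
    """
    return SCMSpec(
        n_predictors=3,
        predictor_names=("X1", "X2", "X3"),
        target_name="Y",
        target_parents={"X1": 1.5},
        noise_scales={"X1": 1.0, "X2": 1.0, "X3": 1.0, "Y": 0.8},
        edges=(("X1", "X2", 0.5),),
        children=(ChildSpec("C", intercept=-0.3, coef_target=1.2),),
        env_interventions={
            "e1": (),
            "e2": (
                InterventionSpec("Y", "mean_shift", 2.5),
                InterventionSpec("Y", "noise_scale", 2.0),
            ),
        },
        seed=seed,
    )
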