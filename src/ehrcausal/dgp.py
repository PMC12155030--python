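"""Structural data generator for EHR-like cohorts with differential monitoring.

The observed data unit is ``O = (W, A, Delta, Delta * Y)``: baseline
covariates ``W``, a binary treatment ``A`` confounded by ``W``, a binary
monitoring indicator ``Delta`` that may depend on both ``W`` and ``A``, and a
binary outcome ``Y`` that is generated for everyone but *recorded* only for
monitored patients (``Delta = 1``).  This mimics electronic-health-record
cohorts in which a condition is documented only when the patient interacts
with the healthcare system.

Three logistic structural equations drive the simulation::

    logit P(A = 1 | W)        = a0 + a' W
    logit P(Delta = 1 | A, W) = d0 + d' W + dA * A
    logit P(Y = 1 | A, W)     = b0 + bA * A + b' W + (c' W) * A + s' W^2

An optional post-treatment binary mediator ``M`` can be switched on, in which
case ``M ~ Bernoulli(expit(m0 + mA * A + m' W))`` and the outcome logit gains
``gamma_M * M``.  Counterfactual outcome columns ``Y1 = Y(a=1, delta=1)`` and
``Y0 = Y(a=0, delta=1)`` are carried alongside each simulated cohort; they are
reachable only through a dedicated accessor so that estimators can never touch
them.

The module also computes the *true* estimands of each configuration: the
marginal causal risk ratio ``Psi = E[Y(1, delta=1)] / E[Y(0, delta=1)]`` and
the quantity targeted by a complete-case ("restrict") analysis, which
standardizes the same conditional means over the covariate distribution of the
monitored subpopulation ``W | Delta = 1``.  With purely binary covariates both
are evaluated by exhaustive summation over the covariate support; otherwise by
large-sample Monte-Carlo integration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "LinearCoefs",
    "MonitoringCoefs",
    "OutcomeCoefs",
    "MediatorSpec",
    "DGPConfig",
    "CohortTable",
    "TrueEstimands",
    "ConfigurationError",
    "simulate_cohort",
    "true_estimands",
    "scenario_preset",
    "SCENARIO_NAMES",
    "write_cohort_csv",
    "read_cohort_csv",
    "config_from_yaml",
    "config_to_yaml",
]

# Structural probabilities are kept strictly inside (0, 1); the clamp is far
# below any probability a realistic coefficient set produces.
PROB_CLAMP = 1.0e-6

HIDDEN_COLUMNS = ("M", "Y1", "Y0")


class ConfigurationError(ValueError):
    """A DGP configuration block is malformed (wrong length, bad values)."""


def _clamp(p: np.ndarray | float) -> np.ndarray:
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: ``binary`` with success probability ``p``, or
    ``normal`` with ``mean``/``sd``."""

    kind: str
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "normal"):
            raise ConfigurationError(
                f"covariate kind must be 'binary' or 'normal', got {self.kind!r}"
            )
        if self.kind == "binary" and not 0.0 < self.p < 1.0:
            raise ConfigurationError(f"binary covariate needs 0 < p < 1, got {self.p}")
        if self.kind == "normal" and self.sd <= 0.0:
            raise ConfigurationError(f"normal covariate needs sd > 0, got {self.sd}")


@dataclass(frozen=True)
class LinearCoefs:
    """Intercept plus per-covariate slopes on the logit scale."""

    intercept: float
    main: tuple[float, ...]

    def logit(self, W: np.ndarray) -> np.ndarray:
        return self.intercept + W @ np.asarray(self.main)


@dataclass(frozen=True)
class MonitoringCoefs(LinearCoefs):
    """Monitoring equation: intercept + covariate slopes + treatment slope."""

    treatment: float = 0.0

    def logit_ad(self, A: np.ndarray | float, W: np.ndarray) -> np.ndarray:
        return self.logit(W) + self.treatment * A


@dataclass(frozen=True)
class OutcomeCoefs:
    """Outcome equation: intercept, treatment main effect, covariate main
    effects, treatment-by-covariate interactions and optional squared terms."""

    intercept: float
    treatment: float
    main: tuple[float, ...]
    interaction: tuple[float, ...] = ()
    squared: tuple[float, ...] = ()

    def logit_aw(self, a: np.ndarray | float, W: np.ndarray) -> np.ndarray:
        p = W.shape[1]
        inter = np.asarray(self.interaction) if self.interaction else np.zeros(p)
        sq = np.asarray(self.squared) if self.squared else np.zeros(p)
        return (
            self.intercept
            + self.treatment * a
            + W @ np.asarray(self.main)
            + a * (W @ inter)
            + (W**2) @ sq
        )


@dataclass(frozen=True)
class MediatorSpec:
    """Post-treatment binary mediator M ~ expit(intercept + treatment*A + main'W);
    the outcome logit gains ``outcome_coef * M``."""

    intercept: float
    treatment: float
    main: tuple[float, ...]
    outcome_coef: float

    def logit_aw(self, a: np.ndarray | float, W: np.ndarray) -> np.ndarray:
        return self.intercept + self.treatment * a + W @ np.asarray(self.main)


@dataclass(frozen=True)
class DGPConfig:
    """Full parameterization of the structural equations."""

    covariates: tuple[CovariateSpec, ...]
    treatment_coefs: LinearCoefs
    monitoring_coefs: MonitoringCoefs
    outcome_coefs: OutcomeCoefs
    mediator: Optional[MediatorSpec] = None
    seed: int = 0

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def mediator_enabled(self) -> bool:
        return self.mediator is not None

    def __post_init__(self) -> None:
        p = self.n_covariates
        if p < 1:
            raise ConfigurationError("at least one covariate is required")

        def check(name: str, coefs: Sequence[float], expected: int) -> None:
            if len(coefs) not in (0, expected):
                raise ConfigurationError(
                    f"{name}: expected {expected} coefficients, got {len(coefs)}"
                )

        check("treatment_coefs.main", self.treatment_coefs.main, p)
        if len(self.treatment_coefs.main) != p:
            raise ConfigurationError("treatment_coefs.main must have one entry per covariate")
        check("monitoring_coefs.main", self.monitoring_coefs.main, p)
        if len(self.monitoring_coefs.main) != p:
            raise ConfigurationError("monitoring_coefs.main must have one entry per covariate")
        check("outcome_coefs.main", self.outcome_coefs.main, p)
        if len(self.outcome_coefs.main) != p:
            raise ConfigurationError("outcome_coefs.main must have one entry per covariate")
        check("outcome_coefs.interaction", self.outcome_coefs.interaction, p)
        check("outcome_coefs.squared", self.outcome_coefs.squared, p)
        if self.mediator is not None:
            check("mediator.main", self.mediator.main, p)
            if len(self.mediator.main) != p:
                raise ConfigurationError("mediator.main must have one entry per covariate")

    @property
    def all_binary(self) -> bool:
        return all(c.kind == "binary" for c in self.covariates)

    # --- conditional-mean helpers used both for simulation and for truth ---

    def p_treatment(self, W: np.ndarray) -> np.ndarray:
        return _clamp(expit(self.treatment_coefs.logit(W)))

    def p_monitoring(self, a: np.ndarray | float, W: np.ndarray) -> np.ndarray:
        return _clamp(expit(self.monitoring_coefs.logit_ad(a, W)))

    def p_outcome(self, a: np.ndarray | float, W: np.ndarray,
                  m: np.ndarray | float | None = None) -> np.ndarray:
        logit = self.outcome_coefs.logit_aw(a, W)
        if self.mediator is not None:
            if m is None:
                raise ValueError("mediator enabled: outcome probability needs m")
            logit = logit + self.mediator.outcome_coef * np.asarray(m)
        return _clamp(expit(logit))

    def mean_outcome(self, a: np.ndarray | float, W: np.ndarray) -> np.ndarray:
        """E[Y(a, delta=1) | W], integrating the mediator out when present."""
        if self.mediator is None:
            return self.p_outcome(a, W)
        pm = _clamp(expit(self.mediator.logit_aw(a, W)))
        return pm * self.p_outcome(a, W, 1.0) + (1.0 - pm) * self.p_outcome(a, W, 0.0)


class CohortTable:
    """A simulated or loaded patient table.

    Estimators receive only the observed frame (``W1..Wp, A, Delta, Y`` with
    ``Y`` missing whenever ``Delta = 0``).  Counterfactual columns and the
    mediator live in a hidden frame reachable only via
    :meth:`counterfactual_frame`, which truth calculators and the
    mediator-conditioning demonstration use.
    """

    def __init__(self, data: pd.DataFrame, n_covariates: int):
        self._data = data.reset_index(drop=True)
        self.n_covariates = n_covariates

    @property
    def covariate_columns(self) -> list[str]:
        return [f"W{j + 1}" for j in range(self.n_covariates)]

    @property
    def n(self) -> int:
        return len(self._data)

    def observed_frame(self) -> pd.DataFrame:
        cols = self.covariate_columns + ["A", "Delta", "Y"]
        return self._data[cols].copy()

    def counterfactual_frame(self) -> pd.DataFrame:
        cols = [c for c in HIDDEN_COLUMNS if c in self._data.columns]
        if not cols:
            raise ValueError("this cohort carries no counterfactual columns")
        return self._data[cols].copy()

    @property
    def has_truth_columns(self) -> bool:
        return any(c in self._data.columns for c in HIDDEN_COLUMNS)

    def full_frame(self) -> pd.DataFrame:
        return self._data.copy()


def simulate_cohort(config: DGPConfig, n: int, seed: int | None = None) -> CohortTable:
    """Draw ``n`` i.i.d. patients from the structural equations.

    Generation order: W -> A -> (M if enabled) -> Y(1), Y(0) -> factual
    Y = Y(A) -> Delta -> mask Y where Delta = 0.  Counterfactual outcomes share
    a single uniform draw per patient, so factual consistency ``Y = Y(A)``
    holds record by record.  Identical ``(config, n, seed)`` give identical
    output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    p = config.n_covariates
    W = np.empty((n, p))
    for j, spec in enumerate(config.covariates):
        if spec.kind == "binary":
            W[:, j] = (rng.random(n) < spec.p).astype(float)
        else:
            W[:, j] = rng.normal(spec.mean, spec.sd, size=n)

    A = (rng.random(n) < config.p_treatment(W)).astype(int)

    columns: dict[str, np.ndarray] = {
        f"W{j + 1}": W[:, j] for j in range(p)
    }
    columns["A"] = A

    if config.mediator is not None:
        uM = rng.random(n)
        M1 = (uM < _clamp(expit(config.mediator.logit_aw(1.0, W)))).astype(int)
        M0 = (uM < _clamp(expit(config.mediator.logit_aw(0.0, W)))).astype(int)
        M = np.where(A == 1, M1, M0)
        uY = rng.random(n)
        Y1 = (uY < config.p_outcome(1.0, W, M1)).astype(int)
        Y0 = (uY < config.p_outcome(0.0, W, M0)).astype(int)
    else:
        M = None
        uY = rng.random(n)
        Y1 = (uY < config.p_outcome(1.0, W)).astype(int)
        Y0 = (uY < config.p_outcome(0.0, W)).astype(int)

    Y = np.where(A == 1, Y1, Y0)
    Delta = (rng.random(n) < config.p_monitoring(A.astype(float), W)).astype(int)

    columns["Delta"] = Delta
    y_obs = pd.array(Y, dtype="Int64")
    y_obs[Delta == 0] = pd.NA
    columns["Y"] = y_obs
    if M is not None:
        columns["M"] = M
    columns["Y1"] = Y1
    columns["Y0"] = Y0

    return CohortTable(pd.DataFrame(columns), n_covariates=p)


@dataclass(frozen=True)
class TrueEstimands:
    """True causal quantities of a configuration.

    ``risk_ratio`` is the marginal causal risk ratio
    ``Psi = E[Y(1, delta=1)] / E[Y(0, delta=1)]`` standardized over the full
    covariate distribution; ``restrict_target`` standardizes the same
    conditional means over ``W | Delta = 1``, i.e. the quantity a complete-case
    analysis converges to.  The mean-of-ratios variants
    ``E[ E(Y|A=1,W) / E(Y|A=0,W) ]`` are exposed as diagnostics only.
    """

    psi1: float
    psi0: float
    risk_ratio: float
    restrict_target: float
    mean_of_ratios: float
    mean_of_ratios_restrict: float
    method: str


def _covariate_support(config: DGPConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive (support, probability) grid for all-binary covariates."""
    probs = [c.p for c in config.covariates]
    rows, weights = [], []
    for cell in itertools.product((0.0, 1.0), repeat=len(probs)):
        w = 1.0
        for val, pj in zip(cell, probs):
            w *= pj if val == 1.0 else 1.0 - pj
        rows.append(cell)
        weights.append(w)
    return np.asarray(rows), np.asarray(weights)


def true_estimands(
    config: DGPConfig, mc_n: int = 1_000_000, mc_seed: int = 987_654_321
) -> TrueEstimands:
    """Compute the true estimands: exactly (exhaustive sum over the covariate
    support) when every covariate is binary, else by Monte-Carlo integration
    over ``mc_n`` covariate draws with a dedicated seed."""
    if config.all_binary:
        W, fw = _covariate_support(config)
        method = f"exact-enumeration(cells={len(fw)})"
    else:
        rng = np.random.default_rng(mc_seed)
        cols = []
        for spec in config.covariates:
            if spec.kind == "binary":
                cols.append((rng.random(mc_n) < spec.p).astype(float))
            else:
                cols.append(rng.normal(spec.mean, spec.sd, size=mc_n))
        W = np.column_stack(cols)
        fw = np.full(mc_n, 1.0 / mc_n)
        method = f"monte-carlo(n={mc_n}, seed={mc_seed})"

    q1 = config.mean_outcome(1.0, W)
    q0 = config.mean_outcome(0.0, W)

    psi1 = float(fw @ q1)
    psi0 = float(fw @ q0)

    # P(Delta = 1 | W), marginalizing the treatment.
    pA = config.p_treatment(W)
    p_delta = pA * config.p_monitoring(1.0, W) + (1.0 - pA) * config.p_monitoring(0.0, W)
    fw_delta = fw * p_delta
    fw_delta = fw_delta / fw_delta.sum()

    restrict_target = float((fw_delta @ q1) / (fw_delta @ q0))

    ratios = q1 / q0
    return TrueEstimands(
        psi1=psi1,
        psi0=psi0,
        risk_ratio=psi1 / psi0,
        restrict_target=restrict_target,
        mean_of_ratios=float(fw @ ratios),
        mean_of_ratios_restrict=float(fw_delta @ ratios),
        method=method,
    )


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------
# Coefficient values are frozen here; each preset satisfies its scenario
# contract (checked by the test suite against the exhaustive-sum oracle):
#
# figure1      differential monitoring depending on (W, A) plus a
#              treatment-by-covariate interaction, so the complete-case
#              ("restrict") target differs from the marginal risk ratio.
# figure3_null exactly null treatment effect with quadratic confounding
#              through a continuous covariate, so a main-terms logistic
#              outcome model is misspecified while the treatment is
#              confounded by W.
# mediator_conditioning
#              treatment affects the outcome only through a post-treatment
#              binary mediator; conditioning on the mediator (as
#              diagnosis-based cohort sampling does) biases the estimate.
# random_monitoring
#              monitoring is a coin flip with P(Delta=1)=0.7, independent of
#              everything, so restrict and intervene targets coincide.

SCENARIO_NAMES = ("figure1", "figure3_null", "mediator_conditioning", "random_monitoring")


def scenario_preset(name: str) -> DGPConfig:
    """Return the frozen configuration of a named study scenario."""
    if name == "figure1":
        return DGPConfig(
            covariates=(
                CovariateSpec("binary", p=0.5),
                CovariateSpec("binary", p=0.4),
                CovariateSpec("binary", p=0.3),
            ),
            treatment_coefs=LinearCoefs(intercept=-0.4, main=(0.8, 0.5, -0.3)),
            monitoring_coefs=MonitoringCoefs(
                intercept=-0.4, main=(1.6, 1.0, 0.0), treatment=0.7
            ),
            outcome_coefs=OutcomeCoefs(
                intercept=-1.6,
                treatment=0.9,
                main=(0.8, 0.6, 0.4),
                interaction=(-1.6, 0.0, 0.0),
            ),
            seed=20_260_101,
        )
    if name == "figure3_null":
        return DGPConfig(
            covariates=(
                CovariateSpec("binary", p=0.5),
                CovariateSpec("binary", p=0.35),
                CovariateSpec("normal", mean=0.0, sd=1.0),
            ),
            treatment_coefs=LinearCoefs(intercept=-0.9, main=(0.5, -0.4, 1.1)),
            monitoring_coefs=MonitoringCoefs(
                intercept=0.9, main=(0.4, 0.0, 0.3), treatment=0.4
            ),
            outcome_coefs=OutcomeCoefs(
                intercept=-1.4,
                treatment=0.0,
                main=(0.5, 0.4, 0.4),
                interaction=(0.0, 0.0, 0.0),
                squared=(0.0, 0.0, 0.9),
            ),
            seed=20_260_102,
        )
    if name == "mediator_conditioning":
        return DGPConfig(
            covariates=(
                CovariateSpec("binary", p=0.5),
                CovariateSpec("binary", p=0.4),
            ),
            treatment_coefs=LinearCoefs(intercept=-0.2, main=(0.5, -0.4)),
            monitoring_coefs=MonitoringCoefs(
                intercept=2.2, main=(0.0, 0.0), treatment=0.0
            ),
            outcome_coefs=OutcomeCoefs(
                intercept=-2.0,
                treatment=0.0,
                main=(0.5, 0.4),
            ),
            mediator=MediatorSpec(
                intercept=-1.0, treatment=1.5, main=(0.6, 0.0), outcome_coef=1.8
            ),
            seed=20_260_103,
        )
    if name == "random_monitoring":
        logit_07 = float(np.log(0.7 / 0.3))
        return DGPConfig(
            covariates=(
                CovariateSpec("binary", p=0.5),
                CovariateSpec("binary", p=0.4),
            ),
            treatment_coefs=LinearCoefs(intercept=-0.3, main=(0.7, 0.4)),
            monitoring_coefs=MonitoringCoefs(
                intercept=logit_07, main=(0.0, 0.0), treatment=0.0
            ),
            outcome_coefs=OutcomeCoefs(
                intercept=-1.4,
                treatment=0.6,
                main=(0.6, 0.5),
            ),
            seed=20_260_104,
        )
    raise ValueError(
        f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
    )


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: CohortTable, path, with_truth: bool = False) -> None:
    """Write the patient table.

    Header is ``W1,...,Wp,A,Delta,Y[,M,Y1,Y0]``; the ``Y`` field is empty when
    ``Delta = 0``.  Hidden columns are written only when ``with_truth`` is set.
    """
    if with_truth and cohort.has_truth_columns:
        df = cohort.full_frame()
    else:
        df = cohort.observed_frame()
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> CohortTable:
    """Read a patient table written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    w_cols = [c for c in df.columns if c.startswith("W")]
    for required in ("A", "Delta", "Y"):
        if required not in df.columns:
            raise ValueError(f"cohort CSV missing required column {required!r}")
    df["Y"] = df["Y"].astype("Int64")
    if (df.loc[df["Delta"] == 0, "Y"].notna()).any():
        raise ValueError("cohort CSV has recorded outcomes for unmonitored records")
    if (df.loc[df["Delta"] == 1, "Y"].isna()).any():
        raise ValueError("cohort CSV has missing outcomes for monitored records")
    return CohortTable(df, n_covariates=len(w_cols))


# ---------------------------------------------------------------------------
# YAML configuration schema
# ---------------------------------------------------------------------------
# covariates:                       # one entry per baseline covariate
#   - {kind: binary, p: 0.5}
#   - {kind: normal, mean: 0.0, sd: 1.0}
# treatment:  {intercept: -0.4, main: [0.8, 0.5]}
# monitoring: {intercept: -0.3, main: [1.2, 0.8], treatment: 0.6}
# outcome:
#   intercept: -1.5
#   treatment: 0.4
#   main: [0.7, 0.5]
#   interaction: [-1.0, 0.0]        # optional, default all zero
#   squared: [0.0, 0.0]             # optional, default all zero
# mediator:                         # optional block
#   {intercept: -1.0, treatment: 1.5, main: [0.6, 0.0], outcome_coef: 1.8}
# seed: 2026


def config_from_yaml(text_or_path) -> DGPConfig:
    """Parse a DGP configuration from YAML text or a file path."""
    if isinstance(text_or_path, str) and "\n" not in text_or_path and not text_or_path.lstrip().startswith("covariates"):
        with open(text_or_path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(text_or_path)
    try:
        covs = tuple(CovariateSpec(**c) for c in raw["covariates"])
        treatment = LinearCoefs(
            intercept=float(raw["treatment"]["intercept"]),
            main=tuple(raw["treatment"]["main"]),
        )
        monitoring = MonitoringCoefs(
            intercept=float(raw["monitoring"]["intercept"]),
            main=tuple(raw["monitoring"]["main"]),
            treatment=float(raw["monitoring"].get("treatment", 0.0)),
        )
        out = raw["outcome"]
        outcome = OutcomeCoefs(
            intercept=float(out["intercept"]),
            treatment=float(out["treatment"]),
            main=tuple(out["main"]),
            interaction=tuple(out.get("interaction", ())),
            squared=tuple(out.get("squared", ())),
        )
        mediator = None
        if raw.get("mediator"):
            med = raw["mediator"]
            mediator = MediatorSpec(
                intercept=float(med["intercept"]),
                treatment=float(med["treatment"]),
                main=tuple(med["main"]),
                outcome_coef=float(med["outcome_coef"]),
            )
    except KeyError as exc:
        raise ConfigurationError(f"config missing required key: {exc}") from exc
    return DGPConfig(
        covariates=covs,
        treatment_coefs=treatment,
        monitoring_coefs=monitoring,
        outcome_coefs=outcome,
        mediator=mediator,
        seed=int(raw.get("seed", 0)),
    )


def config_to_yaml(config: DGPConfig) -> str:
    """Serialize a configuration back to the YAML schema."""
    raw: dict = {
        "covariates": [
            {"kind": c.kind, "p": c.p} if c.kind == "binary"
            else {"kind": c.kind, "mean": c.mean, "sd": c.sd}
            for c in config.covariates
        ],
        "treatment": {
            "intercept": config.treatment_coefs.intercept,
            "main": list(config.treatment_coefs.main),
        },
        "monitoring": {
            "intercept": config.monitoring_coefs.intercept,
            "main": list(config.monitoring_coefs.main),
            "treatment": config.monitoring_coefs.treatment,
        },
        "outcome": {
            "intercept": config.outcome_coefs.intercept,
            "treatment": config.outcome_coefs.treatment,
            "main": list(config.outcome_coefs.main),
            "interaction": list(config.outcome_coefs.interaction),
            "squared": list(config.outcome_coefs.squared),
        },
        "seed": config.seed,
    }
    if config.mediator is not None:
        raw["mediator"] = {
            "intercept": config.mediator.intercept,
            "treatment": config.mediator.treatment,
            "main": list(config.mediator.main),
            "outcome_coef": config.mediator.outcome_coef,
        }
    return yaml.safe_dump(raw, sort_keys=False)
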