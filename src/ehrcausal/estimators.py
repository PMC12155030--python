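"""Risk-ratio estimators under differential monitoring.

All estimators target the marginal causal risk ratio
``Psi = E[Y(1, delta=1)] / E[Y(0, delta=1)]`` for a binary outcome ``Y``
recorded only when the monitoring indicator ``Delta`` is 1.

Two identification strategies are implemented:

* **restrict** — a complete-case analysis: the outcome regression
  ``Qbar(a, w) = E(Y | A=a, Delta=1, W=w)`` is standardized over the covariate
  distribution of the *monitored* subsample.  When monitoring depends on
  ``(W, A)`` and the treatment effect varies across ``W``, this converges to a
  different quantity than ``Psi``.
* **joint intervention** — ``(A, Delta)`` is treated as a joint intervention
  (everyone treated at level ``a`` *and* monitored), so the same ``Qbar`` is
  standardized over the full cohort's covariates.  The g-computation, IPW and
  TMLE estimators all target this quantity; TMLE adds a one-dimensional
  logistic fluctuation along the clever covariate
  ``H_a = 1{A=a, Delta=1} / (gA(a|W) * gDelta(1|a,W))`` so that the efficient
  influence curve's estimating equation is solved, giving double robustness
  and influence-curve-based Wald inference.

Inference is on the log risk-ratio scale throughout (delta method combining
the influence curves of the two counterfactual means, including their
covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .dgp import CohortTable
from .learners import FittedLearner, LearnerSpec, fit_learner, main_terms

__all__ = [
    "EstimateResult",
    "NuisanceFits",
    "EstimationError",
    "PositivityWarning",
    "fit_nuisances",
    "estimate_unadjusted",
    "estimate_restrict",
    "estimate_intervene_gcomp",
    "estimate_intervene_ipw",
    "estimate_intervene_tmle",
]

_Q_EPS = 1.0e-6  # clip Qbar away from {0,1} before taking logits
_TRUNCATION_WARN_SHARE = 0.05


class EstimationError(RuntimeError):
    """The estimator cannot produce a finite estimate on this cohort."""


class PositivityWarning(UserWarning):
    """More than 5% of propensity predictions hit the truncation bound."""


@dataclass
class EstimateResult:
    """Point estimate, log-scale Wald inference and diagnostics for one
    estimator on one cohort."""

    method: str
    psi1: float
    psi0: float
    rr: float
    se_log_rr: float
    ci_lower: float
    ci_upper: float
    level: float
    n_used: int
    diagnostics: dict = field(default_factory=dict)
    ic_log_rr: Optional[np.ndarray] = None

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "psi1": self.psi1,
            "psi0": self.psi0,
            "rr": self.rr,
            "log_rr": float(np.log(self.rr)),
            "se_log_rr": self.se_log_rr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
            "n_used": self.n_used,
        }
        return row


def _z(level: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(0.5 + level / 2.0))


def _wald(log_rr: float, se: float, level: float) -> tuple[float, float]:
    z = _z(level)
    return float(np.exp(log_rr - z * se)), float(np.exp(log_rr + z * se))


def _observed(cohort: CohortTable) -> pd.DataFrame:
    df = cohort.observed_frame()
    df["Y"] = df["Y"].astype("float")
    return df


def _check_arms(df: pd.DataFrame) -> None:
    mon = df[df["Delta"] == 1]
    for a in (0, 1):
        if (mon["A"] == a).sum() == 0:
            raise EstimationError(f"no monitored records in treatment arm A={a}")


# ---------------------------------------------------------------------------
# Nuisance fitting
# ---------------------------------------------------------------------------

@dataclass
class NuisanceFits:
    """Fitted outcome regression and the two propensity models.

    ``predict_Q(a, df)`` evaluates ``Qbar(a, w)``; ``predict_gA(df)`` gives
    ``P(A=1|W)``; ``predict_gD(a, df)`` gives ``P(Delta=1|A=a, W)``.  The
    propensities are truncated to ``[bound, 1 - bound]``.
    """

    q_fit: FittedLearner
    gA_fit: Optional[FittedLearner]
    gD_fit: Optional[FittedLearner]
    covariate_columns: list[str]
    truncation: float

    def predict_Q(self, a: int, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariate_columns].copy()
        X.insert(0, "A", float(a))
        return self.q_fit.predict(X)

    def predict_Q_at_observed(self, df: pd.DataFrame) -> np.ndarray:
        X = df[["A"] + self.covariate_columns].astype(float)
        return self.q_fit.predict(X)

    def predict_gA(self, df: pd.DataFrame) -> np.ndarray:
        p = self.gA_fit.predict(df[self.covariate_columns])
        return np.clip(p, self.truncation, 1.0 - self.truncation)

    def predict_gD(self, a: int, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariate_columns].copy()
        X.insert(0, "A", float(a))
        p = self.gD_fit.predict(X)
        return np.clip(p, self.truncation, 1.0 - self.truncation)

    def truncation_share(self, df: pd.DataFrame) -> float:
        """Share of records for which some weight denominator — gA(a|W) for
        either arm, or gDelta(1|a, W) — falls below the truncation bound.
        A monitoring propensity near one is benign and is not counted."""
        gA_raw = self.gA_fit.predict(df[self.covariate_columns])
        small = (gA_raw < self.truncation) | (1.0 - gA_raw < self.truncation)
        for a in (0, 1):
            X = df[self.covariate_columns].copy()
            X.insert(0, "A", float(a))
            small |= self.gD_fit.predict(X) < self.truncation
        return float(small.mean())


def fit_nuisances(
    cohort: CohortTable,
    q_learner: LearnerSpec,
    gA_learner: Optional[LearnerSpec] = None,
    gD_learner: Optional[LearnerSpec] = None,
    truncation: float = 0.01,
) -> NuisanceFits:
    """Fit ``Qbar`` on monitored records and the propensities on all records."""
    df = _observed(cohort)
    _check_arms(df)
    w_cols = cohort.covariate_columns
    mon = df[df["Delta"] == 1]

    q_fit = fit_learner(q_learner, mon[["A"] + w_cols].astype(float), mon["Y"].to_numpy())
    gA_fit = gD_fit = None
    if gA_learner is not None:
        gA_fit = fit_learner(gA_learner, df[w_cols].astype(float), df["A"].to_numpy())
    if gD_learner is not None:
        gD_fit = fit_learner(
            gD_learner, df[["A"] + w_cols].astype(float), df["Delta"].to_numpy()
        )
    return NuisanceFits(
        q_fit=q_fit,
        gA_fit=gA_fit,
        gD_fit=gD_fit,
        covariate_columns=w_cols,
        truncation=truncation,
    )


def _warn_positivity(nuis: NuisanceFits, df: pd.DataFrame, diagnostics: dict) -> None:
    share = nuis.truncation_share(df)
    diagnostics["truncation_share"] = share
    if share > _TRUNCATION_WARN_SHARE:
        warnings.warn(
            f"{share:.1%} of propensity predictions fall at the truncation "
            f"bound {nuis.truncation}; estimates may be sensitive to "
            "practical positivity violations",
            PositivityWarning,
            stacklevel=3,
        )


def _log_rr_inference(
    D1: np.ndarray,
    D0: np.ndarray,
    psi1: float,
    psi0: float,
    level: float,
) -> tuple[float, float, float, np.ndarray]:
    """Delta-method SE of log(psi1/psi0) from per-record IC contributions."""
    ic = D1 / psi1 - D0 / psi0
    n = len(ic)
    se = float(np.sqrt(np.var(ic) / n))
    log_rr = float(np.log(psi1 / psi0))
    lo, hi = _wald(log_rr, se, level)
    return log_rr, se, level, ic


def _finalize(
    method: str,
    psi1: float,
    psi0: float,
    D1: np.ndarray,
    D0: np.ndarray,
    level: float,
    n_used: int,
    diagnostics: dict,
) -> EstimateResult:
    if psi0 <= 0 or psi1 <= 0:
        raise EstimationError(f"{method}: counterfactual mean estimate is not positive")
    ic = D1 / psi1 - D0 / psi0
    se = float(np.sqrt(np.var(ic) / len(ic)))
    log_rr = float(np.log(psi1 / psi0))
    lo, hi = _wald(log_rr, se, level)
    return EstimateResult(
        method=method,
        psi1=float(psi1),
        psi0=float(psi0),
        rr=float(psi1 / psi0),
        se_log_rr=se,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        n_used=n_used,
        diagnostics=diagnostics,
        ic_log_rr=ic,
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def estimate_unadjusted(
    cohort: CohortTable, level: float = 0.95, continuity: bool = False
) -> EstimateResult:
    """Crude risk ratio among monitored patients from the 2x2 table.

    ``rr = mean(Y | Delta=1, A=1) / mean(Y | Delta=1, A=0)``, with the
    standard log-RR variance ``1/x1 - 1/n1 + 1/x0 - 1/n0``.  Zero events in
    either arm raise an error unless ``continuity`` adds the classic 0.5
    correction to every cell.
    """
    df = _observed(cohort)
    _check_arms(df)
    mon = df[df["Delta"] == 1]
    x1 = float(mon.loc[mon["A"] == 1, "Y"].sum())
    n1 = float((mon["A"] == 1).sum())
    x0 = float(mon.loc[mon["A"] == 0, "Y"].sum())
    n0 = float((mon["A"] == 0).sum())
    if continuity and (x1 == 0 or x0 == 0 or x1 == n1 or x0 == n0):
        x1, x0, n1, n0 = x1 + 0.5, x0 + 0.5, n1 + 1.0, n0 + 1.0
    if x1 == 0 or x0 == 0:
        raise EstimationError("zero events in a treatment arm: risk ratio undefined")
    psi1, psi0 = x1 / n1, x0 / n0
    rr = psi1 / psi0
    se = float(np.sqrt(1.0 / x1 - 1.0 / n1 + 1.0 / x0 - 1.0 / n0))
    log_rr = float(np.log(rr))
    lo, hi = _wald(log_rr, se, level)
    return EstimateResult(
        method="unadjusted",
        psi1=psi1,
        psi0=psi0,
        rr=rr,
        se_log_rr=se,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        n_used=int(n1 + n0),
        diagnostics={"events_treated": x1, "events_control": x0},
    )


def estimate_restrict(
    cohort: CohortTable,
    learner: LearnerSpec,
    level: float = 0.95,
    gA_learner: Optional[LearnerSpec] = None,
) -> EstimateResult:
    """Complete-case standardization (the "restrict" strategy).

    ``Qbar`` is fitted on monitored records and standardized over the
    monitored subsample's covariates.  The SE uses the plug-in's
    influence-curve approximation, which requires a treatment propensity
    *within the monitored subsample*; by default a main-terms logistic is
    used for it.
    """
    df = _observed(cohort)
    _check_arms(df)
    w_cols = cohort.covariate_columns
    mon = df[df["Delta"] == 1].reset_index(drop=True)

    q_fit = fit_learner(learner, mon[["A"] + w_cols].astype(float), mon["Y"].to_numpy())
    gA_spec = gA_learner if gA_learner is not None else main_terms()
    gA_fit = fit_learner(gA_spec, mon[w_cols].astype(float), mon["A"].to_numpy())

    def q(a: int) -> np.ndarray:
        X = mon[w_cols].copy()
        X.insert(0, "A", float(a))
        return q_fit.predict(X)

    q1, q0 = q(1), q(0)
    psi1, psi0 = float(q1.mean()), float(q0.mean())

    gA = np.clip(gA_fit.predict(mon[w_cols]), 0.01, 0.99)
    A = mon["A"].to_numpy(dtype=float)
    Y = mon["Y"].to_numpy(dtype=float)
    D1 = (A / gA) * (Y - q1) + q1 - psi1
    D0 = ((1.0 - A) / (1.0 - gA)) * (Y - q0) + q0 - psi0

    return _finalize(
        "restrict", psi1, psi0, D1, D0, level, len(mon),
        diagnostics={"n_monitored": len(mon)},
    )


def estimate_intervene_gcomp(
    cohort: CohortTable,
    learner: LearnerSpec,
    level: float = 0.95,
    gA_learner: Optional[LearnerSpec] = None,
    gD_learner: Optional[LearnerSpec] = None,
    truncation: float = 0.01,
) -> EstimateResult:
    """Joint-intervention g-computation: ``Qbar`` fitted on monitored records,
    standardized over the *full* cohort's covariates.

    The propensity models (main-terms logistic unless overridden) enter only
    the influence-curve SE and the positivity diagnostics, not the point
    estimate.
    """
    df = _observed(cohort)
    nuis = fit_nuisances(
        cohort,
        learner,
        gA_learner if gA_learner is not None else main_terms(),
        gD_learner if gD_learner is not None else main_terms(),
        truncation=truncation,
    )
    diagnostics: dict = {}
    _warn_positivity(nuis, df, diagnostics)

    q1, q0 = nuis.predict_Q(1, df), nuis.predict_Q(0, df)
    psi1, psi0 = float(q1.mean()), float(q0.mean())

    A = df["A"].to_numpy(dtype=float)
    Delta = df["Delta"].to_numpy(dtype=float)
    Y = np.nan_to_num(df["Y"].to_numpy(dtype=float))
    gA = nuis.predict_gA(df)
    H1 = A * Delta / (gA * nuis.predict_gD(1, df))
    H0 = (1.0 - A) * Delta / ((1.0 - gA) * nuis.predict_gD(0, df))
    q_obs = np.where(A == 1, q1, q0)
    D1 = H1 * (Y - q_obs) + q1 - psi1
    D0 = H0 * (Y - q_obs) + q0 - psi0
    diagnostics.update({"min_weight": float(min(H1[H1 > 0].min(), H0[H0 > 0].min())),
                        "max_weight": float(max(H1.max(), H0.max()))})

    return _finalize("intervene_gcomp", psi1, psi0, D1, D0, level, len(df), diagnostics)


def estimate_intervene_ipw(
    cohort: CohortTable,
    gA_learner: LearnerSpec,
    gD_learner: LearnerSpec,
    truncation: float = 0.01,
    level: float = 0.95,
    normalization: str = "hajek",
) -> EstimateResult:
    """Joint-intervention inverse-probability weighting.

    Weights are ``1{A=a, Delta=1} / (gA(a|W) * gDelta(1|a,W))`` with
    propensities truncated to ``[truncation, 1-truncation]``.  The default
    Hajek form normalizes weights within each arm; ``normalization="ht"``
    gives the unnormalized Horvitz-Thompson mean.
    """
    if normalization not in ("hajek", "ht"):
        raise ValueError("normalization must be 'hajek' or 'ht'")
    df = _observed(cohort)
    _check_arms(df)
    w_cols = cohort.covariate_columns

    gA_fit = fit_learner(gA_learner, df[w_cols].astype(float), df["A"].to_numpy())
    gD_fit = fit_learner(
        gD_learner, df[["A"] + w_cols].astype(float), df["Delta"].to_numpy()
    )
    nuis = NuisanceFits(
        q_fit=None, gA_fit=gA_fit, gD_fit=gD_fit,
        covariate_columns=w_cols, truncation=truncation,
    )
    diagnostics: dict = {"normalization": normalization}
    _warn_positivity(nuis, df, diagnostics)

    A = df["A"].to_numpy(dtype=float)
    Delta = df["Delta"].to_numpy(dtype=float)
    Y = np.nan_to_num(df["Y"].to_numpy(dtype=float))
    gA = nuis.predict_gA(df)
    w1 = A * Delta / (gA * nuis.predict_gD(1, df))
    w0 = (1.0 - A) * Delta / ((1.0 - gA) * nuis.predict_gD(0, df))
    if w1.sum() == 0 or w0.sum() == 0:
        raise EstimationError("all IPW weights are zero in one treatment arm")
    diagnostics.update(
        min_weight=float(min(w1[w1 > 0].min(), w0[w0 > 0].min())),
        max_weight=float(max(w1.max(), w0.max())),
    )

    n = len(df)
    if normalization == "hajek":
        psi1 = float((w1 * Y).sum() / w1.sum())
        psi0 = float((w0 * Y).sum() / w0.sum())
        D1 = w1 * (Y - psi1) / (w1.mean())
        D0 = w0 * (Y - psi0) / (w0.mean())
    else:
        psi1 = float((w1 * Y).mean())
        psi0 = float((w0 * Y).mean())
        D1 = w1 * Y - psi1
        D0 = w0 * Y - psi0

    return _finalize(f"intervene_ipw", psi1, psi0, D1, D0, level, n, diagnostics)


def _fluctuate(Y: np.ndarray, q_init: np.ndarray, H: np.ndarray) -> float:
    """One-dimensional logistic fluctuation: logit(Q*) = logit(Q) + eps*H,
    fitted on the records where H > 0."""
    mask = H > 0
    if mask.sum() == 0:
        raise EstimationError("no records carry weight in the fluctuation step")
    y, q, h = Y[mask], q_init[mask], H[mask]
    if np.allclose(y, y[0]):
        # all-0 or all-1 outcomes in the cell: epsilon diverges; fall back to
        # the empirical solution of the score equation via a capped epsilon
        eps_grid = np.linspace(-10.0, 10.0, 2001)
        scores = [
            float(np.mean(h * (y - expit(logit(q) + e * h)))) for e in eps_grid
        ]
        eps = float(eps_grid[int(np.argmin(np.abs(scores)))])
    else:
        model = sm.GLM(
            y, h[:, None], family=sm.families.Binomial(), offset=logit(q)
        )
        try:
            eps = float(model.fit(maxiter=200, tol=1e-12).params[0])
        except Exception as exc:  # pragma: no cover - solver pathologies
            raise EstimationError(f"targeting step failed to converge: {exc}") from exc
    return eps


def estimate_intervene_tmle(
    cohort: CohortTable,
    q_learner: LearnerSpec,
    gA_learner: LearnerSpec,
    gD_learner: LearnerSpec,
    truncation: float = 0.01,
    level: float = 0.95,
) -> EstimateResult:
    """Targeted maximum likelihood estimation of the joint-intervention risk
    ratio.

    For each arm ``a`` the initial outcome regression is fluctuated along the
    clever covariate ``H_a = 1{A=a, Delta=1} / (gA(a|W) gDelta(1|a,W))`` by a
    single logistic regression with offset ``logit(Qbar)``, after which the
    counterfactual mean is the average of the updated predictions over the
    full cohort.  By construction the empirical mean of each arm's estimated
    efficient influence curve is (numerically) zero, which the result's
    diagnostics report.
    """
    df = _observed(cohort)
    nuis = fit_nuisances(cohort, q_learner, gA_learner, gD_learner, truncation)
    diagnostics: dict = {}
    _warn_positivity(nuis, df, diagnostics)

    n = len(df)
    A = df["A"].to_numpy(dtype=float)
    Delta = df["Delta"].to_numpy(dtype=float)
    Y = np.nan_to_num(df["Y"].to_numpy(dtype=float))
    gA = nuis.predict_gA(df)

    psis, Ds, eps_values, ic_means = {}, {}, {}, {}
    for a in (1, 0):
        # clip away from {0,1} so the fluctuation offset logit(Q) is finite
        q_a = np.clip(nuis.predict_Q(a, df), _Q_EPS, 1.0 - _Q_EPS)
        gD_a = nuis.predict_gD(a, df)
        ind = A == a if a == 1 else A == 0
        H = np.where(ind, Delta / ((gA if a == 1 else 1.0 - gA) * gD_a), 0.0)
        eps = _fluctuate(Y, q_a, H)
        # Updated predictions at the intervened values (A=a, Delta=1); where
        # H > 0 the observed clever covariate equals its intervened value, so
        # the same update applies to the residual term of the IC.
        H_star = 1.0 / ((gA if a == 1 else 1.0 - gA) * gD_a)
        q_star = expit(logit(q_a) + eps * H_star)
        psi = float(q_star.mean())
        D = H * (Y - q_star) + q_star - psi
        psis[a], Ds[a], eps_values[a] = psi, D, eps
        ic_means[a] = float(D.mean())

    diagnostics.update(
        epsilon_1=eps_values[1],
        epsilon_0=eps_values[0],
        ic_mean_1=ic_means[1],
        ic_mean_0=ic_means[0],
        min_weight=float(
            min(
                (Delta / (gA * nuis.predict_gD(1, df)))[(A == 1) & (Delta == 1)].min(initial=np.inf),
                (Delta / ((1 - gA) * nuis.predict_gD(0, df)))[(A == 0) & (Delta == 1)].min(initial=np.inf),
            )
        ),
        max_weight=float(
            max(
                (Delta / (gA * nuis.predict_gD(1, df)))[(A == 1)].max(initial=0.0),
                (Delta / ((1 - gA) * nuis.predict_gD(0, df)))[(A == 0)].max(initial=0.0),
            )
        ),
    )

    for a in (0, 1):
        sd = float(np.std(Ds[a]))
        if sd > 0 and abs(ic_means[a]) > 1e-4 * sd / np.sqrt(n) + 1e-8:
            warnings.warn(
                f"TMLE influence curve for arm {a} has nonzero empirical mean "
                f"({ic_means[a]:.2e}); the targeting step may not have converged",
                UserWarning,
                stacklevel=2,
            )

    return _finalize(
        "intervene_tmle", psis[1], psis[0], Ds[1], Ds[0], level, n, diagnostics
    )
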