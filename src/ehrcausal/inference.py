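"""Confidence intervals, hypothesis tests and Monte-Carlo performance metrics.

Inference is Wald-type on the log risk-ratio scale with standard-normal
quantiles (large-sample EHR context), so the interval/test duality
``reject at level L  <=>  two-sided p-value < 1 - L`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dgp import TrueEstimands
from .estimators import EstimateResult

__all__ = [
    "wald_interval",
    "reject_null",
    "wald_p_value",
    "MCSummary",
    "summarize_replicates",
    "summaries_to_frame",
]


def wald_interval(log_rr: float, se_log_rr: float, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Wald interval on the risk-ratio scale:
    ``exp(log_rr -/+ z_{(1+level)/2} * se)``."""
    if se_log_rr <= 0:
        raise ValueError(f"standard error must be positive, got {se_log_rr}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    z = float(norm.ppf(0.5 + level / 2.0))
    return float(np.exp(log_rr - z * se_log_rr)), float(np.exp(log_rr + z * se_log_rr))


def wald_p_value(log_rr: float, se_log_rr: float, null_rr: float = 1.0) -> float:
    """Two-sided Wald p-value against ``RR = null_rr``."""
    z = (log_rr - np.log(null_rr)) / se_log_rr
    return float(2.0 * norm.sf(abs(z)))


def reject_null(result: EstimateResult, null_rr: float = 1.0) -> bool:
    """True iff ``null_rr`` lies outside the result's confidence interval."""
    if not result.ci_lower < result.ci_upper:
        raise ValueError("result does not carry a valid interval")
    return not (result.ci_lower <= null_rr <= result.ci_upper)


@dataclass(frozen=True)
class MCSummary:
    """Monte-Carlo performance of one method under one scenario and n."""

    method: str
    scenario: str
    n: int
    n_reps: int
    n_failures: int
    mean_log_rr: float
    sd_log_rr: float
    mean_rr: float
    bias_log_rr: float
    rmse_log_rr: float
    coverage_pct: float
    rejection_pct: float
    mean_ci_width: float
    level: float
    seed: int

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_replicates(
    results: Sequence[EstimateResult],
    truth: TrueEstimands,
    level: float = 0.95,
    scenario: str = "",
    n: int = 0,
    seed: int = 0,
    n_failures: int = 0,
    null_rr: float = 1.0,
) -> MCSummary:
    """Aggregate replicate estimates into bias, empirical SE, RMSE, CI
    coverage of the true risk ratio, and null-rejection rate.

    Replicates that failed (degenerate cells) are counted in ``n_failures``
    and excluded, never imputed.
    """
    if not results:
        raise ValueError("no successful replicates to summarize")
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in one summary: {sorted(methods)}")

    log_rrs = np.array([np.log(r.rr) for r in results])
    true_log = float(np.log(truth.risk_ratio))
    covered = np.array(
        [r.ci_lower <= truth.risk_ratio <= r.ci_upper for r in results]
    )
    rejected = np.array([reject_null(r, null_rr) for r in results])
    widths = np.array([np.log(r.ci_upper) - np.log(r.ci_lower) for r in results])

    return MCSummary(
        method=methods.pop(),
        scenario=scenario,
        n=n,
        n_reps=len(results),
        n_failures=n_failures,
        mean_log_rr=float(log_rrs.mean()),
        sd_log_rr=float(log_rrs.std(ddof=1)) if len(log_rrs) > 1 else 0.0,
        mean_rr=float(np.exp(log_rrs).mean()),
        bias_log_rr=float(log_rrs.mean() - true_log),
        rmse_log_rr=float(np.sqrt(np.mean((log_rrs - true_log) ** 2))),
        coverage_pct=float(100.0 * covered.mean()),
        rejection_pct=float(100.0 * rejected.mean()),
        mean_ci_width=float(widths.mean()),
        level=level,
        seed=seed,
    )


def summaries_to_frame(summaries: Iterable[MCSummary]) -> pd.DataFrame:
    """Tidy one-row-per-(method, scenario, n) table."""
    return pd.DataFrame([s.to_row() for s in summaries])
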