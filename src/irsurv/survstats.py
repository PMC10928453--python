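"""Survival analysis: Kaplan–Meier with exponential Greenwood bands,
univariate Cox regression, and the reverse score-threshold analysis.

Conventions, stated once:

* Kaplan–Meier — ``Ŝ(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ)`` over distinct event
  times; a censoring at an event time leaves the risk set *after* that
  time's events.
* Exponential Greenwood — with ``ĉ(t) = Σ dᵢ/(nᵢ(nᵢ−dᵢ))`` and
  ``v(t) = ĉ(t)/ln²Ŝ(t)``, the 1−α band is ``Ŝ^{exp(±z√v)}``, which lies in
  [0, 1] by construction.  Before the first event (Ŝ = 1) the band is
  reported as [1, 1]; where Ŝ = 0 the transform is undefined and the band is
  omitted (NaN).
* Cox — Breslow tie handling; Newton–Raphson on the partial likelihood;
  Wald 95 % intervals ``exp(β ± 1.96·SE)``.  A monotone likelihood (perfect
  separation) is detected by runaway |β| and returned flagged with β capped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError, DegenerateInputError
from .stratify import LogRankResult, logrank

__all__ = [
    "KMCurve",
    "CoxFit",
    "ReverseAnalysisResult",
    "km_estimate",
    "greenwood_ci",
    "cox_fit",
    "reverse_analysis",
]

_BETA_CAP = 50.0


@dataclass
class KMCurve:
    """Kaplan–Meier step function over distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        """Ŝ(t): right-continuous step-function lookup (1 before the first
        event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )
        if self.ci_lower is not None:
            frame["ci_lower"] = self.ci_lower
            frame["ci_upper"] = self.ci_upper
        return frame


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow partial likelihood)."""

    beta: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    standard_error: float
    n_events: int
    separated: bool = False


@dataclass
class ReverseAnalysisResult:
    """Score threshold maximising the log-rank statistic, with KM curves."""

    threshold: float
    groups: pd.Series  # patient_id -> 'high' | 'low'
    logrank: LogRankResult
    km_high: KMCurve
    km_low: KMCurve
    candidate_profile: pd.DataFrame


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("empty survival input")
    if np.any(times <= 0):
        raise DataError("survival times must be strictly positive")

    event_times = np.unique(times[events == 1])
    survival = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        survival[i], at_risk[i], n_events[i] = s, n, d
    return KMCurve(
        event_times=event_times, survival=survival, at_risk=at_risk, n_events=n_events
    )


def greenwood_ci(curve: KMCurve, alpha: float = 0.05) -> KMCurve:
    """Attach pointwise exponential Greenwood bands to a KM curve."""
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    lower = np.full(curve.event_times.size, np.nan)
    upper = np.full(curve.event_times.size, np.nan)
    c_hat = 0.0
    for i in range(curve.event_times.size):
        n, d, s = int(curve.at_risk[i]), int(curve.n_events[i]), curve.survival[i]
        if n > d:
            c_hat += d / (n * (n - d))
        if s <= 0.0 or s >= 1.0:
            if s >= 1.0:
                lower[i] = upper[i] = s  # band degenerate at Ŝ = 1
            continue  # transform undefined at Ŝ = 0: band omitted
        v = c_hat / np.log(s) ** 2
        lower[i] = s ** np.exp(z * np.sqrt(v))
        upper[i] = s ** np.exp(-z * np.sqrt(v))
    return KMCurve(
        event_times=curve.event_times,
        survival=curve.survival,
        at_risk=curve.at_risk,
        n_events=curve.n_events,
        ci_lower=lower,
        ci_upper=upper,
    )


def _cox_score_info(beta: float, x, times, events):
    """Breslow partial-likelihood score and information for scalar beta."""
    score = 0.0
    info = 0.0
    eta = np.clip(beta * x, -700, 700)
    w = np.exp(eta)
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        s0 = w[risk].sum()
        s1 = (w[risk] * x[risk]).sum()
        s2 = (w[risk] * x[risk] ** 2).sum()
        mean = s1 / s0
        score += x[dying].sum() - d * mean
        info += d * (s2 / s0 - mean**2)
    return score, info


def cox_fit(covariate, times, events, max_iter: int = 100, tol: float = 1e-8) -> CoxFit:
    """Univariate Cox fit by Newton–Raphson on the Breslow partial likelihood.

    Converges when |score(β)| < ``tol``.  Perfect separation (monotone
    likelihood) is reported as a flagged fit with |β| capped at 50 rather
    than an exception.
    """
    x = np.asarray(covariate, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (x.size == times.size == events.size):
        raise DataError("covariate, times and events must align")
    if np.any(times <= 0):
        raise DataError("survival times must be strictly positive")
    n_events = int(events.sum())
    if n_events < 1:
        raise DataError("at least one event is required")
    if np.ptp(x) == 0:
        raise DataError("covariate is constant; hazard ratio undefined")

    beta = 0.0
    separated = False
    for _ in range(max_iter):
        score, info = _cox_score_info(beta, x, times, events)
        if abs(score) < tol:
            break
        if info <= 0:
            separated = True
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)  # damped step for stability
        if abs(beta) >= _BETA_CAP:
            separated = True
            beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
            break
    else:
        raise ConvergenceError(
            f"Cox Newton–Raphson did not converge (last |score| = {abs(score):.3e})"
        )
    score, info = _cox_score_info(beta, x, times, events)
    if info <= 1e-6:  # flat likelihood at the optimum: monotone/separated
        separated = True
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    with np.errstate(over="ignore"):
        return CoxFit(
            beta=float(beta),
            hazard_ratio=float(np.exp(beta)),
            ci_lower=float(np.exp(beta - 1.959963984540054 * se)),
            ci_upper=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=float(2 * stats.norm.sf(abs(z))),
            standard_error=se,
            n_events=n_events,
            separated=separated,
        )


def reverse_analysis(
    scores: pd.Series,
    cohort: pd.DataFrame,
    min_group_size: int = 3,
    alpha: float = 0.05,
) -> ReverseAnalysisResult:
    """Find the patient-score threshold maximising the log-rank statistic.

    Candidates are midpoints between consecutive distinct scores; patients
    with ``score >= threshold`` form the high-risk group.  Ties are broken
    towards the smaller threshold.  KM curves (with exponential Greenwood
    bands) of both groups accompany the winning split.
    """
    scores = scores.copy()
    scores.index = scores.index.astype(str)
    cohort = cohort.set_index(cohort["patient_id"].astype(str))
    common = [p for p in scores.index if p in cohort.index]
    if len(common) < 2 * min_group_size:
        raise DegenerateInputError(
            f"need at least {2 * min_group_size} scored patients, got {len(common)}"
        )
    s = scores.loc[common].to_numpy(dtype=float)
    times = cohort.loc[common, "time_months"].to_numpy(dtype=float)
    events = cohort.loc[common, "event"].to_numpy(dtype=int)

    distinct = np.unique(s)
    if distinct.size < 2:
        raise DegenerateInputError("all patient scores identical")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    profile = []
    best: tuple[float, float] | None = None  # (statistic, threshold)
    for threshold in candidates:
        high = s >= threshold
        n_high, n_low = int(high.sum()), int((~high).sum())
        admissible = n_high >= min_group_size and n_low >= min_group_size
        statistic = np.nan
        if admissible:
            res = logrank(times, events, np.where(high, "high", "low"))
            statistic = res.statistic
            if best is None or statistic > best[0] + 1e-12:
                best = (statistic, float(threshold))
        profile.append(
            {"threshold": float(threshold), "statistic": statistic, "admissible": admissible}
        )
    if best is None:
        raise DegenerateInputError(
            "no threshold leaves both groups at min_group_size"
        )
    threshold = best[1]
    high = s >= threshold
    result = logrank(times, events, np.where(high, "high", "low"))
    km_high = greenwood_ci(km_estimate(times[high], events[high]), alpha)
    km_low = greenwood_ci(km_estimate(times[~high], events[~high]), alpha)
    groups = pd.Series(
        np.where(high, "high", "low"),
        index=pd.Index(common, name="patient_id"),
        name="risk_label",
    )
    return ReverseAnalysisResult(
        threshold=threshold,
        groups=groups,
        logrank=result,
        km_high=km_high,
        km_low=km_low,
        candidate_profile=pd.DataFrame(profile),
    )
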