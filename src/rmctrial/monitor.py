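"""Bayesian sequential monitoring: stopping rules, boundaries, final test.

The design monitors two binary outcomes while the trial accrues in cohorts
of 10 patients up to a maximum of 30:

* toxicity — stop if Pr(theta_T > 0.30 | data) > 0.95, prior Beta(0.6, 1.4),
  checked after every treated patient (an extreme toxicity can occur at any
  time);
* futility — stop if Pr(theta_R < 0.30 | data) > 0.90, prior Beta(0.5, 0.5),
  checked at cohort boundaries when 12-week response is assessed.

The final hypothesis test, planned only at full accrual, compares the
trial's posterior response rate (skeptical prior Beta(0.6, 1.4)) with the
historical comparator Beta(13, 32) from 13/45 responses (29%) on
conventional chemotherapy, declaring success when
Pr(theta_R > theta_H | data) > 0.80.

All decision cutoffs are strict (">"), mirroring the protocol's probability
statements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import pandas as pd

from .betabin import (
    BetaDistribution,
    BinomialData,
    prob_greater,
    tail_probability,
    update_beta,
)

__all__ = [
    "StoppingRule",
    "MonitoringPlan",
    "TrialState",
    "PatientOutcome",
    "MonitoringDecision",
    "FinalAnalysisResult",
    "toxicity_rule",
    "futility_rule",
    "historical_control",
    "evaluate_rule",
    "derive_boundary",
    "prior_sensitivity",
    "final_analysis",
    "run_monitoring",
]

#: Historical comparator posterior: 13 responders / 45 patients (29%).
HISTORICAL_RESPONSES = 13
HISTORICAL_N = 45


@dataclass(frozen=True)
class StoppingRule:
    """A posterior-probability stopping rule for one binary outcome.

    ``direction`` gives the tail of interest for the event rate:
    ``"rate_above"`` stops when the rate is credibly above
    ``rate_threshold`` (toxicity); ``"rate_below"`` stops when it is
    credibly below (futility).
    """

    outcome: str  # "toxicity" | "response"
    prior: BetaDistribution
    rate_threshold: float
    posterior_cutoff: float
    direction: str  # "rate_above" | "rate_below"

    def __post_init__(self) -> None:
        if not 0 < self.rate_threshold < 1:
            raise ValueError("rate_threshold must be in (0, 1)")
        if not 0 < self.posterior_cutoff <= 1:
            raise ValueError("posterior_cutoff must be in (0, 1]")
        if self.direction not in ("rate_above", "rate_below"):
            raise ValueError(f"unknown direction {self.direction!r}")


def toxicity_rule() -> StoppingRule:
    """The protocol's toxicity rule: Pr(theta_T > 0.30 | data) > 0.95."""
    return StoppingRule(
        outcome="toxicity",
        prior=BetaDistribution(0.6, 1.4),
        rate_threshold=0.30,
        posterior_cutoff=0.95,
        direction="rate_above",
    )


def futility_rule() -> StoppingRule:
    """The protocol's futility rule: Pr(theta_R < 0.30 | data) > 0.90."""
    return StoppingRule(
        outcome="response",
        prior=BetaDistribution(0.5, 0.5),
        rate_threshold=0.30,
        posterior_cutoff=0.90,
        direction="rate_below",
    )


def historical_control() -> BetaDistribution:
    """Posterior of the historical response rate, Beta(13, 32) from 13/45."""
    return BetaDistribution(HISTORICAL_RESPONSES, HISTORICAL_N - HISTORICAL_RESPONSES)


@dataclass(frozen=True)
class MonitoringPlan:
    cohort_size: int = 10
    max_n: int = 30

    def __post_init__(self) -> None:
        if self.cohort_size < 1 or self.max_n < self.cohort_size:
            raise ValueError("need 1 <= cohort_size <= max_n")

    @property
    def evaluation_points(self) -> list[int]:
        return list(range(self.cohort_size, self.max_n + 1, self.cohort_size))


@dataclass
class TrialState:
    """Running trial counts.

    Patients who never received treatment are excluded (the protocol
    replaced them); patients leaving before the 12-week evaluation count
    as non-responders, so r + q equals the number treated once all are
    evaluated.
    """

    n_treated: int = 0
    r_responses: int = 0
    q_nonresponders: int = 0
    t_tox: int = 0

    def __post_init__(self) -> None:
        if min(self.n_treated, self.r_responses, self.q_nonresponders, self.t_tox) < 0:
            raise ValueError("counts must be non-negative")
        if self.r_responses + self.q_nonresponders > self.n_treated:
            raise ValueError("r + q cannot exceed n_treated")
        if self.t_tox > self.n_treated:
            raise ValueError("t cannot exceed n_treated")


@dataclass(frozen=True)
class PatientOutcome:
    """Per-patient binary outcomes: confirmed 12-week response and TOX."""

    response: bool
    tox: bool


@dataclass(frozen=True)
class MonitoringDecision:
    n_treated: int
    decision: str  # "continue" | "stop_toxicity" | "stop_futility"
    posterior_probabilities: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FinalAnalysisResult:
    probability: float
    success: bool
    planned: bool  # False when called before full accrual


def evaluate_rule(rule: StoppingRule, data: BinomialData) -> tuple[float, bool]:
    """Posterior tail probability for a rule and whether it triggers.

    ``data.successes`` counts the rule's events (responses or TOX),
    ``data.failures`` the complements.  Triggering is strict:
    probability must exceed the cutoff.
    """
    return _evaluate_rule_cached(rule, data.successes, data.failures)


@lru_cache(maxsize=65536)
def _evaluate_rule_cached(
    rule: StoppingRule, successes: int, failures: int
) -> tuple[float, bool]:
    # the monitor and OC simulator revisit the same small count states
    posterior = update_beta(rule.prior, BinomialData(successes, failures))
    direction = "above" if rule.direction == "rate_above" else "below"
    prob = tail_probability(posterior, rule.rate_threshold, direction)
    return prob, prob > rule.posterior_cutoff


def derive_boundary(rule: StoppingRule, n_values: Iterable[int]) -> pd.DataFrame:
    """Derive the stopping boundary by exhaustive enumeration over 0..n.

    For a toxicity-style rule (``rate_above``) the boundary is the
    smallest event count that triggers a stop at each n (stop if
    observed count >= boundary).  For a futility-style rule
    (``rate_below``) it is the largest response count that still
    triggers (stop if observed count <= boundary).  ``critical_count``
    is NA when no count in 0..n triggers.
    """
    rows = []
    for n in n_values:
        if n < 1:
            raise ValueError("n values must be positive")
        triggered = [
            k
            for k in range(n + 1)
            if evaluate_rule(rule, BinomialData(k, n - k))[1]
        ]
        if rule.direction == "rate_above":
            critical = min(triggered) if triggered else None
            action = "stop if events >= critical_count"
        else:
            critical = max(triggered) if triggered else None
            action = "stop if responses <= critical_count"
        rows.append({"n": n, "critical_count": critical, "action": action})
    return pd.DataFrame(rows)


def prior_sensitivity(
    rule: StoppingRule,
    alt_prior: BetaDistribution,
    n_values: Iterable[int],
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Re-derive the boundary under an alternative prior.

    Returns both boundary tables and whether their critical counts
    coincide at every n (the protocol's sensitivity analysis swapped the
    enthusiastic futility prior Beta(0.5, 0.5) for the skeptical
    Beta(0.6, 1.4) and found identical stopping rules).
    """
    n_values = list(n_values)
    base = derive_boundary(rule, n_values)
    alt_rule = StoppingRule(
        outcome=rule.outcome,
        prior=alt_prior,
        rate_threshold=rule.rate_threshold,
        posterior_cutoff=rule.posterior_cutoff,
        direction=rule.direction,
    )
    alt = derive_boundary(alt_rule, n_values)
    identical = bool(
        base["critical_count"].astype(float).fillna(-1.0)
        .eq(alt["critical_count"].astype(float).fillna(-1.0)).all()
    )
    return base, alt, identical


def final_analysis(
    state: TrialState,
    historical: BetaDistribution | None = None,
    success_cutoff: float = 0.80,
    prior: BetaDistribution | None = None,
    planned_n: int = 30,
) -> FinalAnalysisResult:
    """Final hypothesis test against the historical response rate.

    Success iff Pr(theta_R > theta_H | data) > ``success_cutoff`` with
    the skeptical prior Beta(0.6, 1.4) on theta_R.  The test was planned
    only at full accrual; ``planned`` is False otherwise, but the
    probability is still computed.
    """
    if historical is None:
        historical = historical_control()
    if prior is None:
        prior = BetaDistribution(0.6, 1.4)
    posterior = update_beta(
        prior, BinomialData(state.r_responses, state.q_nonresponders)
    )
    prob = prob_greater(posterior, historical)
    return FinalAnalysisResult(
        probability=prob,
        success=prob > success_cutoff,
        planned=state.r_responses + state.q_nonresponders == planned_n,
    )


def run_monitoring(
    plan: MonitoringPlan,
    outcomes: Sequence[PatientOutcome],
    tox_rule: StoppingRule | None = None,
    fut_rule: StoppingRule | None = None,
    *,
    tox_continuous: bool = True,
) -> list[MonitoringDecision]:
    """Apply the monitoring rules to an ordered stream of patient outcomes.

    Toxicity is evaluated after every treated patient (configurable via
    ``tox_continuous``; otherwise only at cohort boundaries), futility
    only at cohort boundaries.  The first triggered stop terminates the
    stream.  Returns the emitted decision sequence; the last element
    carries the terminal decision.
    """
    if tox_rule is None:
        tox_rule = toxicity_rule()
    if fut_rule is None:
        fut_rule = futility_rule()
    if len(outcomes) > plan.max_n:
        outcomes = outcomes[: plan.max_n]

    decisions: list[MonitoringDecision] = []
    r = q = t = 0
    for i, outcome in enumerate(outcomes, start=1):
        r += outcome.response
        q += not outcome.response
        t += outcome.tox

        probs: dict[str, float] = {}
        at_cohort = i in plan.evaluation_points

        if tox_continuous or at_cohort:
            p_tox, tox_trig = evaluate_rule(tox_rule, BinomialData(t, i - t))
            probs["toxicity"] = p_tox
            if tox_trig:
                decisions.append(MonitoringDecision(i, "stop_toxicity", probs))
                return decisions

        if at_cohort:
            p_fut, fut_trig = evaluate_rule(fut_rule, BinomialData(r, q))
            probs["futility"] = p_fut
            if fut_trig:
                decisions.append(MonitoringDecision(i, "stop_futility", probs))
                return decisions

        if at_cohort or (tox_continuous and probs):
            decisions.append(MonitoringDecision(i, "continue", probs))
    return decisions
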