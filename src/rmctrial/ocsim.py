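"""Operating characteristics of the monitoring design by simulation.

Each simulated patient contributes an independent Bernoulli response draw
and an independent Bernoulli extreme-toxicity draw (the protocol specifies
no joint model); the stream is fed through the sequential monitor and
stop frequencies, final-test success and expected sample size are tallied
over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .monitor import (
    MonitoringPlan,
    PatientOutcome,
    StoppingRule,
    TrialState,
    final_analysis,
    futility_rule,
    run_monitoring,
    toxicity_rule,
)

__all__ = ["TrueRates", "TrialOutcome", "OCReport", "simulate_trial",
           "operating_characteristics"]


@dataclass(frozen=True)
class TrueRates:
    orr: float
    tox: float

    def __post_init__(self) -> None:
        if not (0 <= self.orr <= 1 and 0 <= self.tox <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class TrialOutcome:
    stop_reason: str  # "completed" | "stop_toxicity" | "stop_futility"
    n_final: int
    r: int
    t: int
    final_success: bool | None  # None unless the trial completed


@dataclass(frozen=True)
class OCReport:
    prob_stop_futility: float
    prob_stop_toxicity: float
    prob_complete: float
    prob_final_success: float
    expected_sample_size: float
    replicate_count: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def simulate_trial(
    rates: TrueRates,
    plan: MonitoringPlan | None = None,
    tox_rule: StoppingRule | None = None,
    fut_rule: StoppingRule | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrialOutcome:
    """Simulate one trial under assumed true rates through the monitor."""
    if plan is None:
        plan = MonitoringPlan()
    rng = np.random.default_rng(rng)
    responses = rng.random(plan.max_n) < rates.orr
    toxes = rng.random(plan.max_n) < rates.tox
    outcomes = [PatientOutcome(bool(a), bool(b)) for a, b in zip(responses, toxes)]
    decisions = run_monitoring(plan, outcomes, tox_rule, fut_rule)
    last = decisions[-1]
    n_final = last.n_treated
    r = int(np.sum(responses[:n_final]))
    t = int(np.sum(toxes[:n_final]))
    if last.decision == "continue":
        state = TrialState(n_final, r, n_final - r, t)
        success = final_analysis(state).success
        return TrialOutcome("completed", n_final, r, t, success)
    return TrialOutcome(last.decision, n_final, r, t, None)


def operating_characteristics(
    rates: TrueRates,
    plan: MonitoringPlan | None = None,
    tox_rule: StoppingRule | None = None,
    fut_rule: StoppingRule | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> OCReport:
    """Monte Carlo operating characteristics of the design.

    Frequencies carry a standard error of about sqrt(p(1-p)/n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if plan is None:
        plan = MonitoringPlan()
    if tox_rule is None:
        tox_rule = toxicity_rule()
    if fut_rule is None:
        fut_rule = futility_rule()
    rng = np.random.default_rng(seed)
    counts = {"completed": 0, "stop_toxicity": 0, "stop_futility": 0}
    n_success = 0
    total_n = 0
    for _ in range(n_reps):
        out = simulate_trial(rates, plan, tox_rule, fut_rule, rng)
        counts[out.stop_reason] += 1
        total_n += out.n_final
        if out.final_success:
            n_success += 1
    return OCReport(
        prob_stop_futility=counts["stop_futility"] / n_reps,
        prob_stop_toxicity=counts["stop_toxicity"] / n_reps,
        prob_complete=counts["completed"] / n_reps,
        prob_final_success=n_success / n_reps,
        expected_sample_size=total_n / n_reps,
        replicate_count=n_reps,
        seed=seed,
    )


def monte_carlo_se(p: float, n: int) -> float:
    """Standard error of a Monte Carlo frequency estimate."""
    return math.sqrt(max(p * (1 - p), 1e-12) / n)
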