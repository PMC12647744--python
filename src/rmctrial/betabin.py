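"""Beta-binomial posterior arithmetic.

The trial's monitoring rules and final hypothesis test all reduce to three
primitives on Beta distributions: conjugate updating with binomial data,
tail probabilities of a single Beta-distributed rate, and the probability
that one Beta-distributed rate exceeds another independent one.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import integrate
from scipy import stats

__all__ = [
    "BetaDistribution",
    "BinomialData",
    "update_beta",
    "tail_probability",
    "prob_greater",
]


class InvalidPriorError(ValueError):
    """Raised when a Beta distribution has a non-positive shape parameter."""


@dataclass(frozen=True)
class BetaDistribution:
    """Beta(a, b) distribution over a rate in (0, 1).

    Houses priors and posteriors for the response rate, the historical
    response rate and the extreme-toxicity rate.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidPriorError(
                f"Beta shapes must be positive, got a={self.a}, b={self.b}"
            )

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaDistribution":
        return cls(float(d["a"]), float(d["b"]))


@dataclass(frozen=True)
class BinomialData:
    """Observed successes and failures (r responders, q non-responders)."""

    successes: int
    failures: int

    def __post_init__(self) -> None:
        if self.successes < 0 or self.failures < 0:
            raise ValueError("counts must be non-negative")


def update_beta(prior: BetaDistribution, data: BinomialData) -> BetaDistribution:
    """Conjugate update: Beta(a, b) + (r, q) -> Beta(a + r, b + q)."""
    return BetaDistribution(prior.a + data.successes, prior.b + data.failures)


def tail_probability(
    dist: BetaDistribution, threshold: float, direction: str = "above"
) -> float:
    """P(theta > threshold) or P(theta < threshold) for a Beta rate.

    Parameters
    ----------
    dist
        The Beta distribution of the rate.
    threshold
        A rate in the open interval (0, 1).
    direction
        ``"above"`` for the upper tail, ``"below"`` for the lower tail.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    rv = stats.beta(dist.a, dist.b)
    if direction == "above":
        return float(rv.sf(threshold))
    if direction == "below":
        return float(rv.cdf(threshold))
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def prob_greater(
    dist_a: BetaDistribution, dist_b: BetaDistribution, *, tol: float = 1e-10
) -> float:
    """P(theta_A > theta_B) for independent Beta-distributed rates.

    Computed by adaptive quadrature of ``f_A(x) * F_B(x)`` over (0, 1)
    to absolute tolerance ``tol``.  Continuous distributions, so
    P(A > B) + P(B > A) = 1.
    """
    fa = stats.beta(dist_a.a, dist_a.b)
    fb = stats.beta(dist_b.a, dist_b.b)

    def integrand(x: float) -> float:
        return fa.pdf(x) * fb.cdf(x)

    value, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=200,
        points=[dist_a.mean, dist_b.mean],
    )
    return min(1.0, max(0.0, float(value)))
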