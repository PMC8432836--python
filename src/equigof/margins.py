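"""Translation between the two scales on which the equivalence margin lives.

A Lehmann alternative to a continuous model cdf ``F0`` is ``F = F0**theta``.
Closeness of ``F`` to ``F0`` can be expressed either as a bound ``delta`` on
the Kolmogorov (sup-norm) distance ``||F - F0||`` or as a multiplicative
interval ``(1/(1+eps), 1+eps)`` for the Lehmann parameter ``theta``.  For
Lehmann alternatives the two are in one-to-one correspondence: the sup
distance of ``F0**theta`` from ``F0`` is attained where ``F0 = theta**(1/(1-theta))``
and equals ``|theta**(1/(1-theta)) - theta**(theta/(1-theta))|``, so the margin
pair ``(delta, eps)`` satisfies

    (1+eps)**(-1/eps) - (1+eps)**(-(1+eps)/eps) = delta.

This module solves that relation in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["EquivalenceMargin", "delta_from_epsilon", "epsilon_from_delta", "table1"]

#: tolerance on epsilon for the root solve of the margin equation
_EPS_XTOL = 1e-12


@dataclass(frozen=True)
class EquivalenceMargin:
    """A matched pair of equivalence margins.

    Attributes
    ----------
    delta : float
        Maximal tolerated sup-distance ``||F - F0||``, in (0, 1).
    epsilon : float
        Half-width parameter of the multiplicative theta-interval
        ``(1/(1+epsilon), 1+epsilon)``, positive.
    log_upper : float
        ``log(1 + epsilon)``, the right-hand limit for ``log(theta)`` (the
        scale on which proportional-hazards effects are usually reported).
    """

    delta: float
    epsilon: float
    log_upper: float

    @classmethod
    def from_delta(cls, delta: float) -> "EquivalenceMargin":
        eps = epsilon_from_delta(delta)
        return cls(delta=float(delta), epsilon=eps, log_upper=float(np.log1p(eps)))

    @classmethod
    def from_epsilon(cls, epsilon: float) -> "EquivalenceMargin":
        d = delta_from_epsilon(epsilon)
        return cls(delta=d, epsilon=float(epsilon), log_upper=float(np.log1p(epsilon)))


def delta_from_epsilon(epsilon: float) -> float:
    """Sup-distance margin ``delta`` implied by the theta-margin ``epsilon``.

    Evaluates ``(1+eps)**(-1/eps) - (1+eps)**(-(1+eps)/eps)`` in log space,
    which is the Kolmogorov distance between ``F0**(1+eps)`` and ``F0`` for
    any continuous ``F0``.
    """
    epsilon = float(epsilon)
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    le = np.log1p(epsilon)  # log(1 + eps)
    return float(np.exp(-le / epsilon) - np.exp(-(1.0 + epsilon) * le / epsilon))


def epsilon_from_delta(delta: float) -> float:
    """Theta-margin ``epsilon`` implied by the sup-distance margin ``delta``.

    The map ``epsilon -> delta`` is strictly increasing with range (0, 1),
    so the root is unique; it is found by Brent's method on an adaptively
    widened bracket.
    """
    delta = float(delta)
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    lo, hi = 1e-8, 1.0
    while delta_from_epsilon(hi) < delta:
        hi *= 2.0
        if hi > 1e12:  # delta -> 1 only as eps -> inf
            raise ValueError(f"delta={delta} too close to 1 to resolve")
    if delta_from_epsilon(lo) > delta:
        raise ValueError(f"delta={delta} too close to 0 to resolve")
    return float(
        optimize.brentq(lambda e: delta_from_epsilon(e) - delta, lo, hi, xtol=_EPS_XTOL)
    )


def table1(deltas=(0.05, 0.075, 0.10, 0.15, 0.20, 0.25)) -> list[EquivalenceMargin]:
    """Margin-correspondence table for a grid of customary ``delta`` values."""
    return [EquivalenceMargin.from_delta(d) for d in deltas]
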