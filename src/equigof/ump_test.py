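"""Exact UMP equivalence goodness-of-fit test for a fully specified F0.

The hypotheses are H: theta <= 1/(1+eps) or theta >= 1+eps against the
equivalence alternative K: 1/(1+eps) < theta < 1+eps, where theta is the
Lehmann parameter of F = F0**theta.  Since the joint density is a
one-parameter exponential family with sufficient statistic
sum_i log F0(X_i), a UMP level-alpha test exists; it rejects H (i.e.
establishes goodness-of-fit) iff

    c1 < theta_hat = -n / sum_i log F0(x_i) < c2,

with (c1, c2) fixed by requiring rejection probability exactly alpha at
both boundary values of theta.  By the exact chi-square law of theta_hat
the boundary conditions become, with G the chi-square(2n) cdf,

    G(2*theta_b*n/c1) - G(2*theta_b*n/c2) = alpha,   theta_b in {1/(1+eps), 1+eps},

and the power against any theta is G(2*theta*n/c1) - G(2*theta*n/c2).
Everything here is distribution-free: F0 enters only through the statistic.

Solving the two-boundary system
-------------------------------
On the chi-square scale v1 = 2n/c2 < v2 = 2n/c1 each equation pins one
quantity almost independently of the other once n is moderately large (the
opposite chi-square tail becomes negligible), which makes naive nested 1-D
root finds plateau.  The solver therefore runs a Gauss-Seidel fixed point
(alternately solving each equation exactly in one variable via the
chi-square ppf) to enter the basin, then polishes with a damped 2-D Newton
step using the analytic chi-square-pdf Jacobian.  Residuals of both
equations are stored in the result and must verify below a hard cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lehmann import DistributionModel, LehmannSample, theta_hat

__all__ = [
    "CriticalConstants",
    "UmpTestResult",
    "SolverError",
    "critical_constants",
    "power",
    "run_ump_test",
    "sample_size",
    "table2",
    "mc_rejection_rate",
]

#: residual cap on the two boundary-level equations
_RESIDUAL_CAP = 1e-9


class SolverError(RuntimeError):
    """Critical-constant solver failed to verify; carries the last residual."""

    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (residual {residual:.3e})")


@dataclass(frozen=True)
class CriticalConstants:
    """Solved critical interval (c1, c2) for theta_hat, with audit residual."""

    n: int
    alpha: float
    epsilon: float
    c1: float
    c2: float
    residual: float

    def __post_init__(self):
        if not (0 < self.c1 < self.c2):
            raise ValueError("need 0 < c1 < c2")


@dataclass(frozen=True)
class UmpTestResult:
    theta_hat: float
    constants: CriticalConstants
    reject_H: bool  # True = goodness-of-fit established
    n: int
    model_name: str


def _validate(n: int, alpha: float, epsilon: float) -> tuple[int, float, float]:
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = float(alpha)
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    epsilon = float(epsilon)
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return n, alpha, epsilon


def critical_constants(n: int, alpha: float, epsilon: float) -> CriticalConstants:
    """Solve the two boundary-level equations for (c1, c2)."""
    n, alpha, epsilon = _validate(n, alpha, epsilon)
    t1, t2 = 1.0 / (1.0 + epsilon), 1.0 + epsilon
    chi2 = stats.chi2(2 * n)
    G, Q, g = chi2.cdf, chi2.ppf, chi2.pdf

    # Gauss-Seidel warm start on (v1, v2) = (2n/c2, 2n/c1)
    v1 = Q(1.0 - alpha) / t2
    for _ in range(8):
        v2 = Q(min(alpha + G(t1 * v1), 1.0 - 1e-15)) / t1
        v1 = Q(max(G(t2 * v2) - alpha, 1e-300)) / t2
    v2 = Q(min(alpha + G(t1 * v1), 1.0 - 1e-15)) / t1

    def defects(v1, v2):
        return np.array(
            [G(t1 * v2) - G(t1 * v1) - alpha, G(t2 * v2) - G(t2 * v1) - alpha]
        )

    f = defects(v1, v2)
    for _ in range(100):
        if np.max(np.abs(f)) < 1e-13:
            break
        J = np.array(
            [[-t1 * g(t1 * v1), t1 * g(t1 * v2)], [-t2 * g(t2 * v1), t2 * g(t2 * v2)]]
        )
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            break
        lam, accepted = 1.0, False
        for _ in range(60):
            w1, w2 = v1 - lam * step[0], v2 - lam * step[1]
            if 0.0 < w1 < w2:
                fn = defects(w1, w2)
                if np.max(np.abs(fn)) < np.max(np.abs(f)):
                    accepted = True
                    break
            lam /= 2.0
        if not accepted:
            break
        v1, v2, f = w1, w2, fn

    residual = float(np.max(np.abs(f)))
    if residual > _RESIDUAL_CAP:
        raise SolverError(
            f"critical constants did not converge for n={n}, alpha={alpha}, eps={epsilon}",
            residual,
        )
    return CriticalConstants(
        n=n, alpha=alpha, epsilon=epsilon, c1=float(2 * n / v2), c2=float(2 * n / v1),
        residual=residual,
    )


def power(theta: float, constants: CriticalConstants) -> float:
    """Exact rejection probability under F = F0**theta."""
    theta = float(theta)
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    n = constants.n
    chi2 = stats.chi2(2 * n)
    return float(chi2.cdf(2 * theta * n / constants.c1) - chi2.cdf(2 * theta * n / constants.c2))


def run_ump_test(
    sample: LehmannSample,
    model: DistributionModel | None = None,
    alpha: float = 0.05,
    epsilon: float | None = None,
) -> UmpTestResult:
    """Full test: estimate theta, solve the constants, decide.

    The decision uses strict inequalities; theta_hat landing exactly on a
    critical constant (a measure-zero event) does not reject.
    """
    if epsilon is None:
        raise ValueError("epsilon must be supplied")
    model = model if model is not None else sample.model
    th = theta_hat(sample.values, model)
    cc = critical_constants(sample.n, alpha, epsilon)
    return UmpTestResult(
        theta_hat=th,
        constants=cc,
        reject_H=bool(cc.c1 < th < cc.c2),
        n=sample.n,
        model_name=model.name,
    )


def sample_size(
    alpha: float,
    epsilon: float,
    target_power: float,
    theta: float = 1.0,
    n_cap: int = 10_000_000,
) -> int:
    """Smallest n whose exact power at ``theta`` reaches ``target_power``."""
    _, alpha, epsilon = _validate(1, alpha, epsilon)
    if not 1.0 / (1.0 + epsilon) < theta < 1.0 + epsilon:
        raise ValueError("theta must lie strictly inside the equivalence interval")
    if not alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def pw(n):
        return power(theta, critical_constants(n, alpha, epsilon))

    hi = 1
    while pw(hi) < target_power:
        hi *= 2
        if hi > n_cap:
            raise SolverError(f"target power {target_power} unreachable below n={n_cap}", np.nan)
    lo = hi // 2 if hi > 1 else 0  # pw(lo) < target <= pw(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def table2(
    alpha: float = 0.05,
    epsilons=(0.3135, 0.5077, 0.7341),
    ns=(10, 20, 50, 100, 200),
) -> list[dict]:
    """Critical constants and power at theta=1 over an (epsilon, n) grid."""
    rows = []
    for eps in epsilons:
        for n in ns:
            cc = critical_constants(n, alpha, eps)
            rows.append(
                {"epsilon": eps, "n": n, "c1": cc.c1, "c2": cc.c2, "power_at_1": power(1.0, cc)}
            )
    return rows


def mc_rejection_rate(
    model: DistributionModel,
    theta: float,
    n: int,
    alpha: float,
    epsilon: float,
    reps: int,
    seed: int | np.random.Generator | None = None,
    chunk: int = 20_000_000,
) -> float:
    """Monte-Carlo rejection rate of the UMP test, end to end.

    Simulates full samples through the model quantile, recomputes the
    statistic through the model cdf, and applies the solved critical
    interval; chunked over replicates to bound memory.
    """
    cc = critical_constants(n, alpha, epsilon)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = int(reps)
    per = max(1, min(reps, chunk // max(n, 1)))
    hits = 0
    done = 0
    while done < reps:
        r = min(per, reps - done)
        u = rng.random((r, n))
        np.clip(u, 1e-300, 1.0 - 1e-16, out=u)
        x = np.asarray(model.quantile(u ** (1.0 / theta)), dtype=float)
        logF = np.asarray(model.logcdf(x), dtype=float)
        th = -n / logF.sum(axis=1)
        hits += int(np.count_nonzero((cc.c1 < th) & (th < cc.c2)))
        done += r
    return hits / reps
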