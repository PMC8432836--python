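"""Grouped-data multinomial equivalence counterpart of the UMP test.

The support of F0 is cut at the model quantiles j/k into k classes of equal
model probability 1/k.  Under a Lehmann alternative F0**theta the class
masses become pi_j(theta) = F0(b_j)**theta - F0(b_{j-1})**theta; moving
theta to the boundary 1+eps of its equivalence range induces a Euclidean
distance eps_star = ||pi(1+eps) - pi0||_2 which serves as the margin of the
multinomial equivalence problem

    H*: d(pi, pi0) >= eps_star   vs   K*: d(pi, pi0) < eps_star.

The asymptotic test rejects H* iff

    d2(pi_hat, pi0) < eps_star**2 - z_{1-alpha} * v_n(pi_hat, pi0) / sqrt(n),

where d2 is the squared Euclidean distance of the relative frequencies from
pi0 and v_n**2 = 4 * [sum_j a_j**2 pi_hat_j - (sum_j a_j pi_hat_j)**2] with
a_j = pi_hat_j - pi0_j.  The variance is computed in this moment form,
which is algebraically identical to the ratio/double-sum form but never
divides by an empty class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .lehmann import DistributionModel

__all__ = [
    "GroupedSpec",
    "GroupedTestResult",
    "equal_probability_partition",
    "class_masses",
    "eps_star",
    "group_counts",
    "run_grouped_test",
    "grouped_power",
]

#: enumeration guard for exact power: number of count vectors C(n+k-1, k-1)
_ENUM_CAP = 20_000_000


@dataclass(frozen=True)
class GroupedSpec:
    """Equal-probability partition plus (optionally) the distance margin."""

    k: int
    boundaries: np.ndarray  # k-1 increasing interior cut points
    pi0: np.ndarray         # target class masses, 1/k each
    eps_star: Optional[float] = None

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        p = np.asarray(self.pi0, dtype=float)
        if self.k < 2 or b.size != self.k - 1 or p.size != self.k:
            raise ValueError("inconsistent partition sizes")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pi0 must sum to 1")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "pi0", p)

    def with_margin(self, model: DistributionModel, epsilon: float) -> "GroupedSpec":
        return GroupedSpec(
            k=self.k, boundaries=self.boundaries, pi0=self.pi0,
            eps_star=eps_star(self, model, epsilon),
        )


@dataclass(frozen=True)
class GroupedTestResult:
    counts: np.ndarray
    pi_hat: np.ndarray
    d2: float
    v_n: float
    critical_bound: float  # eps_star**2 - z_{1-alpha} v_n / sqrt(n)
    reject_H: bool         # True = equivalence (goodness-of-fit) established
    degenerate: bool       # v_n = 0, decision reduced to d2 < eps_star**2


def equal_probability_partition(model: DistributionModel, k: int) -> GroupedSpec:
    """Cut the support at the model quantiles j/k, j = 1..k-1."""
    k = int(k)
    if k < 2:
        raise ValueError("k must be >= 2")
    b = np.asarray(model.quantile(np.arange(1, k) / k), dtype=float)
    return GroupedSpec(k=k, boundaries=b, pi0=np.full(k, 1.0 / k))


def class_masses(spec: GroupedSpec, model: DistributionModel, theta: float) -> np.ndarray:
    """Class masses of the partition under F = F0**theta."""
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    F = np.concatenate(([0.0], np.asarray(model.cdf(spec.boundaries), dtype=float), [1.0]))
    return np.diff(F ** float(theta))


def eps_star(spec: GroupedSpec, model: DistributionModel, epsilon: float) -> float:
    """Euclidean-distance margin induced by the theta-margin epsilon.

    Distribution-free across continuous F0 at fixed (k, epsilon): the
    boundary cdf values are j/k regardless of the model.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    pi = class_masses(spec, model, 1.0 + float(epsilon))
    return float(np.linalg.norm(pi - spec.pi0))


def group_counts(values, spec: GroupedSpec) -> np.ndarray:
    """Tabulate raw observations into the classes ((b_{j-1}, b_j] convention)."""
    edges = np.concatenate(([-np.inf], spec.boundaries, [np.inf]))
    idx = np.searchsorted(edges, np.asarray(values, dtype=float), side="left") - 1
    idx = np.clip(idx, 0, spec.k - 1)
    return np.bincount(idx, minlength=spec.k)


def _decision_parts(pi_hat: np.ndarray, pi0: np.ndarray, n: int,
                    eps_star_: float, alpha: float):
    """Vectorized core shared by the single test and the power enumerations.

    ``pi_hat`` may be (k,) or (m, k); returns (d2, v_n, bound, reject).
    """
    a = pi_hat - pi0
    d2 = np.sum(a * a, axis=-1)
    vn2 = 4.0 * (np.sum(a * a * pi_hat, axis=-1) - np.sum(a * pi_hat, axis=-1) ** 2)
    vn = np.sqrt(np.maximum(vn2, 0.0))
    z = stats.norm.ppf(1.0 - alpha)
    bound = eps_star_**2 - z * vn / np.sqrt(n)
    degenerate = vn <= 0.0
    bound = np.where(degenerate, eps_star_**2, bound)
    return d2, vn, bound, d2 < bound, degenerate


def run_grouped_test(
    counts, spec: GroupedSpec, alpha: float = 0.05, eps_star_value: float | None = None
) -> GroupedTestResult:
    """Asymptotic multinomial equivalence test on tabulated class counts.

    When the variance estimate vanishes (e.g. pi_hat = pi0 exactly) the
    asymptotic bound is taken at its vn -> 0 limit eps_star**2 and the
    result is flagged degenerate.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size != spec.k:
        raise ValueError(f"need {spec.k} class counts")
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("need at least one observation")
    es = eps_star_value if eps_star_value is not None else spec.eps_star
    if es is None:
        raise ValueError("spec carries no eps_star; pass eps_star_value or use with_margin()")
    alpha = float(alpha)
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    pi_hat = counts / n
    d2, vn, bound, reject, degen = _decision_parts(pi_hat, spec.pi0, n, float(es), alpha)
    return GroupedTestResult(
        counts=counts.astype(int), pi_hat=pi_hat, d2=float(d2), v_n=float(vn),
        critical_bound=float(bound), reject_H=bool(reject), degenerate=bool(degen),
    )


def _compositions(n: int, k: int) -> np.ndarray:
    """All count vectors of length k summing to n, shape (C(n+k-1,k-1), k)."""
    if k == 1:
        return np.array([[n]], dtype=np.int64)
    blocks = [
        np.hstack([np.full((c.shape[0], 1), first, dtype=np.int64), c])
        for first in range(n + 1)
        for c in (_compositions(n - first, k - 1),)
    ]
    return np.vstack(blocks)


def grouped_power(
    spec: GroupedSpec,
    alpha: float,
    pi_true,
    n: int,
    mode: str = "montecarlo",
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
    eps_star_value: float | None = None,
) -> float:
    """Rejection probability of the grouped test under multinomial(n, pi_true).

    ``mode='exact'`` enumerates every count composition and sums multinomial
    probabilities over the rejection region (guarded by a composition-count
    cap); ``mode='montecarlo'`` estimates by simulation.  Both modes decide
    each count vector through the same vectorized kernel as
    :func:`run_grouped_test`.
    """
    pi_true = np.asarray(pi_true, dtype=float)
    if pi_true.size != spec.k or np.any(pi_true < 0) or abs(pi_true.sum() - 1.0) > 1e-9:
        raise ValueError("pi_true must be a probability vector of length k")
    es = eps_star_value if eps_star_value is not None else spec.eps_star
    if es is None:
        raise ValueError("spec carries no eps_star; pass eps_star_value or use with_margin()")
    n = int(n)
    if mode == "exact":
        from math import comb

        m = comb(n + spec.k - 1, spec.k - 1)
        if m > _ENUM_CAP:
            raise ValueError(
                f"exact enumeration would visit {m} compositions (> {_ENUM_CAP}); "
                "use mode='montecarlo'"
            )
        cnt = _compositions(n, spec.k)
        *_, reject, _ = _decision_parts(cnt / n, spec.pi0, n, float(es), alpha)
        if not np.any(reject):
            return 0.0
        pmf = stats.multinomial(n, pi_true).pmf(cnt[reject])
        return float(np.sum(pmf))
    if mode == "montecarlo":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        cnt = rng.multinomial(n, pi_true, size=int(reps))
        *_, reject, _ = _decision_parts(cnt / n, spec.pi0, n, float(es), alpha)
        return float(np.mean(reject))
    raise ValueError(f"unknown mode {mode!r}")
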