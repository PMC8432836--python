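"""The Lehmann-alternative model F = F0**theta: models, sampling, estimation.

If ``X`` has cdf ``F0**theta`` then the probability-integral transform gives
``F0(X) = U**(1/theta)`` for uniform ``U``, so ``-log F0(X)`` is exponential
with rate ``theta`` and the sum ``S = sum_i -log F0(X_i)`` is Gamma(n, 1/theta),
i.e. ``2*theta*S`` is chi-square with 2n degrees of freedom.  Everything in
this module — sampling, the ML estimator ``theta_hat = n/S`` and its exact,
distribution-free law — flows from that identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionModel",
    "LehmannSample",
    "InvalidObservationError",
    "get_model",
    "model_from_callables",
    "sup_distance",
    "sample_lehmann",
    "theta_hat",
    "theta_hat_cdf",
]


class InvalidObservationError(ValueError):
    """An observation sits at or outside the support of the model.

    ``F0(x)`` is 0 or 1 there, the log is degenerate and the Lehmann
    statistic undefined; the data/model pairing should be checked rather
    than the observation clamped.
    """

    def __init__(self, index: int, value: float, model_name: str):
        self.index = index
        self.value = value
        super().__init__(
            f"observation {index} (value {value!r}) has F0(x) in {{0, 1}} under "
            f"model '{model_name}'; check that the data match the model support"
        )


@dataclass(frozen=True)
class DistributionModel:
    """A fully specified continuous model distribution F0.

    ``log_cdf`` and ``log_density_grad`` (the score ``f0'/f0`` of the
    standardized density, needed only by the location-scale score test) are
    optional; numerically stable defaults are derived when absent.
    """

    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    quantile: Callable[[np.ndarray], np.ndarray]
    density: Callable[[np.ndarray], np.ndarray]
    log_density: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float] = (-np.inf, np.inf)
    log_cdf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    log_density_grad: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def logcdf(self, x):
        if self.log_cdf is not None:
            return self.log_cdf(x)
        with np.errstate(divide="ignore"):
            return np.log(self.cdf(x))

    def dlogf(self, x):
        """f0'/f0; analytic when registered, central differences otherwise."""
        if self.log_density_grad is not None:
            return self.log_density_grad(x)
        h = 1e-6 * max(1.0, float(np.max(np.abs(x))) if np.size(x) else 1.0)
        return (self.log_density(np.asarray(x) + h) - self.log_density(np.asarray(x) - h)) / (2 * h)


def _from_frozen(name: str, dist) -> DistributionModel:
    lo, hi = dist.support()
    return DistributionModel(
        name=name,
        cdf=dist.cdf,
        quantile=dist.ppf,
        density=dist.pdf,
        log_density=dist.logpdf,
        support=(float(lo), float(hi)),
        log_cdf=dist.logcdf,
    )


def get_model(name: str, **params) -> DistributionModel:
    """Catalogue of built-in models.

    Supported names: ``standard_normal``/``normal`` (mu, sigma),
    ``exponential`` (rate), ``uniform`` (a, b), ``logistic`` (loc, scale).
    """
    key = name.lower().replace("-", "_")
    if key in ("standard_normal", "norm", "normal", "gaussian"):
        mu = float(params.pop("mu", 0.0))
        sigma = float(params.pop("sigma", 1.0))
        if params:
            raise ValueError(f"unknown parameters for normal model: {sorted(params)}")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        m = _from_frozen(
            "standard_normal" if (mu, sigma) == (0.0, 1.0) else f"normal({mu},{sigma})",
            stats.norm(mu, sigma),
        )
        # standardized score of the normal density: (log f0)'(z) = -(z-mu)/sigma^2
        return DistributionModel(
            **{**m.__dict__, "log_density_grad": lambda x: -(np.asarray(x) - mu) / sigma**2}
        )
    if key in ("exponential", "expon"):
        rate = float(params.pop("rate", 1.0))
        if params:
            raise ValueError(f"unknown parameters for exponential model: {sorted(params)}")
        if rate <= 0:
            raise ValueError("rate must be positive")
        name_ = "standard_exponential" if rate == 1.0 else f"exponential({rate})"
        return _from_frozen(name_, stats.expon(scale=1.0 / rate))
    if key == "uniform":
        a = float(params.pop("a", 0.0))
        b = float(params.pop("b", 1.0))
        if params:
            raise ValueError(f"unknown parameters for uniform model: {sorted(params)}")
        if not b > a:
            raise ValueError("uniform model needs b > a")
        return _from_frozen(f"uniform({a},{b})", stats.uniform(a, b - a))
    if key == "logistic":
        loc = float(params.pop("loc", 0.0))
        scale = float(params.pop("scale", 1.0))
        if params:
            raise ValueError(f"unknown parameters for logistic model: {sorted(params)}")
        m = _from_frozen(f"logistic({loc},{scale})", stats.logistic(loc, scale))
        # (log f0)'(x) = (1 - 2 F0(x))/scale = -tanh((x-loc)/(2 scale))/scale
        return DistributionModel(
            **{
                **m.__dict__,
                "log_density_grad": lambda x: -np.tanh((np.asarray(x) - loc) / (2 * scale)) / scale,
            }
        )
    raise ValueError(f"unknown model name {name!r}")


def model_from_callables(
    name: str,
    cdf: Callable,
    quantile: Callable,
    density: Callable,
    log_density: Optional[Callable] = None,
    support: tuple[float, float] = (-np.inf, np.inf),
) -> DistributionModel:
    """Wrap user-supplied cdf/quantile/density callables as a model."""
    if log_density is None:
        def log_density(x, _d=density):
            with np.errstate(divide="ignore"):
                return np.log(_d(x))
    return DistributionModel(
        name=name, cdf=cdf, quantile=quantile, density=density,
        log_density=log_density, support=support,
    )


@dataclass(frozen=True)
class LehmannSample:
    """An observed or simulated sample tied to a model F0.

    ``theta`` is the generator truth when the sample was simulated and
    ``None`` for observed data.
    """

    values: np.ndarray
    model: DistributionModel
    theta: Optional[float] = None
    n: int = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("sample must be a non-empty 1-D array")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "n", int(v.size))


def sup_distance(theta: float) -> float:
    """Kolmogorov distance between F0**theta and F0 (any continuous F0).

    Equals ``|theta**(1/(1-theta)) - theta**(theta/(1-theta))|``; the
    apparent singularity at theta = 1 is removable with limit 0.
    """
    theta = float(theta)
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if abs(theta - 1.0) < 1e-8:
        # |t^{1/(1-t)} - t^{t/(1-t)}| = t^{1/(1-t)} |1 - t| -> e^{-1}|1-t| near 1
        return abs(theta - 1.0) / np.e
    lt = np.log(theta)
    return float(abs(np.exp(lt / (1.0 - theta)) - np.exp(theta * lt / (1.0 - theta))))


def sample_lehmann(
    model: DistributionModel,
    theta: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> LehmannSample:
    """Draw n i.i.d. observations with cdf F0**theta.

    Inverse transform: ``X = F0^{-1}(U**(1/theta))`` with U uniform on the
    open interval (0, 1); endpoint draws are rejected so every observation
    is strictly interior to the support.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    bad = (u <= 0.0) | (u >= 1.0)
    while np.any(bad):  # astronomically rare; keeps U in the open interval
        u[bad] = rng.random(int(bad.sum()))
        bad = (u <= 0.0) | (u >= 1.0)
    x = np.asarray(model.quantile(u ** (1.0 / theta)), dtype=float)
    return LehmannSample(values=x, model=model, theta=float(theta))


def _log_f0_values(values: np.ndarray, model: DistributionModel) -> np.ndarray:
    """log F0(x_i) with a hard error on boundary observations."""
    values = np.asarray(values, dtype=float)
    p = np.asarray(model.cdf(values), dtype=float)
    bad = ~((p > 0.0) & (p < 1.0))
    if np.any(bad):
        i = int(np.argmax(bad))
        raise InvalidObservationError(i, float(values[i]), model.name)
    return np.asarray(model.logcdf(values), dtype=float)


def theta_hat(sample: "LehmannSample | np.ndarray | Sequence[float]",
              model: Optional[DistributionModel] = None) -> float:
    """ML estimator of the Lehmann parameter: -n / sum_i log F0(x_i)."""
    if isinstance(sample, LehmannSample):
        values, model = sample.values, sample.model
    else:
        if model is None:
            raise ValueError("model required when sample is a raw array")
        values = np.asarray(sample, dtype=float)
    logF = _log_f0_values(values, model)
    return float(-values.size / logF.sum())


def theta_hat_cdf(t: float, theta: float, n: int) -> float:
    """Exact cdf of theta_hat under F = F0**theta: 1 - G_{2n}(2 theta n / t).

    Distribution-free: depends on the sample only through (theta, n).
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    t = float(t)
    if t <= 0:
        return 0.0
    return float(stats.chi2.sf(2.0 * theta * n / t, df=2 * n))
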