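"""Parametric cell-cycle time distributions.

The division waiting time of a basal progenitor is modelled by one of three
laws sharing a common mean ``mean_cycle`` (days):

* ``exponential`` — the Markovian assumption (coefficient of variation 1);
* ``shifted_gamma`` — a refractory minimum ``t_min`` plus a gamma variate,
  ``t_min + Gamma(shape, scale)`` with ``scale = (mean_cycle - t_min)/shape``,
  so the mean is exactly ``mean_cycle`` for every shape;
* ``deterministic`` — the shape -> infinity limit: every cycle equals the mean.

Division rates are reported in /week while durations are in days; the single
conversion constant lives in :mod:`epiclone.units`.

Because labelling and chase protocols catch cells mid-cycle, simulators need
the *residual* time to first division of a cell observed at a uniformly random
phase of its cycle.  :func:`sample_initial_phase` draws from the stationary
renewal residual-life law with density ``(1 - F(u)) / mean_cycle``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .units import DAYS_PER_WEEK

FAMILIES = ("exponential", "shifted_gamma", "deterministic")

# integer codes shared with the numba engine
_FAMILY_CODE = {"exponential": 0, "shifted_gamma": 1, "deterministic": 2}


class InvalidParameterError(ValueError):
    """Raised when a distribution or model parameter is out of range."""


@dataclass(frozen=True)
class CycleTimeDistribution:
    """A validated cell-cycle time law.

    Parameters
    ----------
    family : str
        One of ``exponential``, ``shifted_gamma``, ``deterministic``.
    mean_cycle : float
        Mean cycle time in days; must exceed ``t_min``.
    shape : float
        Gamma shape ``k`` (dimensionless).  Forced to 1 for the exponential
        family; ignored by the deterministic family.
    t_min : float
        Refractory minimum cycle time in days (hard floor of the support).
    """

    family: str
    mean_cycle: float
    shape: float = 1.0
    t_min: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"unknown cycle-time family {self.family!r}; choose from {FAMILIES}"
            )
        if not (self.mean_cycle > 0):
            raise InvalidParameterError("mean_cycle must be positive")
        if not (self.shape > 0):
            raise InvalidParameterError("shape must be positive")
        if self.t_min < 0:
            raise InvalidParameterError("t_min must be non-negative")
        if self.t_min >= self.mean_cycle:
            raise InvalidParameterError(
                f"t_min ({self.t_min} d) must be below mean_cycle ({self.mean_cycle} d)"
            )
        if self.family == "exponential" and (self.shape != 1.0 or self.t_min != 0.0):
            raise InvalidParameterError(
                "exponential family requires shape=1 and t_min=0"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def division_rate_per_week(self) -> float:
        """Implied average division rate lambda = 1/mean_cycle, in /week."""
        return DAYS_PER_WEEK / self.mean_cycle

    @property
    def code(self) -> int:
        return _FAMILY_CODE[self.family]

    @property
    def scale(self) -> float:
        """Gamma scale parameter (days); 0 for the deterministic family."""
        if self.family == "deterministic":
            return 0.0
        return (self.mean_cycle - self.t_min) / self.shape

    @property
    def variance(self) -> float:
        if self.family == "deterministic":
            return 0.0
        return self.shape * self.scale**2

    @property
    def cv(self) -> float:
        """Coefficient of variation of the cycle time."""
        return float(np.sqrt(self.variance) / self.mean_cycle)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "deterministic":
            return (t >= self.mean_cycle).astype(float)
        return stats.gamma.cdf(t - self.t_min, a=self.shape, scale=self.scale)

    def mean_residual_life(self) -> float:
        """Mean of the stationary residual-life law: (mean/2) * (1 + CV^2)."""
        return 0.5 * self.mean_cycle * (1.0 + self.cv**2)

    def to_config(self) -> dict:
        return {
            "family": self.family,
            "mean_cycle_days": self.mean_cycle,
            "shape": self.shape,
            "t_min_days": self.t_min,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "CycleTimeDistribution":
        return cls(
            family=cfg["family"],
            mean_cycle=float(cfg["mean_cycle_days"]),
            shape=float(cfg.get("shape", 1.0)),
            t_min=float(cfg.get("t_min_days", 0.0)),
        )


def make_cycle_distribution(
    family: str, mean_cycle: float, shape: float = 1.0, t_min: float = 0.0
) -> CycleTimeDistribution:
    """Build and validate a :class:`CycleTimeDistribution`.

    ``mean_cycle`` is in days; the implied division rate (/week) is available
    as ``dist.division_rate_per_week``.
    """
    if family == "exponential":
        shape, t_min = 1.0, 0.0
    return CycleTimeDistribution(family=family, mean_cycle=mean_cycle, shape=shape, t_min=t_min)


def from_rate(
    lambda_per_week: float, family: str = "shifted_gamma", shape: float = 8.0, t_min: float = 0.0
) -> CycleTimeDistribution:
    """Cycle law with mean 7/lambda days for a division rate given in /week."""
    if not lambda_per_week > 0:
        raise InvalidParameterError("division rate must be positive")
    return make_cycle_distribution(family, DAYS_PER_WEEK / lambda_per_week, shape, t_min)


def sample_cycle_times(
    dist: CycleTimeDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` cycle times (days)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if dist.family == "deterministic":
        return np.full(n, dist.mean_cycle)
    if dist.family == "exponential":
        return rng.exponential(dist.mean_cycle, size=n)
    return dist.t_min + rng.gamma(dist.shape, dist.scale, size=n)


def sample_initial_phase(
    dist: CycleTimeDistribution, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Time remaining until first division for cells observed at random phase.

    Samples the stationary-renewal residual-life law, density
    ``(1 - F(u)) / mean_cycle``: draw a length-biased cycle L (density
    ``x f(x)/mean``) and return ``U * L`` with U uniform.  For the shifted
    gamma, the length-biased law is the mixture
    ``t_min + Gamma(k, s)`` w.p. ``t_min/mean`` and
    ``t_min + Gamma(k+1, s)`` w.p. ``1 - t_min/mean``.
    """
    if dist.family == "exponential":
        # memoryless: residual law equals the cycle law
        return rng.exponential(dist.mean_cycle, size=n)
    u = rng.random(n)
    if dist.family == "deterministic":
        return u * dist.mean_cycle
    pick = rng.random(n) < dist.t_min / dist.mean_cycle
    y = np.where(
        pick,
        rng.gamma(dist.shape, dist.scale, size=n),
        rng.gamma(dist.shape + 1.0, dist.scale, size=n),
    )
    return u * (dist.t_min + y)
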