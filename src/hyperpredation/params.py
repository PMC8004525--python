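"""Life-history parameterization of the fox-cottontail-hare model.

The twelve rate constants of the dynamical system are not fitted to time
series; they are derived from three per-species life-history quantities that
field guides actually report:

* mean lifespan (years)  ->  mortality = 1 / lifespan,
* annual multiplication factor P(1)/P(0)  ->  reproduction = ln(factor),
  the exponential-growth rate that realizes that factor in one year,
* carrying capacity K (individuals per km^2)  ->  intraspecific
  competition = (reproduction - mortality) / K, the coefficient that puts
  the single-species logistic equilibrium exactly at K.

Units are fixed package-wide: time in years, densities in individuals per
km^2, rates per year.

The reference set used throughout (red fox Vulpes vulpes, Eastern cottontail
Sylvilagus floridanus, European hare Lepus europaeus) comes from lifespans
(3.5, 1.25, 5.5) years, annual factors (3, 4.5, 5) and carrying capacities
(1, 100, 30) per km^2, with prey-to-predator conversion e = 0.91. The two
hunting rates a (foxes on cottontails) and b (foxes on hares) are scenario
knobs and are left unset by the reference builder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

from .exceptions import InvalidInputError

__all__ = [
    "LifeHistory",
    "Parameters",
    "PARAM_NAMES",
    "REFERENCE_LIFE_HISTORIES",
    "mortality_from_lifespan",
    "reproduction_from_annual_factor",
    "competition_from_capacity",
    "parameters_from_life_histories",
    "reference_parameters",
]

#: Canonical ordering of the twelve model rates.
PARAM_NAMES = ("r", "s", "u", "m", "n", "p", "c_VV", "c_SS", "c_LL", "e", "a", "b")


@dataclass(frozen=True)
class LifeHistory:
    """Per-species demographic summary.

    Parameters
    ----------
    mean_lifespan:
        Average individual lifespan, years; must be positive.
    annual_multiplication:
        Ratio P(1)/P(0) of the population after one year of unconstrained
        growth; dimensionless, positive.
    carrying_capacity:
        Single-species equilibrium density, individuals per km^2; positive.
    """

    mean_lifespan: float
    annual_multiplication: float
    carrying_capacity: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidInputError(
                    f"LifeHistory.{f.name} must be a positive finite number, got {value!r}"
                )


#: Life histories behind the reference parameter set (fox, cottontail, hare).
REFERENCE_LIFE_HISTORIES: dict[str, LifeHistory] = {
    "fox": LifeHistory(mean_lifespan=3.5, annual_multiplication=3.0, carrying_capacity=1.0),
    "cottontail": LifeHistory(mean_lifespan=1.25, annual_multiplication=4.5, carrying_capacity=100.0),
    "hare": LifeHistory(mean_lifespan=5.5, annual_multiplication=5.0, carrying_capacity=30.0),
}


@dataclass(frozen=True)
class Parameters:
    """The twelve nonnegative rates of the three-species model.

    ``r, s, u`` are reproduction rates and ``m, n, p`` mortality rates of
    fox (V), cottontail (S) and hare (L) respectively (per year);
    ``c_VV, c_SS, c_LL`` are the intraspecific competition coefficients
    (per (individual/km^2 * year)); ``e`` in (0, 1] is the prey-to-predator
    conversion coefficient; ``a`` and ``b`` are the fox hunting rates on
    cottontails and hares (per (individual/km^2 * year)).

    ``a`` and ``b`` default to ``None`` ("unset"): the reference builder
    deliberately leaves them open for scenario configuration. Operations
    that need the full dynamics call :meth:`require_hunting`.
    """

    r: float
    s: float
    u: float
    m: float
    n: float
    p: float
    c_VV: float
    c_SS: float
    c_LL: float
    e: float = 0.91
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if value is None:
                if name in ("a", "b"):
                    continue
                raise InvalidInputError(f"parameter {name!r} may not be None")
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
                raise InvalidInputError(
                    f"parameter {name!r} must be a nonnegative finite number, got {value!r}"
                )
        if not (0 < self.e <= 1):
            raise InvalidInputError(f"conversion coefficient e must lie in (0, 1], got {self.e}")

    # -- convenience -------------------------------------------------------

    def require_hunting(self) -> tuple[float, float]:
        """Return ``(a, b)``, raising if either hunting rate is unset."""
        if self.a is None or self.b is None:
            raise InvalidInputError(
                "hunting rates a and b are unset; supply them via with_hunting()"
            )
        return float(self.a), float(self.b)

    def with_hunting(self, a: float, b: float) -> "Parameters":
        """Return a copy with the hunting rates set."""
        return replace(self, a=a, b=b)

    def replace(self, **updates: float) -> "Parameters":
        """Return a copy with the named rates replaced."""
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown parameter name(s): {sorted(unknown)}")
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "Parameters":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**data)

    @property
    def net_rates(self) -> tuple[float, float, float]:
        """Net reproduction rates (r - m, s - n, u - p)."""
        return (self.r - self.m, self.s - self.n, self.u - self.p)


def mortality_from_lifespan(lifespan: float) -> float:
    """Mortality rate (per year) as the reciprocal of the mean lifespan.

    Under a constant per-capita death rate mu the mean time to death is
    1/mu, so a species with mean lifespan T gets mu = 1/T.

    >>> round(mortality_from_lifespan(3.5), 5)
    0.28571
    """
    if not (math.isfinite(lifespan) and lifespan > 0):
        raise InvalidInputError(f"lifespan must be positive and finite, got {lifespan!r}")
    return 1.0 / lifespan


def reproduction_from_annual_factor(factor: float) -> float:
    """Reproduction rate (per year) realizing a given one-year multiplication.

    Solves P(1) = factor * P(0) under exponential growth dP/dt = g P,
    giving g = ln(factor). A stationary population (factor 1) gives 0.

    >>> reproduction_from_annual_factor(3.0) == math.log(3)
    True
    """
    if not (math.isfinite(factor) and factor > 0):
        raise InvalidInputError(f"annual factor must be positive and finite, got {factor!r}")
    return math.log(factor)


def competition_from_capacity(growth: float, mortality: float, capacity: float) -> float:
    """Intraspecific competition coefficient from a carrying capacity.

    The single-species subsystem dP/dt = P (g - mu - c P) equilibrates at
    (g - mu)/c; solving for c so that this equals the observed capacity K
    gives c = (g - mu)/K. A nonpositive net rate g - mu yields a
    nonpositive coefficient (the species cannot sustain any capacity) and
    triggers a warning.
    """
    if not (math.isfinite(capacity) and capacity > 0):
        raise InvalidInputError(f"capacity must be positive and finite, got {capacity!r}")
    if growth <= mortality:
        warnings.warn(
            "growth <= mortality: derived competition coefficient is nonpositive",
            stacklevel=2,
        )
    return (growth - mortality) / capacity


def parameters_from_life_histories(
    fox: LifeHistory,
    cottontail: LifeHistory,
    hare: LifeHistory,
    e: float = 0.91,
    a: float | None = None,
    b: float | None = None,
) -> Parameters:
    """Derive the full rate set from three per-species life histories."""
    r = reproduction_from_annual_factor(fox.annual_multiplication)
    s = reproduction_from_annual_factor(cottontail.annual_multiplication)
    u = reproduction_from_annual_factor(hare.annual_multiplication)
    m = mortality_from_lifespan(fox.mean_lifespan)
    n = mortality_from_lifespan(cottontail.mean_lifespan)
    p = mortality_from_lifespan(hare.mean_lifespan)
    return Parameters(
        r=r, s=s, u=u, m=m, n=n, p=p,
        c_VV=competition_from_capacity(r, m, fox.carrying_capacity),
        c_SS=competition_from_capacity(s, n, cottontail.carrying_capacity),
        c_LL=competition_from_capacity(u, p, hare.carrying_capacity),
        e=e, a=a, b=b,
    )


def reference_parameters(a: float | None = None, b: float | None = None) -> Parameters:
    """Build the reference parameter set used throughout the package.

    Exact expressions: r = ln 3, m = 2/7, c_VV = ln 3 - 2/7 (so the fox-only
    equilibrium is exactly 1 per km^2), e = 0.91; s = ln 4.5, n = 4/5,
    c_SS = (ln 4.5 - 4/5)/100; u = ln 5, p = 2/11, c_LL = (ln 5 - 2/11)/30.
    Hunting rates a, b are unset unless given.
    """
    return parameters_from_life_histories(
        REFERENCE_LIFE_HISTORIES["fox"],
        REFERENCE_LIFE_HISTORIES["cottontail"],
        REFERENCE_LIFE_HISTORIES["hare"],
        e=0.91, a=a, b=b,
    )
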