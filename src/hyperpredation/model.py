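"""Right-hand side and Jacobian of the three-species dynamical system.

The state is (V, S, L): fox, cottontail and hare densities per km^2. Each
species grows logistically with separate reproduction and mortality rates;
foxes gain e*a*S + e*b*L per capita from predation, cottontails lose a*V and
hares b*V. Predation is bilinear (Holling type I): at the densities relevant
here (foxes ~1-2.5/km^2, lagomorphs tens per km^2) feeding saturation does
not arise, so the linear regime of a saturating response suffices. There is
no direct cottontail-hare competition: the two lagomorphs occupy different
niches, and their interaction is entirely fox-mediated.

    dV/dt = V (r - c_VV V - m + e a S + e b L)
    dS/dt = S (s - c_SS S - n - a V)
    dL/dt = L (u - c_LL L - p - b V)

Each right-hand side carries its own population as a factor, so the
coordinate faces {V=0}, {S=0}, {L=0} are forward-invariant: an extinct
species stays extinct.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError
from .params import Parameters

__all__ = ["rhs", "jacobian", "total_population", "as_state"]

#: Component order of the state vector.
SPECIES = ("V", "S", "L")


def as_state(state, allow_negative: bool = False) -> np.ndarray:
    """Validate and coerce a state to a float array of shape (3,)."""
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"state must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"state contains non-finite entries: {arr}")
    if not allow_negative and np.any(arr < 0):
        raise InvalidInputError(f"state densities must be nonnegative: {arr}")
    return arr


def rhs(state, params: Parameters, *, validate: bool = True) -> np.ndarray:
    """Time derivative (dV/dt, dS/dt, dL/dt) at a state.

    With ``validate=False`` negative components are accepted; this is used
    internally to evaluate residuals at infeasible equilibrium candidates,
    which are exact algebraic roots regardless of sign.
    """
    y = as_state(state, allow_negative=not validate)
    a, b = params.require_hunting()
    V, S, L = y
    return np.array([
        V * (params.r - params.c_VV * V - params.m + params.e * a * S + params.e * b * L),
        S * (params.s - params.c_SS * S - params.n - a * V),
        L * (params.u - params.c_LL * L - params.p - b * V),
    ])


def jacobian(state, params: Parameters, *, validate: bool = True) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`, rows/columns ordered (V, S, L).

    The (S, L) and (L, S) entries are identically zero: the two prey couple
    only through the predator.
    """
    y = as_state(state, allow_negative=not validate)
    a, b = params.require_hunting()
    V, S, L = y
    e = params.e
    return np.array([
        [params.r - 2 * params.c_VV * V - params.m + e * a * S + e * b * L, e * a * V, e * b * V],
        [-a * S, params.s - 2 * params.c_SS * S - params.n - a * V, 0.0],
        [-b * L, 0.0, params.u - 2 * params.c_LL * L - params.p - b * V],
    ])


def total_population(state) -> float:
    """Total environmental density A = V + S + L.

    A is the quantity whose boundedness confines trajectories to a compact
    set of the first orthant; :func:`hyperpredation.simulate.boundedness_audit`
    monitors it along computed trajectories.
    """
    return float(np.sum(as_state(state)))
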