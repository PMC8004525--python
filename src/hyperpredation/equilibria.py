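"""Closed-form equilibria of the three-species system and their classification.

The system has exactly eight equilibrium candidates, labelled by which
populations persist:

========  ===================  =========================================
label     persisting species   closed form
========  ===================  =========================================
E0        none                 (0, 0, 0)
E1        V                    ((r-m)/c_VV, 0, 0)
E2        S                    (0, (s-n)/c_SS, 0)
E4        L                    (0, 0, (u-p)/c_LL)
E3        V, S                 fox-cottontail subsystem
E5        V, L                 fox-hare subsystem
E6        S, L                 the two prey at their capacities
E7        V, S, L              coexistence
========  ===================  =========================================

Feasibility (all populations nonnegative) and local stability are decided by
closed-form inequalities on the rates; for the two-species and coexistence
points the Routh-Hurwitz conditions reduce to a single extra inequality
(E3, E5) or to nothing at all: a feasible coexistence point E7 is always
locally stable. Because the model admits a global Lyapunov function, the
unique feasible-and-stable equilibrium is in fact the global attractor, and
bistability never occurs away from bifurcation boundaries.

Margin convention
-----------------
Every inequality is reported as a *margin* that is positive exactly when the
condition holds (for "x < y" conditions the margin is y - x). Margins of
exactly zero are classified as not satisfied: boundary parameters belong to
the bifurcation machinery, not to classification. Feasibility margins of the
two- and three-species points are the closed-form population *numerators*
(their denominators are positive), which makes them polynomials of degree
<= 2 in any single rate -- the property :mod:`hyperpredation.bifurcation`
exploits to solve thresholds in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import model
from .exceptions import ClassificationError, DegenerateModelError, InvalidInputError
from .params import Parameters

__all__ = [
    "LABELS",
    "SPECIES_SETS",
    "Equilibrium",
    "RegimeThresholds",
    "RegimeCase",
    "equilibrium_state",
    "component_numerator",
    "feasibility",
    "stability",
    "equilibrium_points",
    "classify",
    "regime_case",
]

LABELS = ("E0", "E1", "E2", "E3", "E4", "E5", "E6", "E7")

#: Which populations persist at each equilibrium.
SPECIES_SETS: dict[str, frozenset[str]] = {
    "E0": frozenset(),
    "E1": frozenset({"V"}),
    "E2": frozenset({"S"}),
    "E3": frozenset({"V", "S"}),
    "E4": frozenset({"L"}),
    "E5": frozenset({"V", "L"}),
    "E6": frozenset({"S", "L"}),
    "E7": frozenset({"V", "S", "L"}),
}


@dataclass(frozen=True)
class Equilibrium:
    """One classified equilibrium candidate.

    ``populations`` is the closed-form candidate and may carry negative
    components when infeasible. ``conditions`` maps condition names to
    margins (positive = satisfied); feasibility margins are prefixed
    ``feas:`` and stability margins ``stab:``. ``stable`` reports the
    closed-form stability column even for infeasible candidates (useful for
    drawing exchange diagrams) but is only meaningful jointly with
    ``feasible``.
    """

    label: str
    populations: np.ndarray
    feasible: bool
    stable: bool
    eigenvalues: np.ndarray
    conditions: dict[str, float]


def _check_denominators(params: Parameters) -> None:
    if min(params.c_VV, params.c_SS, params.c_LL) <= 0:
        raise DegenerateModelError(
            "closed-form equilibria require strictly positive intraspecific "
            f"competition coefficients, got c_VV={params.c_VV}, "
            f"c_SS={params.c_SS}, c_LL={params.c_LL}"
        )


def component_numerator(label: str, species: str, params: Parameters) -> float:
    """Numerator of one population component of an equilibrium closed form.

    The denominators (c_VV, a^2 e + c_VV c_SS, ...) are positive for valid
    parameters, so the numerator carries the sign of the component and is the
    natural feasibility margin. As a function of any single rate it is a
    polynomial of degree at most two.
    """
    r, s, u, m, n, p = params.r, params.s, params.u, params.m, params.n, params.p
    cv, cs, cl, e = params.c_VV, params.c_SS, params.c_LL, params.e
    if label in ("E3", "E5", "E7"):
        a, b = params.require_hunting()
    key = (label, species)
    if key == ("E1", "V"):
        return r - m
    if key in (("E2", "S"), ("E6", "S")):
        return s - n
    if key in (("E4", "L"), ("E6", "L")):
        return u - p
    if key == ("E3", "V"):
        return a * e * (s - n) + cs * (r - m)
    if key == ("E3", "S"):
        return a * (m - r) + cv * (s - n)
    if key == ("E5", "V"):
        return b * e * (u - p) + cl * (r - m)
    if key == ("E5", "L"):
        return b * (m - r) + cv * (u - p)
    if key == ("E7", "V"):
        return b * e * cs * (u - p) + a * e * cl * (s - n) + cs * cl * (r - m)
    if key == ("E7", "S"):
        return a * b * e * (p - u) + b * b * e * (s - n) + a * cl * (m - r) + cv * cl * (s - n)
    if key == ("E7", "L"):
        return a * a * e * (u - p) + a * b * e * (n - s) + b * cs * (m - r) + cv * cs * (u - p)
    raise InvalidInputError(f"no component {species!r} at equilibrium {label!r}")


def _denominator(label: str, params: Parameters) -> float:
    cv, cs, cl, e = params.c_VV, params.c_SS, params.c_LL, params.e
    if label in ("E0", "E6"):
        return 1.0  # E6 handled per-component below
    if label == "E1":
        return cv
    if label == "E2":
        return cs
    if label == "E4":
        return cl
    a, b = params.require_hunting()
    if label == "E3":
        return a * a * e + cv * cs
    if label == "E5":
        return b * b * e + cv * cl
    return b * b * e * cs + a * a * e * cl + cv * cs * cl  # E7


def equilibrium_state(label: str, params: Parameters) -> np.ndarray:
    """Closed-form candidate populations (V, S, L) for one equilibrium.

    Components may be negative (infeasible candidate); they are exact
    algebraic roots of the right-hand side either way.
    """
    if label not in LABELS:
        raise InvalidInputError(f"unknown equilibrium label {label!r}")
    _check_denominators(params)
    pops = np.zeros(3)
    if label == "E6":
        pops[1] = (params.s - params.n) / params.c_SS
        pops[2] = (params.u - params.p) / params.c_LL
        return pops
    den = _denominator(label, params)
    for i, species in enumerate(model.SPECIES):
        if species in SPECIES_SETS[label]:
            pops[i] = component_numerator(label, species, params) / den
    return pops


# ---------------------------------------------------------------------------
# Feasibility and stability (closed-form inequality columns)
# ---------------------------------------------------------------------------


def feasibility(label: str, params: Parameters) -> tuple[bool, dict[str, float]]:
    """Closed-form feasibility verdict and margins for one candidate.

    Margins are the population numerators of the persisting species
    (positive = that population is positive). E0 has no conditions and is
    always feasible. Zero margins count as infeasible (boundary).
    """
    if label not in LABELS:
        raise InvalidInputError(f"unknown equilibrium label {label!r}")
    _check_denominators(params)
    margins = {
        f"feas:{label}.{sp}>0": component_numerator(label, sp, params)
        for sp in model.SPECIES
        if sp in SPECIES_SETS[label]
    }
    return all(v > 0 for v in margins.values()), margins


def stability(label: str, params: Parameters) -> tuple[bool, dict[str, float]]:
    """Closed-form local-stability verdict and margins for one candidate.

    Evaluates the per-equilibrium eigenvalue/Routh-Hurwitz conditions;
    margins are positive when the condition holds. For E3 and E5 the
    two-dimensional Routh-Hurwitz block is automatically stable when the
    candidate is feasible, leaving the single transverse condition; a
    feasible E7 is unconditionally stable, so its stability margins are its
    feasibility margins. The verdict is formal for infeasible candidates.
    """
    if label not in LABELS:
        raise InvalidInputError(f"unknown equilibrium label {label!r}")
    _check_denominators(params)
    r, s, u, m, n, p, e = params.r, params.s, params.u, params.m, params.n, params.p, params.e
    if label in ("E1", "E2", "E3", "E4", "E5", "E6", "E7"):
        a, b = params.require_hunting()
    pops = equilibrium_state(label, params)
    V, S, L = pops

    if label == "E0":
        margins = {"stab:r<m": m - r, "stab:s<n": n - s, "stab:u<p": p - u}
    elif label == "E1":
        margins = {
            "stab:m<r": r - m,
            "stab:s<n+aV1": n + a * V - s,
            "stab:u<p+bV1": p + b * V - u,
        }
    elif label == "E2":
        margins = {"stab:r+eaS2<m": m - r - e * a * S, "stab:n<s": s - n, "stab:u<p": p - u}
    elif label == "E3":
        margins = {"stab:u<p+bV3": p + b * V - u}
    elif label == "E4":
        margins = {"stab:r+ebL4<m": m - r - e * b * L, "stab:s<n": n - s, "stab:p<u": u - p}
    elif label == "E5":
        margins = {"stab:s<n+aV5": n + a * V - s}
    elif label == "E6":
        margins = {"stab:r+eaS6+ebL6<m": m - r - e * a * S - e * b * L}
    else:  # E7: stable whenever feasible
        margins = {
            f"stab:{k.split(':', 1)[1]}": v for k, v in feasibility("E7", params)[1].items()
        }
    return all(v > 0 for v in margins.values()), margins


def _build(label: str, params: Parameters) -> Equilibrium:
    pops = equilibrium_state(label, params)
    feas, fmarg = feasibility(label, params)
    stab, smarg = stability(label, params)
    eigs = np.linalg.eigvals(model.jacobian(pops, params, validate=False))
    return Equilibrium(
        label=label,
        populations=pops,
        feasible=feas,
        stable=stab,
        eigenvalues=eigs,
        conditions={**fmarg, **smarg},
    )


def equilibrium_points(params: Parameters) -> list[Equilibrium]:
    """All eight equilibrium candidates, classified.

    Always returns exactly eight entries, E0..E7 in label order; infeasible
    candidates are included (with their formal stability verdict) so that
    exchange diagrams and sweeps can track them across boundaries.
    """
    _check_denominators(params)
    params.require_hunting()
    return [_build(label, params) for label in LABELS]


def classify(params: Parameters) -> Equilibrium:
    """The unique feasible-and-stable equilibrium -- the global attractor.

    Raises :class:`ClassificationError` if zero or several candidates
    qualify, which signals parameters on a bifurcation boundary (some margin
    is zero to within rounding).
    """
    winners = [eq for eq in equilibrium_points(params) if eq.feasible and eq.stable]
    if len(winners) != 1:
        raise ClassificationError(
            f"expected exactly one feasible-and-stable equilibrium, found "
            f"{[eq.label for eq in winners]}; parameters are on or near a "
            "bifurcation boundary"
        )
    return winners[0]


# ---------------------------------------------------------------------------
# Regime taxonomy by net reproduction rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimeThresholds:
    """Competition-rate thresholds governing the regime taxonomy.

    ``k1 = a (r-m)/(s-n)`` and ``k2 = b (r-m)/(u-p)`` bound the fox
    competition c_VV: below them the foxes exclude the respective prey.
    ``h2 = a e (s-n)/(m-r)`` and ``g2 = b e (u-p)/(m-r)`` (defined when
    foxes cannot persist alone, m > r) bound the prey competition
    coefficients: a prey's subsidy sustains the foxes only while its
    competition coefficient stays below the threshold, i.e. c_SS < h2 makes
    the fox-cottontail point E3 feasible while c_SS > h2 stabilizes the
    cottontail-only point E2 (analogously g2 for E5 versus E4).
    Thresholds whose denominator vanishes or whose sign premise fails are
    NaN.
    """

    k1: float
    k2: float
    h2: float
    g2: float
    net_rates: tuple[float, float, float]


#: Regime index by sign pattern of (r-m, s-n, u-p); True = positive.
_CASE_INDEX = {
    (False, False, False): 1,
    (True, False, False): 2,
    (False, True, False): 3,
    (True, True, False): 4,
    (False, False, True): 5,
    (True, False, True): 6,
    (False, True, True): 7,
    (True, True, True): 8,
}


@dataclass(frozen=True)
class RegimeCase:
    """Outcome taxonomy entry for one sign pattern of the net rates."""

    case: int
    signs: tuple[int, int, int]
    thresholds: RegimeThresholds
    candidates: tuple[str, ...]
    attractor: str


def regime_thresholds(params: Parameters) -> RegimeThresholds:
    a, b = params.require_hunting()
    dr, ds, dl = params.net_rates

    def safe(num: float, den: float) -> float:
        return num / den if den != 0 else math.nan

    return RegimeThresholds(
        k1=safe(a * dr, ds),
        k2=safe(b * dr, dl),
        h2=safe(a * params.e * ds, -dr),
        g2=safe(b * params.e * dl, -dr),
        net_rates=(dr, ds, dl),
    )


def regime_case(params: Parameters) -> RegimeCase:
    """Map the sign pattern of the net reproduction rates to its regime.

    The eight sign patterns of (r-m, s-n, u-p) partition parameter space
    into regimes; within each, the admissible long-run outcomes are decided
    by comparing competition coefficients against the k1/k2/h2/g2
    thresholds, which is equivalent to the closed-form feasibility/stability
    columns. ``candidates`` lists the feasible equilibria and ``attractor``
    the unique feasible-and-stable one. A zero net rate is a boundary case
    and raises.
    """
    dr, ds, dl = params.net_rates
    if 0.0 in (dr, ds, dl):
        raise ClassificationError(
            f"zero net reproduction rate (r-m, s-n, u-p)={params.net_rates}: "
            "sign-pattern regime is undefined on the boundary"
        )
    case = _CASE_INDEX[(dr > 0, ds > 0, dl > 0)]
    points = equilibrium_points(params)
    candidates = tuple(eq.label for eq in points if eq.feasible)
    attractor = classify(params).label
    return RegimeCase(
        case=case,
        signs=(int(math.copysign(1, dr)), int(math.copysign(1, ds)), int(math.copysign(1, dl))),
        thresholds=regime_thresholds(params),
        candidates=candidates,
        attractor=attractor,
    )
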