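"""Transcritical-bifurcation detection and classification.

The equilibria of the model exchange stability through transcritical
bifurcations only: a global Lyapunov function rules out limit cycles (hence
Hopf points), and every third-order partial derivative of the right-hand
side vanishes identically, ruling out pitchforks. At a transcritical
threshold two equilibria whose species sets differ by exactly one species
coincide -- the extra population of the "larger" equilibrium passes through
zero -- and swap stability. The feasibility margin of the larger equilibrium
(the closed-form numerator of the vanishing component) is therefore the same
analytic locus as the transverse stability margin of the smaller one, and it
is a polynomial of degree at most two in any single rate. Thresholds are
solved in closed form from that polynomial and cross-checked by bisection;
each detected point is then classified by Sotomayor's transversality
conditions evaluated numerically on the null eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from . import model
from .equilibria import (
    SPECIES_SETS,
    component_numerator,
    classify,
    equilibrium_state,
)
from .exceptions import (
    ClassificationError,
    InvalidInputError,
    ThresholdNotFoundError,
)
from .params import Parameters

__all__ = [
    "BifurcationPoint",
    "SweepResult",
    "LyapunovForm",
    "SWEEPABLE_PARAMETERS",
    "eigenvalues_at",
    "threshold_solve",
    "sweep",
    "sotomayor_check",
    "lyapunov_matrix",
]

#: Rates along which thresholds may be swept (the ones with known
#: parameter-derivative arrays of the vector field).
SWEEPABLE_PARAMETERS = ("a", "b", "r", "s", "u", "c_VV", "c_SS", "c_LL")


@dataclass(frozen=True)
class BifurcationPoint:
    """A localized stability exchange along one swept rate.

    ``pair`` is ordered (larger, smaller) by species set; ``kind`` is one of
    ``transcritical``, ``saddle-node``, ``degenerate`` (a pitchfork is
    impossible here); ``transversality`` holds the Sotomayor scalars
    ``w.F_mu``, ``w.DF_mu v``, ``w.D2F(v,v)`` and the identically zero
    pitchfork quantity ``w.D3F(v,v,v)``; ``residual`` is the margin at the
    solved critical value.
    """

    parameter: str
    critical_value: float
    pair: tuple[str, str]
    kind: str
    transversality: dict[str, float]
    residual: float


@dataclass(frozen=True)
class SweepResult:
    """Attractor classification along a one-parameter grid."""

    parameter: str
    grid: np.ndarray
    labels: list[str | None]
    points: list[BifurcationPoint]
    chain: tuple[str, ...]
    unresolved: list[tuple[float, float, str, str]]


def eigenvalues_at(label: str, params: Parameters) -> np.ndarray:
    """Eigenvalues of the Jacobian at an equilibrium candidate.

    At E0 these are exactly the net reproduction rates (r-m, s-n, u-p).
    """
    pops = equilibrium_state(label, params)
    if not np.all(np.isfinite(pops)):
        raise InvalidInputError(f"non-finite populations at {label}: {pops}")
    return np.linalg.eigvals(model.jacobian(pops, params, validate=False))


# ---------------------------------------------------------------------------
# Threshold solving
# ---------------------------------------------------------------------------


def _exchange(pair: Sequence[str]) -> tuple[str, str, str]:
    """Order a pair as (larger, smaller) and name the exchanged species."""
    x, y = pair
    if x not in SPECIES_SETS or y not in SPECIES_SETS:
        raise InvalidInputError(f"unknown equilibrium label in pair {pair!r}")
    sx, sy = SPECIES_SETS[x], SPECIES_SETS[y]
    if sx > sy and len(sx - sy) == 1:
        return x, y, next(iter(sx - sy))
    if sy > sx and len(sy - sx) == 1:
        return y, x, next(iter(sy - sx))
    raise ThresholdNotFoundError(
        f"equilibria {x} and {y} do not share a transcritical boundary arc "
        "(their species sets must be nested and differ by one species)"
    )


def _margin_fn(larger: str, species: str, parameter: str, params: Parameters) -> Callable[[float], float]:
    def margin(theta: float) -> float:
        return component_numerator(larger, species, params.replace(**{parameter: theta}))

    return margin


def _closed_form_roots(margin: Callable[[float], float], lo: float, hi: float) -> np.ndarray:
    """Exact roots of the (at most quadratic) margin polynomial.

    Three-point Lagrange interpolation over the bracket is exact because the
    margin is a polynomial of degree <= 2 in the swept rate.
    """
    xs = np.array([lo, 0.5 * (lo + hi), hi])
    ys = np.array([margin(x) for x in xs])
    # polynomial coefficients (highest first), exact for degree <= 2
    coeffs = np.linalg.solve(np.vander(xs, 3), ys)
    scale = max(np.max(np.abs(ys)), 1e-300)
    if abs(coeffs[0]) < 1e-12 * scale / max(hi - lo, 1e-300) ** 2:
        if abs(coeffs[1]) < 1e-12 * scale / max(hi - lo, 1e-300):
            raise ThresholdNotFoundError("margin is constant over the bracket")
        return np.array([-coeffs[2] / coeffs[1]])
    roots = np.roots(coeffs)
    return np.sort(roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real)


def threshold_solve(
    pair: Sequence[str],
    parameter: str,
    params: Parameters,
    bracket: tuple[float, float],
) -> BifurcationPoint:
    """Locate the stability exchange between two adjacent equilibria.

    The margin (vanishing-component numerator of the larger equilibrium)
    must change sign over ``bracket``; the root is found both in closed form
    (the margin is affine or quadratic in the swept rate) and by bisection,
    the two solutions are required to coincide to 1e-9, and one Jacobian
    eigenvalue of each equilibrium in the pair is verified to cross zero at
    the threshold. Brackets containing several roots (possible for quadratic
    margins) are rejected by the sign-change requirement; sweep() supplies
    isolating brackets.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise InvalidInputError(
            f"parameter {parameter!r} is not sweepable; choose from {SWEEPABLE_PARAMETERS}"
        )
    larger, smaller, species = _exchange(pair)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise InvalidInputError(f"bracket must satisfy lo < hi, got {bracket!r}")
    margin = _margin_fn(larger, species, parameter, params)
    f_lo, f_hi = margin(lo), margin(hi)
    if f_lo == 0.0 or f_hi == 0.0 or np.sign(f_lo) == np.sign(f_hi):
        raise ThresholdNotFoundError(
            f"margin of {larger}/{smaller} does not change sign over "
            f"{parameter} in [{lo}, {hi}] (values {f_lo:.3e}, {f_hi:.3e})"
        )
    root_bisect = brentq(margin, lo, hi, xtol=1e-14)
    roots = _closed_form_roots(margin, lo, hi)
    in_bracket = roots[(roots >= lo) & (roots <= hi)]
    candidates = in_bracket if in_bracket.size else roots
    root = float(candidates[np.argmin(np.abs(candidates - root_bisect))])
    if abs(root - root_bisect) > 1e-9 * max(1.0, abs(root)):
        raise ThresholdNotFoundError(
            f"closed-form root {root} and bisection root {root_bisect} disagree"
        )

    critical = params.replace(**{parameter: root})
    for label in (larger, smaller):
        eigs = eigenvalues_at(label, critical)
        if np.min(np.abs(eigs)) > 1e-6 * max(1.0, np.max(np.abs(eigs))):
            raise ThresholdNotFoundError(
                f"no eigenvalue of {label} crosses zero at {parameter}={root}"
            )

    kind, transversality = _sotomayor(parameter, smaller, critical)
    return BifurcationPoint(
        parameter=parameter,
        critical_value=root,
        pair=(larger, smaller),
        kind=kind,
        transversality=transversality,
        residual=margin(root),
    )


# ---------------------------------------------------------------------------
# Sotomayor transversality tests
# ---------------------------------------------------------------------------


def _f_mu(parameter: str, state: np.ndarray, params: Parameters) -> np.ndarray:
    """Partial derivative of the vector field w.r.t. one rate."""
    V, S, L = state
    e = params.e
    table = {
        "a": (e * S * V, -S * V, 0.0),
        "b": (e * L * V, 0.0, -L * V),
        "r": (V, 0.0, 0.0),
        "s": (0.0, S, 0.0),
        "u": (0.0, 0.0, L),
        "c_VV": (-V * V, 0.0, 0.0),
        "c_SS": (0.0, -S * S, 0.0),
        "c_LL": (0.0, 0.0, -L * L),
    }
    return np.array(table[parameter])


def _df_mu(parameter: str, state: np.ndarray, params: Parameters) -> np.ndarray:
    """State-Jacobian of :func:`_f_mu`."""
    V, S, L = state
    e = params.e
    table = {
        "a": [[e * S, e * V, 0], [-S, -V, 0], [0, 0, 0]],
        "b": [[e * L, 0, e * V], [0, 0, 0], [-L, 0, -V]],
        "r": [[1, 0, 0], [0, 0, 0], [0, 0, 0]],
        "s": [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        "u": [[0, 0, 0], [0, 0, 0], [0, 0, 1]],
        "c_VV": [[-2 * V, 0, 0], [0, 0, 0], [0, 0, 0]],
        "c_SS": [[0, 0, 0], [0, -2 * S, 0], [0, 0, 0]],
        "c_LL": [[0, 0, 0], [0, 0, 0], [0, 0, -2 * L]],
    }
    return np.array(table[parameter], dtype=float)


def _d2f(x: np.ndarray, y: np.ndarray, params: Parameters) -> np.ndarray:
    """Second derivative of the vector field as a bilinear form D2F(x, y)."""
    a, b = params.require_hunting()
    e = params.e
    return np.array([
        -2 * params.c_VV * x[0] * y[0]
        + e * a * (x[0] * y[1] + x[1] * y[0])
        + e * b * (x[0] * y[2] + x[2] * y[0]),
        -a * (x[0] * y[1] + x[1] * y[0]) - 2 * params.c_SS * x[1] * y[1],
        -b * (x[0] * y[2] + x[2] * y[0]) - 2 * params.c_LL * x[2] * y[2],
    ])


def _null_vector(matrix: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unit-norm real null eigenvector; flags a non-simple zero eigenvalue."""
    eigvals, eigvecs = np.linalg.eig(matrix)
    order = np.argsort(np.abs(eigvals))
    scale = max(1.0, float(np.max(np.abs(eigvals))))
    simple = np.abs(eigvals[order[1]]) > 1e-6 * scale
    vec = np.real(eigvecs[:, order[0]])
    vec = vec / np.linalg.norm(vec)
    lead = np.nonzero(np.abs(vec) > 1e-12)[0]
    if lead.size and vec[lead[0]] < 0:
        vec = -vec
    return vec, simple


def _crossing_speed(parameter: str, boundary_label: str, critical: Parameters) -> float:
    """d(lambda)/d(mu) of the critical eigenvalue along the equilibrium branch.

    Central finite difference of the eigenvalue nearest zero of the boundary
    equilibrium's Jacobian. This captures stability exchanges that happen
    through motion of the equilibrium itself, which the fixed-state scalar
    ``w.DF_mu.v`` misses whenever the vanishing species' equation does not
    contain the swept rate (e.g. the coexistence/hare-extinction exchange
    swept in the cottontail hunting rate a).
    """
    mu0 = float(getattr(critical, parameter))
    delta = 1e-6 * max(1.0, abs(mu0))

    def critical_eig(mu: float) -> float:
        eigs = eigenvalues_at(boundary_label, critical.replace(**{parameter: mu}))
        return float(np.real(eigs[np.argmin(np.abs(eigs))]))

    return (critical_eig(mu0 + delta) - critical_eig(mu0 - delta)) / (2 * delta)


def _sotomayor(parameter: str, boundary_label: str, critical: Parameters) -> tuple[str, dict[str, float]]:
    x0 = equilibrium_state(boundary_label, critical)
    J = model.jacobian(x0, critical, validate=False)
    v, simple_right = _null_vector(J)
    w, simple_left = _null_vector(J.T)
    scalars = {
        "w.F_mu": float(w @ _f_mu(parameter, x0, critical)),
        "w.DF_mu.v": float(w @ (_df_mu(parameter, x0, critical) @ v)),
        "w.D2F(v,v)": float(w @ _d2f(v, v, critical)),
        # every third partial of the vector field is identically zero
        "w.D3F(v,v,v)": 0.0,
        "dlambda/dmu": _crossing_speed(parameter, boundary_label, critical),
    }
    if not (simple_right and simple_left):
        return "degenerate", scalars
    tol = 1e-8
    if abs(scalars["w.F_mu"]) < tol:
        crosses = abs(scalars["w.DF_mu.v"]) > tol or abs(scalars["dlambda/dmu"]) > tol
        if crosses and abs(scalars["w.D2F(v,v)"]) > tol:
            return "transcritical", scalars
        return "degenerate", scalars
    if abs(scalars["w.D2F(v,v)"]) > tol:
        return "saddle-node", scalars
    return "degenerate", scalars


def sotomayor_check(point: BifurcationPoint, params: Parameters) -> tuple[str, dict[str, float]]:
    """Re-run the Sotomayor classification of a localized point.

    Evaluates the three transversality scalars on the left/right null
    eigenvectors of the Jacobian at the boundary equilibrium of
    ``point.pair`` with the swept rate set to the critical value, and
    returns ``(kind, scalars)``. The pitchfork quantity is exactly zero for
    this vector field (all third-order partials vanish).
    """
    critical = params.replace(**{point.parameter: point.critical_value})
    return _sotomayor(point.parameter, point.pair[1], critical)


# ---------------------------------------------------------------------------
# One-parameter sweeps
# ---------------------------------------------------------------------------


def sweep(
    parameter: str,
    prange: tuple[float, float],
    n_grid: int,
    params: Parameters,
) -> SweepResult:
    """Classify the attractor along a rate grid and localize every exchange.

    Grid points where classification fails (some margin numerically zero)
    are recorded as boundary samples (label ``None``), not fatal. Each
    change of attractor label between classified neighbours is localized
    with :func:`threshold_solve` on the bracketing subinterval; exchanges
    that cannot be resolved there (non-adjacent labels from a too-coarse
    grid) are reported in ``unresolved``.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise InvalidInputError(
            f"parameter {parameter!r} is not sweepable; choose from {SWEEPABLE_PARAMETERS}"
        )
    if n_grid < 2:
        raise InvalidInputError("n_grid must be at least 2")
    grid = np.linspace(float(prange[0]), float(prange[1]), int(n_grid))
    labels: list[str | None] = []
    for theta in grid:
        try:
            labels.append(classify(params.replace(**{parameter: theta})).label)
        except ClassificationError:
            labels.append(None)

    points: list[BifurcationPoint] = []
    unresolved: list[tuple[float, float, str, str]] = []
    prev_idx: int | None = None
    for idx, label in enumerate(labels):
        if label is None:
            continue
        if prev_idx is not None and labels[prev_idx] != label:
            lo, hi = float(grid[prev_idx]), float(grid[idx])
            try:
                points.append(
                    threshold_solve((labels[prev_idx], label), parameter, params, (lo, hi))
                )
            except ThresholdNotFoundError:
                unresolved.append((lo, hi, labels[prev_idx], label))
        prev_idx = idx

    chain: list[str] = []
    for label in labels:
        if label is not None and (not chain or chain[-1] != label):
            chain.append(label)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        labels=labels,
        points=points,
        chain=tuple(chain),
        unresolved=unresolved,
    )


# ---------------------------------------------------------------------------
# Lyapunov quadratic form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LyapunovForm:
    """The equilibrium-independent quadratic form of the Lyapunov derivative."""

    matrix: np.ndarray
    minors: tuple[float, float, float]
    negative_definite: bool


def lyapunov_matrix(params: Parameters, weights: Sequence[float] = None) -> LyapunovForm:
    """Quadratic form governing global stability, for given species weights.

    The time derivative of the Lyapunov candidate built from weighted
    Volterra terms is P^T A P with P the deviation from equilibrium and A
    the same symmetric matrix for every equilibrium:

        diag(-w_V c_VV, -w_S c_SS, -w_L c_LL)
        with off-diagonals a (e w_V - w_S)/2 and b (e w_V - w_L)/2
        coupling fox to each prey, and no direct prey-prey entry.

    Negative definiteness of A (checked via the leading principal minors)
    certifies global asymptotic stability of whichever equilibrium is
    locally stable. The default weights (1, e, e) annihilate both
    off-diagonal entries, leaving a manifestly negative-definite diagonal
    matrix for any positive competition coefficients.
    """
    a, b = params.require_hunting()
    if weights is None:
        weights = (1.0, params.e, params.e)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidInputError(f"weights must be three positive finite reals, got {weights!r}")
    wV, wS, wL = w
    e = params.e
    A = np.array([
        [-wV * params.c_VV, a * (e * wV - wS) / 2, b * (e * wV - wL) / 2],
        [a * (e * wV - wS) / 2, -wS * params.c_SS, 0.0],
        [b * (e * wV - wL) / 2, 0.0, -wL * params.c_LL],
    ])
    m1 = A[0, 0]
    m2 = float(np.linalg.det(A[:2, :2]))
    m3 = float(np.linalg.det(A))
    return LyapunovForm(
        matrix=A,
        minors=(float(m1), m2, m3),
        negative_definite=bool(m1 < 0 and m2 > 0 and m3 < 0),
    )
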