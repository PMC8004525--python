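"""Shared fixtures and random-parameter samplers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hyperpredation import Parameters, reference_parameters
from hyperpredation.equilibria import LABELS, feasibility, stability


@pytest.fixture(scope="session")
def reference() -> Parameters:
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_ab(reference: Parameters) -> Parameters:
    """Reference rates with the ensemble-study hunting rates."""
    return reference.with_hunting(0.2, 0.5)


def all_margins(params: Parameters) -> list[float]:
    """Every feasibility and stability margin of all eight candidates."""
    values: list[float] = []
    for label in LABELS:
        values.extend(feasibility(label, params)[1].values())
        values.extend(stability(label, params)[1].values())
    return values


def random_parameter_sets(
    rng: np.random.Generator,
    count: int,
    margin_floor: float = 1e-6,
) -> list[Parameters]:
    """Broad random rate draws with all classification margins away from zero.

    Rates span the biologically plausible decade around the reference set;
    draws landing within ``margin_floor`` of any feasibility/stability
    boundary are rejected (those belong to the bifurcation solver, not to
    classification).
    """
    sets: list[Parameters] = []
    while len(sets) < count:
        params = Parameters(
            r=rng.uniform(0.05, 2.0),
            s=rng.uniform(0.05, 2.0),
            u=rng.uniform(0.05, 2.0),
            m=rng.uniform(0.05, 2.0),
            n=rng.uniform(0.05, 2.0),
            p=rng.uniform(0.05, 2.0),
            c_VV=rng.uniform(0.02, 1.0),
            c_SS=rng.uniform(0.02, 1.0),
            c_LL=rng.uniform(0.02, 1.0),
            e=rng.uniform(0.5, 1.0),
            a=rng.uniform(0.0, 3.0),
            b=rng.uniform(0.0, 3.0),
        )
        if min(abs(v) for v in all_margins(params)) > margin_floor:
            sets.append(params)
    return sets


def random_feasible_e7_sets(rng: np.random.Generator, count: int) -> list[Parameters]:
    """Random draws conditioned on a feasible coexistence equilibrium."""
    sets: list[Parameters] = []
    while len(sets) < count:
        params = Parameters(
            r=rng.uniform(0.6, 2.0),
            s=rng.uniform(0.6, 2.0),
            u=rng.uniform(0.6, 2.0),
            m=rng.uniform(0.05, 0.5),
            n=rng.uniform(0.05, 0.5),
            p=rng.uniform(0.05, 0.5),
            c_VV=rng.uniform(0.05, 1.0),
            c_SS=rng.uniform(0.05, 1.0),
            c_LL=rng.uniform(0.05, 1.0),
            e=rng.uniform(0.5, 1.0),
            a=rng.uniform(0.0, 0.6),
            b=rng.uniform(0.0, 0.6),
        )
        feasible, margins = feasibility("E7", params)
        if feasible and min(margins.values()) > 1e-6:
            sets.append(params)
    return sets


def random_states(rng: np.random.Generator, count: int, scale: float = 50.0) -> np.ndarray:
    return rng.uniform(0.0, scale, size=(count, 3))
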