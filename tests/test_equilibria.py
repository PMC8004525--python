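"""Closed-form equilibria, feasibility/stability columns, regime taxonomy."""

import numpy as np
import pytest

from hyperpredation import (
    Parameters,
    classify,
    equilibrium_points,
    equilibrium_state,
    integrate,
    regime_case,
    rhs,
    steady_state,
)
from hyperpredation.equilibria import LABELS, SPECIES_SETS, feasibility, stability
from hyperpredation.exceptions import (
    ClassificationError,
    DegenerateModelError,
    InvalidInputError,
)

from conftest import random_parameter_sets


def _decayed(**kw):
    """A parameter set template with every net rate negative."""
    base = dict(r=0.2, s=0.3, u=0.25, m=0.9, n=0.8, p=0.7,
                c_VV=0.5, c_SS=0.4, c_LL=0.3, e=0.91, a=0.5, b=0.5)
    base.update(kw)
    return Parameters(**base)


def test_census_returns_exactly_eight_labelled_candidates(ref_ab):
    points = equilibrium_points(ref_ab)
    assert [eq.label for eq in points] == list(LABELS)


def test_single_species_candidates_sit_at_their_capacities(ref_ab):
    by_label = {eq.label: eq for eq in equilibrium_points(ref_ab)}
    assert by_label["E1"].populations == pytest.approx([1.0, 0, 0], abs=1e-12)
    assert by_label["E2"].populations == pytest.approx([0, 100.0, 0], abs=1e-9)
    assert by_label["E4"].populations == pytest.approx([0, 0, 30.0], abs=1e-9)
    assert by_label["E6"].populations == pytest.approx([0, 100.0, 30.0], abs=1e-9)


def test_every_candidate_is_an_exact_root_of_the_dynamics():
    rng = np.random.default_rng(23)
    for params in random_parameter_sets(rng, 200):
        for eq in equilibrium_points(params):
            scale = max(1.0, float(np.max(np.abs(eq.populations)))) ** 2
            assert np.max(np.abs(rhs(eq.populations, params, validate=False))) < 1e-10 * scale


def test_zero_competition_is_degenerate(ref_ab):
    with pytest.raises(DegenerateModelError):
        equilibrium_points(ref_ab.replace(c_SS=0.0))


def test_only_extinction_is_feasible_and_stable_when_all_nets_negative():
    params = _decayed()
    winners = [eq.label for eq in equilibrium_points(params) if eq.feasible and eq.stable]
    assert winners == ["E0"]
    feasible = [eq.label for eq in equilibrium_points(params) if eq.feasible]
    assert feasible == ["E0"]


@pytest.mark.parametrize(
    ("label", "change", "expected"),
    [
        ("E1", dict(), True),            # reference has r > m
        ("E6", dict(s=0.5, n=0.8), False),  # cottontail net negative
        ("E2", dict(s=0.5, n=0.8), False),
    ],
)
def test_feasibility_column(reference, label, change, expected):
    params = reference.with_hunting(0.2, 0.5).replace(**change)
    verdict, margins = feasibility(label, params)
    assert verdict is expected
    assert margins  # named inequality margins are exposed


def test_stability_margins_match_verdict_sign(ref_ab):
    for label in LABELS:
        verdict, margins = stability(label, ref_ab)
        assert verdict == all(v > 0 for v in margins.values())


def test_decoupled_limit_reduces_to_independent_logistics(reference):
    params = reference.with_hunting(0.0, 0.0)
    by_label = {eq.label: eq for eq in equilibrium_points(params)}
    v1 = (params.r - params.m) / params.c_VV
    s2 = (params.s - params.n) / params.c_SS
    l4 = (params.u - params.p) / params.c_LL
    assert by_label["E7"].populations == pytest.approx([v1, s2, l4], rel=1e-12)
    assert by_label["E3"].populations == pytest.approx([v1, s2, 0.0], rel=1e-12)
    assert by_label["E5"].populations == pytest.approx([v1, 0.0, l4], rel=1e-12)


class TestClassify:
    def test_all_negative_nets_give_extinction(self):
        assert classify(_decayed()).label == "E0"

    def test_fox_only_regime(self):
        assert classify(_decayed(r=1.2, m=0.3)).label == "E1"

    def test_reference_study_attractor_matches_long_run_integration(self, ref_ab):
        attractor = classify(ref_ab)
        assert attractor.label == "E3"
        traj = integrate(ref_ab, (0.4, 1.0, 3.0), t_end=500.0)
        settled = steady_state(traj, ref_ab)
        assert settled is not None
        assert np.max(np.abs(settled - attractor.populations)) < 1e-6

    def test_boundary_parameters_raise(self, reference):
        # r == m puts E0/E1 exactly on their exchange: no strict winner
        params = reference.with_hunting(0.2, 0.5).replace(
            r=0.9, m=0.9, s=0.5, n=0.8, u=0.5, p=0.7
        )
        with pytest.raises(ClassificationError):
            classify(params)

    def test_unique_attractor_on_random_sets(self):
        rng = np.random.default_rng(29)
        for params in random_parameter_sets(rng, 200):
            winners = [
                eq.label for eq in equilibrium_points(params) if eq.feasible and eq.stable
            ]
            assert len(winners) == 1, (params, winners)


def test_stability_verdicts_agree_with_numeric_eigenvalues():
    rng = np.random.default_rng(31)
    for params in random_parameter_sets(rng, 200):
        for eq in equilibrium_points(params):
            if not eq.feasible:
                continue
            numeric = bool(np.max(np.real(eq.eigenvalues)) < 0)
            assert eq.stable == numeric, (eq.label, params)


class TestRegimeCase:
    """Outcome taxonomy by the sign pattern of the net reproduction rates.

    The prey-threshold direction follows the closed forms: with foxes unable
    to persist alone (r < m), low prey competition feeds the predator (the
    two-species point is feasible and stable), high prey competition leaves
    the prey alone.
    """

    def test_cottontail_regime_splits_at_h2(self):
        base = _decayed(s=1.0, n=0.5, a=1.0, b=0.5, r=0.5, m=1.0)
        thr = regime_case(base).thresholds
        assert thr.h2 == pytest.approx(1.0 * 0.91 * 0.5 / 0.5)
        low = regime_case(base.replace(c_SS=0.5))   # c_SS < h2
        high = regime_case(base.replace(c_SS=1.5))  # c_SS > h2
        assert low.case == 3 and high.case == 3
        assert low.attractor == "E3"
        assert high.attractor == "E2"

    def test_hare_regime_splits_at_g2(self):
        base = _decayed(u=1.0, p=0.5, a=0.5, b=1.0, r=0.5, m=1.0)
        thr = regime_case(base).thresholds
        assert thr.g2 == pytest.approx(1.0 * 0.91 * 0.5 / 0.5)
        low = regime_case(base.replace(c_LL=0.5))   # c_LL < g2
        high = regime_case(base.replace(c_LL=1.5))  # c_LL > g2
        assert low.case == 5 and high.case == 5
        assert low.attractor == "E5"
        assert high.attractor == "E4"

    def test_fox_only_sign_pattern(self):
        result = regime_case(_decayed(r=1.2, m=0.3))
        assert result.case == 2
        assert result.candidates == ("E0", "E1")
        assert result.attractor == "E1"

    def test_fox_competition_splits_at_k1(self):
        base = _decayed(r=1.0, m=0.4, s=1.0, n=0.5, a=1.0, b=0.2)
        thr = regime_case(base).thresholds  # k1 = a (r-m)/(s-n) = 1.2
        assert thr.k1 == pytest.approx(1.2)
        assert regime_case(base.replace(c_VV=0.6)).attractor == "E1"
        assert regime_case(base.replace(c_VV=2.0)).attractor == "E3"

    def test_zero_net_rate_is_a_boundary_error(self):
        with pytest.raises(ClassificationError, match="zero net"):
            regime_case(_decayed(r=0.9, m=0.9))


def test_unknown_label_rejected(ref_ab):
    with pytest.raises(InvalidInputError):
        equilibrium_state("E8", ref_ab)


def test_species_sets_form_the_cube():
    assert len(SPECIES_SETS) == 8
    assert sorted(len(s) for s in SPECIES_SETS.values()) == [0, 1, 1, 1, 2, 2, 2, 3]
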