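"""Threshold solving, Sotomayor classification, sweeps, Lyapunov form."""

import numpy as np
import pytest

from hyperpredation import (
    eigenvalues_at,
    lyapunov_matrix,
    sotomayor_check,
    sweep,
    threshold_solve,
)
from hyperpredation.equilibria import SPECIES_SETS, component_numerator, equilibrium_state
from hyperpredation.exceptions import InvalidInputError, ThresholdNotFoundError

from conftest import random_feasible_e7_sets, random_parameter_sets


def test_extinction_eigenvalues_are_the_net_rates(ref_ab):
    eigs = np.sort_complex(eigenvalues_at("E0", ref_ab))
    assert eigs == pytest.approx(np.sort(ref_ab.net_rates), abs=1e-14)


def test_prey_pair_eigenvalues_contain_negated_net_rates(ref_ab):
    # at E6 the prey directions contribute -c_SS*S6 = n-s and -c_LL*L6 = p-u
    eigs = eigenvalues_at("E6", ref_ab)
    for expected in (ref_ab.n - ref_ab.s, ref_ab.p - ref_ab.u):
        assert np.min(np.abs(eigs - expected)) < 1e-9


def test_feasible_coexistence_is_always_locally_stable():
    rng = np.random.default_rng(37)
    for params in random_feasible_e7_sets(rng, 500):
        assert np.max(np.real(eigenvalues_at("E7", params))) < 0.0, params


class TestThresholdSolve:
    def test_fox_hare_collapse_threshold_has_closed_form(self, ref_ab):
        """L5(b) = 0 is affine with root b* = c_VV (u-p)/(r-m)."""
        point = threshold_solve(("E5", "E1"), "b", ref_ab, (1.0, 2.0))
        expected = ref_ab.c_VV * (ref_ab.u - ref_ab.p) / (ref_ab.r - ref_ab.m)
        assert point.critical_value == pytest.approx(expected, rel=1e-9)
        assert point.pair == ("E5", "E1")
        assert point.kind == "transcritical"
        assert abs(point.residual) < 1e-10

    def test_quadratic_margin_yields_two_reentrant_roots(self, ref_ab):
        """The coexistence/hare-extinction margin is quadratic in a."""
        first = threshold_solve(("E7", "E3"), "a", ref_ab, (0.005, 0.1))
        second = threshold_solve(("E3", "E7"), "a", ref_ab, (0.1, 0.3))
        assert first.critical_value < second.critical_value
        # both roots annihilate the quadratic L7 numerator
        for point in (first, second):
            margin = component_numerator(
                "E7", "L", ref_ab.replace(a=point.critical_value)
            )
            assert abs(margin) < 1e-10

    def test_cottontail_exclusion_threshold_matches_net_rate(self, ref_ab):
        # S3(a) = 0 at a = c_VV (s-n)/(r-m) = s-n for the reference c_VV
        point = threshold_solve(("E3", "E1"), "a", ref_ab, (0.6, 0.8))
        assert point.critical_value == pytest.approx(ref_ab.s - ref_ab.n, rel=1e-9)

    def test_non_adjacent_pair_has_no_boundary_arc(self, ref_ab):
        with pytest.raises(ThresholdNotFoundError, match="boundary arc"):
            threshold_solve(("E1", "E2"), "a", ref_ab, (0.1, 1.0))

    def test_no_sign_change_in_bracket(self, ref_ab):
        with pytest.raises(ThresholdNotFoundError, match="does not change sign"):
            threshold_solve(("E5", "E1"), "b", ref_ab, (2.0, 3.0))

    def test_unsweepable_parameter_rejected(self, ref_ab):
        with pytest.raises(InvalidInputError, match="not sweepable"):
            threshold_solve(("E5", "E1"), "m", ref_ab, (0.1, 1.0))


class TestSotomayor:
    def test_detected_points_are_transcritical_with_zero_pitchfork(self, ref_ab):
        point = threshold_solve(("E5", "E1"), "b", ref_ab, (1.0, 2.0))
        kind, scalars = sotomayor_check(point, ref_ab)
        assert kind == "transcritical"
        assert scalars["w.F_mu"] == pytest.approx(0.0, abs=1e-8)
        assert scalars["w.D3F(v,v,v)"] == 0.0
        assert abs(scalars["w.D2F(v,v)"]) > 1e-8

    def test_hunting_rate_derivative_vanishes_on_boundary_equilibrium(self, ref_ab):
        """F_a = (eSV, -SV, 0) is zero wherever S = 0, so w.F_a = 0 there."""
        point = threshold_solve(("E7", "E5"), "a", ref_ab, (0.26, 0.3))
        assert point.kind == "transcritical"
        assert point.transversality["w.F_mu"] == pytest.approx(0.0, abs=1e-8)

    def test_exchange_invisible_to_fixed_state_scalar_still_crosses(self, ref_ab):
        """Swept in a, the E7/E3 exchange moves through branch motion only:
        w.DF_a.v is identically zero, yet the critical eigenvalue crosses
        zero with nonzero speed and the point is transcritical."""
        point = threshold_solve(("E7", "E3"), "a", ref_ab, (0.1, 0.3))
        assert point.kind == "transcritical"
        assert point.transversality["w.DF_mu.v"] == pytest.approx(0.0, abs=1e-10)
        assert abs(point.transversality["dlambda/dmu"]) > 1e-3


def test_transcritical_coincidence_of_margins():
    """Feasibility boundary of the larger equilibrium is the stability
    boundary of the smaller one: S7 = 0 is the locus s = n + a V5, and
    L7 = 0 the locus u = p + b V3 (two independently coded margins)."""
    rng = np.random.default_rng(41)
    for params in random_parameter_sets(rng, 300):
        a, b = params.require_hunting()
        e = params.e
        den5 = b * b * e + params.c_VV * params.c_LL
        v5 = equilibrium_state("E5", params)[0]
        lhs = component_numerator("E7", "S", params)
        rhs_ = (params.s - params.n - a * v5) * den5
        assert abs(lhs - rhs_) <= 1e-9 * max(1.0, abs(lhs))
        den3 = a * a * e + params.c_VV * params.c_SS
        v3 = equilibrium_state("E3", params)[0]
        lhs = component_numerator("E7", "L", params)
        rhs_ = (params.u - params.p - b * v3) * den3
        assert abs(lhs - rhs_) <= 1e-9 * max(1.0, abs(lhs))


class TestSweep:
    def test_reentrant_coexistence_chain(self, ref_ab):
        """Raising the cottontail hunting rate walks the community through
        coexistence, hare extinction, coexistence again, and cottontail
        extinction."""
        result = sweep("a", (0.005, 0.6), 120, ref_ab)
        assert result.chain == ("E7", "E3", "E7", "E5")
        assert len(result.points) == 3
        assert result.unresolved == []
        values = [p.critical_value for p in result.points]
        assert values == sorted(values)
        assert all(p.kind == "transcritical" for p in result.points)

    def test_labels_change_only_at_detected_points(self, ref_ab):
        result = sweep("a", (0.005, 0.6), 120, ref_ab)
        thresholds = [p.critical_value for p in result.points]
        for theta, label, nxt_theta, nxt_label in zip(
            result.grid, result.labels, result.grid[1:], result.labels[1:]
        ):
            if label != nxt_label and None not in (label, nxt_label):
                assert any(theta < t < nxt_theta for t in thresholds)

    def test_quiet_range_yields_single_label_no_points(self, ref_ab):
        result = sweep("b", (2.0, 3.0), 25, ref_ab)
        assert len(result.chain) == 1
        assert result.points == []

    def test_discovered_arcs_are_cube_edges(self, ref_ab):
        for prm, rng_ in (("a", (0.005, 0.6)), ("b", (0.3, 2.0))):
            for point in sweep(prm, rng_, 80, ref_ab).points:
                big, small = point.pair
                assert SPECIES_SETS[big] > SPECIES_SETS[small]
                assert len(SPECIES_SETS[big] - SPECIES_SETS[small]) == 1


def test_no_hopf_at_detected_points(ref_ab):
    """The eigenvalue crossing zero at each threshold is real: no conjugate
    pair reaches the imaginary axis with nonzero imaginary part."""
    result = sweep("a", (0.005, 0.6), 120, ref_ab)
    for point in result.points:
        critical = ref_ab.replace(a=point.critical_value)
        for label in point.pair:
            eigs = eigenvalues_at(label, critical)
            nearest = eigs[np.argmin(np.abs(eigs))]
            assert abs(np.imag(nearest)) < 1e-6


class TestLyapunovForm:
    def test_default_weights_cancel_cross_terms(self, ref_ab):
        form = lyapunov_matrix(ref_ab)
        off = form.matrix - np.diag(np.diag(form.matrix))
        assert np.allclose(off, 0.0, atol=1e-15)
        assert form.negative_definite
        m1, m2, m3 = form.minors
        assert m1 < 0 < m2 and m3 < 0

    def test_unbalanced_weights_break_definiteness(self, ref_ab):
        form = lyapunov_matrix(ref_ab, weights=(1.0, 500.0, 0.91))
        assert not form.negative_definite

    def test_matrix_is_symmetric(self, ref_ab):
        form = lyapunov_matrix(ref_ab, weights=(1.0, 0.4, 1.7))
        assert np.array_equal(form.matrix, form.matrix.T)

    def test_weights_must_be_positive(self, ref_ab):
        with pytest.raises(InvalidInputError):
            lyapunov_matrix(ref_ab, weights=(1.0, -1.0, 1.0))
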