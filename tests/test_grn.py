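"""Gene-regulatory ODE models: responses, equilibria, steady states."""

import math

import numpy as np
import pytest

from alleleinteract.grn import (
    AlleleParams,
    GenotypeSystem,
    ResponseSpec,
    SolverOptions,
    _integrate_to_rest,
    find_equilibria,
    genotype_quintet,
    response,
    steady_state,
    two_locus_quintets,
)
from alleleinteract.metrics import allele_interaction, call_signs


def hill_down(theta=5.0, p=2.0):
    return ResponseSpec("hill_down", theta=theta, p=p)


def hill_up(theta=5.0, p=2.0):
    return ResponseSpec("hill_up", theta=theta, p=p)


class TestResponse:
    @pytest.mark.parametrize(
        "spec, u, expected",
        [
            (hill_up(5, 2), 5.0, 0.5),  # threshold midpoint
            (hill_up(1, 2), 2.0, 0.8),  # 4/(4+1)
            (hill_down(5, 2), 5.0, 0.5),
            (ResponseSpec("bump_up", mu=10, sigma=3), 10.0, 1.0),  # unit peak
            (ResponseSpec("bump_down", mu=10, sigma=3), 10.0, 0.0),
            (ResponseSpec("hill_up", theta=1, p=1, constant_value=0.25), 42.0, 0.25),
        ],
    )
    def test_values(self, spec, u, expected):
        assert response(spec, u) == pytest.approx(expected)

    def test_bounds_and_shape(self):
        u = np.linspace(0, 500, 2001)
        for spec, shape in [
            (hill_up(50, 3), "increasing"),
            (hill_down(50, 3), "decreasing"),
            (ResponseSpec("bump_up", mu=100, sigma=20), "unimodal"),
        ]:
            r = response(spec, u)
            assert np.all((0 <= r) & (r <= 1))
            d = np.diff(r)
            if shape == "increasing":
                assert np.all(d >= 0)
            elif shape == "decreasing":
                assert np.all(d <= 0)
            else:
                peak = np.argmax(r)
                assert u[peak] == pytest.approx(100, abs=u[1])
                assert np.all(d[: peak] >= 0) and np.all(d[peak:] <= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            response(hill_up(), -1.0)

    def test_derivative_matches_finite_difference(self):
        u = np.linspace(0.1, 300, 50)
        h = 1e-6
        for spec in (hill_up(30, 2.5), hill_down(7, 1.0), ResponseSpec("bump_down", mu=40, sigma=9)):
            num = (response(spec, u + h) - response(spec, u - h)) / (2 * h)
            assert spec.derivative(u) == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestRhs:
    def test_constant_response_linear_decay(self):
        a = AlleleParams(2.0, 1.0, ResponseSpec("hill_up", theta=1, p=1, constant_value=1.0))
        sys = GenotypeSystem((a,))
        assert sys.rhs([3.0])[0] == pytest.approx(-1.0)

    def test_fixed_point_has_zero_rate(self):
        a = AlleleParams(10.0, 1.0, hill_down(5, 2))
        sys = GenotypeSystem((a,))
        assert sys.rhs([5.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        a = AlleleParams(10.0, 1.0, hill_down())
        with pytest.raises(ValueError):
            GenotypeSystem((a, a)).rhs([1.0])


class TestEquilibria:
    def test_negative_feedback_unique_stable_root(self):
        a = AlleleParams(10.0, 1.0, hill_down(5, 2))
        eqs = find_equilibria(GenotypeSystem((a,)))
        assert len(eqs) == 1
        assert eqs[0].stable
        assert eqs[0].total == pytest.approx(5.0, rel=1e-10)

    def test_homozygote_negative_feedback_root(self):
        # total solves u^3 + 25 u - 500 = 0
        a = AlleleParams(10.0, 1.0, hill_down(5, 2))
        eqs = find_equilibria(GenotypeSystem((a, a)))
        expected = np.roots([1, 0, 25, -500])
        expected = float(expected[np.isreal(expected)].real[0])
        assert len(eqs) == 1
        assert eqs[0].total == pytest.approx(expected, rel=1e-10)
        assert eqs[0].total == pytest.approx(6.893984, rel=1e-6)

    def test_positive_feedback_bistability(self):
        # u^2 - 12u + 25 = 0 plus the off state
        a = AlleleParams(12.0, 1.0, hill_up(5, 2))
        eqs = find_equilibria(GenotypeSystem((a,)))
        assert [round(e.u_star, 6) for e in eqs] == pytest.approx(
            [0.0, 6 - math.sqrt(11), 6 + math.sqrt(11)], abs=1e-6
        )
        assert [e.stable for e in eqs] == [True, False, True]


class TestSteadyState:
    def test_basins_split_at_unstable_root(self):
        a = AlleleParams(12.0, 1.0, hill_up(5, 2))
        sys = GenotypeSystem((a,))
        assert steady_state(sys, [1.0]).total == pytest.approx(0.0, abs=1e-9)
        assert steady_state(sys, [4.0]).total == pytest.approx(6 + math.sqrt(11), rel=1e-9)

    def test_constant_response_closed_form(self):
        c = 0.4
        a1 = AlleleParams(10.0, 2.0, ResponseSpec("hill_up", theta=1, p=1, constant_value=c))
        a2 = AlleleParams(6.0, 3.0, ResponseSpec("hill_up", theta=1, p=1, constant_value=c))
        eq = steady_state(GenotypeSystem((a1, a2)), [7.0, 7.0])
        assert eq.state == pytest.approx((10 * c / 2, 6 * c / 3), rel=1e-9)

    def test_flow_attractor_agrees_with_time_integration(self, rng):
        """Equal decay rates: root bracketing equals explicit integration."""
        opts = SolverOptions()
        for _ in range(60):
            kind = rng.choice(["hill_up", "hill_down"])
            alleles = tuple(
                AlleleParams(
                    rng.uniform(1, 300),
                    1.0,
                    ResponseSpec(kind, theta=rng.uniform(1, 300), p=rng.uniform(1, 4)),
                )
                for _ in range(2)
            )
            sys = GenotypeSystem(alleles)
            init = rng.uniform(0, 300, size=2)
            fast = steady_state(sys, init, opts)
            slow = _integrate_to_rest(sys, init, opts)
            assert fast.total == pytest.approx(float(np.sum(slow)), rel=1e-6, abs=1e-6)

    def test_unequal_decay_integration_matches_scalar_roots(self, rng):
        for _ in range(25):
            alleles = tuple(
                AlleleParams(
                    rng.uniform(1, 300),
                    rng.uniform(1, 5),
                    ResponseSpec("bump_up", mu=rng.uniform(1, 300), sigma=rng.uniform(1, 100)),
                    w=rng.uniform(0.5, 2),
                )
                for _ in range(2)
            )
            sys = GenotypeSystem(alleles)
            eq = steady_state(sys, rng.uniform(0, 50, size=2), SolverOptions())
            roots = [e.u_star for e in find_equilibria(sys)]
            assert min(abs(eq.u_star - r) for r in roots) <= 1e-6 * (1 + eq.u_star)


class TestQuintets:
    def test_constant_responses_give_additivity(self, rng):
        const = ResponseSpec("hill_up", theta=1, p=1, constant_value=1.0)
        q = genotype_quintet(
            AlleleParams(10.0, 1.0, const), AlleleParams(6.0, 1.0, const), rng=rng
        )
        assert q.values() == pytest.approx((20, 16, 12, 10, 6), rel=1e-9)
        t = allele_interaction(q)
        assert t.values() == pytest.approx((0, 0, 0), abs=1e-6)

    def test_negative_autoregulation_worked_example(self, rng):
        a = AlleleParams(10.0, 1.0, hill_down(5, 2))
        q = genotype_quintet(a, a, rng=rng)
        assert q.h1 == pytest.approx(5.0, rel=1e-9)
        assert q.x11 == pytest.approx(6.893984, rel=1e-6)
        t = allele_interaction(q.oriented())
        assert t.d11 == pytest.approx(-3.106016, rel=1e-5)
        assert t.d11 < 0

    def test_positive_autoregulation_deltas_nonnegative(self, rng):
        """Called interaction signs under Hill-up feedback are never negative."""
        for _ in range(150):
            alleles = [
                AlleleParams(
                    rng.uniform(1, 300),
                    1.0,
                    ResponseSpec("hill_up", theta=rng.uniform(1, 300), p=rng.uniform(1, 4)),
                )
                for _ in range(2)
            ]
            q = genotype_quintet(alleles[0], alleles[1], rng=rng)
            if min(q.x11, q.x22) < 0.01 or min(q.values()) <= 0:
                continue  # null allele / degenerate: excluded by the filters
            motif = call_signs(q, tol=0.05)
            assert all(s >= 0 for s in motif.signs())

    def test_negative_autoregulation_deltas_nonpositive(self, rng):
        for _ in range(150):
            alleles = [
                AlleleParams(
                    rng.uniform(1, 300),
                    1.0,
                    ResponseSpec("hill_down", theta=rng.uniform(1, 300), p=rng.uniform(1, 4)),
                )
                for _ in range(2)
            ]
            q = genotype_quintet(alleles[0], alleles[1], rng=rng)
            motif = call_signs(q, tol=0.05)
            assert all(s <= 0 for s in motif.signs())


class TestTwoLocus:
    def test_inactive_coupling_gives_additivity_at_both_loci(self, rng):
        """Constant locus-1 response breaks the loop: both quintets additive."""
        const = ResponseSpec("hill_up", theta=1, p=1, constant_value=0.8)
        a1 = AlleleParams(10.0, 1.0, const)
        a2 = AlleleParams(4.0, 1.0, const)
        l2 = AlleleParams(50.0, 1.0, ResponseSpec("hill_up", theta=1, p=1, constant_value=0.6))
        q1, q2 = two_locus_quintets(a1, a2, l2, rng=rng)
        assert allele_interaction(q1).values() == pytest.approx((0, 0, 0), abs=1e-6)
        assert allele_interaction(q2).values() == pytest.approx((0, 0, 0), abs=1e-6)

    def test_constant_locus1_response_keeps_locus1_additive(self, rng):
        # a broken loop (no feedback to locus 1) leaves the polymorphic locus
        # additive even when locus 2 still responds to it
        const = ResponseSpec("hill_up", theta=1, p=1, constant_value=0.8)
        a1 = AlleleParams(10.0, 1.0, const)
        a2 = AlleleParams(4.0, 1.0, const)
        l2 = AlleleParams(50.0, 1.0, hill_up(8.0, 2.0))
        q1, _ = two_locus_quintets(a1, a2, l2, rng=rng)
        assert allele_interaction(q1).values() == pytest.approx((0, 0, 0), abs=1e-6)

    def test_loop_sign_is_product_of_action_signs(self):
        from alleleinteract.grn import TwoLocusSystem

        a = AlleleParams(10.0, 1.0, hill_down())
        b = AlleleParams(10.0, 1.0, hill_up())
        assert TwoLocusSystem((a, a), b).loop_sign == -1
        assert TwoLocusSystem((b, b), b).loop_sign == 1
        assert TwoLocusSystem((a, a), a).loop_sign == 1
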