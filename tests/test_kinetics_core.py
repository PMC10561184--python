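"""Rate-constant primitives: TST, Eckart tunneling, Marcus theory, diffusion."""

import math

import numpy as np
import pytest
import scipy.constants as sc
from hypothesis import given
from hypothesis import strategies as st

from radkin import (
    CONSTANTS,
    EckartParameters,
    MarcusInput,
    Medium,
    ReactionChannel,
    collins_kimball,
    eckart_kappa,
    evaluate_channel,
    marcus_barrier,
    marcus_lambda,
    smoluchowski_kd,
    tst_barrier,
    tst_rate,
)
from radkin.kinetics_core import KineticsError

# ---------------------------------------------------------------------------
# Independent brute-force oracle: dense trapezoidal quadrature of the
# textbook asymmetric-Eckart transmission probability.  Written separately
# from the package implementation (vectorized trapezoid vs adaptive
# quadrature) and kept deliberately plain.
# ---------------------------------------------------------------------------

_KCAL = sc.calorie * 1000.0
_HC = sc.h * sc.c * 100.0


def _oracle_logsinh(x):
    with np.errstate(divide="ignore"):
        return np.where(x > 0, x - np.log(2) + np.log1p(-np.exp(-2 * x)), -np.inf)


def _oracle_logcosh(x):
    x = np.abs(x)
    return x - np.log(2) + np.log1p(np.exp(-2 * x))


def oracle_eckart_kappa(v1_kcal, v2_kcal, omega_cm, temperature, n=200_001):
    v1 = v1_kcal * _KCAL / sc.N_A
    v2 = v2_kcal * _KCAL / sc.N_A
    kt = sc.k * temperature
    quantum = _HC * omega_cm
    a1 = 2 * np.pi * v1 / quantum
    a2 = 2 * np.pi * v2 / quantum
    denom = 1 / np.sqrt(a1) + 1 / np.sqrt(a2)
    energy = np.linspace(max(0.0, v1 - v2), v1 + 40 * kt, n)
    xi = energy / v1
    a = 2 * np.sqrt(np.clip(a1 * xi, 0, None)) / denom
    open_ch = (xi - 1) * a1 + a2
    b = 2 * np.sqrt(np.clip(open_ch, 0, None)) / denom
    disc = a1 * a2 - np.pi**2 / 4
    log_num = np.log(2) + _oracle_logsinh(a) + _oracle_logsinh(b)
    if disc >= 0:
        log_den = np.logaddexp(_oracle_logcosh(a + b), _oracle_logcosh(2 * np.sqrt(disc)))
    else:
        lc = _oracle_logcosh(a + b)
        log_den = lc + np.log1p(np.cos(2 * np.sqrt(-disc)) * np.exp(-lc))
    log_p = np.where(open_ch > 0, log_num - log_den, -np.inf)
    integrand = np.exp(log_p + (v1 - energy) / kt)
    return np.trapezoid(integrand, energy) / kt


# Frozen oracle value for the symmetric reference barrier, computed with the
# function above at n = 2_000_001 (converged to ~1e-10 relative).
ORACLE_SYMMETRIC_5_5_1500 = 8.191668558733372


class TestTstRate:
    def test_barrierless_prefactor(self):
        assert tst_rate(0.0) == pytest.approx(6.212e12, rel=1e-3)
        assert CONSTANTS.rt() == pytest.approx(0.5925, abs=1e-4)

    def test_printed_tunneling_channel(self):
        # high-barrier aliphatic H-transfer with strong tunneling
        assert tst_rate(21.4, tunneling=66.9) == pytest.approx(8.70e-2, rel=0.05)

    def test_marcus_barrier_feeds_tst(self):
        barrier = marcus_barrier(
            MarcusInput(reorganization_energy=31.7, reaction_free_energy=-14.9)
        )
        assert barrier == pytest.approx(2.23, abs=0.01)
        assert tst_rate(barrier) == pytest.approx(1.45e11, rel=0.05)

    def test_linear_in_kappa_and_sigma(self):
        base = tst_rate(10.0)
        assert tst_rate(10.0, tunneling=3.0) == pytest.approx(3 * base)
        assert tst_rate(10.0, symmetry_number=2) == pytest.approx(2 * base)

    def test_strictly_decreasing_in_barrier(self):
        rates = [tst_rate(g) for g in np.linspace(0, 30, 31)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_domain_errors(self):
        with pytest.raises(KineticsError):
            tst_rate(10.0, tunneling=-1.0)
        with pytest.raises(KineticsError):
            tst_rate(10.0, symmetry_number=0)

    @given(
        st.floats(min_value=0.0, max_value=30.0),
        st.floats(min_value=0.1, max_value=1e4),
        st.integers(min_value=1, max_value=4),
    )
    def test_barrier_recovered_by_inversion(self, barrier, kappa, sigma):
        rate = tst_rate(barrier, kappa, sigma)
        assert tst_barrier(rate, kappa, sigma) == pytest.approx(barrier, abs=1e-10)


class TestEckartKappa:
    def test_classical_limit(self):
        params = EckartParameters(
            forward_barrier=5.0, reverse_barrier=5.0, imaginary_frequency=1.0
        )
        assert eckart_kappa(params) == pytest.approx(1.0, abs=1e-3)

    def test_frozen_symmetric_reference(self):
        params = EckartParameters(
            forward_barrier=5.0, reverse_barrier=5.0, imaginary_frequency=1500.0
        )
        assert eckart_kappa(params, 298.15) == pytest.approx(
            ORACLE_SYMMETRIC_5_5_1500, rel=5e-3
        )

    @pytest.mark.parametrize("v1", [1.0, 5.0, 12.0, 25.0])
    @pytest.mark.parametrize("dv", [0.0, 8.0])
    @pytest.mark.parametrize("omega,temperature", [(300.0, 250.0), (1500.0, 298.15), (3500.0, 350.0)])
    def test_agrees_with_quadrature_oracle(self, v1, dv, omega, temperature):
        params = EckartParameters(
            forward_barrier=v1, reverse_barrier=v1 + dv, imaginary_frequency=omega
        )
        expected = oracle_eckart_kappa(v1, v1 + dv, omega, temperature)
        assert eckart_kappa(params, temperature) == pytest.approx(expected, rel=5e-3)

    def test_doubling_temperature_reduces_tunneling(self):
        params = EckartParameters(
            forward_barrier=5.0, reverse_barrier=5.0, imaginary_frequency=1500.0
        )
        cold = eckart_kappa(params, 298.15)
        hot = eckart_kappa(params, 596.30)
        assert hot < cold
        # the oracle sees the same ordering
        assert oracle_eckart_kappa(5, 5, 1500, 596.30) < oracle_eckart_kappa(
            5, 5, 1500, 298.15
        )

    def test_always_at_least_one(self):
        for omega in (300.0, 1200.0, 3000.0):
            params = EckartParameters(
                forward_barrier=8.0, reverse_barrier=14.0, imaginary_frequency=omega
            )
            assert eckart_kappa(params) >= 1.0


class TestMarcus:
    @pytest.mark.parametrize(
        "lam, dg0, expected",
        [
            (31.7, -14.9, 2.23),   # normal region
            (22.8, -27.4, 0.23),   # inverted region
            (20.0, -20.0, 0.0),    # barrierless activation point
        ],
    )
    def test_barrier_examples(self, lam, dg0, expected):
        assert marcus_barrier(
            MarcusInput(reorganization_energy=lam, reaction_free_energy=dg0)
        ) == pytest.approx(expected, abs=0.01)

    @given(
        st.floats(min_value=1.0, max_value=60.0),
        st.floats(min_value=-80.0, max_value=40.0),
    )
    def test_parabola_with_vertex_at_minus_lambda(self, lam, dg0):
        h = 1e-3
        center = marcus_barrier(reorganization_energy=lam, reaction_free_energy=dg0)
        left = marcus_barrier(reorganization_energy=lam, reaction_free_energy=dg0 - h)
        right = marcus_barrier(reorganization_energy=lam, reaction_free_energy=dg0 + h)
        # constant second difference = lambda/2 * h^2 / lambda^2 ... i.e. h^2/(2 lambda)
        assert (left + right - 2 * center) == pytest.approx(h * h / (2 * lam), rel=1e-4)
        assert center >= 0.0
        # symmetry about the vertex
        mirrored = marcus_barrier(
            reorganization_energy=lam, reaction_free_energy=-2 * lam - dg0
        )
        assert mirrored == pytest.approx(center, rel=1e-9, abs=1e-12)

    def test_lambda_sign_conventions(self):
        assert marcus_lambda(20.0, 0.0, "plus") == 20.0
        assert marcus_lambda(20.0, 0.0, "minus") == 20.0
        assert marcus_lambda(15.0, -5.0, "minus") == 20.0
        assert marcus_lambda(15.0, -5.0, "plus") == 10.0

    def test_lambda_error_advises_other_convention(self):
        with pytest.raises(KineticsError, match="minus"):
            marcus_lambda(5.0, -10.0, "plus")
        with pytest.raises(KineticsError):
            marcus_barrier(reorganization_energy=-1.0, reaction_free_energy=0.0)


class TestDiffusion:
    def test_equal_radii_closed_form(self):
        # for r_a = r_b the radius cancels: k_D = 8 k_B T N_A / (3 eta)
        eta = 8.91e-4
        expected = 8 * sc.k * 298.15 * sc.N_A / (3 * eta) * 1000.0
        assert smoluchowski_kd(2.0, 2.0, eta, 298.15) == pytest.approx(expected)
        assert expected == pytest.approx(7.4e9, rel=0.01)
        assert smoluchowski_kd(3.7, 3.7, eta, 298.15) == pytest.approx(expected)

    def test_viscosity_scaling(self):
        base = smoluchowski_kd(2.0, 2.0, 8.91e-4)
        assert smoluchowski_kd(2.0, 2.0, 2 * 8.91e-4) == pytest.approx(base / 2)

    @pytest.mark.parametrize(
        "k_act, k_d, expected",
        [
            (1e3, 1e9, 9.99999e2),
            (2e9, 2e9, 1e9),
            # fast thermal rate capped by a back-solved diffusion limit
            (4.1996e12, 4.3545e9, 4.35e9),
        ],
    )
    def test_collins_kimball_examples(self, k_act, k_d, expected):
        assert collins_kimball(k_act, k_d) == pytest.approx(expected, rel=2e-3)

    def test_collins_kimball_degenerate(self):
        assert collins_kimball(0.0, 0.0) == 0.0
        assert collins_kimball(5.0, math.inf) == 5.0

    def test_collins_kimball_bound_exhaustively(self):
        rng = np.random.default_rng(42)
        k_act = 10 ** rng.uniform(-3, 14, size=1_000_000)
        k_d = 10 ** rng.uniform(-3, 14, size=1_000_000)
        k_app = k_d * k_act / (k_d + k_act)
        assert np.all(k_app <= np.minimum(k_act, k_d) * (1 + 1e-12))
        # spot-check the scalar implementation against the vector identity
        for i in range(0, 1_000_000, 100_000):
            assert collins_kimball(k_act[i], k_d[i]) == pytest.approx(k_app[i])


class TestEvaluateChannel:
    WATER = Medium(
        name="water", is_aqueous=True, ph=7.4, diffusion_limit_override={"HO": 2.3e9}
    )

    def test_barrierless_uses_medium_override(self):
        ch = ReactionChannel(
            mechanism="FHT",
            site="1OH",
            radical="HO",
            medium="water",
            species_state="neutral",
            barrierless=True,
        )
        ev = evaluate_channel(ch, self.WATER)
        assert ev.apparent_rate == 2.3e9

    def test_printed_policy_prefers_fixed_rate(self):
        ch = ReactionChannel(
            mechanism="FHT",
            site="7CH",
            radical="HO",
            medium="water",
            species_state="neutral",
            activation_free_energy=6.0,
            tunneling=0.6,
            fixed_rate=1.6e8,
        )
        assert evaluate_channel(ch, self.WATER, policy="printed").apparent_rate == 1.6e8
        recomputed = evaluate_channel(ch, self.WATER, policy="recompute")
        expected = collins_kimball(tst_rate(6.0, 0.6), 2.3e9)
        assert recomputed.apparent_rate == pytest.approx(expected)

    def test_apparent_rate_respects_both_bounds(self):
        ch = ReactionChannel(
            mechanism="SET",
            site="mol",
            radical="HO",
            medium="water",
            species_state="monoanion",
            marcus=MarcusInput(reorganization_energy=20.2, reaction_free_energy=-17.4),
        )
        ev = evaluate_channel(ch, self.WATER, policy="recompute")
        assert ev.apparent_rate <= ev.diffusion_rate
        assert ev.apparent_rate <= ev.thermal_rate
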