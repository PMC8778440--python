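"""Equilibrium solver: exchange closure, mass balances, oracle equivalence."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from oligosaxs.components import CosolventModel, ProteinStateModel, SampleComposition
from oligosaxs.constants import CONST
from oligosaxs.equilibrium import (
    bulk_composition,
    effective_constant,
    mean_molar_volume,
    phi_from_exchange,
    solve_distribution,
)
from oligosaxs.thermo import IonicEnvironment, ThermoTriplet


def _dG_from_K(K, T=298.15):
    """kJ/mol giving equilibrium constant K at temperature T."""
    return -CONST.R * T * math.log(K) / 1e3


def _states(specs):
    return [
        ProteinStateModel(id=i, alpha=a, m=m, m2=m2, R=R, Z=0.0, d=1.0)
        for i, a, m, m2, R in specs
    ]


TINY = 1e-6  # hydration-site count that switches the shell bookkeeping off


class TestExchangeClosure:
    @pytest.mark.parametrize(
        "K, x, expected",
        [(5.0, 0.0, 1.0), (1.0, 0.5, 0.5), (2.0, 0.2, 8.0 / 9.0)],
    )
    def test_closed_form(self, K, x, expected):
        assert phi_from_exchange(K, x) == pytest.approx(expected, rel=1e-12)

    def test_roundtrip_recovers_K(self):
        """Substituting φ back into the exchange quotient returns K_ex."""
        K, x = 2.0, 0.2
        phi = phi_from_exchange(K, x)
        assert phi * x / ((1 - phi) * (1 - x)) == pytest.approx(K, rel=1e-12)

    def test_saturated_cosolvent_warns(self):
        with pytest.warns(UserWarning):
            assert phi_from_exchange(2.0, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            phi_from_exchange(0.0, 0.2)


class TestEffectiveConstant:
    def test_pure_water_identity(self):
        assert effective_constant(3.7, 1.0, 1.0, 1.0, 404, 753, 2) == pytest.approx(3.7)

    def test_site_count_exponent(self):
        """Exponent m_j/α_j − m_1 = 753/2 − 404 = −27.5 on X_Wb."""
        k = effective_constant(1.0, 1.0, 1.0, 0.99, 404, 753, 2)
        assert k == pytest.approx(0.99 ** (-27.5), rel=1e-12)

    def test_monotone_in_phi1(self):
        ks = [
            effective_constant(1.0, p, 0.999, 0.999, 404, 753, 2)
            for p in (0.95, 0.97, 0.99)
        ]
        assert ks[0] < ks[1] < ks[2]

    def test_zero_phi_rejected(self):
        with pytest.raises(ValueError):
            effective_constant(1.0, 0.0, 1.0, 1.0, 404, 753, 2)


class TestBulkComposition:
    def test_no_protein_limit(self):
        x_Gb, X_Wb, X_Gb = bulk_composition(0.0, 0.005, [1.0], [1.0], [404], [1])
        assert x_Gb == pytest.approx(0.005, rel=1e-12)

    def test_no_cosolvent(self):
        x_Gb, X_Wb, X_Gb = bulk_composition(1e-4, 0.0, [1.0], [0.9], [404], [1])
        assert x_Gb == 0.0 and X_Gb == 0.0

    def test_internal_consistency(self):
        """x_Gb from the closed form equals X_Gb/(X_Gb + X_Wb)."""
        x_Gb, X_Wb, X_Gb = bulk_composition(1e-4, 0.005, [1.0], [0.99], [404], [1])
        assert x_Gb == pytest.approx(X_Gb / (X_Gb + X_Wb), rel=1e-14)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            bulk_composition(0.5, 0.0, [1.0], [1.0], [404], [1])


class TestMeanMolarVolume:
    def test_limits(self):
        s = SampleComposition(c0=0.0, M1=17000, C_G0=0.0, pH=7, T=CONST.T0)
        states = _states([("1", 1, 404, 465, 17)])
        nu, _ = mean_molar_volume(s, states, [1.0], [1.0], 0.018, 0.2, CONST.T0)
        assert nu == pytest.approx(0.018, rel=1e-12)

    def test_linear_mixing_without_protein(self):
        s = SampleComposition(c0=0.0, M1=17000, C_G0=0.56, pH=7, T=CONST.T0)
        states = _states([("1", 1, 404, 465, 17)])
        nu, _ = mean_molar_volume(s, states, [1.0], [1.0], 0.018, 0.2, CONST.T0)
        xg = s.x_G
        assert nu == pytest.approx((1 - xg) * 0.018 + xg * 0.2, rel=1e-12)

    def test_unit_density_kills_site_term(self):
        s = SampleComposition(c0=2.0, M1=17000, C_G0=0.0, pH=7, T=CONST.T0)
        states = _states([("1", 1, 404, 465, 17)])  # d=1
        nu, C_P = mean_molar_volume(s, states, [1.0], [1.0], 0.018, 0.2, CONST.T0)
        assert C_P == pytest.approx(s.X_P / nu, rel=1e-14)
        base = s.nu_P(CONST.T0) * s.X_P + 0.018 * (1 - s.X_P)
        assert nu == pytest.approx(base, rel=1e-12)


def _mass_action_oracle(Kbars, alphas, C_P):
    """Independent brute-force mass-action solver.

    ``Kbars[a]`` maps aggregation number a to C_a/C_1^a (cumulative
    constants); root-scan + bisection on the monomer concentration.
    """

    def total(C1):
        return sum(a * Kbars[a] * C1**a for a in alphas) - C_P

    C1 = brentq(total, C_P * 1e-30, C_P, xtol=1e-30, rtol=8.9e-16, maxiter=500)
    return np.array([a * Kbars[a] * C1**a / C_P for a in alphas])


class TestSolveDistribution:
    def test_single_state(self):
        states = _states([("1", 1, 404, 465, 17)])
        s = SampleComposition(c0=2.0, M1=17000, C_G0=0.1, pH=7, T=CONST.T0)
        cos = CosolventModel("G", 0.2, 100.0)
        sol = solve_distribution(
            states, {}, {"1": ThermoTriplet(_dG_from_K(2.0), 0, 0)}, s,
            IonicEnvironment(pH=7, I_S=0.0), cosolvent=cos, electrostatics=False,
        )
        assert sol.x[0] == pytest.approx(1.0)
        assert sol.phi[0] == pytest.approx(phi_from_exchange(2.0, sol.x_Gb), rel=1e-12)

    def test_monomer_dimer_closed_form(self):
        """K̄ = 10⁵ M⁻¹ at C_P = 10⁻⁴ M gives x = (0.2, 0.8)."""
        states = _states([("1", 1, TINY, TINY, 17), ("2", 2, TINY, TINY, 26)])
        s = SampleComposition(c0=1e-4 * 17000, M1=17000, C_G0=0, pH=7, T=CONST.T0)
        sol = solve_distribution(
            states, {"2": ThermoTriplet(_dG_from_K(math.sqrt(1e5)), 0, 0)}, None, s,
            IonicEnvironment(pH=7, I_S=0.0), electrostatics=False,
        )
        # C_P differs infinitesimally from 1e-4 via <nu>; compare to the
        # quadratic closed form at the solver's own C_P
        Kb = 1e5
        C1 = (-1 + math.sqrt(1 + 8 * Kb * sol.C_P)) / (4 * Kb)
        assert sol.x[0] == pytest.approx(C1 / sol.C_P, abs=1e-8)
        assert sol.x[0] == pytest.approx(0.2, abs=1e-3)
        assert sol.x[1] == pytest.approx(0.8, abs=1e-3)

    def test_insulin_scheme_against_oracle(self):
        """Monomer/dimer/tetramer/hexamer populations at the printed
        constants K̄12 = 2.22e5, K̄24 = 40, K̄46 = 220 M⁻¹ match an
        independent mass-action solver to 1e-8."""
        K12b, K24b, K46b = 2.22e5, 40.0, 220.0
        # printed relations: K̄12=K12², K̄24=(K14/K12)⁴, K̄46=K16⁶/(K14⁴K12²)
        K12 = K12b ** (1 / 2)
        K14 = (K24b ** (1 / 4)) * K12
        K16 = (K46b * K14**4 * K12**2) ** (1 / 6)
        states = _states(
            [("1", 1, TINY, TINY, 9.6), ("2", 2, TINY, TINY, 13.2),
             ("4", 4, TINY, TINY, 23.3), ("6", 6, TINY, TINY, 27.0)]
        )
        C_P = 3e-4
        s = SampleComposition(c0=C_P * 5800, M1=5800, C_G0=0, pH=3, T=CONST.T0)
        transitions = {
            "2": ThermoTriplet(_dG_from_K(K12), 0, 0),
            "4": ThermoTriplet(_dG_from_K(K14), 0, 0),
            "6": ThermoTriplet(_dG_from_K(K16), 0, 0),
        }
        sol = solve_distribution(
            states, transitions, None, s, IonicEnvironment(pH=3, I_S=0.0),
            electrostatics=False,
        )
        # cumulative constants C_a = Kbar_a C1^a for the oracle
        Kbars = {1: 1.0, 2: K12b, 4: K24b * K12b**2, 6: K46b * K24b * K12b**3}
        expected = _mass_action_oracle(Kbars, [1, 2, 4, 6], sol.C_P)
        assert np.max(np.abs(sol.x - expected)) < 1e-8
        assert sol.x.sum() == pytest.approx(1.0, abs=1e-12)

    def test_effective_constants_consistent_with_mass_action(self):
        """At realistic hydration-site counts the converged populations obey
        mass action for the solver's own effective constants to 1e-8."""
        states = _states([("1", 1, 404, 465, 17), ("2", 2, 753, 827, 26)])
        s = SampleComposition(c0=10.0, M1=17000, C_G0=0, pH=7, T=320.0)
        sol = solve_distribution(
            states, {"2": ThermoTriplet(-10.0, 0, 0)}, None, s,
            IonicEnvironment(pH=7, I_S=0.0), electrostatics=False,
        )
        Kbar_eff = sol.K_1j[1] ** 2  # C2/C1^2 from the effective constant
        expected = _mass_action_oracle({1: 1.0, 2: Kbar_eff}, [1, 2], sol.C_P)
        assert np.max(np.abs(sol.x - expected)) < 1e-8

    def test_mass_balances_after_convergence(self, md_model, truth_values):
        """Σx = 1 and both solvent balances hold to 1e-10 at a realistic
        cosolvent condition."""
        k = 11  # 10 g/L, 333 K, 0.25 M cosolvent
        sol = md_model.solve_curve_equilibrium(k, truth_values)
        assert sol.x.sum() == pytest.approx(1.0, abs=1e-10)
        sample = [c for c in [md_model.curves[k]]][0]
        s = SampleComposition(c0=sample.c0, M1=md_model.M1, C_G0=sample.C_G0,
                              pH=md_model.pH, T=sample.T, nu_G0=0.16)
        m = [st.m for st in md_model.states]
        alpha = [st.alpha for st in md_model.states]
        x_Gb, X_Wb, X_Gb = bulk_composition(s.X_P, s.x_G, sol.x, sol.phi, m, alpha)
        assert x_Gb == pytest.approx(sol.x_Gb, abs=1e-10)
        assert X_Wb == pytest.approx(sol.X_Wb, abs=1e-10)

    def test_dilute_limit_decouples_phi(self):
        """X_P → 0: φ_j → closed-form exchange occupancy at x_G."""
        states = _states([("1", 1, 404, 465, 17)])
        cos = CosolventModel("G", 0.2, 100.0)
        Kex = 3.0
        s = SampleComposition(c0=1e-9, M1=17000, C_G0=0.1, pH=7, T=CONST.T0)
        sol = solve_distribution(
            states, {}, {"1": ThermoTriplet(_dG_from_K(Kex), 0, 0)}, s,
            IonicEnvironment(pH=7, I_S=0.0), cosolvent=cos, electrostatics=False,
        )
        assert sol.phi[0] == pytest.approx(phi_from_exchange(Kex, s.x_G), rel=1e-7)

    def test_elementary_constants_composition_invariant(self):
        """K_W1j and K_ex do not move with X_P or x_G; effective K_1j does."""
        states = _states([("1", 1, 404, 465, 17), ("2", 2, 753, 827, 26)])
        cos = CosolventModel("G", 0.2, 100.0)
        transitions = {"2": ThermoTriplet(-10.0, 0, 0)}
        exchanges = {"1": ThermoTriplet(1.0, 0, 0), "2": ThermoTriplet(-2.0, 0, 0)}
        KW, Kex, K1 = [], [], []
        for c0, CG in [(2.0, 0.05), (10.0, 0.05), (2.0, 0.25), (10.0, 0.25)]:
            s = SampleComposition(c0=c0, M1=17000, C_G0=CG, pH=7, T=CONST.T0)
            sol = solve_distribution(
                states, transitions, exchanges, s, IonicEnvironment(pH=7, I_S=0.0),
                cosolvent=cos, electrostatics=False,
            )
            KW.append(sol.K_W1j[1])
            Kex.append(tuple(sol.K_ex))
            K1.append(sol.K_1j[1])
        assert np.ptp(KW) / KW[0] < 1e-12
        assert all(k == Kex[0] for k in Kex)
        assert np.ptp(K1) / K1[0] > 1e-6  # effective constant does vary

    def test_nonreference_first_state_rejected(self):
        states = _states([("2", 2, 404, 465, 17)])
        s = SampleComposition(c0=2.0, M1=17000, C_G0=0, pH=7, T=CONST.T0)
        with pytest.raises(ValueError):
            solve_distribution(states, {}, None, s, IonicEnvironment(pH=7, I_S=0.0))
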