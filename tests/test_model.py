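"""Forward intensity assembly, merit function and phase diagram."""

import math

import numpy as np
import pytest

from oligosaxs.constants import CONST
from oligosaxs.curves import ScatteringCurve
from oligosaxs.model import FitParameter, ParameterSet
from oligosaxs.simulate import build_scenario_model, monomer_dimer_scenario


class TestNumberDensity:
    def test_nominal_density(self, md_model, truth_values):
        """n = c°N_A/M1 = 7.08·10¹⁶ cm⁻³ for 2 g/L of a 17 kDa monomer
        (here M1 = 17.6 kDa, same arithmetic) at T°."""
        k = 0  # 2 g/L, 298.15 K, no cosolvent
        curve = md_model.curves[k]
        sol = md_model.solve_curve_equilibrium(k, truth_values)
        n = md_model._number_density(curve, sol)
        expected = curve.c0 * CONST.N_A / md_model.M1 * 1e-3
        assert n == pytest.approx(expected, rel=1e-10)
        # spec-scale cross-check with M1 = 17 kDa
        assert 2.0 * CONST.N_A / 17000 * 1e-3 == pytest.approx(7.08e16, rel=1e-3)

    def test_thermal_expansion_dilutes(self, md_model, truth_values):
        k_cold, k_hot = 0, 4  # same c0, CG=0; 298 K vs 333 K
        n_cold = md_model._number_density(
            md_model.curves[k_cold], md_model.solve_curve_equilibrium(k_cold, truth_values)
        )
        n_hot = md_model._number_density(
            md_model.curves[k_hot], md_model.solve_curve_equilibrium(k_hot, truth_values)
        )
        assert n_hot < n_cold


class TestModelIntensity:
    def test_doubling_concentration_doubles_intensity(self, md_scenario):
        """Single-state, near-ideal solution: dΣ/dΩ scales linearly in n."""
        from oligosaxs.components import ProteinStateModel
        from oligosaxs.simulate import make_toy_structure

        mono = make_toy_structure("sphere", 15.5, 200, seed=21)
        states = [
            ProteinStateModel(id="N", alpha=1, m=404, m2=465, R=17.0, Z=0.0,
                              d=1.07, structure=mono)
        ]
        q = md_scenario.q
        curves = [
            ScatteringCurve(q=q, I=np.ones_like(q), sigma=np.ones_like(q),
                            c0=c0, T=298.15)
            for c0 in (1.0, 2.0)
        ]
        from oligosaxs.model import SaxsGlobalModel

        model = SaxsGlobalModel(curves, states, {}, M1=17600.0, pH=5.0,
                                I_S=0.01, electrostatics=False)
        vals = model.params.values()
        vals.update({"J_0": 0.01, "J_1": 0.01, "d_att_0": 1.0, "d_att_1": 1.0})
        I1 = model.model_intensity(0, vals)
        I2 = model.model_intensity(1, vals)
        assert np.allclose(I2, 2 * I1, rtol=1e-2)

    def test_parts_are_consistent(self, md_model, truth_values):
        """I = n·P·S_M with every factor finite and β ∈ [0, 1]."""
        I, parts = md_model.model_intensity(11, truth_values, return_parts=True)
        assert np.all(np.isfinite(I)) and np.all(I > 0)
        assert np.allclose(I, parts["n"] * parts["P"] * parts["S_M"])
        assert np.all((parts["beta"] >= 0) & (parts["beta"] <= 1))

    def test_unknown_cosolvent_rejected(self, md_scenario, md_batch):
        curves, _ = md_batch
        bad = ScatteringCurve(
            q=curves[0].q, I=curves[0].I, sigma=curves[0].sigma,
            c0=2.0, T=298.15, G="nope", C_G0=0.1,
        )
        with pytest.raises(ValueError, match="nope"):
            build_scenario_model(md_scenario, [bad])


class TestMeritFunction:
    def test_chi2_zero_at_self(self, md_scenario, md_model, truth_values):
        """χ² vanishes when the data equal the model exactly."""
        from oligosaxs.simulate import simulate_batch

        curves, truth = simulate_batch(md_scenario, seed=1, noise=False)
        model = build_scenario_model(md_scenario, curves)
        vals = model.params.values()
        vals.update(truth)
        assert model.chi2(vals) == pytest.approx(0.0, abs=1e-16)

    def test_chi2_unit_offset(self, md_scenario):
        """Every residual at exactly 1σ gives χ² = 1; per-curve values of
        0.5 and 1.5 average to 1 (per-curve means first, then the mean
        over curves)."""
        from oligosaxs.simulate import simulate_batch

        curves, truth = simulate_batch(md_scenario, seed=1, noise=False)
        curves = curves[:2]
        shifted = []
        for k, c in enumerate(curves):
            off = math.sqrt(0.5) if k == 0 else math.sqrt(1.5)
            shifted.append(
                ScatteringCurve(q=c.q, I=c.I + off * c.sigma, sigma=c.sigma,
                                c0=c.c0, T=c.T, G=c.G, C_G0=c.C_G0)
            )
        model = build_scenario_model(md_scenario, shifted)
        vals = model.params.values()
        vals.update({k: v for k, v in truth.items() if k in vals})
        per_curve = model._per_curve_table(vals)["chi2"].to_numpy()
        assert per_curve == pytest.approx([0.5, 1.5], rel=1e-10)
        assert model.chi2(vals) == pytest.approx(1.0, rel=1e-10)

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            ScatteringCurve(
                q=np.linspace(0.01, 0.3, 30), I=np.ones(30), sigma=np.zeros(30),
                c0=2.0, T=298.15,
            )

    def test_regularization_zero_when_uniform(self, md_model):
        vals = md_model.params.values()
        for k in range(len(md_model.curves)):
            vals[f"J_{k}"] = 1.3
            vals[f"d_att_{k}"] = 7.0
        assert md_model.regularization(vals) == 0.0

    def test_regularization_pair_example(self, md_scenario):
        """Two curves differing only in T with J = 1.0 vs 1.1 contribute
        (1 − 1.1/1.0)² + (1 − 1.0/1.1)²."""
        from oligosaxs.simulate import simulate_batch

        curves, truth = simulate_batch(md_scenario, seed=1, noise=False)
        pair = [c for c in curves if c.c0 == 2.0 and c.C_G0 == 0.0][:2]
        model = build_scenario_model(md_scenario, pair)
        vals = model.params.values()
        vals.update({"J_0": 1.0, "J_1": 1.1, "d_att_0": 5.0, "d_att_1": 5.0})
        expected = (1 - 1.1 / 1.0) ** 2 + (1 - 1.0 / 1.1) ** 2
        assert model.regularization(vals) == pytest.approx(expected, rel=1e-12)

    def test_isolated_curve_contributes_nothing(self, md_scenario):
        from oligosaxs.simulate import simulate_batch

        curves, _ = simulate_batch(md_scenario, seed=1, noise=False)
        model = build_scenario_model(md_scenario, [curves[0]])
        assert model.regularization() == 0.0

    def test_merit_decomposition_exact(self, md_model, truth_values):
        gamma = 1e-7
        chi2 = md_model.chi2(truth_values)
        L = md_model.regularization(truth_values)
        H = md_model.merit(truth_values, gamma=gamma)
        assert H - chi2 - gamma * L == 0.0

    def test_objective_invariant_under_curve_reordering(self, md_scenario):
        from oligosaxs.simulate import simulate_batch

        curves, truth = simulate_batch(md_scenario, seed=1)
        perm = [5, 2, 9, 0, 7, 1, 11, 4, 8, 3, 10, 6]
        model_a = build_scenario_model(md_scenario, curves)
        model_b = build_scenario_model(md_scenario, [curves[i] for i in perm])
        vals_a = model_a.params.values()
        vals_a.update(truth)
        vals_b = model_b.params.values()
        vals_b.update({k: v for k, v in truth.items() if not k.startswith(("J_", "d_att_"))})
        for new_k, old_k in enumerate(perm):
            vals_b[f"J_{new_k}"] = truth[f"J_{old_k}"]
            vals_b[f"d_att_{new_k}"] = truth[f"d_att_{old_k}"]
        assert model_b.chi2(vals_b) == pytest.approx(model_a.chi2(vals_a), rel=1e-12)
        assert model_b.regularization(vals_b) == pytest.approx(
            model_a.regularization(vals_a), rel=1e-12
        )


class TestParameterSet:
    def test_duplicate_rejected(self):
        ps = ParameterSet([FitParameter("a", 1.0)])
        with pytest.raises(ValueError):
            ps.add(FitParameter("a", 2.0))

    def test_vector_roundtrip(self):
        ps = ParameterSet(
            [FitParameter("a", 1.0, 0, 2, free=True), FitParameter("b", 5.0)]
        )
        vals = ps.with_vector(np.array([1.5]))
        assert vals == {"a": 1.5, "b": 5.0}

    def test_out_of_bounds_value_rejected(self):
        with pytest.raises(ValueError):
            FitParameter("a", 3.0, 0.0, 2.0)


class TestPhaseDiagram:
    def test_populations_normalized_and_consistent(self, md_model, truth_values):
        T_grid = np.linspace(298.15, 348.15, 6)
        table, contours = md_model.phase_diagram(
            T_grid, np.array([0.0, 0.25]), c0=2.0, G="EC", vals=truth_values
        )
        sums = table.groupby(["T", "C_G0"])["x"].sum()
        assert np.allclose(sums, 1.0, atol=1e-10)
        # the zero-cosolvent column equals a 1-D temperature scan
        t1d, _ = md_model.phase_diagram(
            T_grid, np.array([0.0]), c0=2.0, G=None, vals=truth_values
        )
        a = table[(table.C_G0 == 0.0) & (table.state == "I")].sort_values("T")["x"]
        b = t1d[t1d.state == "I"].sort_values("T")["x"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-10)

    def test_transition_contour_found(self, md_model, truth_values):
        """The monomer-dimer scenario crosses x_I = 0.5 inside the grid."""
        T_grid = np.linspace(298.15, 348.15, 11)
        _, contours = md_model.phase_diagram(
            T_grid, np.array([0.0]), c0=10.0, G=None, vals=truth_values
        )
        assert len(contours["I"]) == 1
        T_half = contours["I"][0][0]
        assert 298.15 < T_half < 348.15
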