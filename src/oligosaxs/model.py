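"""Global SAXS model: forward intensity and regularized batch fitting.

The central objects follow the statsmodels convention:

* :class:`SaxsGlobalModel` is built from a batch of labeled curves and
  the structural/thermodynamic configuration; it exposes the forward
  model ``model_intensity``, the merit-function pieces ``chi2`` /
  ``regularization``, ``fit()`` and ``phase_diagram``.
* :class:`SaxsFitResults` carries the estimates, covariance-based
  uncertainties, per-curve diagnostics and a ``summary()`` table.

For every curve k the theoretical intensity is the chain

    equilibrium (x_j, φ_j) → SLDs (ρ_0, ρ_ld,j) → form factors P_j, P¹_j
    → β(q) → PY+RPA S(q) → S_M(q) → dΣ/dΩ(q) = n·P(q)·S_M(q),

with n = c·N_A/M1 the monomer number density (c corrected from c° for
the thermal expansion of the solvent).  The merit function is
H = χ² + γL with the average reduced chi-square χ² and the neighbor
regularization L tying the per-curve attraction parameters (J, d)
across adjacent conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .components import CosolventModel, ProteinStateModel, SampleComposition
from .constants import CONST
from .curves import ScatteringCurve
from .equilibrium import EquilibriumSolution, solve_distribution
from .formfactor import (
    EnsembleScattering,
    StateScattering,
    effective_form_factor,
)
from .hydration import build_shells, local_domain, sld_bulk, sld_local
from .structurefactor import (
    InteractionModel,
    average_radius_charge,
    measured_structure_factor,
    py_hardsphere_sq,
    rpa_structure_factor,
)
from .thermo import IonicEnvironment, ThermoTriplet, water_molar_volume

__all__ = ["FitParameter", "ParameterSet", "SaxsGlobalModel", "SaxsFitResults"]


@dataclass
class FitParameter:
    """One named model parameter with box bounds and a free/fixed flag."""

    name: str
    value: float
    lower: float = -np.inf
    upper: float = np.inf
    free: bool = False

    def __post_init__(self) -> None:
        if not self.lower <= self.value <= self.upper:
            raise ValueError(f"{self.name}: value {self.value} outside bounds")


class ParameterSet:
    """Ordered collection of :class:`FitParameter` with vector views."""

    def __init__(self, params: Sequence[FitParameter] = ()) -> None:
        self._params: dict[str, FitParameter] = {}
        for p in params:
            self.add(p)

    def add(self, p: FitParameter) -> None:
        if p.name in self._params:
            raise ValueError(f"duplicate parameter {p.name}")
        self._params[p.name] = p

    def __getitem__(self, name: str) -> FitParameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def names(self) -> list[str]:
        return list(self._params)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self._params.values() if p.free]

    def values(self) -> dict[str, float]:
        return {p.name: p.value for p in self._params.values()}

    def vector(self) -> np.ndarray:
        return np.array([self._params[n].value for n in self.free_names])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self._params[n].lower for n in self.free_names])
        hi = np.array([self._params[n].upper for n in self.free_names])
        return lo, hi

    def with_vector(self, vec: np.ndarray) -> dict[str, float]:
        vals = self.values()
        vals.update(dict(zip(self.free_names, vec)))
        return vals

    def set_values(self, vals: Mapping[str, float]) -> None:
        for name, v in vals.items():
            self._params[name].value = float(v)

    def set_free(self, names: Sequence[str], bounds: Mapping[str, tuple[float, float]] | None = None) -> None:
        for n in names:
            p = self._params[n]
            p.free = True
            if bounds and n in bounds:
                p.lower, p.upper = bounds[n]

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            [FitParameter(p.name, p.value, p.lower, p.upper, p.free) for p in self]
        )


class SaxsGlobalModel:
    """Forward model and global fit for a batch of SAXS curves.

    Parameters
    ----------
    curves : batch of :class:`ScatteringCurve` (Nc ≥ 1).
    states : protein states; first entry is the monomeric reference.
        Each state's ``structure`` is a :class:`~oligosaxs.formfactor.Structure`
        or a list of them (conformational ensemble).
    transitions : initial ``ThermoTriplet`` per non-reference state id
        (non-electrostatic 1→j formation in water).
    exchanges : initial ``ThermoTriplet`` keyed by (cosolvent id, state id).
    cosolvents : cosolvent models keyed by id.
    M1 : monomer molecular weight [g mol^-1].
    pH : sample pH (shared across the batch).
    I_S : added (buffer) ionic strength [M].
    environment : optional explicit :class:`IonicEnvironment` overriding
        pH/I_S defaults (microion radius a, etc.).
    electrostatics : include the Debye–Hückel term (default True).
    """

    def __init__(
        self,
        curves: Sequence[ScatteringCurve],
        states: Sequence[ProteinStateModel],
        transitions: Mapping[str, ThermoTriplet],
        exchanges: Mapping[tuple[str, str], ThermoTriplet] | None = None,
        cosolvents: Mapping[str, CosolventModel] | None = None,
        *,
        M1: float,
        pH: float = 7.0,
        I_S: float = 0.01,
        environment: IonicEnvironment | None = None,
        electrostatics: bool = True,
    ) -> None:
        if len(curves) < 1:
            raise ValueError("need at least one curve")
        self.curves = list(curves)
        self.states = list(states)
        self.cosolvents = dict(cosolvents or {})
        self.M1 = M1
        self.pH = pH
        self.electrostatics = electrostatics
        self.env = environment or IonicEnvironment(pH=pH, I_S=I_S)
        self._exchanges0 = dict(exchanges or {})

        for c in self.curves:
            if c.G is not None and c.G not in self.cosolvents:
                raise ValueError(f"curve references unknown cosolvent {c.G!r}")

        # scattering bases (expensive; built once per distinct structure)
        self._bases: dict[str, StateScattering | EnsembleScattering] = {}
        for st in self.states:
            if st.structure is None:
                continue
            members = st.structure if isinstance(st.structure, (list, tuple)) else [st.structure]
            built = []
            for s in members:
                shells = build_shells(s.coords, s.elements)
                built.append(StateScattering(s, shells))
            self._bases[st.id] = built[0] if len(built) == 1 else EnsembleScattering(built)
        missing = [st.id for st in self.states if st.id not in self._bases]
        if missing:
            raise ValueError(f"states without structures: {missing}")

        self.params = self._build_parameters(transitions)
        self._neighbors = self._build_neighbor_map()

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------
    def _build_parameters(self, transitions: Mapping[str, ThermoTriplet]) -> ParameterSet:
        ps = ParameterSet()
        for st in self.states[1:]:
            t = transitions[st.id]
            ps.add(FitParameter(f"dG_W_{st.id}", t.dG0, -400.0, 400.0))
            ps.add(FitParameter(f"dS_W_{st.id}", t.dS0, -5000.0, 5000.0))
            ps.add(FitParameter(f"dCp_W_{st.id}", t.dCp, -20000.0, 20000.0))
        for (g, sid), t in self._exchanges0.items():
            ps.add(FitParameter(f"dG_ex_{g}_{sid}", t.dG0, -30.0, 30.0))
            ps.add(FitParameter(f"dS_ex_{g}_{sid}", t.dS0, -200.0, 200.0))
            ps.add(FitParameter(f"dCp_ex_{g}_{sid}", t.dCp, -200.0, 200.0))
        for st in self.states:
            ps.add(FitParameter(f"d_hyd_{st.id}", st.d, 1.0, 1.15))
            ps.add(FitParameter(f"R_{st.id}", st.R, 0.5 * st.R, 2.0 * st.R))
        ps.add(FitParameter("I_S", self.env.I_S, 0.0, 1.0))
        for k in range(len(self.curves)):
            ps.add(FitParameter(f"J_{k}", 0.5, 0.01, 10.0))
            ps.add(FitParameter(f"d_att_{k}", 5.0, 0.5, 50.0))
        return ps

    def _triplets(self, vals: Mapping[str, float]):
        transitions = {
            st.id: ThermoTriplet(
                vals[f"dG_W_{st.id}"], vals[f"dS_W_{st.id}"], vals[f"dCp_W_{st.id}"]
            )
            for st in self.states[1:]
        }
        exchanges: dict[str, dict[str, ThermoTriplet]] = {}
        for (g, sid) in self._exchanges0:
            exchanges.setdefault(g, {})[sid] = ThermoTriplet(
                vals[f"dG_ex_{g}_{sid}"], vals[f"dS_ex_{g}_{sid}"], vals[f"dCp_ex_{g}_{sid}"]
            )
        return transitions, exchanges

    # ------------------------------------------------------------------
    # forward model
    # ------------------------------------------------------------------
    def solve_curve_equilibrium(
        self, k: int, vals: Mapping[str, float] | None = None
    ) -> EquilibriumSolution:
        """Equilibrium state distribution at the conditions of curve k."""
        vals = vals if vals is not None else self.params.values()
        curve = self.curves[k]
        transitions, exchanges = self._triplets(vals)
        states = [
            ProteinStateModel(
                id=st.id, alpha=st.alpha, m=st.m, m2=st.m2,
                R=vals[f"R_{st.id}"], Z=st.Z, d=vals[f"d_hyd_{st.id}"],
                structure=st.structure,
            )
            for st in self.states
        ]
        cos = self.cosolvents.get(curve.G) if curve.G else None
        sample = SampleComposition(
            c0=curve.c0, M1=self.M1, C_G0=curve.C_G0, pH=self.pH, T=curve.T,
            nu_G0=cos.nu_Gb0 if cos else 0.2,
        )
        env = IonicEnvironment(pH=self.pH, I_S=vals["I_S"], a=self.env.a)
        return solve_distribution(
            states, transitions, exchanges.get(curve.G) if curve.G else None,
            sample, env, cosolvent=cos, electrostatics=self.electrostatics,
        )

    def model_intensity(
        self, k: int, vals: Mapping[str, float] | None = None,
        return_parts: bool = False,
    ):
        """Theoretical dΣ/dΩ(q) [cm^-1] for curve k."""
        vals = vals if vals is not None else self.params.values()
        curve = self.curves[k]
        q = curve.q
        sol = self.solve_curve_equilibrium(k, vals)
        cos = self.cosolvents.get(curve.G) if curve.G else None
        b_G = cos.b_G if cos else 0.0

        rho0 = sld_bulk(sol.x_Gb, sol.nu_Wb, sol.nu_Gb, CONST.b_W, b_G)
        tables = []
        for j, st in enumerate(self.states):
            d_j = vals[f"d_hyd_{st.id}"]
            ld = local_domain(
                st.m, st.m2, sol.phi[j], sol.x_Gb,
                sol.nu_Wb / d_j, sol.nu_Gb, sol.nu_Wb, sol.nu_Gb,
            )
            rho_ld = sld_local(ld, CONST.b_W, b_G)
            tables.append(
                self._bases[st.id].form_factor_table(q, rho0, rho_ld, alpha=st.alpha)
            )
        P, P1, beta = effective_form_factor(sol.x, tables)

        # monomer number density, thermal-expansion corrected [cm^-3]
        n_cm3 = self._number_density(curve, sol)
        R_avg, Z_avg, inv_alpha, n_part = average_radius_charge(
            sol.x, [st.alpha for st in self.states],
            [vals[f"R_{st.id}"] for st in self.states],
            [st.Z for st in self.states],
            n_cm3 * 1e-24,  # cm^-3 -> Å^-3
        )
        inter = InteractionModel(
            R=R_avg, Z=Z_avg, J=vals[f"J_{k}"], d=vals[f"d_att_{k}"],
            kappa_D=sol.env.kappa_D, eps=sol.env.eps, n_part=n_part, T=curve.T,
        )
        S0 = py_hardsphere_sq(q, R_avg, inter.eta)
        S = rpa_structure_factor(q, S0, inter)
        S_M = measured_structure_factor(S, beta)
        I = n_cm3 * P * S_M
        if return_parts:
            return I, dict(
                solution=sol, P=P, P1=P1, beta=beta, S0=S0, S=S, S_M=S_M,
                rho0=rho0, interaction=inter, n=n_cm3,
            )
        return I

    def _number_density(self, curve: ScatteringCurve, sol: EquilibriumSolution) -> float:
        """n = c(T)·N_A/M1 in cm^-3 with solvent thermal expansion."""
        cos = self.cosolvents.get(curve.G) if curve.G else None
        nu_mix_T = sol.nu_Wb
        nu_mix_T0 = CONST.nu_Wb0
        if cos is not None:
            # molar-fraction weighting of the solvent mixture
            sample = SampleComposition(
                c0=curve.c0, M1=self.M1, C_G0=curve.C_G0, pH=self.pH, T=curve.T,
                nu_G0=cos.nu_Gb0,
            )
            nu_mix_T = (1 - sample.x_G) * sol.nu_Wb + sample.x_G * cos.molar_volume(curve.T)
            nu_mix_T0 = (1 - sample.x_G) * CONST.nu_Wb0 + sample.x_G * cos.nu_Gb0
        c_T = curve.c0 * nu_mix_T0 / nu_mix_T
        return c_T * CONST.N_A / self.M1 * 1e-3  # per L -> per cm^3

    # ------------------------------------------------------------------
    # merit function
    # ------------------------------------------------------------------
    def chi2(self, vals: Mapping[str, float] | None = None) -> float:
        """Average reduced chi-square over the batch.

        χ² = (1/Nc) Σ_k (1/Nq_k) Σ_i [(I_expt − I_theo)/σ]².
        """
        vals = vals if vals is not None else self.params.values()
        total = 0.0
        for k, curve in enumerate(self.curves):
            I_theo = self.model_intensity(k, vals)
            total += float(np.mean(((curve.I - I_theo) / curve.sigma) ** 2))
        return total / len(self.curves)

    def _build_neighbor_map(self) -> list[list[int]]:
        """For each curve, its neighbor in each of the four curve parameters.

        The p-neighbor of curve k is the curve identical in the other
        three labels, nearest in p (ties broken toward the smaller
        value); -1 when no such curve exists.
        """
        labels = [c.curve_params for c in self.curves]
        nbrs: list[list[int]] = []
        for k, lab in enumerate(labels):
            row = []
            for p in range(4):
                best, best_key = -1, None
                for k2, lab2 in enumerate(labels):
                    if k2 == k or lab2[p] == lab[p]:
                        continue
                    if any(lab2[pp] != lab[pp] for pp in range(4) if pp != p):
                        continue
                    if p == 2:  # categorical cosolvent type
                        key = (0.0, str(lab2[p]))
                    else:
                        key = (abs(float(lab2[p]) - float(lab[p])), float(lab2[p]))
                    if best_key is None or key < best_key:
                        best, best_key = k2, key
                row.append(best)
            nbrs.append(row)
        return nbrs

    def regularization_terms(self, vals: Mapping[str, float] | None = None) -> np.ndarray:
        """Individual (1 − X_{i,k'}/X_{i,k}) terms of the penalty L."""
        vals = vals if vals is not None else self.params.values()
        terms = []
        for i, base in enumerate(("J", "d_att")):
            for k in range(len(self.curves)):
                Xk = vals[f"{base}_{k}"]
                if Xk == 0:
                    raise ValueError("per-curve parameter hit zero; bounds must exclude 0")
                for p in range(4):
                    k2 = self._neighbors[k][p]
                    if k2 < 0:
                        continue
                    terms.append(1.0 - vals[f"{base}_{k2}"] / Xk)
        return np.asarray(terms, dtype=float)

    def regularization(self, vals: Mapping[str, float] | None = None) -> float:
        """Neighbor-coupling penalty L = Σ_i Σ_k Σ_p (1 − X_{i,k'}/X_{i,k})²."""
        t = self.regularization_terms(vals)
        return float(np.sum(t**2)) if len(t) else 0.0

    def merit(self, vals: Mapping[str, float] | None = None, gamma: float = 1e-7) -> float:
        """Merit function H = χ² + γL."""
        return self.chi2(vals) + gamma * self.regularization(vals)

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def _residuals(self, vals: Mapping[str, float], gamma: float) -> np.ndarray:
        Nc = len(self.curves)
        res = []
        for k, curve in enumerate(self.curves):
            I_theo = self.model_intensity(k, vals)
            res.append((curve.I - I_theo) / (curve.sigma * math.sqrt(Nc * curve.N_q)))
        if gamma > 0:
            res.append(math.sqrt(gamma) * self.regularization_terms(vals))
        return np.concatenate(res)

    def fit(
        self,
        *,
        gamma: float = 1e-7,
        seed: int = 1,
        global_stage: bool = True,
        de_maxiter: int = 40,
        de_popsize: int = 12,
        xtol: float = 1e-10,
        verbose: bool = False,
    ) -> "SaxsFitResults":
        """Minimize H = χ² + γL.

        A seeded differential-evolution global stage explores the shared
        (non per-curve) free parameters; a trust-region least-squares
        polish then refines all free parameters jointly.  Uncertainties
        are covariance-based (Gauss–Newton approximation at the optimum).
        """
        self._check_identifiability()
        ps = self.params
        free = ps.free_names
        if not free:
            raise ValueError("no free parameters declared")

        per_curve = {n for n in free if n.startswith(("J_", "d_att_"))}
        global_free = [n for n in free if n not in per_curve]

        if global_stage and global_free:
            lo, hi = ps.bounds()
            gidx = [free.index(n) for n in global_free]
            x_full = ps.vector()

            def obj(xg: np.ndarray) -> float:
                x = x_full.copy()
                x[gidx] = xg
                r = self._residuals(ps.with_vector(x), gamma)
                return float(np.sum(r * r))

            de = differential_evolution(
                obj,
                bounds=list(zip(lo[gidx], hi[gidx])),
                seed=seed,
                maxiter=de_maxiter,
                popsize=de_popsize,
                tol=1e-8,
                polish=False,
                init="sobol",
                updating="deferred",
                disp=verbose,
            )
            x_full[gidx] = de.x
            ps.set_values(ps.with_vector(x_full))

        lo, hi = ps.bounds()
        x0 = np.clip(ps.vector(), lo, hi)
        ls = least_squares(
            lambda x: self._residuals(ps.with_vector(x), gamma),
            x0,
            bounds=(lo, hi),
            xtol=xtol,
            ftol=1e-12,
            gtol=1e-12,
            method="trf",
            verbose=2 if verbose else 0,
        )
        ps.set_values(ps.with_vector(ls.x))
        vals = ps.values()

        chi2 = self.chi2(vals)
        L = self.regularization(vals)
        H = chi2 + gamma * L

        bse = self._covariance_errors(ls, free)
        per_curve_df = self._per_curve_table(vals)
        return SaxsFitResults(
            model=self, params=ps.copy(), chi2=chi2, L=L, H=H, gamma=gamma,
            bse=bse, per_curve=per_curve_df, optimizer=ls, seed=seed,
        )

    def _covariance_errors(self, ls, free: list[str]) -> dict[str, float]:
        """Covariance-based standard errors from the unscaled residual Jacobian."""
        n_data = sum(c.N_q for c in self.curves)
        Nc = len(self.curves)
        # rows of ls.jac are scaled by 1/sqrt(Nc*Nq_k); undo the (uniform) scaling
        scales = np.concatenate(
            [np.full(c.N_q, math.sqrt(Nc * c.N_q)) for c in self.curves]
        )
        J = ls.jac[: n_data] * scales[:, None]
        try:
            cov = np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(free), np.nan)
        return dict(zip(free, se))

    def _per_curve_table(self, vals: Mapping[str, float]) -> pd.DataFrame:
        rows = []
        for k, curve in enumerate(self.curves):
            I_theo = self.model_intensity(k, vals)
            rows.append(
                dict(
                    curve=k, label=curve.label, c0=curve.c0, T=curve.T,
                    G=curve.G or "", C_G0=curve.C_G0,
                    chi2=float(np.mean(((curve.I - I_theo) / curve.sigma) ** 2)),
                    J=vals[f"J_{k}"], d=vals[f"d_att_{k}"],
                )
            )
        return pd.DataFrame(rows)

    def _check_identifiability(self) -> None:
        cos_used = {c.G for c in self.curves if c.G}
        orphans = [
            n for n in self.params.free_names
            if n.startswith("dG_ex_") and not any(f"_{g}_" in n for g in cos_used)
        ]
        if orphans:
            warnings.warn(
                "free exchange parameters unconstrained by any curve: "
                + ", ".join(orphans)
            )

    # ------------------------------------------------------------------
    # phase diagram
    # ------------------------------------------------------------------
    def phase_diagram(
        self,
        T_grid: np.ndarray,
        C_G_grid: np.ndarray,
        c0: float,
        G: str | None = None,
        vals: Mapping[str, float] | None = None,
    ) -> tuple[pd.DataFrame, dict[str, list[tuple[float, float]]]]:
        """State populations over a temperature × cosolvent-concentration grid.

        Returns a long-format table of x_j(T, C_G°) and, per state, the
        points where x_j crosses 0.5 (linear interpolation along T).
        """
        vals = vals if vals is not None else self.params.values()
        transitions, exchanges = self._triplets(vals)
        cos = self.cosolvents.get(G) if G else None
        rows = []
        for CG in np.atleast_1d(C_G_grid):
            for T in np.atleast_1d(T_grid):
                sample = SampleComposition(
                    c0=c0, M1=self.M1, C_G0=float(CG) if cos else 0.0,
                    pH=self.pH, T=float(T), nu_G0=cos.nu_Gb0 if cos else 0.2,
                )
                env = IonicEnvironment(pH=self.pH, I_S=vals["I_S"], a=self.env.a)
                states = [
                    ProteinStateModel(
                        id=st.id, alpha=st.alpha, m=st.m, m2=st.m2,
                        R=vals[f"R_{st.id}"], Z=st.Z, d=vals[f"d_hyd_{st.id}"],
                    )
                    for st in self.states
                ]
                sol = solve_distribution(
                    states, transitions, exchanges.get(G) if G else None,
                    sample, env, cosolvent=cos, electrostatics=self.electrostatics,
                )
                for st, xj in zip(self.states, sol.x):
                    rows.append(dict(T=float(T), C_G0=float(CG), state=st.id, x=float(xj)))
        table = pd.DataFrame(rows)
        contours: dict[str, list[tuple[float, float]]] = {st.id: [] for st in self.states}
        for st in self.states:
            sub = table[table.state == st.id]
            for CG, grp in sub.groupby("C_G0"):
                g = grp.sort_values("T")
                xv, Tv = g["x"].to_numpy(), g["T"].to_numpy()
                for i in range(len(xv) - 1):
                    lo, hi = xv[i], xv[i + 1]
                    if (lo - 0.5) * (hi - 0.5) < 0:
                        frac = (0.5 - lo) / (hi - lo)
                        contours[st.id].append((Tv[i] + frac * (Tv[i + 1] - Tv[i]), float(CG)))
        return table, contours


@dataclass
class SaxsFitResults:
    """Results of a global fit: estimates, uncertainties, diagnostics."""

    model: SaxsGlobalModel
    params: ParameterSet
    chi2: float
    L: float
    H: float
    gamma: float
    bse: dict[str, float]
    per_curve: pd.DataFrame
    optimizer: object = None
    seed: int = 1

    def predict(self, k: int) -> np.ndarray:
        """Best-fit theoretical curve for batch index k."""
        return self.model.model_intensity(k, self.params.values())

    def equilibrium(self, k: int) -> EquilibriumSolution:
        return self.model.solve_curve_equilibrium(k, self.params.values())

    def summary(self) -> str:
        lines = [
            "Global SAXS fit",
            "=" * 64,
            f"curves: {len(self.model.curves)}   states: {len(self.model.states)}",
            f"chi2 = {self.chi2:.4f}   gamma*L = {self.gamma * self.L:.4g}   "
            f"H = {self.H:.4f}",
            "-" * 64,
            f"{'parameter':<24}{'value':>14}{'std err':>14}",
        ]
        for name in self.params.free_names:
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<24}{self.params[name].value:>14.5g}{se:>14.3g}")
        lines.append("-" * 64)
        lines.append("per-curve (J, d, chi2):")
        for _, r in self.per_curve.iterrows():
            lines.append(
                f"  #{int(r.curve):>2} c0={r.c0:g} T={r['T']:g} G={r.G or '-':<6}"
                f" C_G0={r.C_G0:g}  J={r.J:.3f} d={r.d:.2f}  chi2={r.chi2:.3f}"
            )
        return "\n".join(lines)
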