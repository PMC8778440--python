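"""Coupled oligomerization / preferential-solvation equilibrium solver.

For a protein distributed among Ns states in a water–cosolvent binary
solvent the model couples, at fixed composition (X_P, x_G), pH and T:

* the state-formation equilibria 1 → j in water, with constants K_W1j
  split into non-electrostatic (three-parameter ΔG(T) law) and
  Debye–Hückel electrostatic contributions,
* the Schellman exchange equilibria at each state surface,
  G_s,j + W_b ⇌ G_b + W_s,j, with constants K_ex,j,
* the solvent mass balances that connect the bulk composition to the
  shell occupancies.

The 2·Ns unknowns are the monomer fractions x_j and first-shell water
occupancies φ_j.  A damped fixed-point iteration updates the bulk
quantities (x_Gb, X_Wb, C_P, ⟨ν⟩, counterion ionic strength) from the
current (x, φ); each sweep solves the φ_j in closed form and the x_j by
1-D root finding on the monomer concentration through the effective
mass-action constants

    K_1j = K_W1j · φ_1^{m_1} · X_Wb^{m_j/α_j − m_1} / φ_j^{m_j/α_j}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .components import CosolventModel, ProteinStateModel, SampleComposition
from .constants import CONST
from .thermo import (
    IonicEnvironment,
    ThermoTriplet,
    counterion_ionic_strength,
    debye_kappa,
    electrostatic_state_energy,
    water_dielectric,
    water_molar_volume,
)

__all__ = [
    "EquilibriumSolution",
    "phi_from_exchange",
    "effective_constant",
    "bulk_composition",
    "mean_molar_volume",
    "solve_distribution",
]


def phi_from_exchange(K_ex: float, x_Gb: float) -> float:
    """First-shell water occupancy φ from the exchange constant.

    Closed-form inversion of K_ex = φ·x_Gb / ((1−φ)(1−x_Gb)):

        φ = K_ex (1 − x_Gb) / (x_Gb + K_ex (1 − x_Gb)).
    """
    if K_ex <= 0:
        raise ValueError("exchange constant must be positive")
    if not 0.0 <= x_Gb <= 1.0:
        raise ValueError("bulk cosolvent fraction must lie in [0, 1]")
    if x_Gb == 1.0:
        warnings.warn("x_Gb = 1 with finite K_ex: returning the phi = 0 limit")
        return 0.0
    w = K_ex * (1.0 - x_Gb)
    return w / (x_Gb + w)


def effective_constant(
    K_W1j: float,
    phi_1: float,
    phi_j: float,
    X_Wb: float,
    m_1: float,
    m_j: float,
    alpha_j: float,
) -> float:
    """Effective 1→j equilibrium constant in the binary solvent.

    K_1j = K_W1j · φ_1^{m_1} · X_Wb^{m_j/α_j − m_1} / φ_j^{m_j/α_j}.
    Computed in log space to tame the large hydration-site exponents.
    """
    if K_W1j <= 0:
        raise ValueError("K_W1j must be positive")
    for name, val in (("phi_1", phi_1), ("phi_j", phi_j), ("X_Wb", X_Wb)):
        if not 0.0 < val <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {val}")
    log_k = (
        math.log(K_W1j)
        + m_1 * math.log(phi_1)
        + (m_j / alpha_j - m_1) * math.log(X_Wb)
        - (m_j / alpha_j) * math.log(phi_j)
    )
    return math.exp(log_k)


def bulk_composition(
    X_P: float,
    x_G: float,
    x: Sequence[float],
    phi: Sequence[float],
    m: Sequence[float],
    alpha: Sequence[float],
) -> tuple[float, float, float]:
    """Bulk-solvent composition (x_Gb, X_Wb, X_Gb) from the shell bookkeeping.

    Solvent mass balances:

        X_Wb = (1−X_P)(1−x_G) − X_P Σ_j m_j x_j α_j⁻¹ φ_j
        X_Gb = (1−X_P) x_G − X_P Σ_j m_j x_j α_j⁻¹ (1−φ_j)
        x_Gb = X_Gb / (X_Gb + X_Wb)
    """
    bound_w = X_P * sum(mj * xj / aj * pj for mj, xj, aj, pj in zip(m, x, alpha, phi))
    bound_g = X_P * sum(
        mj * xj / aj * (1.0 - pj) for mj, xj, aj, pj in zip(m, x, alpha, phi)
    )
    if x_G == 0.0:  # no cosolvent anywhere, regardless of phi
        bound_g = 0.0
    X_Wb = (1.0 - X_P) * (1.0 - x_G) - bound_w
    X_Gb = (1.0 - X_P) * x_G - bound_g
    denom = X_Wb + X_Gb
    if X_Wb <= 0 or denom <= 0 or X_Gb < -1e-14:
        raise ValueError(
            "infeasible composition: protein hydration shells exhaust the solvent"
        )
    X_Gb = max(X_Gb, 0.0)
    return X_Gb / denom, X_Wb, X_Gb


def mean_molar_volume(
    sample: SampleComposition,
    states: Sequence[ProteinStateModel],
    x: Sequence[float],
    phi: Sequence[float],
    nu_Wb: float,
    nu_Gb: float,
    T: float,
) -> tuple[float, float]:
    """Average molar volume ⟨ν⟩ [L mol^-1] and monomer molarity C_P [M].

    ⟨ν⟩ = ν_P X_P + (ν_Wb(1−x_G) + ν_Gb x_G)(1−X_P)
          + X_P Σ_j m_j x_j α_j⁻¹ [(ν_Ws,j − ν_Wb)φ_j + (ν_Gs,j − ν_Gb)(1−φ_j)]

    with ν_Ws,j = ν_Wb/d_j and ν_Gs,j = ν_Gb (only hydration water is
    compacted relative to the bulk).  C_P = X_P/⟨ν⟩.
    """
    X_P, x_G = sample.X_P, sample.x_G
    site_term = 0.0
    for st, xj, pj in zip(states, x, phi):
        nu_Wsj = nu_Wb / st.d
        # nu_Gs,j = nu_Gb by convention, so the cosolvent site term vanishes
        site_term += st.m * xj / st.alpha * (nu_Wsj - nu_Wb) * pj
    nu = (
        sample.nu_P(T) * X_P
        + (nu_Wb * (1.0 - x_G) + nu_Gb * x_G) * (1.0 - X_P)
        + X_P * site_term
    )
    return nu, X_P / nu


@dataclass
class EquilibriumSolution:
    """Solved state distribution and solvent bookkeeping at one condition."""

    x: np.ndarray
    phi: np.ndarray
    x_Gb: float
    X_Wb: float
    X_Gb: float
    C_P: float
    nu_mean: float
    nu_Wb: float
    nu_Gb: float
    K_W1j: np.ndarray
    K_ex: np.ndarray
    K_1j: np.ndarray
    dG_1j: np.ndarray
    env: IonicEnvironment
    T: float
    converged: bool = True
    iterations: int = 0
    residual: float = 0.0

    @property
    def C(self) -> np.ndarray:
        """Molar concentrations C_j = C_P x_j / α_j of each state [M]."""
        return self.C_P * self.x / self._alpha

    _alpha: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _mass_action_fractions(
    log_K_1j: np.ndarray, alpha: np.ndarray, C_P: float
) -> np.ndarray:
    """State fractions x_j from effective constants by 1-D root finding.

    C_j = (K_1j C_1)^{α_j} (1 M standard state); conservation
    Σ_j α_j C_j = C_P fixes the monomer concentration C_1.  Solved in
    log space so that extreme constants (large hydration exponents)
    cannot overflow.
    """
    log_CP = math.log(C_P)

    def excess(t: float) -> float:
        # log Σ_j α_j (K_1j e^t)^α_j − log C_P, monotone increasing in t
        terms = np.log(alpha) + alpha * (log_K_1j + t)
        m = terms.max()
        return m + math.log(np.exp(terms - m).sum()) - log_CP

    hi = log_CP  # monomer term alone already reaches C_P at t = log C_P
    # bracket low enough that every state term falls below C_P
    lo = min(
        (log_CP - 5.0 - math.log(a)) / a - lk for a, lk in zip(alpha, log_K_1j)
    )
    lo = min(lo, log_CP) - 5.0
    t = brentq(excess, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    log_x = np.log(alpha) + alpha * (log_K_1j + t) - log_CP
    x = np.exp(log_x - log_x.max())
    return x / x.sum()


def solve_distribution(
    states: Sequence[ProteinStateModel],
    transitions: Mapping[str, ThermoTriplet],
    exchanges: Mapping[str, ThermoTriplet] | None,
    sample: SampleComposition,
    env: IonicEnvironment,
    cosolvent: CosolventModel | None = None,
    *,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 500,
    electrostatics: bool = True,
) -> EquilibriumSolution:
    """Solve the coupled 2·Ns nonlinear system for (x_j, φ_j).

    Parameters
    ----------
    states : protein states; the first entry must be the monomeric
        reference state (α=1).
    transitions : per-state ``ThermoTriplet`` for the non-electrostatic
        1→j formation free energy, keyed by state id (state 1 omitted).
    exchanges : per-state ``ThermoTriplet`` for the cosolvent–water
        exchange, keyed by state id; ``None`` when no cosolvent.
    sample : composition (fixes X_P, x_G, pH, T).
    env : ionic environment carrying the added ionic strength and the
        microion radius; ε and κ_D are recomputed at the sample T.
    cosolvent : cosolvent model, or ``None`` for pure water.
    electrostatics : include the Debye–Hückel term in K_W1j.
    """
    if states[0].alpha != 1:
        raise ValueError("the first state must be the monomeric reference (alpha=1)")
    Ns = len(states)
    T = sample.T
    alpha = np.array([s.alpha for s in states], dtype=float)
    m = np.array([s.m for s in states], dtype=float)
    Z = np.array([s.Z for s in states], dtype=float)
    R = np.array([s.R for s in states], dtype=float)

    nu_Wb = water_molar_volume(T)
    has_cosolvent = cosolvent is not None and sample.x_G > 0
    nu_Gb = cosolvent.molar_volume(T) if cosolvent is not None else nu_Wb * 2

    # temperature-dependent elementary constants
    dG_nel = np.zeros(Ns)
    for j, st in enumerate(states[1:], start=1):
        dG_nel[j] = transitions[st.id].gibbs(T)
    K_ex = np.ones(Ns)
    if has_cosolvent and exchanges is not None:
        for j, st in enumerate(states):
            if st.id in exchanges:
                K_ex[j] = exchanges[st.id].equilibrium_constant(T)

    eps = water_dielectric(T)
    x = np.zeros(Ns)
    x[0] = 1.0
    phi = np.ones(Ns)
    x_Gb = sample.x_G
    X_Wb = 1.0 - sample.X_P
    log_K_1j = np.zeros(Ns)
    log_K_W1j = np.zeros(Ns)
    I_S_extra = 0.0

    converged = False
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        x_Gb, X_Wb, X_Gb = bulk_composition(
            sample.X_P, sample.x_G, x, phi, m, alpha
        )
        nu_mean, C_P = mean_molar_volume(sample, states, x, phi, nu_Wb, nu_Gb, T)

        if electrostatics:
            I_S_extra = 0.0
            if has_cosolvent and cosolvent.ionic:
                C_G = sample.x_G * (1.0 - sample.X_P) / nu_mean
                I_S_extra = C_G  # 1:1 dissociation: ½(C + C)
            I_ci = counterion_ionic_strength(C_P, x, alpha, Z)
            I = env.I_S + I_S_extra + I_ci
            kappa = debye_kappa(I, eps, T)
            G_el = np.array(
                [
                    electrostatic_state_energy(Zj, Rj, kappa, env.a, eps)
                    for Zj, Rj in zip(Z, R)
                ]
            )
            dG_el = G_el / alpha - G_el[0]
        else:
            I_ci, kappa, dG_el = 0.0, 0.0, np.zeros(Ns)

        log_K_W1j = -(dG_nel + dG_el) / (CONST.R * T)
        phi_new = np.array([phi_from_exchange(k, x_Gb) for k in K_ex])
        log_K_1j = (
            log_K_W1j
            + m[0] * math.log(phi_new[0])
            + (m / alpha - m[0]) * math.log(X_Wb)
            - (m / alpha) * np.log(phi_new)
        )
        log_K_1j[0] = 0.0
        x_new = _mass_action_fractions(log_K_1j, alpha, C_P)
        # clamp underflowing oligomer fractions
        x_new = np.where((alpha > 1) & (x_new < 1e-15), 0.0, x_new)
        x_new /= x_new.sum()

        residual = float(np.max(np.abs(x_new - x)) + np.max(np.abs(phi_new - phi)))
        x = (1.0 - damping) * x + damping * x_new
        phi = (1.0 - damping) * phi + damping * phi_new
        if residual < tol:
            x, phi = x_new, phi_new
            converged = True
            break

    if not converged:
        raise RuntimeError(
            f"equilibrium solver did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )

    # final self-consistent bookkeeping at the converged point
    x_Gb, X_Wb, X_Gb = bulk_composition(sample.X_P, sample.x_G, x, phi, m, alpha)
    nu_mean, C_P = mean_molar_volume(sample, states, x, phi, nu_Wb, nu_Gb, T)
    if electrostatics:
        I_ci = counterion_ionic_strength(C_P, x, alpha, Z)
        I_total = env.I_S + I_S_extra + I_ci
        kappa = debye_kappa(I_total, eps, T)
    else:
        I_ci, kappa = 0.0, 0.0
    env_T = IonicEnvironment(
        pH=sample.pH, I_S=env.I_S + I_S_extra, I_ci=I_ci, a=env.a, eps=eps, kappa_D=kappa
    )
    dG_1j = -CONST.R * T * log_K_1j
    with np.errstate(over="ignore"):
        K_1j = np.exp(log_K_1j)
        K_W1j = np.exp(log_K_W1j)
    sol = EquilibriumSolution(
        x=x,
        phi=phi,
        x_Gb=x_Gb,
        X_Wb=X_Wb,
        X_Gb=X_Gb,
        C_P=C_P,
        nu_mean=nu_mean,
        nu_Wb=nu_Wb,
        nu_Gb=nu_Gb,
        K_W1j=K_W1j,
        K_ex=K_ex,
        K_1j=K_1j,
        dG_1j=dG_1j,
        env=env_T,
        T=T,
        converged=converged,
        iterations=it,
        residual=residual,
    )
    sol._alpha = alpha
    return sol
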