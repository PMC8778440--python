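"""Effective protein–protein interactions: HSDY potential, PY + RPA.

A mixture of states is mapped onto a one-component fluid of effective
particles with number-weighted average radius R and charge Z,

    R = (1/⟨α⁻¹⟩) Σ_j x_j α_j⁻¹ R_j,   ⟨α⁻¹⟩ = Σ_j x_j α_j⁻¹,

interacting through a hard-sphere double-Yukawa (HSDY) potential

    u(r) = u_HS(r) + B1C e^{−κ_D(r−2R)}/r + B1A e^{−(r−2R)/d}/r

with a DLVO screened-Coulomb repulsion, B1C = Z²q_e²/(4πε₀ε(1+κ_D R)²),
and a generic attraction of contact depth J (u_YA(2R) = −J, so
B1A = −2JR) and range d.  The structure factor is the Percus–Yevick
hard-sphere solution S0(q) perturbed by the Yukawa tails through the
random-phase approximation,

    1/S(q) = 1/S0(q) + n_part·ũ(q)/(k_B T),

where ũ(q) is the analytic Fourier transform of each tail truncated at
contact (r > 2R).  The measured structure factor couples to the form
factors through β(q): S_M(q) = 1 + β(q)[S(q) − 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CONST

__all__ = [
    "InteractionModel",
    "average_radius_charge",
    "hsdy_potential",
    "yukawa_ft",
    "py_hardsphere_sq",
    "rpa_structure_factor",
    "measured_structure_factor",
]


@dataclass
class InteractionModel:
    """Effective one-component interaction parameters for one condition.

    R [Å]: average protein radius; Z: average net charge; J [k_BT]:
    attraction depth at contact; d [Å]: attraction range; kappa_D
    [Å^-1]; eps: solvent dielectric constant; n_part [Å^-3]: particle
    number density; T [K].
    """

    R: float
    Z: float
    J: float
    d: float
    kappa_D: float
    eps: float
    n_part: float
    T: float

    def __post_init__(self) -> None:
        if self.R <= 0 or self.d <= 0:
            raise ValueError("R and d must be positive")
        if self.eta >= 0.5:
            raise ValueError(f"volume fraction eta={self.eta:.3f} out of PY range")

    @property
    def eta(self) -> float:
        """Hard-sphere volume fraction."""
        return self.n_part * 4.0 * math.pi * self.R**3 / 3.0

    @property
    def B1C(self) -> float:
        """Repulsive Yukawa prefactor [J·Å] (DLVO screened Coulomb)."""
        # q_e^2 Z^2 / (4 pi eps0 eps (1+kappa R)^2); converted so that
        # B1C/r with r in Å gives Joules
        per_m = CONST.q_e**2 * self.Z**2 / (
            4.0 * math.pi * CONST.eps0 * self.eps * (1.0 + self.kappa_D * self.R) ** 2
        )
        return per_m / 1e-10  # J·m -> J·Å

    @property
    def B2C(self) -> float:
        return self.kappa_D

    @property
    def B1A(self) -> float:
        """Attractive Yukawa prefactor [J·Å]; u_YA(2R) = −J·k_BT exactly."""
        return -2.0 * self.J * CONST.k_B * self.T * self.R

    @property
    def B2A(self) -> float:
        return 1.0 / self.d


def average_radius_charge(
    x: Sequence[float],
    alpha: Sequence[float],
    R: Sequence[float],
    Z: Sequence[float],
    n_monomer: float,
) -> tuple[float, float, float, float]:
    """Number-weighted average radius, charge, ⟨α⁻¹⟩ and particle density.

    ``n_monomer`` is the nominal monomer number density [Å^-3]; the
    particle density is n_part = n·⟨α⁻¹⟩.
    """
    x = np.asarray(x, float)
    alpha = np.asarray(alpha, float)
    inv_alpha = float(np.sum(x / alpha))
    R_avg = float(np.sum(x / alpha * np.asarray(R, float))) / inv_alpha
    Z_avg = float(np.sum(x / alpha * np.asarray(Z, float))) / inv_alpha
    return R_avg, Z_avg, inv_alpha, n_monomer * inv_alpha


def hsdy_potential(r: np.ndarray, model: InteractionModel) -> np.ndarray:
    """HSDY pair potential u(r) [J]; +inf inside the hard core r < 2R."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sigma = 2.0 * model.R
    with np.errstate(over="ignore"):
        tail = (
            model.B1C * np.exp(-model.B2C * (r - sigma)) / r
            + model.B1A * np.exp(-model.B2A * (r - sigma)) / r
        )
    return np.where(r < sigma, np.inf, tail)


def yukawa_ft(q: np.ndarray, B1: float, B2: float, R: float) -> np.ndarray:
    """3-D Fourier transform of the truncated Yukawa tail [J·Å³].

    ũ(q) = 4π ∫_{2R}^∞ r² (B1 e^{−B2(r−2R)}/r) j0(qr) dr
         = (4π B1/q)·[B2 sin(2Rq) + q cos(2Rq)]/(B2² + q²).
    """
    q = np.asarray(q, dtype=float)
    if B2 <= 0:
        raise ValueError("B2 must be positive")
    s = 2.0 * R * q
    return 4.0 * math.pi * B1 * (B2 * np.sin(s) + q * np.cos(s)) / (q * (B2**2 + q**2))


def py_hardsphere_sq(q: np.ndarray, R: float, eta: float) -> np.ndarray:
    """Percus–Yevick hard-sphere structure factor S0(q).

    Analytic Wertheim–Thiele solution for spheres of diameter 2R;
    S0(0) = (1−η)⁴/(1+2η)².  Small-A kernels switch to series to avoid
    cancellation.
    """
    if not 0.0 <= eta < 0.5:
        raise ValueError(f"volume fraction eta={eta} outside [0, 0.5)")
    q = np.asarray(q, dtype=float)
    if eta == 0.0:
        return np.ones_like(q)
    A = q * 2.0 * R
    a = (1.0 + 2.0 * eta) ** 2 / (1.0 - eta) ** 4
    b = -6.0 * eta * (1.0 + eta / 2.0) ** 2 / (1.0 - eta) ** 4
    g = eta * a / 2.0

    small = A < 0.1
    As = np.where(small, 1.0, A)  # avoid division warnings
    sinA, cosA = np.sin(As), np.cos(As)
    f1 = (sinA - As * cosA) / As**3
    f2 = (2.0 * As * sinA + (2.0 - As**2) * cosA - 2.0) / As**4
    f3 = (
        -(As**4) * cosA
        + 4.0 * ((3.0 * As**2 - 6.0) * cosA + (As**3 - 6.0 * As) * sinA + 6.0)
    ) / As**6
    A2 = A * A
    f1 = np.where(small, 1.0 / 3.0 - A2 / 30.0 + A2 * A2 / 840.0, f1)
    f2 = np.where(small, 1.0 / 4.0 - A2 / 36.0 + A2 * A2 / 960.0, f2)
    f3 = np.where(small, 1.0 / 6.0 - A2 / 48.0 + A2 * A2 / 1200.0, f3)
    nC = -24.0 * eta * (a * f1 + b * f2 + g * f3)
    return 1.0 / (1.0 - nC)


def rpa_structure_factor(
    q: np.ndarray, S0: np.ndarray, model: InteractionModel
) -> np.ndarray:
    """RPA-perturbed structure factor 1/S = 1/S0 + n·ũ(q)/(k_B T)."""
    q = np.asarray(q, dtype=float)
    u_tilde = np.zeros_like(q)
    if model.Z != 0.0 and model.kappa_D > 0.0:
        u_tilde += yukawa_ft(q, model.B1C, model.B2C, model.R)
    elif model.Z != 0.0:
        # unscreened limit: treat as kappa -> 0 Yukawa (pure Coulomb tail)
        u_tilde += yukawa_ft(q, model.B1C, 1e-12, model.R)
    if model.J != 0.0:
        u_tilde += yukawa_ft(q, model.B1A, model.B2A, model.R)
    inv_S = 1.0 / S0 + model.n_part * u_tilde / (CONST.k_B * model.T)
    if np.any(inv_S <= 0):
        raise ValueError(
            "RPA instability: S(q) <= 0; weaken the attraction J or lower the density"
        )
    return 1.0 / inv_S


def measured_structure_factor(S: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Measured structure factor S_M(q) = 1 + β(q)[S(q) − 1]."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta must lie in [0, 1]")
    return 1.0 + beta * (np.asarray(S, float) - 1.0)
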