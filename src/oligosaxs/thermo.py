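"""Temperature-dependent thermodynamics, molar volumes and electrostatics.

This module hosts the elementary thermodynamic machinery of the model:

* the three-parameter temperature law for Gibbs free-energy changes
  ΔG(T) = ΔG° + (ΔCp − ΔS°)(T − T°) − ΔCp·T·ln(T/T°),
* thermal-expansion laws for the molar volumes of water, cosolvent and
  protein,
* the protein net charge from Henderson–Hasselbalch titration of the
  side chains and termini,
* the ionic strength (added microions plus protein counterions) and the
  Debye screening parameter,
* the Debye–Hückel self-energy of a charged spherical macroion, used to
  split the state-formation free energy into electrostatic and
  non-electrostatic parts.

Energies are J mol^-1, lengths Å, concentrations mol L^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import CONST

__all__ = [
    "ThermoTriplet",
    "IonicEnvironment",
    "gibbs_at_temperature",
    "water_molar_volume",
    "expanded_molar_volume",
    "water_dielectric",
    "protein_charge",
    "load_pka_table",
    "ionic_strength",
    "counterion_ionic_strength",
    "debye_kappa",
    "electrostatic_state_energy",
]


@dataclass(frozen=True)
class ThermoTriplet:
    """Reference thermodynamic parameters of one elementary process.

    Parameters
    ----------
    dG0 : reference Gibbs free-energy change at T° [kJ mol^-1].
    dS0 : reference entropy change at T° [J mol^-1 K^-1].
    dCp : heat-capacity change, temperature independent [J mol^-1 K^-1].
    """

    dG0: float = 0.0
    dS0: float = 0.0
    dCp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dG0", "dS0", "dCp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def gibbs(self, T: float) -> float:
        """ΔG(T) in J mol^-1 (note interface kJ -> internal J)."""
        return gibbs_at_temperature(self, T)

    def equilibrium_constant(self, T: float) -> float:
        """K(T) = exp(−ΔG(T)/RT), dimensionless."""
        return math.exp(-self.gibbs(T) / (CONST.R * T))


def gibbs_at_temperature(triplet: ThermoTriplet, T: float) -> float:
    """Gibbs free-energy change at temperature ``T`` [J mol^-1].

    Uses the classical-thermodynamics law with temperature-independent
    ΔCp and natural logarithm,

        ΔG(T) = ΔG° + (ΔCp − ΔS°)(T − T°) − ΔCp·T·ln(T/T°).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    T0 = CONST.T0
    dG0 = triplet.dG0 * 1e3  # kJ/mol -> J/mol
    return dG0 + (triplet.dCp - triplet.dS0) * (T - T0) - triplet.dCp * T * math.log(T / T0)


def water_molar_volume(T: float) -> float:
    """Molar volume of bulk water at ``T`` [L mol^-1].

    ν_Wb(T) = ν_Wb°·exp(α_W(T−T°) + ½β_W(T−T°)²).  Outside the validity
    window [240, 380] K a warning is emitted and the expansion is still
    evaluated.
    """
    if not 240.0 <= T <= 380.0:
        warnings.warn(
            f"water molar volume expansion evaluated outside [240, 380] K (T={T})",
            stacklevel=2,
        )
    dT = T - CONST.T0
    return CONST.nu_Wb0 * math.exp(CONST.alpha_W * dT + 0.5 * CONST.beta_W * dT * dT)


def expanded_molar_volume(nu0: float, alpha: float, T: float) -> float:
    """Molar volume ν°·exp(α(T−T°)) [L mol^-1] for cosolvent or protein."""
    if nu0 <= 0:
        raise ValueError("reference molar volume must be positive")
    return nu0 * math.exp(alpha * (T - CONST.T0))


def water_dielectric(T: float) -> float:
    """Relative dielectric constant of pure water at ``T`` [K].

    Malmberg–Maryott empirical polynomial in Celsius temperature;
    ε ≈ 78.3 at 25 °C.  The cosolvent effect on ε is neglected
    (second-order at the ≤0.25 M concentrations the model addresses).
    """
    t = T - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t * t - 1.410e-6 * t**3


# ---------------------------------------------------------------------------
# Protein net charge
# ---------------------------------------------------------------------------

_ACIDIC = {"D", "E", "C", "Y", "cterm"}
_BASIC = {"H", "K", "R", "nterm"}


def load_pka_table() -> dict[str, float]:
    """Load the packaged side-chain/termini pKa table.

    The table ships as a small key–value text file and can be overridden
    by passing an explicit mapping to :func:`protein_charge`.
    """
    table: dict[str, float] = {}
    text = resources.files("oligosaxs.data").joinpath("pka.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()
        table[key] = float(value)
    return table


def protein_charge(
    sequence: str,
    pH: float,
    pka_table: Mapping[str, float] | None = None,
) -> float:
    """Net protein charge Z at ``pH`` in elementary charges.

    Henderson–Hasselbalch sum of fractional charges over the titratable
    side chains (D, E, H, K, R, C, Y) and the two termini.  The result is
    continuous and monotonically non-increasing in pH.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    table = dict(pka_table) if pka_table is not None else load_pka_table()
    counts: dict[str, int] = {"nterm": 1, "cterm": 1}
    for aa in sequence.upper():
        if aa not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"unknown residue code: {aa!r}")
        if aa in table:
            counts[aa] = counts.get(aa, 0) + 1
    z = 0.0
    for group, n in counts.items():
        pka = table[group]
        if group in _BASIC:
            z += n / (1.0 + 10.0 ** (pH - pka))
        elif group in _ACIDIC:
            z -= n / (1.0 + 10.0 ** (pka - pH))
    return z


# ---------------------------------------------------------------------------
# Ionic strength and Debye–Hückel electrostatics
# ---------------------------------------------------------------------------


def ionic_strength(species: Iterable[tuple[float, float]]) -> float:
    """Ionic strength I = ½ Σ z_i² C_i [M] over microion species.

    ``species`` iterates over (C_i [M], z_i) pairs.  The protein macroion
    itself is never passed here: Debye screening is by small ions and
    the macroion is the screened object.
    """
    I = 0.0
    for C, z in species:
        if C < 0:
            raise ValueError(f"negative concentration {C}")
        I += 0.5 * z * z * C
    return I


def counterion_ionic_strength(
    C_P: float, x: Sequence[float], alpha: Sequence[float], Z: Sequence[float]
) -> float:
    """Ionic strength of the protein counterions [M].

    Electroneutrality fixes the counterion concentration
    C_ci = C_P Σ_j x_j α_j⁻¹ |Z_j| with |z_ci| = 1, so
    I_ci = ½ C_ci.
    """
    C_ci = C_P * sum(xj / aj * abs(Zj) for xj, aj, Zj in zip(x, alpha, Z))
    return ionic_strength([(C_ci, 1.0)])


def debye_kappa(I: float, eps: float, T: float) -> float:
    """Reciprocal Debye screening length κ_D [Å^-1].

    κ_D = (2 N_A q_e² I / (ε0 ε k_B T))^{1/2} with I converted from
    mol L^-1 to number per m³.
    """
    if I < 0:
        raise ValueError("ionic strength must be non-negative")
    if eps <= 1:
        raise ValueError("relative dielectric constant must exceed 1")
    n_per_m3 = I * 1e3 * CONST.N_A  # mol/L -> per m^3
    kappa_m = math.sqrt(2.0 * CONST.q_e**2 * n_per_m3 / (CONST.eps0 * eps * CONST.k_B * T))
    return kappa_m * 1e-10  # m^-1 -> Å^-1


def electrostatic_state_energy(
    Z: float, R: float, kappa_D: float, a: float, eps: float
) -> float:
    """Debye–Hückel self-energy of a charged spherical state [J mol^-1].

    G_el = N_A q_e² Z² / (8π ε0 ε R) · [1 − κ_D R / (1 + κ_D (R + a))]

    with the state radius ``R`` and mean microion radius ``a`` in Å and
    κ_D in Å^-1.  Even in Z; strictly decreasing in κ_D for Z≠0;
    vanishes as R → ∞.
    """
    if R <= 0:
        raise ValueError("state radius must be positive")
    R_m = R * 1e-10
    bracket = 1.0 - (kappa_D * R) / (1.0 + kappa_D * (R + a))
    per_molecule = CONST.q_e**2 * Z * Z / (8.0 * math.pi * CONST.eps0 * eps * R_m) * bracket
    return per_molecule * CONST.N_A


@dataclass
class IonicEnvironment:
    """Ionic milieu of one sample condition.

    Fields follow the model's bookkeeping: ``I_S`` is the added ionic
    strength (buffer microions plus cosolvent microions when the
    cosolvent is ionic), ``I_ci`` the counterion contribution from
    electroneutrality, ``I = I_S + I_ci``; ``a`` is the mean microion
    radius [Å]; ``eps`` the solvent relative dielectric constant;
    ``kappa_D`` the reciprocal Debye length [Å^-1].
    """

    pH: float
    I_S: float
    I_ci: float = 0.0
    a: float = 2.0
    eps: float = 78.3
    kappa_D: float = 0.0

    def __post_init__(self) -> None:
        if self.I < 0 or self.kappa_D < 0:
            raise ValueError("ionic strength and kappa_D must be non-negative")
        if self.eps <= 1:
            raise ValueError("eps must exceed 1")

    @property
    def I(self) -> float:
        return self.I_S + self.I_ci

    def with_temperature(self, T: float) -> "IonicEnvironment":
        """Return a copy with ε(T) and κ_D(I, ε, T) refreshed."""
        eps = water_dielectric(T)
        return IonicEnvironment(
            pH=self.pH,
            I_S=self.I_S,
            I_ci=self.I_ci,
            a=self.a,
            eps=eps,
            kappa_D=debye_kappa(self.I, eps, T),
        )
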