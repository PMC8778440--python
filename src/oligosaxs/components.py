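"""Domain objects describing protein states, cosolvents and samples."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from .constants import CONST
from .thermo import expanded_molar_volume


@dataclass
class ProteinStateModel:
    """One protein state j (folded oligomer or unfolded chain).

    Parameters
    ----------
    id : label, e.g. ``"N"``, ``"I"``, ``"U"`` or ``"1"``, ``"2"``, ``"4"``, ``"6"``.
    alpha : aggregation number α_j (number of monomers, ≥1).
    m : number of water sites in the first hydration shell.
    m2 : number of sites in the second hydration shell.
    R : effective state radius [Å] (used for Debye–Hückel self-energy and
        for the interaction-radius average).
    Z : net number of elementary charges at the sample pH.
    d : relative mass density of first-shell hydration water, in [1, 1.15].
    structure : atomic structure, ensemble (list of structures) or None for
        pure-thermodynamics work.
    """

    id: str
    alpha: int
    m: float
    m2: float
    R: float
    Z: float
    d: float = 1.07
    structure: Any = None

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("aggregation number alpha must be >= 1")
        if self.m <= 0 or self.m2 <= 0:
            raise ValueError("hydration-site counts must be positive")
        if self.R <= 0:
            raise ValueError("state radius must be positive")
        if not 1.0 <= self.d <= 1.15:
            raise ValueError("relative hydration-water density d must lie in [1, 1.15]")


@dataclass
class CosolventModel:
    """Cosolvent (e.g. a modified sugar) dissolved with the protein.

    ``nu_Gb0`` is the bulk molar volume at T° [L mol^-1] (must exceed the
    water molar volume: the site-displacement bookkeeping of the local
    domain requires a cosolvent larger than water), ``alpha_G`` the
    thermal expansivity [K^-1], ``N_Ge`` the number of electrons and
    ``ionic`` whether the compound dissociates into a pair of 1:1
    microions in water.
    """

    id: str
    nu_Gb0: float
    N_Ge: float
    alpha_G: float = 0.0
    ionic: bool = False

    def __post_init__(self) -> None:
        if self.nu_Gb0 <= CONST.nu_Wb0:
            raise ValueError("cosolvent molar volume must exceed the water molar volume")
        if self.N_Ge <= 0:
            raise ValueError("cosolvent electron count must be positive")

    @property
    def b_G(self) -> float:
        """Cosolvent X-ray scattering length [cm]."""
        return CONST.r_e * self.N_Ge

    def molar_volume(self, T: float) -> float:
        """ν_Gb(T) = ν_Gb°·exp(α_G(T−T°)) [L mol^-1]."""
        return expanded_molar_volume(self.nu_Gb0, self.alpha_G, T)


@dataclass
class SampleComposition:
    """Nominal composition of one sample condition.

    Built from the experimentally controlled quantities: protein w/v
    concentration ``c0`` [g L^-1] at T°, monomer molecular weight ``M1``
    [g mol^-1], cosolvent molarity ``C_G0`` [M] at T°, pH and temperature
    ``T`` [K].  The nominal molar fractions X_P (protein monomers) and
    x_G (cosolvent fraction of the solvent) are temperature independent
    and derived once at T°.

    ``nu_P0`` is the protein molar volume at T° [L mol^-1]; by default
    0.73 mL/g of partial specific volume.  ``alpha_P`` is the protein
    thermal expansivity (default 0).
    """

    c0: float
    M1: float
    C_G0: float
    pH: float
    T: float
    nu_P0: float | None = None
    alpha_P: float = 0.0
    nu_G0: float = 0.2
    X_P: float = field(init=False)
    x_G: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.C_G0 < 0 or self.M1 <= 0 or self.T <= 0:
            raise ValueError("invalid sample composition")
        if self.nu_P0 is None:
            self.nu_P0 = 0.73e-3 * self.M1  # L/mol from 0.73 mL/g
        n_P = self.c0 / self.M1  # mol protein monomers per liter at T0
        solvent_volume = 1.0 - n_P * self.nu_P0 - self.C_G0 * self.nu_G0
        if solvent_volume <= 0:
            raise ValueError("infeasible composition: no room left for water")
        n_W = solvent_volume / CONST.nu_Wb0
        n_G = self.C_G0
        total = n_P + n_G + n_W
        self.X_P = n_P / total
        self.x_G = n_G / (n_G + n_W) if n_G > 0 else 0.0

    def nu_P(self, T: float) -> float:
        return expanded_molar_volume(self.nu_P0, self.alpha_P, T)

    @property
    def C_P0(self) -> float:
        """Nominal monomer molarity at T° [M]."""
        return self.c0 / self.M1

    @property
    def x_W(self) -> float:
        return 1.0 - self.x_G
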