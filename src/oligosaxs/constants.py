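"""Physical constants and reference values used throughout the package.

All quantities are SI unless noted.  The SAXS-specific conventions follow
the package-wide unit system: lengths in Å at interfaces, scattering
lengths in cm, scattering length densities (SLD) in cm^-2, molar volumes
in L mol^-1, energies in J mol^-1 internally (kJ mol^-1 at interfaces),
concentrations in mol L^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable container of the physical constants of the model.

    Attributes
    ----------
    N_A : Avogadro number [mol^-1].
    k_B : Boltzmann constant [J K^-1].
    R : molar gas constant [J mol^-1 K^-1].
    q_e : proton charge [C].
    eps0 : vacuum permittivity [C^2 J^-1 m^-1].
    r_e : classical electron radius [cm].
    T0 : reference temperature [K].
    nu_Wb0 : molar volume of bulk water at ``T0`` [L mol^-1].
    alpha_W : water thermal expansivity at ``T0`` [K^-1].
    beta_W : first derivative of the water expansivity [K^-2].
    N_We : number of electrons of a water molecule.
    """

    N_A: float = 6.02214076e23
    k_B: float = 1.380649e-23
    R: float = 8.31446261815324
    q_e: float = 1.6e-19
    eps0: float = 8.8541878128e-12
    r_e: float = 0.28e-12
    T0: float = 298.15
    nu_Wb0: float = 0.018
    alpha_W: float = 2.5e-4
    beta_W: float = 9.8e-6
    N_We: int = 10

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name} must be strictly positive")

    @property
    def b_W(self) -> float:
        """X-ray scattering length of one water molecule [cm]."""
        return self.r_e * self.N_We

    @property
    def water_site_volume_A3(self) -> float:
        """Volume of one water molecule at ``T0`` [Å^3]."""
        # 1 L = 1e27 Å^3
        return self.nu_Wb0 * 1e27 / self.N_A


#: Module-level read-only constants instance.
CONST = PhysicalConstants()
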