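"""Hydration-shell site construction and local-domain scattering densities.

The protein is buried in a close-packed lattice of dummy solvent spheres
whose individual volume equals one water molecule (≈29.9 Å³, sphere
radius ≈1.93 Å).  Lattice points overlapping the van der Waals envelope
are discarded; the survivors are binned into shells of 2.8 Å thickness
by their distance to the nearest atom surface.  Two shells are kept by
default.

Preferential solvation changes the composition of the "local domain"
(first plus second shell): a bound cosolvent molecule is larger than the
water site it replaces, so its excess volume spills into the second
shell, displacing k_j of the m_j2 sites there; the remainder fills with
bulk solvent.  The local-domain composition then fixes a single
scattering length density ρ_ld,j assigned uniformly to every shell site
of state j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import CONST

__all__ = [
    "VDW_RADII",
    "HydrationShellModel",
    "LocalDomain",
    "build_shells",
    "local_domain",
    "released_waters",
    "sld_bulk",
    "sld_local",
]


def released_waters(reactant_sites, product_sites) -> float:
    """First-shell waters released to the bulk by a formation process.

    For a reaction Σ reactants → Σ products between protein states, the
    released count is Σ m(reactants) − Σ m(products): e.g. dimerization
    of two monomers with m1 first-shell sites into a dimer with m2 sites
    frees 2·m1 − m2 waters (per dimer; half that per monomer).  Positive
    values drive the formation entropy up.
    """
    return float(sum(reactant_sites) - sum(product_sites))

#: van der Waals radii [Å] (Bondi) for the united-atom surface definition.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "MN": 2.05,
    "CU": 1.40,
    "X": 1.70,  # pseudo-atoms of toy structures
}


@dataclass
class HydrationShellModel:
    """Dummy-sphere hydration sites around one structure.

    ``positions`` are site centers [Å]; ``shell_index`` ∈ {1, 2};
    ``m`` / ``m2`` are the first/second-shell counts; ``site_volume`` is
    the per-site volume [Å^3] (one water molecule) and ``site_radius``
    the equivalent sphere radius [Å].
    """

    positions: np.ndarray
    shell_index: np.ndarray
    thickness: float
    site_volume: float

    def __post_init__(self) -> None:
        if self.m == 0:
            raise ValueError("empty first hydration shell")

    @property
    def m(self) -> int:
        return int(np.sum(self.shell_index == 1))

    @property
    def m2(self) -> int:
        return int(np.sum(self.shell_index == 2))

    @property
    def site_radius(self) -> float:
        return (3.0 * self.site_volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def _fcc_lattice(lo: np.ndarray, hi: np.ndarray, site_volume: float,
                 offset: np.ndarray | None = None) -> np.ndarray:
    """Close-packed (fcc) lattice points filling the box [lo, hi].

    The conventional cubic cell holds 4 sites, so its edge is
    (4·site_volume)^{1/3}; nearest-neighbour spacing is edge/√2.
    """
    edge = (4.0 * site_volume) ** (1.0 / 3.0)
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    ) * edge
    if offset is None:
        offset = np.zeros(3)
    n = np.ceil((hi - lo) / edge).astype(int) + 1
    ii, jj, kk = np.meshgrid(
        np.arange(n[0]), np.arange(n[1]), np.arange(n[2]), indexing="ij"
    )
    cells = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * edge + lo + offset * edge
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    keep = np.all((pts >= lo - edge) & (pts <= hi + edge), axis=1)
    return pts[keep]


def build_shells(
    coords: np.ndarray,
    elements: list[str] | np.ndarray,
    n_shells: int = 2,
    thickness: float = 2.8,
    offset: np.ndarray | None = None,
) -> HydrationShellModel:
    """Build hydration-shell dummy-sphere sites around an atomic structure.

    Parameters
    ----------
    coords : (N, 3) atomic coordinates [Å].
    elements : element symbols (key into :data:`VDW_RADII`).
    n_shells : number of shells (default 2).
    thickness : shell thickness [Å] (default 2.8).
    offset : optional fractional lattice offset in [0,1)^3, used to probe
        lattice-registration jitter.

    A lattice point with distance s to the nearest atom *surface* belongs
    to shell ⌈s/thickness⌉ if 0 < s ≤ n_shells·thickness.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one atom")
    radii = np.array([VDW_RADII.get(str(e).upper(), VDW_RADII["X"]) for e in elements])
    if len(radii) != len(coords):
        raise ValueError("elements and coords length mismatch")

    v_site = CONST.water_site_volume_A3
    margin = n_shells * thickness + radii.max() + 2.0
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    pts = _fcc_lattice(lo, hi, v_site, offset=offset)

    tree = cKDTree(coords)
    k = min(len(coords), 24)
    dist, idx = tree.query(pts, k=k, workers=-1)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    surf = dist - radii[idx]
    s = surf.min(axis=1)

    inside = s > 0
    within = s <= n_shells * thickness
    keep = inside & within
    shell = np.ceil(s[keep] / thickness).astype(int)
    model = HydrationShellModel(
        positions=pts[keep],
        shell_index=shell,
        thickness=thickness,
        site_volume=v_site,
    )
    return model


@dataclass
class LocalDomain:
    """Composition of the first+second shell region of one state."""

    k: float
    N_W1: float
    N_G1: float
    N_W2: float
    N_G2: float
    x_Gld: float
    nu_Wld: float
    nu_Gld: float

    def __post_init__(self) -> None:
        if min(self.N_W1, self.N_G1, self.N_W2, self.N_G2) < 0:
            raise ValueError("occupancies must be non-negative")
        if not 0.0 <= self.x_Gld <= 1.0:
            raise ValueError("local-domain cosolvent fraction must lie in [0, 1]")


def local_domain(
    m: float,
    m2: float,
    phi: float,
    x_Gb: float,
    nu_Wsj: float,
    nu_Gsj: float,
    nu_Wb: float,
    nu_Gb: float,
) -> LocalDomain:
    """Local-domain occupancies and molar volumes of one state.

    First shell: N_W1 = m·φ waters, N_G1 = m(1−φ) cosolvents.  Each bound
    cosolvent overflows into the second shell, displacing

        k = m (1−φ)(ν_Gs − ν_Ws)/ν_Wb

    of the m2 sites there; the remaining m2−k fill with bulk solvent of
    composition x_Gb (volume-weighted partition between water and the
    larger cosolvent molecule).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if not 0.0 <= x_Gb < 1.0:
        raise ValueError("x_Gb must lie in [0, 1)")
    if nu_Gsj < nu_Wsj:
        raise ValueError("cosolvent site volume must be >= water site volume")
    k = m * (1.0 - phi) * (nu_Gsj - nu_Wsj) / nu_Wb
    if k > m2:
        warnings.warn("second-shell overflow: k > m2; clamping", stacklevel=2)
        k = m2
    N_W1 = m * phi
    N_G1 = m * (1.0 - phi)
    avail = m2 - k
    denom = 1.0 + x_Gb * (nu_Gb / nu_Wb - 1.0)
    N_W2 = avail * (1.0 - x_Gb) / denom
    N_G2 = avail * x_Gb / denom
    total = N_W1 + N_W2 + N_G1 + N_G2
    x_Gld = (N_G1 + N_G2) / total if total > 0 else 0.0
    nu_Wld = (
        (N_W1 * nu_Wsj + N_W2 * nu_Wb) / (N_W1 + N_W2) if N_W1 + N_W2 > 0 else nu_Wb
    )
    nu_Gld = (
        (N_G1 * nu_Gsj + N_G2 * nu_Gb) / (N_G1 + N_G2) if N_G1 + N_G2 > 0 else nu_Gb
    )
    return LocalDomain(
        k=k,
        N_W1=N_W1,
        N_G1=N_G1,
        N_W2=N_W2,
        N_G2=N_G2,
        x_Gld=x_Gld,
        nu_Wld=nu_Wld,
        nu_Gld=nu_Gld,
    )


def _molar_to_molecular_cm3(nu: float) -> float:
    """Molar volume [L mol^-1] -> per-molecule volume [cm^3]."""
    return nu * 1e3 / CONST.N_A


def sld_bulk(x_Gb: float, nu_Wb: float, nu_Gb: float, b_W: float, b_G: float) -> float:
    """Bulk binary-solvent SLD ρ_0 [cm^-2].

    ρ_0 = [x_Gb·b_G + (1−x_Gb)·b_W] / [x_Gb·ν_Gb + (1−x_Gb)·ν_Wb]
    with per-molecule volumes; ≈9.37·10¹⁰ cm^-2 for pure water at 25 °C.
    """
    num = x_Gb * b_G + (1.0 - x_Gb) * b_W
    den = x_Gb * _molar_to_molecular_cm3(nu_Gb) + (1.0 - x_Gb) * _molar_to_molecular_cm3(
        nu_Wb
    )
    return num / den


def sld_local(domain: LocalDomain, b_W: float, b_G: float) -> float:
    """Local-domain SLD ρ_ld,j [cm^-2], assigned uniformly to all sites."""
    x = domain.x_Gld
    num = x * b_G + (1.0 - x) * b_W
    den = x * _molar_to_molecular_cm3(domain.nu_Gld) + (1.0 - x) * _molar_to_molecular_cm3(
        domain.nu_Wld
    )
    return num / den
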