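"""Readers and writers: PDB structures, 3-column SAXS curves, manifests,
configuration files and tabular reports."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .curves import ScatteringCurve
from .formfactor import ATOMIC_VOLUMES, ELEMENT_ELECTRONS, Structure

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_curve",
    "write_curve",
    "read_manifest",
    "write_manifest",
    "load_config",
]


def read_pdb(
    path: str | Path,
    chains: Sequence[str] | None = None,
    keep_hetero: bool = False,
    keep_waters: bool = False,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only altLoc '' or 'A' atoms are kept; waters and hetero residues are
    stripped by default; occupancy-weighted scattering lengths are used
    for partial-occupancy atoms.  ``chains`` restricts to the named
    chain ids (e.g. ``["A", "B"]`` for an insulin monomer out of the
    hexamer file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    coords, elements, occ = [], [], []
    wanted = {c.upper() for c in chains} if chains else None
    for chain in model:
        if wanted is not None and chain.id.upper() not in wanted:
            continue
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag == "W" and not keep_waters:
                continue
            if hetflag.startswith("H_") and not keep_hetero:
                continue
            for atom in residue:
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                el = (atom.element or "").strip().upper()
                if not el:
                    raise ValueError(
                        f"{path.name}: atom {atom.get_full_id()} has no element"
                    )
                if el == "H":  # united-atom treatment
                    continue
                if el not in ELEMENT_ELECTRONS:
                    raise ValueError(f"{path.name}: unknown element {el!r}")
                coords.append(atom.coord)
                elements.append(el)
                occ.append(atom.get_occupancy() or 1.0)
    if not coords:
        raise ValueError(f"{path.name}: no atoms selected")
    return Structure.from_elements(
        np.asarray(coords, float), elements, np.asarray(occ, float), label=path.stem
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a (toy) structure as minimal ATOM records."""
    with open(path, "w") as fh:
        for i, (xyz, el) in enumerate(zip(structure.coords, structure.elements), 1):
            el_out = str(el)[:2].upper()
            if el_out == "X":
                el_out = "C"
            name = f"{el_out:<3}"
            fh.write(
                f"ATOM  {i:5d}  {name}"          # serial, name (cols 13-16)
                f" DUM A{min(i, 9999):4d}    "    # altLoc, resName, chain, resSeq
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {el_out:>2}\n"
            )
        fh.write("END\n")


def read_curve(
    path: str | Path,
    c0: float = 0.0,
    T: float = 298.15,
    G: str | None = None,
    C_G0: float = 0.0,
    q_unit: str = "A",
) -> ScatteringCurve:
    """Read a 3-column ASCII SAXS curve (q, dΣ/dΩ, σ); '#' comments skipped.

    ``q_unit="nm"`` converts from nm^-1 to Å^-1.
    """
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(
                f"{path.name}:{ln}: expected 3 columns (q, I, sigma), got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts[:3]])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{ln}: non-numeric row") from exc
    if len(rows) < 20:
        raise ValueError(f"{path.name}: fewer than 20 data points")
    arr = np.asarray(rows, float)
    q, I, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    if q_unit == "nm":
        q = q / 10.0
    order = np.argsort(q)
    if not np.array_equal(order, np.arange(len(q))):
        warnings.warn(f"{path.name}: q not ascending; sorting")
        q, I, sig = q[order], I[order], sig[order]
    return ScatteringCurve(q=q, I=I, sigma=sig, c0=c0, T=T, G=G, C_G0=C_G0,
                           label=path.stem)


def write_curve(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    """Write a curve as 3-column ASCII with a '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# q [1/A]  dSigma/dOmega [1/cm]  sigma [1/cm]\n")
        if header:
            fh.write(f"# {header}\n")
        fh.write(
            f"# c0={curve.c0:g} g/L  T={curve.T:g} K  G={curve.G or '-'} "
            f"C_G0={curve.C_G0:g} M\n"
        )
        for qi, Ii, si in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{qi:.8e} {Ii:.8e} {si:.8e}\n")


def write_manifest(curves: Sequence[ScatteringCurve], paths: Sequence[str],
                   out: str | Path) -> None:
    """Write a batch manifest mapping curve files to their labels (TSV)."""
    df = pd.DataFrame(
        {
            "file": paths,
            "c0": [c.c0 for c in curves],
            "T": [c.T for c in curves],
            "G": [c.G or "-" for c in curves],
            "C_G0": [c.C_G0 for c in curves],
        }
    )
    df.to_csv(out, sep="\t", index=False)


def read_manifest(path: str | Path, q_unit: str = "A") -> list[ScatteringCurve]:
    """Read a manifest and load every referenced curve (paths relative to
    the manifest's directory)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"file", "c0", "T", "G", "C_G0"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if df["file"].duplicated().any():
        raise ValueError("duplicate curve files in manifest")
    curves = []
    for _, row in df.iterrows():
        g = None if str(row["G"]) in ("-", "nan", "") else str(row["G"])
        curves.append(
            read_curve(
                path.parent / str(row["file"]),
                c0=float(row["c0"]), T=float(row["T"]), G=g,
                C_G0=float(row["C_G0"]), q_unit=q_unit,
            )
        )
    return curves


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration (states / cosolvents / transitions /
    exchanges / fit sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
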