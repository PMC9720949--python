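"""Structure-derived hydrodynamic descriptors via a convex-hull model.

The procedure follows the convex-hull school of hydrodynamic modelling:
the smallest convex envelope of the heavy atoms stands in for the
hydrodynamic volume of the molecule, and classical solution relations
(Stokes-Einstein, Svedberg) convert the hull-equivalent radius into
translational/rotational transport coefficients.  The 13-factor panel:

    vbar (mL/g), Ro (A), Rg (A), Dmax (A), axial_ratio, f/f0,
    Dt (cm^2/s), Rtrans (A), s (sec), Dr (1/s), Rrot (A), tauC (ns),
    asphericity

All physical constants and hydration factors are configurable and recorded
with the panel; agreement with any particular external tool's constants is
not asserted -- the contracts are geometric and algebraic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.constants import Avogadro, Boltzmann
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}
DEFAULT_ATOM_MASS = 12.011

# Average residue masses (Da, water subtracted), 1-letter codes.
RESIDUE_MASSES_1: dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}

# Cohn-Edsall-style partial specific volumes (mL/g), 1-letter codes.
VBAR_TABLE: dict[str, float] = {
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63,
    "E": 0.66, "Q": 0.67, "G": 0.64, "H": 0.67, "I": 0.90,
    "L": 0.90, "K": 0.82, "M": 0.75, "F": 0.77, "P": 0.76,
    "S": 0.63, "T": 0.70, "V": 0.86, "W": 0.74, "Y": 0.71,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Point-mass representation of a structure (coordinates in Angstrom,
    masses in Dalton)."""

    coords: np.ndarray  # (n, 3)
    masses: np.ndarray  # (n,)
    elements: list[str]
    residues: list[str]  # 1-letter codes (or raw names for hetero groups)
    chains: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def residue_composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for aa in self.residues:
            comp[aa] = comp.get(aa, 0) + 1
        return comp


@dataclass(frozen=True)
class HydroConstants:
    """Solution conditions and hydration factors for the panel."""

    temperature: float = 293.15        # K
    viscosity: float = 1.002e-3        # Pa s (water at 293 K)
    solvent_density: float = 0.998     # g/mL
    hydration_expansion_trans: float = 1.10  # Rtrans / hull radius
    hydration_expansion_rot: float = 1.16    # Rrot / hull radius

    def to_dict(self) -> dict[str, float]:
        return {
            "temperature": self.temperature,
            "viscosity": self.viscosity,
            "solvent_density": self.solvent_density,
            "hydration_expansion_trans": self.hydration_expansion_trans,
            "hydration_expansion_rot": self.hydration_expansion_rot,
        }


@dataclass
class HydrodynamicProperties:
    vbar: float          # mL/g
    Ro: float            # A
    Rg: float            # A
    Dmax: float          # A
    axial_ratio: float
    f_f0: float
    Dt: float            # cm^2/s
    Rtrans: float        # A
    s: float             # sec
    Dr: float            # 1/s
    Rrot: float          # A
    tauC: float          # ns
    asphericity: float
    degenerate: bool = False
    constants: HydroConstants = field(default_factory=HydroConstants)

    def to_dict(self) -> dict[str, float]:
        return {
            "vbar": self.vbar, "Ro": self.Ro, "Rg": self.Rg,
            "Dmax": self.Dmax, "axial_ratio": self.axial_ratio,
            "f_f0": self.f_f0, "Dt": self.Dt, "Rtrans": self.Rtrans,
            "s": self.s, "Dr": self.Dr, "Rrot": self.Rrot,
            "tauC": self.tauC, "asphericity": self.asphericity,
        }


def read_pdb(path: str | Path, drop_hydrogens: bool = True) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a point-mass model.

    Highest-occupancy alternate locations are kept; hydrogens are dropped
    by default; unknown elements get a carbon mass with a warning.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise IOError(f"unreadable or empty PDB file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    coords, masses, elements, residues, chains = [], [], [], [], []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            one = _THREE_TO_ONE.get(resname, resname)
            for atom in residue.get_list():
                if atom.is_disordered():
                    atom = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0),
                    )[-1]
                element = (atom.element or "").strip().upper()
                if drop_hydrogens and element in ("H", "D"):
                    continue
                if element not in ATOMIC_MASSES:
                    warnings.warn(
                        f"unknown element {element!r}; using default mass"
                    )
                    mass = DEFAULT_ATOM_MASS
                else:
                    mass = ATOMIC_MASSES[element]
                coords.append(atom.get_coord())
                masses.append(mass)
                elements.append(element)
                residues.append(one)
                chains.append(chain.id)
    if not coords:
        raise IOError(f"no atoms parsed from {path}")
    return StructureModel(
        coords=np.array(coords, dtype=float),
        masses=np.array(masses),
        elements=elements,
        residues=residues,
        chains=chains,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Minimal single-model PDB writer (pseudo-atom friendly)."""
    with open(path, "w") as fh:
        for i in range(model.n_atoms):
            x, y, z = model.coords[i]
            element = model.elements[i][:2].rjust(2)
            resname = model.residues[i]
            resname3 = {v: k for k, v in _THREE_TO_ONE.items()}.get(
                resname, resname
            )[:3]
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {resname3:<3s} {model.chains[i][:1]}"
                f"{(i % 9999) + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {element}\n"
            )
        fh.write("END\n")


def _gyration_tensor(
    coords: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    if weights is None:
        weights = np.ones(len(coords))
    w = weights / weights.sum()
    center = (coords * w[:, None]).sum(axis=0)
    d = coords - center
    return (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)


def radius_of_gyration(
    model: StructureModel, mass_weighted: bool = True
) -> float:
    """Root-mean-square (mass-weighted by default) distance from the
    centroid, in Angstrom."""
    weights = model.masses if mass_weighted else None
    tensor = _gyration_tensor(model.coords, weights)
    return float(math.sqrt(max(np.trace(tensor), 0.0)))


def asphericity(model: StructureModel, mass_weighted: bool = True) -> float:
    """Gyration-tensor shape anisotropy in [0, 1]: 0 for isotropic clouds,
    1 for collinear ones."""
    weights = model.masses if mass_weighted else None
    tensor = _gyration_tensor(model.coords, weights)
    lam = np.linalg.eigvalsh(tensor)
    total = lam.sum()
    if total <= 0:
        return 0.0
    pair = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    return float(1.0 - 3.0 * pair / total**2)


def convex_hull_metrics(
    model: StructureModel,
) -> tuple[float, float, float, bool]:
    """(hull volume A^3, Dmax A, axial ratio, degenerate flag).

    Dmax is the largest pairwise distance among hull vertices (all points
    for degenerate clouds).  The axial ratio compares the largest and
    smallest principal semi-axes of the gyration-equivalent ellipsoid.
    """
    coords = model.coords
    degenerate = False
    try:
        if len(coords) < 4:
            raise QhullError("fewer than 4 points")
        hull = ConvexHull(coords)
        volume = float(hull.volume)
        vertices = coords[hull.vertices]
    except QhullError:
        degenerate = True
        volume = 0.0
        vertices = coords
    dmax = float(pdist(vertices).max()) if len(vertices) > 1 else 0.0
    lam = np.linalg.eigvalsh(_gyration_tensor(coords, model.masses))
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        axial = math.inf
        degenerate = True
    else:
        axial = float(math.sqrt(lam[2] / lam[0]))
    return volume, dmax, axial, degenerate


def _vbar(model: StructureModel) -> float:
    """Composition-weighted partial specific volume (mL/g)."""
    comp = model.residue_composition()
    known = {aa: n for aa, n in comp.items() if aa in VBAR_TABLE}
    if not known:
        warnings.warn("no standard residues; using mean vbar")
        return float(np.mean(list(VBAR_TABLE.values())))
    if len(known) < len(comp):
        warnings.warn("unknown residues in vbar computation; using mean value")
    mean_vbar = float(np.mean(list(VBAR_TABLE.values())))
    num = 0.0
    den = 0.0
    for aa, n in comp.items():
        mass = RESIDUE_MASSES_1.get(aa, 110.0)
        v = VBAR_TABLE.get(aa, mean_vbar)
        num += n * mass * v
        den += n * mass
    return num / den


def hydrodynamic_panel(
    model: StructureModel,
    constants: HydroConstants = HydroConstants(),
    vbar_table: Mapping[str, float] | None = None,
) -> HydrodynamicProperties:
    """Compute the 13-factor hydrodynamic panel for one structure."""
    if vbar_table is not None:
        comp = model.residue_composition()
        num = sum(
            n * RESIDUE_MASSES_1.get(aa, 110.0) * vbar_table.get(aa, 0.73)
            for aa, n in comp.items()
        )
        den = sum(n * RESIDUE_MASSES_1.get(aa, 110.0) for aa, n in comp.items())
        vbar = num / den
    else:
        vbar = _vbar(model)

    mass = model.total_mass  # Da == g/mol
    # anhydrous volume in A^3: (g/mol * mL/g) -> mL/mol -> cm^3 -> A^3
    v_anh = mass * vbar / Avogadro * 1e24
    ro = (3.0 * v_anh / (4.0 * math.pi)) ** (1.0 / 3.0)

    rg = radius_of_gyration(model)
    volume, dmax, axial, degenerate = convex_hull_metrics(model)
    if volume > 0:
        r_hull = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    else:
        r_hull = ro  # degenerate clouds fall back to the anhydrous sphere
    r_trans = constants.hydration_expansion_trans * r_hull
    r_rot = constants.hydration_expansion_rot * r_hull
    f_f0 = max(r_trans / ro, 1.0)

    kT = Boltzmann * constants.temperature
    eta = constants.viscosity
    r_trans_m = r_trans * 1e-10
    r_rot_m = r_rot * 1e-10
    dt = kT / (6.0 * math.pi * eta * r_trans_m) * 1e4  # cm^2/s
    friction = 6.0 * math.pi * eta * r_trans_m  # kg/s
    buoyancy = 1.0 - vbar * constants.solvent_density
    s = (mass / 1000.0 / Avogadro) * buoyancy / friction  # sec
    dr = kT / (8.0 * math.pi * eta * r_rot_m**3)  # 1/s
    tau_c = 1.0 / (6.0 * dr) * 1e9  # ns

    return HydrodynamicProperties(
        vbar=vbar,
        Ro=ro,
        Rg=rg,
        Dmax=dmax,
        axial_ratio=axial,
        f_f0=f_f0,
        Dt=dt,
        Rtrans=r_trans,
        s=s,
        Dr=dr,
        Rrot=r_rot,
        tauC=tau_c,
        asphericity=asphericity(model),
        degenerate=degenerate,
        constants=constants,
    )


def sasa_descriptors(path: str | Path) -> dict[str, float]:
    """Optional Shrake-Rupley solvent-accessible-surface descriptors of a
    PDB structure (not part of the 46-feature panel).

    Returns the hydrophobic-atom SASA summed over all apolar residues and
    over exposed apolar residues (residue SASA > 20 A^2).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    ShrakeRupley().compute(model, level="R")
    apolar = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
    all_h = 0.0
    exposed_h = 0.0
    for chain in model:
        for residue in chain:
            if residue.get_resname() not in apolar:
                continue
            area = float(residue.sasa)
            all_h += area
            if area > 20.0:
                exposed_h += area
    return {"all_hydrophobic_sasa": all_h, "exposed_hydrophobic_sasa": exposed_h}
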