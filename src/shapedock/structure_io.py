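"""Small-molecule 3D structure I/O.

Reads and writes MOL2 (TRIPOS), PDB (ATOM/HETATM), SDF (V2000) and XYZ files
and normalizes everything into the internal :class:`Molecule`. Coordinates are
taken exactly as found in the file — no re-centering, no optimization — and
hydrogens are retained when present, since every downstream shape quantity
(volume, surface, moments) depends on the atom set as given.

SDF goes through RDKit (sanitization off, so geometry-only records survive);
the remaining formats are parsed directly because the dialect rules this
package needs (altLoc filtering, element inference, strict atom-order
preservation, MOL2 writing) are not all available upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .elements import BONDI, VdwRadiusTable, _normalize_symbol
from .errors import (
    ElementResolutionError,
    EmptyStructureError,
    FormatError,
)

RDLogger.DisableLog("rdApp.*")

FORMATS = ("sdf", "xyz", "pdb", "mol2")

_EXT_TO_FORMAT = {
    ".sdf": "sdf",
    ".sd": "sdf",
    ".mol": "sdf",
    ".xyz": "xyz",
    ".pdb": "pdb",
    ".ent": "pdb",
    ".mol2": "mol2",
}

# Two-letter elements that legitimately appear in PDB atom names; used only
# when the element columns (77-78) are blank.
_TWO_LETTER = {"Cl", "Br", "Si", "Se", "Zn", "Mg", "Na", "Ca", "Fe", "Mn", "Cu", "As", "Te"}


@dataclass(frozen=True)
class Molecule:
    """An element-labelled 3D atom set, the unit of all shape computation.

    Attributes
    ----------
    name : str
        Text label (file title or generated id).
    symbols : tuple of str
        Element symbol per atom, case-normalized, file order preserved.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian coordinates in Angstrom.
    bonds : tuple of (int, int, float), optional
        Bond list as (i, j, order); order 1.5 denotes aromatic, amide bonds
        are order 1. ``None`` when the source format carries no topology.
    source_format : str or None
        One of {"sdf", "xyz", "pdb", "mol2"} for file-derived molecules.
    """

    name: str
    symbols: tuple[str, ...]
    coords: np.ndarray
    bonds: tuple[tuple[int, int, float], ...] | None = None
    source_format: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(_normalize_symbol(s) for s in self.symbols))
        n = len(self.symbols)
        if n == 0:
            raise EmptyStructureError(f"molecule '{self.name}' has no atoms")
        if coords.shape != (n, 3):
            raise ValueError(f"coords shape {coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"molecule '{self.name}' has non-finite coordinates")
        if self.bonds is not None:
            bonds = tuple((int(i), int(j), float(o)) for i, j, o in self.bonds)
            for i, j, _ in bonds:
                if i == j or not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"invalid bond ({i}, {j}) in molecule '{self.name}'")
            object.__setattr__(self, "bonds", bonds)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for s in self.symbols if s != "H")

    def validate_elements(self, table: VdwRadiusTable = BONDI) -> None:
        for s in self.symbols:
            if s not in table:
                raise ElementResolutionError(
                    f"element '{s}' in molecule '{self.name}' not in radius table '{table.label}'"
                )

    def translated(self, shift) -> "Molecule":
        return Molecule(self.name, self.symbols, self.coords + np.asarray(shift, float),
                        self.bonds, self.source_format)

    def transformed(self, rotation, shift=(0.0, 0.0, 0.0)) -> "Molecule":
        """Apply a rigid motion x -> R x + t."""
        rot = np.asarray(rotation, float)
        return Molecule(self.name, self.symbols,
                        self.coords @ rot.T + np.asarray(shift, float),
                        self.bonds, self.source_format)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in FORMATS:
            raise FormatError(f"unsupported format '{fmt}' (supported: {FORMATS})")
        return f
    try:
        return _EXT_TO_FORMAT[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"cannot infer format from extension of '{path}'") from None


def read_molecule(path: str | Path, fmt: str | None = None,
                  radius_table: VdwRadiusTable = BONDI) -> Molecule:
    """Read one molecule from a structure file.

    Coordinates come through exactly as stored. Raises
    :class:`~shapedock.errors.EmptyStructureError` for zero-atom files and
    :class:`~shapedock.errors.ElementResolutionError` when a symbol is not
    covered by ``radius_table``.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    reader = {"sdf": _read_sdf, "xyz": _read_xyz, "pdb": _read_pdb, "mol2": _read_mol2}[f]
    mol = reader(path)
    mol.validate_elements(radius_table)
    return mol


def read_molecules(path: str | Path, fmt: str | None = None,
                   radius_table: VdwRadiusTable = BONDI) -> list[Molecule]:
    """Read all records of a multi-record SDF (other formats yield one)."""
    path = Path(path)
    f = _infer_format(path, fmt)
    if f != "sdf":
        return [read_molecule(path, f, radius_table)]
    mols = _read_sdf_all(path)
    for m in mols:
        m.validate_elements(radius_table)
    return mols


def write_molecule(molecule: Molecule, path: str | Path, fmt: str | None = None) -> None:
    """Write a molecule; the file re-reads to the same atoms within 1e-4 A."""
    path = Path(path)
    f = _infer_format(path, fmt)
    writer = {"sdf": _write_sdf, "xyz": _write_xyz, "pdb": _write_pdb, "mol2": _write_mol2}[f]
    path.parent.mkdir(parents=True, exist_ok=True)
    writer(molecule, path)


# ---------------------------------------------------------------- XYZ

def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise EmptyStructureError(f"empty XYZ file: {path}")
    try:
        count = int(lines[0].split()[0])
        body = lines[2:2 + count]
    except (ValueError, IndexError):
        # headerless dialect: every line is "El x y z"
        count = None
        body = [ln for ln in lines if ln.strip()]
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"malformed XYZ record in {path}: {ln!r}")
        symbols.append(parts[0])
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not symbols:
        raise EmptyStructureError(f"no atoms parsed from {path}")
    if count is not None and len(symbols) != count:
        raise FormatError(f"XYZ header declares {count} atoms, found {len(symbols)} in {path}")
    name = lines[1].strip() if count is not None and len(lines) > 1 and lines[1].strip() else path.stem
    return Molecule(name, tuple(symbols), np.array(coords), None, "xyz")


def _write_xyz(mol: Molecule, path: Path) -> None:
    out = [str(mol.n_atoms), mol.name]
    for s, (x, y, z) in zip(mol.symbols, mol.coords):
        out.append(f"{s} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------- PDB

def _pdb_element(line: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem
    name = line[12:16]
    alpha = "".join(c for c in name if c.isalpha())
    if not alpha:
        raise FormatError(f"cannot infer element from PDB atom name {name!r}")
    cand = _normalize_symbol(alpha[:2])
    if cand in _TWO_LETTER:
        return cand
    return alpha[0]


def _read_pdb(path: Path) -> Molecule:
    symbols, coords = [], []
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        altloc = line[16] if len(line) > 16 else " "
        if altloc not in (" ", "A"):
            continue
        symbols.append(_pdb_element(line))
        coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not symbols:
        raise EmptyStructureError(f"no ATOM/HETATM records parsed from {path}")
    return Molecule(path.stem, tuple(symbols), np.array(coords), None, "pdb")


def _write_pdb(mol: Molecule, path: Path) -> None:
    out = [f"COMPND    {mol.name}"]
    counts: dict[str, int] = {}
    for i, (s, (x, y, z)) in enumerate(zip(mol.symbols, mol.coords), start=1):
        counts[s] = counts.get(s, 0) + 1
        name = f"{s}{counts[s]}"[:4]
        out.append(
            f"HETATM{i:>5} {name:<4} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {s:>2}"
        )
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------- MOL2

_MOL2_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0, "un": 1.0, "nc": 0.0}


def _read_mol2(path: Path) -> Molecule:
    name = path.stem
    section = None
    symbols: list[str] = []
    coords: list[list[float]] = []
    bonds: list[tuple[int, int, float]] = []
    mol_lines = 0
    for raw in path.read_text().splitlines():
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            mol_lines = 0
            continue
        if section == "MOLECULE":
            mol_lines += 1
            if mol_lines == 1 and line.strip():
                name = line.strip()
        elif section == "ATOM" and line.strip():
            parts = line.split()
            # id name x y z sybyl_type [...]
            symbols.append(parts[5].split(".")[0])
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
        elif section == "BOND" and line.strip():
            parts = line.split()
            order = _MOL2_ORDER.get(parts[3].lower(), 1.0)
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, order))
    if not symbols:
        raise EmptyStructureError(f"no TRIPOS ATOM records parsed from {path}")
    return Molecule(name, tuple(symbols), np.array(coords),
                    tuple(bonds) if bonds else None, "mol2")


def _mol2_bond_type(order: float) -> str:
    if order == 1.5:
        return "ar"
    return str(int(round(order)))


def _write_mol2(mol: Molecule, path: Path) -> None:
    bonds = mol.bonds or ()
    out = [
        "@<TRIPOS>MOLECULE",
        mol.name,
        f"{mol.n_atoms} {len(bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    counts: dict[str, int] = {}
    for i, (s, (x, y, z)) in enumerate(zip(mol.symbols, mol.coords), start=1):
        counts[s] = counts.get(s, 0) + 1
        out.append(f"{i:>7} {s}{counts[s]:<3} {x:>12.4f} {y:>12.4f} {z:>12.4f} {s:<5} 1 LIG 0.0000")
    if bonds:
        out.append("@<TRIPOS>BOND")
        for k, (i, j, order) in enumerate(bonds, start=1):
            out.append(f"{k:>6} {i + 1:>5} {j + 1:>5} {_mol2_bond_type(order):>4}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------- SDF (RDKit)

_RD_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_ORDER_RD = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
             3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}


def _mol_from_rdkit(rdmol: Chem.Mol, fallback_name: str) -> Molecule:
    if rdmol.GetNumAtoms() == 0:
        raise EmptyStructureError("SDF record has no atoms")
    conf = rdmol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    symbols = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RD_ORDER.get(b.GetBondType(), 1.0))
        for b in rdmol.GetBonds()
    )
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else fallback_name
    return Molecule(name, symbols, coords, bonds or None, "sdf")


def _read_sdf_all(path: Path) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = [_mol_from_rdkit(m, path.stem) for m in supplier if m is not None]
    if not mols:
        raise EmptyStructureError(f"no molecules parsed from {path}")
    return mols


def _read_sdf(path: Path) -> Molecule:
    return _read_sdf_all(path)[0]


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Build an (unsanitized) RDKit molecule carrying geometry and bonds."""
    rw = Chem.RWMol()
    for s in mol.symbols:
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    if mol.bonds:
        for i, j, order in mol.bonds:
            rw.AddBond(i, j, _ORDER_RD.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(mol.n_atoms)
    for idx, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
    out = rw.GetMol()
    out.AddConformer(conf)
    out.SetProp("_Name", mol.name)
    return out


def _write_sdf(mol: Molecule, path: Path) -> None:
    block = Chem.MolToMolBlock(to_rdkit(mol), kekulize=False)
    path.write_text(block + "$$$$\n")


def write_sdf_records(mols: list[Molecule], path: str | Path) -> None:
    """Write a multi-record SDF (one $$$$-terminated block per molecule)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    blocks = [Chem.MolToMolBlock(to_rdkit(m), kekulize=False) + "$$$$\n" for m in mols]
    path.write_text("".join(blocks))
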