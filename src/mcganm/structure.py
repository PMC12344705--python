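"""PDB structures: parsing, writing and heavy-atom/mass bookkeeping.

This module is the coordinate substrate for the whole package.  It wraps
biotite's fixed-column PDB reader/writer behind small, explicit domain types:

* :class:`AtomRecord` — one atom with element, mass, B-factor and flags.
* :class:`Structure`  — an ordered list of atoms grouped into residues
  (keyed by ``(chain_id, residue_number, insertion_code)``), with an optional
  ligand selection.

Hydrogens are parsed and retained but flagged, so every downstream network
computation can work on heavy atoms only.  Alternate locations are resolved
to the highest-occupancy conformation (ties broken by file order).  Masses
come from the standard atomic-weight table shipped with biotite; an element
that cannot be resolved to a mass raises before any model is built.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bstinfo
import biotite.structure.io.pdb as bstpdb

from .errors import (
    FieldOverflowError,
    LookupKeyError,
    PDBFormatError,
    SelectorError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "ResidueKey",
    "read_pdb",
    "write_pdb",
    "residue_heavy_atoms",
    "atomic_mass",
]

#: Residue identity: (chain_id, residue_number, insertion_code).
ResidueKey = tuple[str, int, str]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL", "TIP3"}
_HYDROGEN_ELEMENTS = {"H", "D", "T"}

#: Minimum heavy atoms for a complete standard amino-acid backbone (N, CA, C, O).
_MIN_BACKBONE_HEAVY = 4


def atomic_mass(element: str) -> float:
    """Standard atomic weight (amu) of ``element``; raises on unknown symbols."""
    try:
        mass = bstinfo.mass(element.capitalize(), is_residue=False)
    except KeyError:
        mass = None
    if mass is None or mass <= 0.0:
        raise LookupKeyError(f"no atomic mass for element {element!r}")
    return float(mass)


@dataclass(frozen=True, eq=False)
class AtomRecord:
    """One PDB atom with the annotations the network model needs."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float
    b_factor: float  # Å²
    mass: float  # amu
    is_hetero: bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.mass <= 0.0:
            raise ValueError(f"atom {self.serial}: non-positive mass")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered collection of atoms grouped into residues.

    ``residues`` preserves file order; atoms inside a residue preserve file
    order too.  ``ligand_indices`` indexes into ``atoms`` and marks the
    ligand of interest (never waters unless explicitly selected).
    """

    atoms: list[AtomRecord]
    ligand_indices: list[int] = field(default_factory=list)
    source: str | None = None

    def __post_init__(self) -> None:
        self._residue_atoms: dict[ResidueKey, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._residue_atoms.setdefault(atom.residue_key, []).append(i)

    # -- residue bookkeeping -------------------------------------------------

    @property
    def residues(self) -> list[ResidueKey]:
        """Residue keys in file order."""
        return list(self._residue_atoms)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        try:
            idx = self._residue_atoms[key]
        except KeyError:
            raise LookupKeyError(f"unknown residue {key!r}") from None
        return [self.atoms[i] for i in idx]

    def residue_atom_indices(self, key: ResidueKey) -> list[int]:
        try:
            return list(self._residue_atoms[key])
        except KeyError:
            raise LookupKeyError(f"unknown residue {key!r}") from None

    def residue_name(self, key: ResidueKey) -> str:
        return self.residue_atoms(key)[0].residue_name

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    # -- selections ----------------------------------------------------------

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.ligand_indices]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in atoms])

    def incomplete_residues(self) -> list[ResidueKey]:
        """Standard amino-acid residues with fewer than 4 heavy atoms."""
        bad = []
        for key in self.residues:
            atoms = self.residue_atoms(key)
            if atoms[0].is_hetero:
                continue
            if sum(a.is_heavy for a in atoms) < _MIN_BACKBONE_HEAVY:
                bad.append(key)
        return bad

    def chain_gaps(self) -> list[tuple[ResidueKey, ResidueKey]]:
        """Adjacent same-chain residue pairs with a numbering discontinuity.

        Reported, never repaired: externally completed models are accepted
        as-is, loop rebuilding is out of scope.
        """
        gaps = []
        protein = [k for k in self.residues
                   if not self.residue_atoms(k)[0].is_hetero]
        for prev, cur in zip(protein, protein[1:]):
            if prev[0] == cur[0] and cur[1] - prev[1] > 1:
                gaps.append((prev, cur))
        return gaps

    def with_coordinates(
        self, atom_indices: Sequence[int], new_coords: np.ndarray
    ) -> "Structure":
        """Copy of the structure with ``atoms[atom_indices]`` moved."""
        new_coords = np.asarray(new_coords, dtype=float)
        atoms = list(self.atoms)
        for i, pos in zip(atom_indices, new_coords):
            atoms[i] = replace(atoms[i], position=pos)
        return Structure(atoms, list(self.ligand_indices), self.source)


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def _match_selector(atom: AtomRecord, selector: str) -> bool:
    """Match ``chain:resname:resnum`` with ``*`` wildcards in any field."""
    parts = selector.split(":")
    if len(parts) != 3:
        raise SelectorError(
            f"selector {selector!r} must have the form chain:resname:resnum"
        )
    chain, resname, resnum = (p.strip() or "*" for p in parts)
    if not fnmatch.fnmatchcase(atom.chain_id, chain):
        return False
    if not fnmatch.fnmatchcase(atom.residue_name, resname):
        return False
    if resnum != "*" and str(atom.residue_number) != resnum:
        return False
    return True


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _prescan(path: Path) -> None:
    """Validate the fixed-column numeric fields so parse failures carry a
    line number (the backend reports none)."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"line {lineno}: truncated ATOM/HETATM record"
                )
            for lo, hi, what in (
                (30, 38, "x"), (38, 46, "y"), (46, 54, "z"),
                (22, 26, "residue number"),
            ):
                text = line[lo:hi].strip()
                try:
                    float(text) if hi > 26 else int(text)
                except ValueError:
                    raise PDBFormatError(
                        f"line {lineno}: unparseable {what} field {text!r}"
                    ) from None


def read_pdb(
    path: str | Path,
    ligand_selector: str | None = None,
    include_waters: bool = False,
) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB file with at least one ATOM record.
    ligand_selector
        Optional ``chain:resname:resnum`` pattern (``*`` wildcards) naming
        the ligand of interest among HETATM records.  Waters never match
        unless their residue name is given explicitly.
    include_waters
        Keep water records in the atom list (they are excluded by default;
        they are never network nodes either way).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan(path)

    pdb_file = bstpdb.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(
            model=1,
            altloc="occupancy",
            extra_fields=["atom_id", "b_factor", "occupancy"],
        )
    except Exception as exc:  # backend error without line context
        raise PDBFormatError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")

    elements = np.asarray(arr.element, dtype=object)
    blank = np.array([not str(e).strip() for e in elements])
    if blank.any():
        inferred = bst.infer_elements(arr.atom_name[blank])
        elements[blank] = inferred

    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        element = str(elements[i]).strip().capitalize()
        name = str(arr.atom_name[i])
        res_name = str(arr.res_name[i])
        if not include_waters and res_name in _WATER_NAMES:
            continue
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=name,
                element=element,
                chain_id=str(arr.chain_id[i]),
                residue_name=res_name,
                residue_number=int(arr.res_id[i]),
                insertion_code=str(arr.ins_code[i]),
                position=arr.coord[i],
                occupancy=float(arr.occupancy[i]),
                b_factor=float(arr.b_factor[i]),
                mass=atomic_mass(element),
                is_hetero=bool(arr.hetero[i]),
            )
        )

    structure = Structure(atoms, source=str(path))
    if ligand_selector is not None:
        waters_ok = _selector_names_water(ligand_selector)
        ligand = [
            i for i, a in enumerate(atoms)
            if a.is_hetero
            and (a.residue_name not in _WATER_NAMES or waters_ok)
            and _match_selector(a, ligand_selector)
        ]
        if not ligand:
            raise SelectorError(
                f"ligand selector {ligand_selector!r} matched no HETATM atom"
            )
        structure.ligand_indices = ligand
    incomplete = structure.incomplete_residues()
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residue(s) with fewer than 4 heavy atoms "
            f"(first: {incomplete[0]})",
            stacklevel=2,
        )
    return structure


def _selector_names_water(selector: str) -> bool:
    parts = selector.split(":")
    return len(parts) == 3 and parts[1].strip().upper() in _WATER_NAMES


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _needs_ter(prev: AtomRecord, cur: AtomRecord) -> bool:
    if prev.chain_id != cur.chain_id:
        return True
    if prev.is_hetero != cur.is_hetero:
        return True
    delta = cur.residue_number - prev.residue_number
    return delta > 1 or (delta < 0)


def write_pdb(
    structure: Structure,
    path: str | Path,
    b_column_override: Sequence[float] | None = None,
    occupancy_override: Sequence[float] | None = None,
    remarks: Iterable[str] = (),
    ter_at_discontinuities: bool = True,
) -> None:
    """Write ``structure`` as a fixed-column PDB file.

    ``b_column_override`` / ``occupancy_override`` replace the respective
    columns atom-by-atom (used e.g. to carry restraint force constants).
    TER records separate chains and, when ``ter_at_discontinuities``,
    sequence breaks inside a chain.  Round-tripping preserves atom order,
    names, residue numbering and coordinates to the 3-decimal PDB grid.
    """
    atoms = structure.atoms
    if not atoms:
        raise ValueError("cannot write an empty structure")
    coords = structure.coords()
    if np.abs(coords).max() >= 10000.0:
        raise FieldOverflowError(
            "coordinate magnitude >= 10000 Å does not fit the PDB column"
        )

    n = len(atoms)
    arr = bst.AtomArray(n)
    arr.coord = coords
    arr.set_annotation("chain_id", np.array([a.chain_id for a in atoms]))
    arr.set_annotation("res_id", np.array([a.residue_number for a in atoms]))
    arr.set_annotation("ins_code", np.array([a.insertion_code for a in atoms]))
    arr.set_annotation("res_name", np.array([a.residue_name for a in atoms]))
    arr.set_annotation("atom_name", np.array([a.name for a in atoms]))
    arr.set_annotation("element", np.array([a.element.upper() for a in atoms]))
    arr.set_annotation("hetero", np.array([a.is_hetero for a in atoms]))
    arr.set_annotation("atom_id", np.array([a.serial for a in atoms]))
    bvals = (np.asarray(b_column_override, dtype=float)
             if b_column_override is not None
             else np.array([a.b_factor for a in atoms]))
    occ = (np.asarray(occupancy_override, dtype=float)
           if occupancy_override is not None
           else np.array([a.occupancy for a in atoms]))
    if bvals.shape != (n,) or occ.shape != (n,):
        raise ValueError("override column length must match atom count")
    if np.abs(occ).max() >= 1000.0 or np.abs(bvals).max() >= 1000.0:
        raise FieldOverflowError(
            "occupancy/B value >= 1000 does not fit its 6-character column"
        )
    arr.set_annotation("b_factor", bvals)
    arr.set_annotation("occupancy", occ)

    pdb_file = bstpdb.PDBFile()
    pdb_file.set_structure(arr)
    lines = [ln for ln in pdb_file.lines
             if ln.startswith(("ATOM", "HETATM"))]

    out: list[str] = [f"REMARK   3 {r}" for r in remarks]
    for i, line in enumerate(lines):
        if i > 0 and ter_at_discontinuities and _needs_ter(atoms[i - 1], atoms[i]):
            out.append("TER")
        out.append(line)
    out.append("TER")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def residue_heavy_atoms(structure: Structure, residue_key: ResidueKey) -> list[AtomRecord]:
    """Heavy atoms of one residue, file order preserved."""
    return [a for a in structure.residue_atoms(residue_key) if a.is_heavy]
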