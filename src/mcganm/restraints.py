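"""Truncation of the HR region and zoned harmonic restraints.

For truncated-sphere simulations the HR region of each conformer is
extracted as a standalone structure, and every atom is assigned to a
concentric distance shell around the ligand (or an explicit point).  Each
shell carries a harmonic force constant; the innermost shell is always
unrestrained so docking-scale motions stay free while the outer shells keep
the truncated structure from disintegrating.

Built-in schemes (distances from the ligand, constants in kcal/mol·Å²):

* ``minimization`` — flexible within 15 Å, 50 beyond (energy-minimization
  rule).
* ``case1`` — 0 within 15 Å, 10 on 15–20 Å, 50 beyond 20 Å.
* ``case2`` — 0 within 10 Å, 25 on 10–15 Å, 35 on 15–20 Å, 50 beyond 20 Å.
* ``case3`` — 0 within 15 Å, 10 on 15–20 Å, 25 on 20–25 Å, 50 beyond 25 Å.

No scheme is a default: production choices differ between minimization and
MD stages, so callers (and the CLI) must name one explicitly.

Shell membership uses half-open intervals [low, high): an atom exactly on a
boundary belongs to the outer (stiffer) shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    FieldOverflowError,
    ReferenceError_,
    SelectionError,
    SpecError,
)
from .conformers import Conformer
from .network import MCGModel
from .structure import AtomRecord, Structure, write_pdb

__all__ = [
    "TruncationScheme",
    "RestraintAssignment",
    "SCHEMES",
    "truncate_structure",
    "shell_distance",
    "assign_restraints",
    "write_restraint_files",
]


@dataclass(frozen=True)
class TruncationScheme:
    """Ordered concentric shells: (outer radius Å, force constant)."""

    name: str
    shells: tuple[tuple[float, float], ...]
    reference: Literal["ligand", "point"] = "ligand"

    def __post_init__(self) -> None:
        if len(self.shells) < 2:
            raise SpecError("a scheme needs at least an inner and outer shell")
        radii = [r for r, _ in self.shells]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise SpecError("shell radii must be strictly increasing")
        if not math.isinf(radii[-1]):
            raise SpecError("the last shell must extend to infinity")
        constants = [k for _, k in self.shells]
        if any(k < 0 for k in constants):
            raise SpecError("force constants must be non-negative")
        if constants[0] != 0.0:
            raise SpecError("the inner shell must be flexible (k = 0)")

    @property
    def force_constants(self) -> tuple[float, ...]:
        return tuple(k for _, k in self.shells)

    def shell_of(self, distance: float) -> int:
        """Shell index by half-open [low, high); boundary → outer shell."""
        finite = [r for r, _ in self.shells[:-1]]
        # side='right': distance equal to an outer radius falls outward
        return int(np.searchsorted(finite, distance, side="right"))


SCHEMES: dict[str, TruncationScheme] = {
    "minimization": TruncationScheme(
        "minimization", ((15.0, 0.0), (math.inf, 50.0))),
    "case1": TruncationScheme(
        "case1", ((15.0, 0.0), (20.0, 10.0), (math.inf, 50.0))),
    "case2": TruncationScheme(
        "case2", ((10.0, 0.0), (15.0, 25.0), (20.0, 35.0), (math.inf, 50.0))),
    "case3": TruncationScheme(
        "case3", ((15.0, 0.0), (20.0, 10.0), (25.0, 25.0), (math.inf, 50.0))),
}


@dataclass
class RestraintAssignment:
    """Per-atom shell membership: (serial, distance Å, shell, k)."""

    per_atom: list[tuple[int, float, int, float]]
    scheme: TruncationScheme

    def shell_counts(self) -> list[int]:
        counts = [0] * len(self.scheme.shells)
        for _, _, shell, _ in self.per_atom:
            counts[shell] += 1
        return counts


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def truncate_structure(
    conformer: Conformer,
    model: MCGModel,
    structure: Structure,
    include_ligand: bool = False,
) -> Structure:
    """Extract the HR residues with the conformer's coordinates applied.

    Only heavy atoms survive (they are the atoms the model represents);
    chain and residue identifiers are preserved, and the PDB writer inserts
    TER records at sequence discontinuities of the truncated selection.
    """
    if not model.hr_residues:
        raise SelectionError("model has no HR residues to truncate")
    if conformer.coordinates.shape != (model.n_nodes, 3):
        raise ConsistencyError(
            f"conformer has {conformer.coordinates.shape[0]} nodes, "
            f"model has {model.n_nodes}"
        )
    atom_to_node: dict[int, int] = {}
    for node in model.nodes:
        if node.kind == "atom":
            atom_to_node[node.source_atoms[0]] = node.index

    keep: list[int] = []
    coords: list[np.ndarray] = []
    for i, atom in enumerate(structure.atoms):
        if atom.residue_key not in model.hr_residues or not atom.is_heavy:
            continue
        if i not in atom_to_node:
            raise ConsistencyError(
                f"HR heavy atom {atom.serial} has no node: conformer/model/"
                "structure mismatch"
            )
        keep.append(i)
        coords.append(conformer.coordinates[atom_to_node[i]])
    if include_ligand:
        for i in structure.ligand_indices:
            atom = structure.atoms[i]
            if atom.is_heavy and i not in keep:
                keep.append(i)
                coords.append(atom.position)
    moved = structure.with_coordinates(keep, np.stack(coords))
    new_index = {old: new for new, old in enumerate(keep)}
    atoms = [moved.atoms[i] for i in keep]
    ligand = [new_index[i] for i in structure.ligand_indices if i in new_index]
    return Structure(atoms, ligand)


# ---------------------------------------------------------------------------
# restraint assignment
# ---------------------------------------------------------------------------

def shell_distance(
    atom: AtomRecord | np.ndarray,
    reference: Structure | Sequence[AtomRecord] | np.ndarray,
) -> float:
    """Distance to the restraint reference.

    For a ligand reference (a Structure with ligand atoms, or a sequence of
    atoms) this is the minimum distance to any ligand heavy atom; for a
    point (a 3-vector) it is the plain Euclidean distance.
    """
    pos = atom.position if isinstance(atom, AtomRecord) else np.asarray(atom, float)
    if isinstance(reference, Structure):
        ref_atoms = [a for a in reference.ligand_atoms if a.is_heavy]
        if not ref_atoms:
            raise ReferenceError_("structure has no ligand heavy atoms")
        ref = np.stack([a.position for a in ref_atoms])
    elif isinstance(reference, np.ndarray) and reference.shape == (3,):
        ref = reference.reshape(1, 3)
    else:
        ref_atoms = [a for a in reference if isinstance(a, AtomRecord) and a.is_heavy]
        if ref_atoms:
            ref = np.stack([a.position for a in ref_atoms])
        else:
            ref = np.asarray(reference, dtype=float).reshape(-1, 3)
            if ref.size == 0:
                raise ReferenceError_("empty distance reference")
    return float(np.min(np.linalg.norm(ref - pos, axis=1)))


def assign_restraints(
    truncated: Structure,
    scheme: TruncationScheme,
    reference: Structure | Sequence[AtomRecord] | np.ndarray | None = None,
    per_residue: bool = False,
) -> RestraintAssignment:
    """Assign every truncated atom to a shell of ``scheme``.

    ``reference`` defaults to the truncated structure's own ligand atoms.
    With ``per_residue`` the zone of a whole residue follows its Cα
    distance (falling back to the first heavy atom when no Cα exists),
    mirroring residue-based zone wording; the default is per-atom.
    """
    if reference is None:
        reference = truncated
    per_atom: list[tuple[int, float, int, float]] = []
    if per_residue:
        for key in truncated.residues:
            atoms = truncated.residue_atoms(key)
            anchor = next((a for a in atoms if a.name == "CA"),
                          next((a for a in atoms if a.is_heavy), atoms[0]))
            d = shell_distance(anchor, reference)
            shell = scheme.shell_of(d)
            k = scheme.shells[shell][1]
            for a in atoms:
                per_atom.append((a.serial, d, shell, k))
    else:
        for a in truncated.atoms:
            d = shell_distance(a, reference)
            shell = scheme.shell_of(d)
            per_atom.append((a.serial, d, shell, scheme.shells[shell][1]))
    return RestraintAssignment(per_atom=per_atom, scheme=scheme)


def write_restraint_files(
    assignment: RestraintAssignment,
    truncated: Structure,
    dialect: Literal["constraint-pdb", "flat-tsv"],
    path: str | Path,
) -> None:
    """Emit the restraints in an MD-ready text dialect.

    ``constraint-pdb``: the truncated reference coordinates with the
    per-atom force constant in the occupancy column (the convention NAMD's
    ``consref``/``conskfile`` pair reads).  ``flat-tsv``: one row per atom,
    (serial, chain, resnum, atomname, distance, k).  Both are byte-stable
    for identical input.
    """
    by_serial = {a.serial: a for a in truncated.atoms}
    if set(by_serial) != {s for s, _, _, _ in assignment.per_atom}:
        raise ConsistencyError("assignment does not cover the structure")
    kmax = max(k for _, _, _, k in assignment.per_atom)
    if kmax >= 1000.0:
        raise FieldOverflowError(
            f"force constant {kmax} does not fit the 6-character occupancy "
            "column"
        )
    if dialect == "constraint-pdb":
        k_by_serial = {s: k for s, _, _, k in assignment.per_atom}
        occ = [k_by_serial[a.serial] for a in truncated.atoms]
        write_pdb(truncated, path, occupancy_override=occ)
    elif dialect == "flat-tsv":
        lines = ["serial\tchain\tresnum\tatomname\tdistance\tk"]
        for serial, d, _, k in assignment.per_atom:
            a = by_serial[serial]
            lines.append(
                f"{serial}\t{a.chain_id}\t{a.residue_number}\t{a.name}"
                f"\t{d:.4f}\t{k:.2f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise SpecError(f"unknown restraint dialect {dialect!r}")
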