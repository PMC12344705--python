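"""Conformer generation by deformation along slow normal modes.

A conformer is the native node set displaced along one low-frequency mode,
in one direction, scaled so that the Cα root-mean-square deviation from the
native structure hits a prescribed target exactly (the construction is
linear, so the scale is a single division — no iteration, no minimization).

Labels follow the mXa/mXb convention: mode rank X, deformed in the positive
('a') or negative ('b') direction of the harmonic motion, the sign fixed by
the eigenvector orientation rule (largest-magnitude component positive).
The default schedule — slowest three modes, both directions, Cα-RMSD
targets 1.0, 1.5, 2.0, 2.5, 3.0 and 4.0 Å — yields 36 conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, SpecError
from .network import MCGModel, ModeSet
from .structure import Structure

__all__ = [
    "DeformationSchedule",
    "Conformer",
    "cartesian_mode_displacement",
    "generate_conformer",
    "generate_ensemble",
    "rmsd",
    "write_conformer_pdbs",
]

DEFAULT_RMSD_TARGETS = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)  # Å
DEFAULT_MODE_RANKS = (1, 2, 3)

#: required agreement between achieved and requested Cα RMSD, Å
RMSD_TARGET_TOL = 1e-6


@dataclass(frozen=True)
class DeformationSchedule:
    """Which modes, directions and Cα-RMSD levels to generate."""

    mode_indices: tuple[int, ...] = DEFAULT_MODE_RANKS
    directions: tuple[str, ...] = ("+", "-")
    rmsd_targets: tuple[float, ...] = DEFAULT_RMSD_TARGETS

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.mode_indices):
            raise SpecError("mode ranks are 1-based (1 = slowest nonzero)")
        if any(t <= 0 for t in self.rmsd_targets):
            raise SpecError("RMSD targets must be strictly positive")
        if any(b <= a for a, b in zip(self.rmsd_targets,
                                      self.rmsd_targets[1:])):
            raise SpecError("RMSD targets must be strictly increasing")
        if any(d not in ("+", "-") for d in self.directions):
            raise SpecError("directions must be '+' or '-'")

    @property
    def n_conformers(self) -> int:
        return (len(self.mode_indices) * len(self.directions)
                * len(self.rmsd_targets))


@dataclass
class Conformer:
    """One deformed coordinate set with its provenance."""

    label: str  # "mXa" / "mXb"
    mode_rank: int
    direction: str
    rmsd_target: float  # Å
    achieved_calpha_rmsd: float  # Å
    coordinates: np.ndarray  # (N, 3), Å
    scale_factor: float  # signed scale applied to the Cartesian displacement


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
         selection: Sequence[int] | None = None) -> float:
    """Root-mean-square deviation √(Σ|r_i − r_i^ref|²/N), no superposition.

    Coordinates are compared in their common frame, which is what the
    deformation construction requires (superposing would absorb part of the
    rigid-body content of a mode).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if selection is not None:
        a = a[np.asarray(selection, dtype=int)]
        b = b[np.asarray(selection, dtype=int)]
    if a.shape[0] < 1:
        raise ValueError("empty selection")
    diff = a - b
    return float(np.sqrt(np.einsum("ij,ij->", diff, diff) / a.shape[0]))


def cartesian_mode_displacement(
    modes: ModeSet, model: MCGModel, mode_rank: int
) -> np.ndarray:
    """Back-transform nonzero mode ``mode_rank`` to Cartesian space.

    Node i moves by ``u_k(3i..3i+2)/√m_i``; the field is not renormalised,
    so its overall scale is the (arbitrary) eigenvector norm.
    """
    _, vec = modes.nonzero_mode(mode_rank)
    disp = vec.reshape(model.n_nodes, 3) / np.sqrt(model.masses)[:, None]
    return disp


def generate_conformer(
    model: MCGModel,
    modes: ModeSet,
    mode_rank: int,
    direction: str,
    target_rmsd: float,
    rmsd_selection: Sequence[int] | None = None,
    structure: Structure | None = None,
) -> Conformer:
    """Deform the native nodes along one mode to an exact Cα-RMSD target.

    ``rmsd_selection`` defaults to the Cα-bearing nodes (HR Cα atom nodes
    plus LR nodes); pass explicit node indices to scale against any subset.
    All nodes move — the mode is a global displacement field.
    """
    if direction not in ("+", "-"):
        raise SpecError("direction must be '+' or '-'")
    if target_rmsd <= 0:
        raise SpecError("target RMSD must be positive")
    if rmsd_selection is None:
        if structure is None:
            raise ValueError(
                "default Cα selection requires the structure; pass "
                "rmsd_selection explicitly for synthetic models"
            )
        rmsd_selection = model.calpha_node_indices(structure)
    sel = np.asarray(rmsd_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty RMSD selection")

    disp = cartesian_mode_displacement(modes, model, mode_rank)
    native = model.positions
    unit_rmsd = rmsd(native + disp, native, sel)
    if unit_rmsd < 1e-12:
        raise GeometryError(
            f"mode {mode_rank} displacement vanishes on the RMSD selection"
        )
    scale = (1.0 if direction == "+" else -1.0) * target_rmsd / unit_rmsd
    coords = native + scale * disp
    achieved = rmsd(coords, native, sel)
    suffix = "a" if direction == "+" else "b"
    return Conformer(
        label=f"m{mode_rank}{suffix}",
        mode_rank=mode_rank,
        direction=direction,
        rmsd_target=float(target_rmsd),
        achieved_calpha_rmsd=achieved,
        coordinates=coords,
        scale_factor=float(scale),
    )


def generate_ensemble(
    model: MCGModel,
    modes: ModeSet,
    schedule: DeformationSchedule = DeformationSchedule(),
    rmsd_selection: Sequence[int] | None = None,
    structure: Structure | None = None,
) -> list[Conformer]:
    """All conformers of the schedule, ordered (mode, direction, target)."""
    out = []
    for rank in schedule.mode_indices:
        for direction in schedule.directions:
            for target in schedule.rmsd_targets:
                out.append(
                    generate_conformer(
                        model, modes, rank, direction, target,
                        rmsd_selection=rmsd_selection, structure=structure,
                    )
                )
    return out


def write_conformer_pdbs(
    conformers: Sequence[Conformer],
    model: MCGModel,
    structure: Structure,
    out_dir: str | Path,
    stem: str = "conformer",
) -> list[Path]:
    """One PDB per conformer plus a manifest TSV.

    Atom nodes carry their displaced atom; LR residue nodes are written as
    single Cα (or pseudo-centroid ``CEN``) records so the file remains a
    valid PDB trace of the mixed-resolution model.
    """
    from .structure import write_pdb  # local import avoids cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = ["label\ttarget_rmsd\tachieved_rmsd\tscale_factor\tfile"]
    for conf in conformers:
        moved_atoms: list[int] = []
        moved_coords: list[np.ndarray] = []
        for node in model.nodes:
            if node.kind == "atom":
                moved_atoms.append(node.source_atoms[0])
                moved_coords.append(conf.coordinates[node.index])
            else:
                # move the placement atom (Cα) of the LR residue
                if model.lr_placement == "calpha":
                    for ai in node.source_atoms:
                        if structure.atoms[ai].name == "CA":
                            moved_atoms.append(ai)
                            moved_coords.append(conf.coordinates[node.index])
                            break
        deformed = structure.with_coordinates(moved_atoms,
                                              np.stack(moved_coords))
        keep = sorted(moved_atoms)
        sub = Structure([deformed.atoms[i] for i in keep])
        target_tag = f"{conf.rmsd_target:g}".replace(".", "p")
        path = out_dir / f"{stem}_{conf.label}_rmsd{target_tag}.pdb"
        write_pdb(sub, path, remarks=[
            f"MCG conformer {conf.label} target {conf.rmsd_target:.3f} A "
            f"achieved {conf.achieved_calpha_rmsd:.6f} A"
        ])
        paths.append(path)
        manifest.append(
            f"{conf.label}\t{conf.rmsd_target:.3f}"
            f"\t{conf.achieved_calpha_rmsd:.8f}\t{conf.scale_factor:.8g}"
            f"\t{path.name}"
        )
    (out_dir / f"{stem}_manifest.tsv").write_text("\n".join(manifest) + "\n")
    return paths
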