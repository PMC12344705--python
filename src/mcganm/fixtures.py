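"""Self-contained toy structures and networks for testing and examples.

Real elastic-network inputs are crystal structures; everything here builds
small stand-ins with known geometry so every operation in the package can
be exercised deterministically and offline.  The toys are *not*
stereochemically realistic proteins — backbone atoms sit on idealised
curves and "side chains" are seeded pseudo-atoms — but they are valid
:class:`~mcganm.structure.Structure` objects that round-trip through the
PDB writer, have ligand records, chains and a smooth synthetic B-factor
profile, which is all the network machinery ever looks at.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import SpecError
from .network import MCGModel, Node, SpringNetwork
from .structure import AtomRecord, Structure, atomic_mass, write_pdb

__all__ = [
    "ToySpec",
    "make_toy_structure",
    "make_toy_pdb",
    "make_connected_network_fixture",
]

# idealised alpha-helix parameters: 2.3 Å radius, 100° twist, 1.5 Å rise
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RISE = 1.5
_CA_SPACING = 3.8  # Å, extended-chain Cα spacing

_SIDECHAIN_ELEMENTS = ("C", "C", "O", "N", "S", "C", "C", "C")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy structure.

    ``atoms_per_residue`` counts heavy atoms (>= 4: N, CA, C, O, then
    pseudo side-chain atoms).  ``chain_split`` starts chain B at that
    residue index.  ``ligand`` is ``(n_atoms, offset_Å)``: a HETATM cluster
    displaced laterally from the centroid of the last chain — so on a
    two-chain toy an HR sphere around the ligand covers that chain and
    only the near part of the other, giving a genuinely mixed model.
    """

    n_residues: int
    atoms_per_residue: int = 5
    geometry: Literal["helix", "extended", "random-walk"] = "helix"
    rng_seed: int = 0
    chain_split: int | None = None
    ligand: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise SpecError("a toy structure needs at least 2 residues")
        if self.atoms_per_residue < 4:
            raise SpecError("need at least the 4 backbone heavy atoms")
        if self.chain_split is not None and not (
            0 < self.chain_split < self.n_residues
        ):
            raise SpecError("chain_split must fall inside the chain")


def _backbone_curve(spec: ToySpec, rng: np.random.Generator) -> np.ndarray:
    """Cα positions along the requested geometry."""
    n = spec.n_residues
    if spec.geometry == "helix":
        t = np.arange(n)
        return np.stack([
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * t),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * t),
            _HELIX_RISE * t,
        ], axis=1)
    if spec.geometry == "extended":
        t = np.arange(n)
        return np.stack([
            _CA_SPACING * t,
            0.8 * (-1.0) ** t,
            np.zeros(n),
        ], axis=1)
    if spec.geometry == "random-walk":
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        return np.cumsum(_CA_SPACING * steps, axis=0)
    raise SpecError(f"unknown geometry {spec.geometry!r}")


def make_toy_structure(spec: ToySpec) -> Structure:
    """Deterministic toy structure; identical spec → identical structure."""
    rng = np.random.default_rng(spec.rng_seed)
    ca = _backbone_curve(spec, rng)
    n = spec.n_residues

    atoms: list[AtomRecord] = []
    serial = 1
    # smooth B-factor profile: low-frequency sinusoid + seeded noise, so
    # correlation tests have a non-degenerate, reproducible target
    b_profile = (
        12.0 + 6.0 * np.sin(2.0 * np.pi * np.arange(n) / max(10, n // 3))
        + rng.normal(scale=0.5, size=n)
    )

    for i in range(n):
        chain = "A"
        resnum = i + 1
        if spec.chain_split is not None and i >= spec.chain_split:
            chain = "B"
            resnum = i - spec.chain_split + 1
        axis = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        axis = axis / (np.linalg.norm(axis) + 1e-12)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        positions = {
            "N": ca[i] - 1.46 * axis + 0.4 * perp,
            "CA": ca[i],
            "C": ca[i] + 1.52 * axis + 0.4 * perp,
            "O": ca[i] + 1.52 * axis + 1.6 * perp,
        }
        names = ["N", "CA", "C", "O"]
        elements = ["N", "C", "C", "O"]
        side_dir = np.cross(axis, perp)
        for s in range(spec.atoms_per_residue - 4):
            elem = _SIDECHAIN_ELEMENTS[s % len(_SIDECHAIN_ELEMENTS)]
            name = f"{elem}B{s + 1}"[:4]
            jitter = rng.normal(scale=0.25, size=3)
            positions[name] = ca[i] + (1.5 + 1.2 * s) * side_dir + jitter
            names.append(name)
            elements.append(elem)
        for name, elem in zip(names, elements):
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem, chain_id=chain,
                residue_name="GLY" if spec.atoms_per_residue == 4 else "ALA",
                residue_number=resnum, insertion_code="",
                position=positions[name], occupancy=1.0,
                b_factor=float(b_profile[i]), mass=atomic_mass(elem),
                is_hetero=False,
            ))
            serial += 1

    ligand_indices: list[int] = []
    if spec.ligand is not None:
        n_lig, offset = spec.ligand
        anchor = (ca[spec.chain_split:] if spec.chain_split is not None
                  else ca)
        centroid = anchor.mean(axis=0) + np.array([offset, 0.0, 0.0])
        for m in range(n_lig):
            pos = centroid + rng.normal(scale=1.2, size=3)
            ligand_indices.append(len(atoms))
            atoms.append(AtomRecord(
                serial=serial, name=f"C{m + 1}", element="C", chain_id="L",
                residue_name="LIG", residue_number=900, insertion_code="",
                position=pos, occupancy=1.0, b_factor=20.0,
                mass=atomic_mass("C"), is_hetero=True,
            ))
            serial += 1
    return Structure(atoms, ligand_indices, source=f"toy(seed={spec.rng_seed})")


def make_toy_pdb(spec: ToySpec, path: str | Path) -> Structure:
    """Write the toy as a PDB file (seed recorded in a REMARK line)."""
    structure = make_toy_structure(spec)
    write_pdb(structure, path, remarks=[
        f"SYNTHETIC TOY STRUCTURE seed={spec.rng_seed} "
        f"geometry={spec.geometry} n_residues={spec.n_residues}",
    ])
    return structure


def make_connected_network_fixture(
    n_nodes: int,
    seed: int = 0,
    uniform_mass: bool = False,
) -> tuple[MCGModel, SpringNetwork]:
    """Random guaranteed-connected spring network for eigen-solver tests.

    A banded chain (each node bonded to its three predecessors) makes the
    graph connected and generically rigid — central-force springs on a bare
    chain would leave floppy hinge mechanisms and spurious zero modes.
    Extra random edges add coupling; spring constants are small positive
    integers so contact-count weighting paths are exercised too.
    """
    if n_nodes < 2:
        raise SpecError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 3.0 * n_nodes ** (1 / 3) + 3.0, size=(n_nodes, 3))
    masses = (np.full(n_nodes, 12.0) if uniform_mass
              else rng.choice([12.011, 14.007, 15.999, 32.06], size=n_nodes))

    nodes = [
        Node(i, "atom", pos[i], float(masses[i]), ("A", i + 1, ""), (i,))
        for i in range(n_nodes)
    ]
    edges = {(max(0, i - band), i)
             for i in range(1, n_nodes) for band in (1, 2, 3)}
    n_extra = 2 * n_nodes
    for _ in range(n_extra):
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        edges.add((min(i, j), max(i, j)))
    items = sorted(edges)
    gamma = rng.integers(1, 4, size=len(items)).astype(float)
    i_arr = np.array([e[0] for e in items])
    j_arr = np.array([e[1] for e in items])
    model = MCGModel(nodes=nodes, hr_residues=frozenset(n.residue_key for n in nodes))
    network = SpringNetwork(i_arr, j_arr, gamma, gamma_unit=1.0,
                            n_nodes=n_nodes)
    return model, network
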