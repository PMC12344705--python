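"""Mixed coarse-grained elastic network: nodes, springs, Hessian, modes.

The model describes a protein at two resolutions simultaneously.  Inside a
high-resolution (HR) region — typically a 30 Å sphere around a ligand or
functional site — every heavy atom is a network node.  Everywhere else (the
low-resolution, LR, region) each residue contributes a single node placed at
its Cα atom or heavy-atom centroid.  Nodes closer than a cutoff ``rc``
(default 10 Å, measured between heavy atoms) are connected by harmonic
springs.  A spring between two nodes carries the constant

    gamma_ij = gamma0 * (number of heavy-atom pairs, one atom from each
                         node, within rc)

so an atom–atom spring has gamma0 and a residue–residue spring is weighted
by the inter-residue contact count.  In the all-atom limit (every residue
HR) the model reduces to a conventional uniform-gamma heavy-atom ANM.

The 3N×3N Hessian of the network potential is mass-weighted,
``M^(-1/2) H M^(-1/2)``, and diagonalised; the six zero modes are the rigid
translations/rotations, and mean-square fluctuations over the remaining
modes are validated against crystallographic B-factors via Pearson
correlation (scale-free, so the spring unit gamma0 never matters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
import scipy.stats
from scipy.spatial import cKDTree

from .errors import (
    DiagnosticError,
    GeometryError,
    LookupKeyError,
    ModelError,
    RangeError,
    SelectionError,
    StatisticsError,
)
from .structure import ResidueKey, Structure, residue_heavy_atoms

__all__ = [
    "Node",
    "MCGModel",
    "SpringNetwork",
    "HessianModel",
    "ModeSet",
    "FluctuationProfile",
    "select_hr_region",
    "build_mcg_nodes",
    "build_spring_network",
    "assemble_hessian",
    "compute_modes",
    "residue_fluctuations",
    "bfactor_correlation",
    "rigid_body_basis",
]

DEFAULT_CUTOFF = 10.0  # Å, heavy-atom contact cutoff
DEFAULT_HR_RADIUS = 30.0  # Å, HR sphere radius
RECOMMENDED_CUTOFF_RANGE = (6.0, 10.0)  # Å
CHAIN_PROMOTION_FRACTION = 0.5  # promote a chain wholly to HR above this

LRPlacement = Literal["calpha", "centroid"]


@dataclass(frozen=True, eq=False)
class Node:
    """One network node: a single heavy atom (HR) or a whole residue (LR)."""

    index: int
    kind: Literal["atom", "residue"]
    position: np.ndarray  # (3,), Å
    mass: float  # amu
    residue_key: ResidueKey
    source_atoms: tuple[int, ...]  # indices into Structure.atoms

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        n_src = len(self.source_atoms)
        if self.kind == "atom" and n_src != 1:
            raise ValueError("atom node must represent exactly one atom")
        if self.kind == "residue" and n_src < 1:
            raise ValueError("residue node must represent >= 1 heavy atom")


@dataclass
class MCGModel:
    """The mixed-resolution node set over a structure.

    Node order is fixed: HR atom nodes in structure order, then LR residue
    nodes in structure order.  ``masses`` are atomic masses for atom nodes
    and residue heavy-atom mass sums for residue nodes.
    """

    nodes: list[Node]
    hr_residues: frozenset[ResidueKey]
    cutoff_rc: float = DEFAULT_CUTOFF
    lr_placement: LRPlacement = "calpha"
    hr_center: np.ndarray | None = None
    hr_radius: float = DEFAULT_HR_RADIUS

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([n.position for n in self.nodes])

    @property
    def masses(self) -> np.ndarray:
        return np.array([n.mass for n in self.nodes])

    def node_residues(self) -> list[ResidueKey]:
        return [n.residue_key for n in self.nodes]

    def calpha_node_indices(self, structure: Structure) -> list[int]:
        """Nodes standing in for Cα positions: HR Cα atom nodes plus LR
        residue nodes (which sit at Cα under ``calpha`` placement).

        Under centroid placement the residue node substitutes for the Cα
        with a warning, keeping RMSD targeting well-defined.
        """
        out = []
        warned = False
        for node in self.nodes:
            if node.kind == "atom":
                atom = structure.atoms[node.source_atoms[0]]
                if atom.name == "CA" and not atom.is_hetero:
                    out.append(node.index)
            else:
                if self.lr_placement == "centroid" and not warned:
                    warnings.warn(
                        "centroid-placed LR nodes substitute for Cα in the "
                        "RMSD selection",
                        stacklevel=2,
                    )
                    warned = True
                out.append(node.index)
        return out


@dataclass
class SpringNetwork:
    """Symmetric spring set stored once per unordered node pair (i < j)."""

    i: np.ndarray  # int array
    j: np.ndarray  # int array
    gamma: np.ndarray  # spring constants, gamma0 units
    gamma_unit: float = 1.0
    n_nodes: int = 0

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.i >= self.j):
            raise ValueError("edges must be stored with i < j")
        if np.any(self.gamma <= 0):
            raise ValueError("spring constants must be positive")
        if self.n_nodes == 0 and self.i.size:
            self.n_nodes = int(self.j.max()) + 1

    @property
    def n_edges(self) -> int:
        return int(self.i.size)

    def edges(self) -> list[tuple[int, int, float]]:
        return list(zip(self.i.tolist(), self.j.tolist(), self.gamma.tolist()))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.i, 1)
        np.add.at(deg, self.j, 1)
        return deg

    def n_components(self) -> int:
        adj = sp.coo_matrix(
            (np.ones(self.n_edges), (self.i, self.j)),
            shape=(self.n_nodes, self.n_nodes),
        )
        return int(csgraph.connected_components(adj, directed=False)[0])


@dataclass
class HessianModel:
    """Mass-weighted Hessian of the network potential (sparse, symmetric)."""

    hessian: sp.csr_matrix  # M^(-1/2) H M^(-1/2), shape (3N, 3N)
    unweighted: sp.csr_matrix  # H itself
    masses: np.ndarray  # (N,), amu

    @property
    def dimension(self) -> int:
        return self.hessian.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.masses.size


@dataclass
class ModeSet:
    """Eigenpairs of the mass-weighted Hessian, ascending by eigenvalue.

    ``eigenvectors[:, k]`` is the mass-weighted mode ``u_k``.  Zero
    (rigid-body) modes are identified by a relative threshold and excluded
    from slow-mode indexing: nonzero mode rank 1 is the 7th eigenpair of a
    connected network.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int
    zero_tolerance: float

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes:]

    def nonzero_mode(self, rank: int) -> tuple[float, np.ndarray]:
        """Eigenpair of the ``rank``-th (1-based) nonzero mode."""
        if rank < 1:
            raise RangeError("mode rank is 1-based")
        idx = self.n_zero_modes + rank - 1
        if idx >= self.n_modes:
            raise RangeError(
                f"mode rank {rank} exceeds the {self.n_modes - self.n_zero_modes} "
                "computed nonzero modes"
            )
        return float(self.eigenvalues[idx]), self.eigenvectors[:, idx]


@dataclass
class FluctuationProfile:
    """Per-node and per-residue mean-square fluctuations ⟨ΔR_i²⟩ (Å²)."""

    per_node_msf: np.ndarray
    per_residue_msf: dict[ResidueKey, float]
    n_modes_used: int | str


# ---------------------------------------------------------------------------
# HR region selection
# ---------------------------------------------------------------------------

def select_hr_region(
    structure: Structure,
    center: np.ndarray | Sequence[float] | str | None = None,
    radius: float = DEFAULT_HR_RADIUS,
    promote_chains: bool = True,
    promotion_fraction: float = CHAIN_PROMOTION_FRACTION,
) -> frozenset[ResidueKey]:
    """Select HR residues: any heavy atom within ``radius`` of the center.

    ``center`` is a 3-vector, or the string ``"ligand"`` (use every ligand
    heavy atom as a reference point), or None (same as ``"ligand"``).  When
    ``promote_chains`` is set, any chain with more than ``promotion_fraction``
    of its residues selected is promoted wholly to HR — mirroring the
    modelling choice of treating a subunit at full resolution when the
    sphere covers most of it.
    """
    if radius <= 0:
        raise SelectionError("HR radius must be positive")
    if center is None or (isinstance(center, str) and center == "ligand"):
        ref_points = np.array(
            [a.position for a in structure.ligand_atoms if a.is_heavy]
        )
        if ref_points.size == 0:
            raise SelectionError(
                "HR selection around the ligand requires ligand atoms; "
                "pass an explicit center or a ligand selector at read time"
            )
    elif isinstance(center, str):
        raise SelectionError(f"unrecognised center spec {center!r}")
    else:
        ref_points = np.asarray(center, dtype=float).reshape(1, 3)

    tree = cKDTree(ref_points)
    selected: set[ResidueKey] = set()
    protein_residues = [
        key for key in structure.residues
        if not structure.residue_atoms(key)[0].is_hetero
    ]
    for key in protein_residues:
        heavy = residue_heavy_atoms(structure, key)
        if not heavy:
            continue
        dists, _ = tree.query(np.stack([a.position for a in heavy]))
        if np.min(dists) <= radius:
            selected.add(key)
    if not selected:
        raise SelectionError("empty HR selection")

    if promote_chains:
        by_chain: dict[str, list[ResidueKey]] = {}
        for key in protein_residues:
            by_chain.setdefault(key[0], []).append(key)
        for chain, keys in by_chain.items():
            n_sel = sum(k in selected for k in keys)
            if n_sel > promotion_fraction * len(keys):
                selected.update(keys)
    return frozenset(selected)


# ---------------------------------------------------------------------------
# node construction
# ---------------------------------------------------------------------------

def build_mcg_nodes(
    structure: Structure,
    hr_residues: frozenset[ResidueKey] | set[ResidueKey],
    lr_placement: LRPlacement = "calpha",
    cutoff_rc: float = DEFAULT_CUTOFF,
    include_hetero: bool = False,
    hr_center: np.ndarray | None = None,
    hr_radius: float = DEFAULT_HR_RADIUS,
) -> MCGModel:
    """Build the mixed-resolution node set.

    HR residues contribute one node per heavy atom; every other (LR)
    residue contributes a single node at its Cα or heavy-atom mass centroid,
    carrying the residue's summed heavy-atom mass.  Hetero residues
    (ligand, ions) are not nodes unless ``include_hetero`` is set, in which
    case their heavy atoms join the HR atom set.
    """
    hr_residues = frozenset(hr_residues)
    residue_keys = list(structure.residues)
    known = set(residue_keys)
    unknown = hr_residues - known
    if unknown:
        raise LookupKeyError(f"HR residues not in structure: {sorted(unknown)}")

    def is_node_residue(key: ResidueKey) -> bool:
        hetero = structure.residue_atoms(key)[0].is_hetero
        return include_hetero or not hetero

    nodes: list[Node] = []
    # HR atom nodes first, structure order
    for key in residue_keys:
        if key not in hr_residues or not is_node_residue(key):
            continue
        for ai in structure.residue_atom_indices(key):
            atom = structure.atoms[ai]
            if not atom.is_heavy:
                continue
            nodes.append(Node(len(nodes), "atom", atom.position,
                              atom.mass, key, (ai,)))
    # then LR residue nodes, structure order
    missing_ca: list[ResidueKey] = []
    for key in residue_keys:
        if key in hr_residues or not is_node_residue(key):
            continue
        heavy_idx = [
            ai for ai in structure.residue_atom_indices(key)
            if structure.atoms[ai].is_heavy
        ]
        if not heavy_idx:
            continue
        heavy = [structure.atoms[ai] for ai in heavy_idx]
        mass = float(sum(a.mass for a in heavy))
        if lr_placement == "calpha":
            ca = [a for a in heavy if a.name == "CA"]
            if not ca:
                missing_ca.append(key)
                continue
            pos = ca[0].position
        else:
            weights = np.array([a.mass for a in heavy])
            pos = np.average(np.stack([a.position for a in heavy]),
                             axis=0, weights=weights)
        nodes.append(Node(len(nodes), "residue", pos, mass, key,
                          tuple(heavy_idx)))
    if missing_ca:
        raise ModelError(
            f"LR residues without a Cα under calpha placement: {missing_ca}"
        )
    if not nodes:
        raise ModelError("no nodes: empty structure or all-hetero input")
    return MCGModel(
        nodes=nodes,
        hr_residues=hr_residues,
        cutoff_rc=cutoff_rc,
        lr_placement=lr_placement,
        hr_center=None if hr_center is None else np.asarray(hr_center, float),
        hr_radius=hr_radius,
    )


# ---------------------------------------------------------------------------
# spring network
# ---------------------------------------------------------------------------

def build_spring_network(
    model: MCGModel,
    structure: Structure,
    gamma0: float = 1.0,
) -> SpringNetwork:
    """Connect nodes by heavy-atom contact counting at the model's cutoff.

    One rule covers every node-kind combination: the spring constant of a
    pair is gamma0 times the number of heavy-atom contacts (pairs of atoms
    within ``rc``, one from each node's source atoms); the edge exists iff
    that count is at least one.  Atom–atom pairs therefore get gamma0 iff
    the two atoms are within the cutoff, and residue-involving pairs get
    the contact-count weighting.
    """
    rc = model.cutoff_rc
    lo, hi = RECOMMENDED_CUTOFF_RANGE
    if not (lo <= rc <= hi):
        warnings.warn(
            f"cutoff {rc} Å outside the recommended {lo}-{hi} Å heavy-atom "
            "range",
            stacklevel=2,
        )

    atom_pos: list[np.ndarray] = []
    atom_node: list[int] = []
    for node in model.nodes:
        for ai in node.source_atoms:
            atom_pos.append(structure.atoms[ai].position)
            atom_node.append(node.index)
    pos = np.stack(atom_pos)
    owner = np.asarray(atom_node)

    tree = cKDTree(pos)
    pairs = tree.query_pairs(rc, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        ni, nj = owner[a], owner[b]
        if ni == nj:
            continue  # same node (or same LR residue): never a self-spring
        key = (ni, nj) if ni < nj else (nj, ni)
        counts[key] = counts.get(key, 0) + 1

    if not counts:
        raise ModelError("no springs at this cutoff: network is empty")
    items = sorted(counts.items())
    i = np.array([k[0] for k, _ in items])
    j = np.array([k[1] for k, _ in items])
    gamma = gamma0 * np.array([c for _, c in items], dtype=float)
    network = SpringNetwork(i, j, gamma, gamma_unit=gamma0,
                            n_nodes=model.n_nodes)

    deg = network.degrees()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size == model.n_nodes:
        raise ModelError("fully disconnected network")
    if isolated.size:
        warnings.warn(
            f"{isolated.size} isolated node(s) (degree 0), e.g. node "
            f"{int(isolated[0])} of residue "
            f"{model.nodes[int(isolated[0])].residue_key}; the network has "
            f"{network.n_components()} connected component(s)",
            stacklevel=2,
        )
    return network


# ---------------------------------------------------------------------------
# Hessian
# ---------------------------------------------------------------------------

def assemble_hessian(network: SpringNetwork, model: MCGModel) -> HessianModel:
    """Assemble the 3N×3N network Hessian and mass-weight it.

    Each spring contributes the standard anisotropic-network superblock
    ``H_ij = -(gamma_ij / R_ij²) d_ij d_ijᵀ`` (``d_ij`` the equilibrium
    inter-node vector); diagonal superblocks make every superblock row sum
    to zero, which is exactly translational invariance of the potential.
    The returned ``hessian`` is ``M^(-1/2) H M^(-1/2)`` with each node mass
    repeated over x, y, z.
    """
    if network.n_edges == 0:
        raise ModelError("empty spring network")
    n = model.n_nodes
    pos = model.positions

    d = pos[network.j] - pos[network.i]  # (E, 3)
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < 1e-12):
        bad = int(np.argmin(r2))
        raise GeometryError(
            f"coincident node pair ({network.i[bad]}, {network.j[bad]}): "
            f"separation < 1e-6 Å"
        )
    blocks = -(network.gamma / r2)[:, None, None] * np.einsum(
        "ei,ej->eij", d, d
    )  # (E, 3, 3)

    rows, cols, vals = [], [], []
    xyz = np.arange(3)
    ii, jj = np.meshgrid(xyz, xyz, indexing="ij")
    for e in range(network.n_edges):
        bi, bj = 3 * network.i[e], 3 * network.j[e]
        block = blocks[e]
        rows.append((bi + ii).ravel()); cols.append((bj + jj).ravel())
        vals.append(block.ravel())
        rows.append((bj + ii).ravel()); cols.append((bi + jj).ravel())
        vals.append(block.T.ravel())
        # diagonal accumulation: H_ii = -sum_j H_ij
        rows.append((bi + ii).ravel()); cols.append((bi + jj).ravel())
        vals.append(-block.ravel())
        rows.append((bj + ii).ravel()); cols.append((bj + jj).ravel())
        vals.append(-block.T.ravel())

    h = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    h = (h + h.T) * 0.5  # enforce exact symmetry

    masses = model.masses
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    scale = sp.diags(inv_sqrt_m)
    h_mw = (scale @ h @ scale).tocsr()
    h_mw = (h_mw + h_mw.T) * 0.5
    return HessianModel(hessian=h_mw, unweighted=h, masses=masses)


# ---------------------------------------------------------------------------
# modes
# ---------------------------------------------------------------------------

# below this dimension a dense eigendecomposition is both faster and exact
_DENSE_LIMIT = 1500


def compute_modes(
    hessian: HessianModel,
    n_modes: int | str = "all",
    zero_tolerance: float = 1e-8,
    expected_zero_modes: int | None = None,
) -> ModeSet:
    """Diagonalise the mass-weighted Hessian, ascending eigenvalues.

    ``n_modes="all"`` (or a small dimension) takes the dense symmetric
    path; otherwise a shift-inverted Lanczos solve returns the requested
    lowest eigenpairs with the same ordering contract.  Zero modes are
    ``λ < zero_tolerance × λ_max(computed)``; pass ``expected_zero_modes=6``
    to fail loudly when a supposedly connected network does not produce the
    six rigid-body motions.

    Each eigenvector is oriented so its largest-magnitude component is
    positive, making the '+' deformation direction reproducible across
    solvers.
    """
    dim = hessian.dimension
    if n_modes == "all":
        k = dim
    else:
        k = int(n_modes)
        if k < 1 or k > dim:
            raise RangeError(f"n_modes {k} outside [1, {dim}]")

    if k == dim or dim <= _DENSE_LIMIT:
        dense = hessian.hessian.toarray()
        evals, evecs = scipy.linalg.eigh(dense)
        evals, evecs = evals[:k], evecs[:, :k]
    else:
        # shift-invert around a slightly negative sigma: H is PSD, so
        # H - sigma*I is positive definite and factorizable
        evals, evecs = spla.eigsh(
            hessian.hessian, k=k, sigma=-1e-6, which="LM"
        )
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]

    # classify against the matrix scale (largest diagonal entry), which is
    # identical for dense and partial solves of the same Hessian
    scale = float(hessian.hessian.diagonal().max())
    if scale <= 0:
        raise DiagnosticError("mass-weighted Hessian has no positive diagonal")
    if float(np.min(evals)) < -zero_tolerance * scale:
        raise DiagnosticError(
            "mass-weighted Hessian is not numerically positive semidefinite"
        )
    evals = np.clip(evals, 0.0, None)
    n_zero = int(np.sum(evals < zero_tolerance * scale))

    if expected_zero_modes is not None and n_zero != expected_zero_modes:
        raise DiagnosticError(
            f"found {n_zero} zero modes, expected {expected_zero_modes}; "
            "the network may be disconnected or contain coincident nodes"
        )

    # deterministic sign: largest-|component| entry made positive
    flip = evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])] < 0
    evecs = evecs * np.where(flip, -1.0, 1.0)

    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        n_zero_modes=n_zero,
        zero_tolerance=zero_tolerance,
    )


def rigid_body_basis(model: MCGModel) -> np.ndarray:
    """Orthonormal basis of the analytic rigid-body space, mass-weighted.

    Columns span the three translations (√m_i e_a) and three rotations
    (√m_i (e_a × r_i)); used to verify that the computed zero modes are the
    rigid motions and nothing else.
    """
    pos = model.positions - model.positions.mean(axis=0)
    sqrt_m = np.sqrt(model.masses)
    n = model.n_nodes
    basis = np.zeros((3 * n, 6))
    for a in range(3):
        vec = np.zeros((n, 3))
        vec[:, a] = 1.0
        basis[:, a] = (sqrt_m[:, None] * vec).ravel()
        axis = np.zeros(3)
        axis[a] = 1.0
        rot = np.cross(np.broadcast_to(axis, pos.shape), pos)
        basis[:, 3 + a] = (sqrt_m[:, None] * rot).ravel()
    q, _ = np.linalg.qr(basis)
    return q


# ---------------------------------------------------------------------------
# fluctuations & validation
# ---------------------------------------------------------------------------

def residue_fluctuations(
    modes: ModeSet,
    model: MCGModel,
    structure: Structure | None = None,
    n_modes_used: int | str = "all",
) -> FluctuationProfile:
    """Mean-square fluctuations per node and per residue.

    Cartesian per-node MSF is the mode sum ⟨ΔR_i²⟩ = Σ_k |u_k(3i..3i+2)|² /
    (m_i λ_k) over nonzero modes — the 1/m_i back-transforms the
    mass-weighted eigenvectors.  Per-residue values take the Cα atom node
    for HR residues and the single node for LR residues.
    """
    available = modes.n_modes - modes.n_zero_modes
    if n_modes_used == "all":
        use = available
    else:
        use = int(n_modes_used)
        if use < 1 or use > available:
            raise RangeError(
                f"n_modes_used {use} outside the {available} computed "
                "nonzero modes"
            )
    sl = slice(modes.n_zero_modes, modes.n_zero_modes + use)
    lam = modes.eigenvalues[sl]
    vec = modes.eigenvectors[:, sl]

    n = model.n_nodes
    comp2 = (vec ** 2).reshape(n, 3, use).sum(axis=1)  # |u_k(3i..3i+2)|²
    per_node = (comp2 / lam[None, :]).sum(axis=1) / model.masses

    per_residue: dict[ResidueKey, float] = {}
    for node in model.nodes:
        key = node.residue_key
        if node.kind == "residue":
            per_residue[key] = float(per_node[node.index])
        else:
            if structure is not None:
                atom = structure.atoms[node.source_atoms[0]]
                if atom.name == "CA":
                    per_residue[key] = float(per_node[node.index])
            elif key not in per_residue:
                per_residue[key] = float(per_node[node.index])
    # HR residues lacking a Cα node (unusual): fall back to the residue mean
    if structure is not None:
        hr_nodes_by_res: dict[ResidueKey, list[int]] = {}
        for node in model.nodes:
            if node.kind == "atom":
                hr_nodes_by_res.setdefault(node.residue_key, []).append(node.index)
        for key, idx in hr_nodes_by_res.items():
            if key not in per_residue:
                per_residue[key] = float(np.mean(per_node[idx]))

    return FluctuationProfile(
        per_node_msf=per_node,
        per_residue_msf=per_residue,
        n_modes_used=n_modes_used if n_modes_used == "all" else use,
    )


def bfactor_correlation(
    profile: FluctuationProfile,
    structure: Structure,
) -> float:
    """Pearson r between per-residue MSF and experimental Cα B-factors.

    Scale-free: any positive affine rescaling of the MSF (including the
    conventional 8π²/3 B-factor constant) leaves r unchanged, so no unit
    conversion is applied.
    """
    msf, bexp = [], []
    for key, value in profile.per_residue_msf.items():
        ca = [a for a in structure.residue_atoms(key) if a.name == "CA"]
        if not ca:
            continue
        msf.append(value)
        bexp.append(ca[0].b_factor)
    if len(msf) < 3:
        raise StatisticsError(
            f"only {len(msf)} residues with both MSF and Cα B-factor"
        )
    bexp_arr = np.asarray(bexp)
    if np.ptp(bexp_arr) == 0:
        raise StatisticsError("experimental B-factor column is constant")
    return float(scipy.stats.pearsonr(np.asarray(msf), bexp_arr)[0])


# ---------------------------------------------------------------------------
# artifact export
# ---------------------------------------------------------------------------

def write_edge_list_tsv(network: SpringNetwork, model: MCGModel,
                        path: str | Path) -> None:
    """Edge list as TSV: i, j, gamma, inter-node distance (Å)."""
    pos = model.positions
    dist = np.linalg.norm(pos[network.j] - pos[network.i], axis=1)
    lines = ["i\tj\tgamma\tdistance"]
    for e in range(network.n_edges):
        lines.append(
            f"{network.i[e]}\t{network.j[e]}\t{network.gamma[e]:.6g}"
            f"\t{dist[e]:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_modes_tsv(modes: ModeSet, path: str | Path,
                    max_modes: int | None = None) -> None:
    """Eigenvalue table plus per-component eigenvector columns."""
    k = modes.n_modes if max_modes is None else min(max_modes, modes.n_modes)
    header = "component\t" + "\t".join(
        f"mode{m}_lambda_{modes.eigenvalues[m]:.8g}" for m in range(k)
    )
    lines = [header]
    for row in range(modes.eigenvectors.shape[0]):
        lines.append(
            f"{row}\t" + "\t".join(
                f"{modes.eigenvectors[row, m]:.8g}" for m in range(k)
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fluctuation_report(
    profile: FluctuationProfile,
    structure: Structure,
    path: str | Path,
) -> None:
    """Per-residue TSV: chain, resnum, icode, msf, experimental Cα B."""
    lines = ["chain\tresnum\ticode\tmsf\texperimental_B"]
    for key, value in profile.per_residue_msf.items():
        ca = [a for a in structure.residue_atoms(key) if a.name == "CA"]
        bexp = f"{ca[0].b_factor:.4f}" if ca else "NA"
        lines.append(f"{key[0]}\t{key[1]}\t{key[2]}\t{value:.8g}\t{bexp}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hessian_mtx(hessian: HessianModel, path: str | Path) -> None:
    """Mass-weighted Hessian in Matrix Market sparse format."""
    import scipy.io

    scipy.io.mmwrite(str(path), hessian.hessian.tocoo())
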