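"""Truncate the high-resolution region and assign zoned restraints.

Extracts the HR residues of a slow-mode conformer as a standalone
structure and classifies every atom into concentric shells around the
ligand, each with a harmonic force constant (kcal/mol·Å²).  The inner
15 Å stays flexible; the outer shells hold the truncated structure
together during minimization or MD.
"""

from pathlib import Path

import mcganm as m

spec = m.ToySpec(n_residues=50, atoms_per_residue=6, geometry="helix",
                 rng_seed=7, chain_split=25, ligand=(5, 6.0))
structure = m.make_toy_structure(spec)
hr = m.select_hr_region(structure, "ligand", radius=30.0)
model = m.build_mcg_nodes(structure, hr, cutoff_rc=10.0)
network = m.build_spring_network(model, structure)
modes = m.compute_modes(m.assemble_hessian(network, model),
                        expected_zero_modes=6)
conformer = m.generate_conformer(model, modes, 1, "+", 1.0,
                                 structure=structure)

truncated = m.truncate_structure(conformer, model, structure)
print(f"truncated HR region: {len(truncated.atoms)} heavy atoms, "
      f"{len(truncated.residues)} residues")

for name in ("minimization", "case1", "case2", "case3"):
    scheme = m.SCHEMES[name]
    assignment = m.assign_restraints(truncated, scheme, reference=structure)
    counts = assignment.shell_counts()
    zones = ", ".join(
        f"k={k:g}: {c} atoms" for (_, k), c in zip(scheme.shells, counts)
    )
    print(f"  {name:<13s} {zones}")

out = Path("scratch_restraints")
out.mkdir(exist_ok=True)
assignment = m.assign_restraints(truncated, m.SCHEMES["case3"],
                                 reference=structure)
m.write_restraint_files(assignment, truncated, "constraint-pdb",
                        out / "case3_consref.pdb")
m.write_restraint_files(assignment, truncated, "flat-tsv",
                        out / "case3_restraints.tsv")
print(f"wrote case3 restraint files to {out}/")
print("# the constraint PDB carries each atom's force constant in the")
print("# occupancy column, the convention harmonic-restraint MD inputs use")
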