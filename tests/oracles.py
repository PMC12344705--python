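"""Independent brute-force reference computations used by the tests.

Everything here deliberately avoids the package's own code paths: dense
numpy arithmetic, O(n²) scans and textbook formulas, so a test comparing a
package result against an oracle is a genuine dual-route check.
"""

import numpy as np


def pair_potential_energy(x, edges, rest_lengths):
    """V = Σ_edges γ/2 (|r_i − r_j| − L_e)² for flat coordinates x."""
    pos = x.reshape(-1, 3)
    v = 0.0
    for (i, j, gamma), length in zip(edges, rest_lengths):
        v += 0.5 * gamma * (np.linalg.norm(pos[i] - pos[j]) - length) ** 2
    return v


def finite_difference_hessian(x0, edges, rest_lengths, h=1e-4):
    """Central-difference Hessian of the pair potential at x0 (flat)."""
    n = x0.size
    hess = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            val = (
                pair_potential_energy(xpp, edges, rest_lengths)
                - pair_potential_energy(xpm, edges, rest_lengths)
                - pair_potential_energy(xmp, edges, rest_lengths)
                + pair_potential_energy(xmm, edges, rest_lengths)
            ) / (4 * h * h)
            hess[a, b] = hess[b, a] = val
    return hess


def dense_anm_hessian(positions, edges):
    """Analytic dense ANM Hessian built pair-by-pair (no sparse machinery)."""
    n = positions.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    for i, j, gamma in edges:
        d = positions[j] - positions[i]
        r2 = float(d @ d)
        block = -(gamma / r2) * np.outer(d, d)
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block.T
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block.T
    return hess


def brute_force_contact_edges(node_atoms, atom_positions, cutoff):
    """All-pairs contact counting: {(i, j): count} over node pairs.

    ``node_atoms`` maps node index → list of heavy-atom indices.
    """
    counts = {}
    nodes = sorted(node_atoms)
    for ai, ni in enumerate(nodes):
        for nj in nodes[ai + 1:]:
            c = 0
            for a in node_atoms[ni]:
                for b in node_atoms[nj]:
                    if np.linalg.norm(
                        atom_positions[a] - atom_positions[b]
                    ) <= cutoff:
                        c += 1
            if c:
                counts[(ni, nj)] = c
    return counts


def two_pass_pearson(x, y):
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self):
        return len({self.find(i) for i in range(len(self.parent))})
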