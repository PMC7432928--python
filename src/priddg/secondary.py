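"""Three-class secondary structure from backbone hydrogen bonds.

Kabsch–Sander style assignment: an amide hydrogen is reconstructed on each
backbone nitrogen, the electrostatic H-bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

is evaluated between every CO(i)/NH(j) pair, and E < -0.5 kcal/mol marks a
hydrogen bond. N-turn patterns yield helices (DSSP H/G/I), bridge patterns
yield strands (DSSP E/B), everything else is coil. Only the 3-class collapse
{helix, strand, coil} is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SecondaryStructureAssignment", "assign_secondary_structure"]

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0


@dataclass
class SecondaryStructureAssignment:
    labels: dict  # residue key -> "helix" | "strand" | "coil"

    def __getitem__(self, key):
        return self.labels[key]

    def fraction(self, label):
        if not self.labels:
            return 0.0
        return sum(1 for v in self.labels.values() if v == label) / len(self.labels)


def _chain_segments(residues):
    """Split protein residues into covalently continuous chain segments."""
    segs = []
    cur = []
    for r in residues:
        if r.kind != "amino-acid":
            continue
        if cur:
            prev = cur[-1]
            broken = prev.chain != r.chain
            if not broken:
                c, n = prev.atom("C"), r.atom("N")
                broken = c is None or n is None or (
                    np.linalg.norm(c.coords - n.coords) > 2.5)
            if broken:
                segs.append(cur)
                cur = []
        cur.append(r)
    if cur:
        segs.append(cur)
    return segs


def _hbond_matrix(chain):
    """hb[i, j] True when CO(i) accepts an H-bond from NH(j)."""
    n = len(chain)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    N = np.full((n, 3), np.nan)
    H = np.full((n, 3), np.nan)
    for i, r in enumerate(chain):
        for nm, arr in (("C", C), ("O", O), ("N", N)):
            a = r.atom(nm)
            if a is not None:
                arr[i] = a.coords
    # amide H: 1.0 A from N along the C(i-1)->O(i-1) reverse direction
    for i in range(1, n):
        if np.any(np.isnan(N[i])) or np.any(np.isnan(C[i - 1])):
            continue
        d = C[i - 1] - O[i - 1]
        nrm = np.linalg.norm(d)
        if nrm > 0:
            H[i] = N[i] + d / nrm
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):  # acceptor CO
        if np.any(np.isnan(C[i])):
            continue
        for j in range(n):  # donor NH
            if i == j or abs(i - j) < 2:
                continue
            if chain[j].name == "PRO" or np.any(np.isnan(H[j])):
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < HB_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb


def _assign_segment(chain):
    n = len(chain)
    labels = ["coil"] * n
    if n < 3:
        return labels
    hb = _hbond_matrix(chain)

    def turn(i, k):
        return i + k < n and hb[i, i + k]

    helix = [False] * n
    for k in (4, 3, 5):
        for i in range(1, n - k):
            if turn(i - 1, k) and turn(i, k):
                for j in range(i, min(i + k, n)):
                    helix[j] = True

    strand = [False] * n
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                strand[i] = strand[j] = True

    for i in range(n):
        if helix[i]:
            labels[i] = "helix"
        elif strand[i]:
            labels[i] = "strand"
    return labels


def assign_secondary_structure(structure):
    """Assign helix/strand/coil to every protein residue of a structure."""
    labels = {}
    protein = [r for r in structure.residues if r.kind == "amino-acid"]
    for seg in _chain_segments(protein):
        seg_labels = _assign_segment(seg)
        for r, lab in zip(seg, seg_labels):
            labels[r.key] = lab
    return SecondaryStructureAssignment(labels)
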