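"""Ideal residue templates and covalent connectivity.

Templates come from the Chemical Component Dictionary bundled with biotite:
idealized coordinates for the 20 amino acids and the 4 ribonucleotides,
reduced to heavy atoms. They serve two purposes: donor geometry when grafting
a mutant side chain, and reference bond/1-3 distances for the simplified
minimization potential.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as bstinfo

from .structure import AA_1TO3, RNA_CODES

# atoms never present in a polymer context
_DROP = {"OXT", "OP3", "HXT", "HOP3"}


@lru_cache(maxsize=None)
def residue_template(resname):
    """Heavy-atom ideal template: (names tuple, Nx3 coords, element tuple)."""
    arr = bstinfo.residue(resname)
    if arr is None:
        raise KeyError(f"no template for residue {resname}")
    mask = (arr.element != "H") & ~np.isin(arr.atom_name, list(_DROP))
    names = tuple(arr.atom_name[mask])
    coords = np.asarray(arr.coord[mask], dtype=float)
    elements = tuple(arr.element[mask])
    return names, coords, elements


@lru_cache(maxsize=None)
def residue_bonds(resname):
    """Intra-residue heavy-atom bonds as a frozenset of atom-name pairs."""
    arr = bstinfo.residue(resname)
    names = arr.atom_name
    elements = arr.element
    bonds = set()
    bl, _ = arr.bonds.get_all_bonds()
    for i in range(len(names)):
        for j in bl[i]:
            if j < 0 or j <= i:
                continue
            if elements[i] == "H" or elements[j] == "H":
                continue
            a, b = names[i], names[j]
            if a in _DROP or b in _DROP:
                continue
            bonds.add((a, b))
    return frozenset(bonds)


def template_for_aa(aa1):
    return residue_template(AA_1TO3[aa1])


def build_bond_list(cplx):
    """All heavy-atom covalent bonds of a complex as index pairs into the
    flat atom order of ``cplx`` (residue-internal bonds from the CCD plus
    peptide C–N and phosphodiester O3'–P links between consecutive residues
    of the same chain)."""
    index = {}
    flat = []
    for r in cplx.residues:
        for a in r.atoms:
            index[(r.key, a.name)] = len(flat)
            flat.append((r, a))
    bonds = []
    for r in cplx.residues:
        try:
            for a, b in residue_bonds(r.name):
                ia = index.get((r.key, a))
                ib = index.get((r.key, b))
                if ia is not None and ib is not None:
                    bonds.append((ia, ib))
        except Exception:
            continue  # unknown residue: no template bonds
    # inter-residue links
    for prev, nxt in zip(cplx.residues, cplx.residues[1:]):
        if prev.chain != nxt.chain:
            continue
        if prev.kind == "amino-acid" and nxt.kind == "amino-acid":
            pair = (index.get((prev.key, "C")), index.get((nxt.key, "N")))
        elif prev.kind == "nucleotide" and nxt.kind == "nucleotide":
            pair = (index.get((prev.key, "O3'")), index.get((nxt.key, "P")))
        else:
            continue
        if pair[0] is not None and pair[1] is not None:
            # only bond if geometrically plausible (guards chain breaks)
            d = np.linalg.norm(flat[pair[0]][1].coords - flat[pair[1]][1].coords)
            if d < 2.5:
                bonds.append(pair)
    return bonds


def angles_from_bonds(n_atoms, bonds):
    """1-3 atom pairs implied by the bond list (for Urey–Bradley-style
    distance restraints)."""
    neigh = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        neigh[i].append(j)
        neigh[j].append(i)
    pairs = set()
    for k in range(n_atoms):
        ns = neigh[k]
        for x in range(len(ns)):
            for y in range(x + 1, len(ns)):
                a, b = sorted((ns[x], ns[y]))
                pairs.add((a, b))
    bondset = {tuple(sorted(b)) for b in bonds}
    return sorted(pairs - bondset)
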