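"""Mutant structure construction.

A single missense mutation replaces one residue's side chain with an
ideal-geometry template of the target amino acid. The backbone (N, CA, C, O)
is kept; the template is superimposed on the backbone and, when both wild
type and mutant have a gamma-position atom, the new side chain is rotated
about the CA-CB axis so its chi1 direction matches the wild type's. Missing
heavy atoms of incomplete residues are rebuilt from the same templates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import templates
from .structure import AA_1TO3, AA_3TO1, Atom, PROTEIN_BACKBONE

__all__ = ["MutationSpec", "MutationError", "build_mutant",
           "complete_structure", "parse_mutation"]

# first side-chain atom beyond CB, used to align chi1
_GAMMA = ("CG", "CG1", "OG", "OG1", "SG")


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One single-point substitution in author (PDB) numbering."""
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    icode: str = " "

    def __post_init__(self):
        if self.wt_aa not in AA_1TO3 or self.mut_aa not in AA_1TO3:
            raise MutationError(
                f"unknown amino-acid code in {self.wt_aa}->{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise MutationError("wild-type and mutant residues are identical")

    @property
    def site_key(self):
        return (self.chain, self.position, self.icode)

    def label(self):
        return f"{self.chain}:{self.wt_aa}{self.position}{self.mut_aa}"


def parse_mutation(text):
    """Parse ``chain:wtPOSmut`` (e.g. ``A:T217A``) into a MutationSpec."""
    try:
        chain, rest = text.strip().split(":")
        wt, mut = rest[0].upper(), rest[-1].upper()
        pos = int(rest[1:-1])
    except Exception:
        raise MutationError(
            f"cannot parse mutation {text!r}; expected e.g. A:T217A") from None
    return MutationSpec(chain, pos, wt, mut)


def _kabsch(P, Q):
    """Rotation R, translation t minimizing ||R P + t - Q||."""
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, Qc - R @ Pc


def _rotation_about_axis(axis, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _template_atoms(resname):
    names, coords, elements = templates.residue_template(resname)
    return {n: (c, e) for n, c, e in zip(names, coords, elements)}


def _graft_sidechain(res, new_resname):
    """New side-chain heavy atoms for ``res`` with ``new_resname``'s ideal
    geometry, superimposed on the residue backbone and chi1-aligned."""
    tmpl = _template_atoms(new_resname)
    anchor_names = [n for n in ("N", "CA", "C") if res.atom(n) is not None]
    if len(anchor_names) < 3:
        raise MutationError(
            f"residue {res.key} lacks backbone atoms for side-chain grafting")
    P = np.array([tmpl[n][0] for n in anchor_names])
    Q = np.array([res.atom(n).coords for n in anchor_names])
    R, t = _kabsch(P, Q)
    placed = {n: (R @ c + t, e) for n, (c, e) in tmpl.items()}

    # chi1 alignment: rotate about CA-CB so the gamma atom matches wild type
    wt_gamma = next((res.atom(g) for g in _GAMMA if res.atom(g)), None)
    new_gamma_name = next((g for g in _GAMMA if g in placed), None)
    if wt_gamma is not None and new_gamma_name is not None and "CB" in placed:
        ca = res.atom("CA").coords
        cb = placed["CB"][0]
        axis = cb - ca
        v_wt = wt_gamma.coords - cb
        v_new = placed[new_gamma_name][0] - cb
        # project onto plane normal to the axis and measure the angle
        ax = axis / np.linalg.norm(axis)
        p_wt = v_wt - np.dot(v_wt, ax) * ax
        p_new = v_new - np.dot(v_new, ax) * ax
        if np.linalg.norm(p_wt) > 1e-6 and np.linalg.norm(p_new) > 1e-6:
            cosang = np.clip(
                np.dot(p_wt, p_new)
                / (np.linalg.norm(p_wt) * np.linalg.norm(p_new)), -1, 1)
            ang = np.arccos(cosang)
            if np.dot(np.cross(p_new, p_wt), ax) < 0:
                ang = -ang
            rot = _rotation_about_axis(ax, ang)
            placed = {
                n: ((rot @ (c - cb) + cb) if n not in PROTEIN_BACKBONE
                    and n != "CB" else c, e)
                for n, (c, e) in placed.items()
            }

    side = {}
    for n, (c, e) in placed.items():
        if n in PROTEIN_BACKBONE:
            continue
        side[n] = (c, e)
    return side


def build_mutant(wt, spec):
    """Return a copy of ``wt`` with the mutation applied.

    Every residue except the mutated site is untouched; the site keeps its
    backbone and gains an ideal-geometry side chain of the mutant type.
    """
    res = wt.find_residue(spec.chain, spec.position, spec.icode)
    if res is None:
        raise MutationError(
            f"no residue {spec.chain}:{spec.position} in structure")
    if res.kind != "amino-acid":
        raise MutationError(f"residue {res.key} is not an amino acid")
    if res.code != spec.wt_aa:
        raise MutationError(
            f"wild-type mismatch at {spec.chain}:{spec.position}: found "
            f"{res.code}, mutation specifies {spec.wt_aa}")

    out = wt.copy()
    target = out.get_residue(res.key)
    new_name = AA_1TO3[spec.mut_aa]
    side = _graft_sidechain(target, new_name)

    new_atoms = [replace(a, coords=a.coords.copy())
                 for a in target.atoms if not a.is_sidechain]
    for n, (c, e) in sorted(side.items()):
        new_atoms.append(Atom(
            name=n, element=e, coords=np.asarray(c, dtype=float),
            occupancy=1.0, is_sidechain=True, residue_key=target.key))
    target.atoms = new_atoms
    target.name = new_name
    target.code = spec.mut_aa
    out.provenance = dict(out.provenance, mutation=spec.label())
    return out


def complete_structure(cplx):
    """Rebuild missing heavy atoms of standard residues from ideal templates
    (superimposed on the atoms that are present). Returns a new structure and
    the list of (residue key, added atom names)."""
    out = cplx.copy()
    added = []
    for r in out.residues:
        if r.kind == "other":
            continue
        try:
            tmpl = _template_atoms(r.name)
        except KeyError:
            continue
        have = {a.name for a in r.atoms}
        need = [n for n in tmpl if n not in have]
        if r.kind == "nucleotide":
            first = next(x for x in out.residues if x.chain == r.chain)
            if r is first:
                need = [n for n in need if n not in ("P", "OP1", "OP2")]
        if not need:
            continue
        shared = [n for n in tmpl if n in have]
        if len(shared) < 3:
            raise MutationError(
                f"residue {r.key} too incomplete to rebuild ({len(shared)} "
                "anchor atoms)")
        P = np.array([tmpl[n][0] for n in shared])
        Q = np.array([r.atom(n).coords for n in shared])
        R, t = _kabsch(P, Q)
        backbone = (PROTEIN_BACKBONE if r.kind == "amino-acid" else None)
        for n in need:
            c, e = tmpl[n]
            is_side = (n not in PROTEIN_BACKBONE) if backbone else None
            if is_side is None:
                from .structure import RNA_BACKBONE
                is_side = n not in RNA_BACKBONE
            r.atoms.append(Atom(
                name=n, element=e, coords=R @ c + t, occupancy=1.0,
                is_sidechain=is_side, residue_key=r.key))
        added.append((r.key, need))
    return out, added
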