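"""Pairwise force-field energy features.

Three mutation features are energy differences between the minimized mutant
and wild-type complexes:

* ``dd_evdw``   — change in the cross-partner Lennard-Jones energy
  (complex minus unbound partners; with rigid partner extraction this is
  the protein–RNA cross term).
* ``dd_evdw_rep`` — change in the repulsive (r^-12) LJ component between the
  mutated residue and the RNA nucleotides.
* ``dd_eelec``  — change in the Coulomb energy between the mutated residue
  and its contact residues/nucleotides (any side-chain/base atom within
  10 A of any side-chain atom of the site; contacts are recomputed per
  structure).

All sums run over heavy-atom pairs with no cutoff; Coulomb uses
332.0716 kcal*A/(mol*e^2) and a relative dielectric of 1 (gas phase).
"""

from __future__ import annotations

import numpy as np

from .forcefield import COULOMB_CONSTANT, load_default_params

__all__ = ["lj_energy", "lj_repulsive_energy", "contact_set", "elec_energy",
           "dd_evdw", "dd_evdw_rep", "dd_eelec", "EnergyBreakdown",
           "CONTACT_CUTOFF"]

CONTACT_CUTOFF = 10.0  # A


def _group_arrays(pairs, params):
    eps, rmin, q, xyz = params.arrays(pairs)
    return eps, rmin, q, xyz


def _partner_pairs(cplx, chains):
    return [(r, a) for r, a in cplx.atoms(heavy_only=True)
            if r.chain in chains]


def lj_energy(groupA, groupB, params=None):
    """Lennard-Jones cross energy between two disjoint atom groups
    (sequences of (Residue, Atom) pairs), kcal/mol."""
    params = params or load_default_params()
    if not groupA or not groupB:
        return 0.0
    epsA, rmA, _, xA = _group_arrays(groupA, params)
    epsB, rmB, _, xB = _group_arrays(groupB, params)
    r = np.linalg.norm(xA[:, None, :] - xB[None, :, :], axis=-1)
    eps = np.sqrt(epsA[:, None] * epsB[None, :])
    rm = rmA[:, None] + rmB[None, :]
    sr6 = (rm / r) ** 6
    return float(np.sum(eps * (sr6 ** 2 - 2.0 * sr6)))


def lj_repulsive_energy(site_residue, rna_pairs, params=None):
    """Repulsive-only LJ term (eps_ij (r_min,ij / r)^12) between the mutated
    residue's atoms and RNA atoms; non-negative."""
    params = params or load_default_params()
    site_pairs = [(site_residue, a) for a in site_residue.atoms
                  if a.element != "H"]
    if not site_pairs or not rna_pairs:
        return 0.0
    epsA, rmA, _, xA = _group_arrays(site_pairs, params)
    epsB, rmB, _, xB = _group_arrays(rna_pairs, params)
    r = np.linalg.norm(xA[:, None, :] - xB[None, :, :], axis=-1)
    eps = np.sqrt(epsA[:, None] * epsB[None, :])
    rm = rmA[:, None] + rmB[None, :]
    return float(np.sum(eps * (rm / r) ** 12))


def contact_set(cplx, site_key, cutoff=CONTACT_CUTOFF):
    """Residues/nucleotides with any side-chain (protein) or base (RNA) atom
    within ``cutoff`` of any side-chain atom of the mutated site. The site
    itself is excluded; glycine's side chain is represented by its CA."""
    site = cplx.get_residue(site_key)
    site_atoms = site.sidechain_atoms()
    if not site_atoms:
        return set()
    xs = np.array([a.coords for a in site_atoms])
    out = set()
    for r in cplx.residues:
        if r.key == site_key or r.kind == "other":
            continue
        sc = r.sidechain_atoms()
        if not sc:
            continue
        xr = np.array([a.coords for a in sc])
        d = np.linalg.norm(xs[:, None, :] - xr[None, :, :], axis=-1)
        if d.min() < cutoff:
            out.add(r.key)
    return out


def elec_energy(site_residue, contact_residues, params=None):
    """Coulomb energy between every heavy atom of the site and every heavy
    atom of its contact residues (kcal/mol, relative dielectric 1)."""
    params = params or load_default_params()
    site_pairs = [(site_residue, a) for a in site_residue.atoms
                  if a.element != "H"]
    other = [(r, a) for r in contact_residues for a in r.atoms
             if a.element != "H"]
    if not site_pairs or not other:
        return 0.0
    _, _, qA, xA = _group_arrays(site_pairs, params)
    _, _, qB, xB = _group_arrays(other, params)
    r = np.linalg.norm(xA[:, None, :] - xB[None, :, :], axis=-1)
    return float(np.sum(COULOMB_CONSTANT * qA[:, None] * qB[None, :] / r))


def _cross_partner_lj(cplx, params):
    p1 = _partner_pairs(cplx, cplx.partner1)
    p2 = _partner_pairs(cplx, cplx.partner2)
    return lj_energy(p1, p2, params)


def dd_evdw(wt_cplx, mut_cplx, params=None):
    """ddE_vdw = [E(complex) - E(P1) - E(P2)]_mut - [...]_wt; with rigid
    extraction the partner self-terms cancel and this reduces to the change
    in the protein–RNA cross LJ energy."""
    params = params or load_default_params()
    return _cross_partner_lj(mut_cplx, params) - _cross_partner_lj(wt_cplx, params)


def dd_evdw_rep(wt_cplx, mut_cplx, site_key, params=None):
    """Change in site-vs-RNA repulsive LJ energy, mutant minus wild type."""
    params = params or load_default_params()
    out = []
    for cplx in (wt_cplx, mut_cplx):
        site = cplx.get_residue(site_key)
        rna = _partner_pairs(cplx, cplx.partner2)
        out.append(lj_repulsive_energy(site, rna, params))
    return out[1] - out[0]


def dd_eelec(wt_cplx, mut_cplx, site_key, params=None):
    """Change in site-vs-contacts Coulomb energy, mutant minus wild type.
    Contact sets are recomputed independently for each structure."""
    params = params or load_default_params()
    out = []
    for cplx in (wt_cplx, mut_cplx):
        site = cplx.get_residue(site_key)
        contacts = [cplx.get_residue(k) for k in contact_set(cplx, site_key)]
        out.append(elec_energy(site, contacts, params))
    return out[1] - out[0]


class EnergyBreakdown:
    """Convenience container for the three energy terms of one structure
    pair comparison."""

    def __init__(self, e_vdw, e_vdw_repulsive, e_elec, pair_count=0):
        if e_vdw_repulsive < 0:
            raise ValueError("repulsive energy must be >= 0")
        self.e_vdw = e_vdw
        self.e_vdw_repulsive = e_vdw_repulsive
        self.e_elec = e_elec
        self.pair_count = pair_count
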