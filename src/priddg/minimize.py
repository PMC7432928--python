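"""Backbone-restrained energy minimization with a simplified potential.

The built-in backend mimics a restrained gas-phase minimization: harmonic
bond terms and 1-3 (Urey–Bradley-style) distance terms keep covalent
geometry near ideal template values, Lennard-Jones and Coulomb terms act
between all non-bonded heavy-atom pairs within a cutoff, and harmonic
positional restraints hold the backbone atoms of every residue near their
input positions. Minimization runs a fixed number of L-BFGS steps and is
deterministic for a fixed input.

External engines (e.g. a molecular-dynamics package) can be plugged in by
implementing the same ``minimize(structure, settings)`` signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import templates
from .forcefield import COULOMB_CONSTANT, load_default_params

__all__ = ["MinimizationSettings", "MissingAtomsError", "minimize",
           "total_energy", "check_atoms_complete"]

K_BOND = 300.0   # kcal/mol/A^2
K_ANGLE = 60.0   # kcal/mol/A^2 on 1-3 distances
PAIRLIST_SKIN = 2.0  # A


@dataclass(frozen=True)
class MinimizationSettings:
    """Settings of the restrained minimization.

    ``n_steps`` caps the number of minimizer iterations (default 1000);
    ``restraint_k`` is the harmonic force constant on backbone atoms
    (kcal/mol/A^2, default 5); ``nonbonded_cutoff`` truncates LJ/Coulomb
    pair interactions (A, default 12).
    """
    n_steps: int = 1000
    restraint_k: float = 5.0
    nonbonded_cutoff: float = 12.0

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.restraint_k < 0:
            raise ValueError("restraint_k must be >= 0")


class MissingAtomsError(ValueError):
    pass


def check_atoms_complete(cplx):
    """Return a list of (residue key, missing atom names) for standard
    residues whose heavy atoms are incomplete w.r.t. the ideal template."""
    missing = []
    for r in cplx.residues:
        if r.kind == "other":
            continue
        try:
            names, _, _ = templates.residue_template(r.name)
        except KeyError:
            continue
        have = {a.name for a in r.atoms}
        # 5'-terminal nucleotides legitimately lack the phosphate group
        need = [n for n in names if n not in have]
        if r.kind == "nucleotide" and r is _first_in_chain(cplx, r):
            need = [n for n in need if n not in ("P", "OP1", "OP2")]
        if need:
            missing.append((r.key, need))
    return missing


def _first_in_chain(cplx, res):
    for r in cplx.residues:
        if r.chain == res.chain:
            return r
    return None


def _flat_atoms(cplx):
    flat = []
    for r in cplx.residues:
        for a in r.atoms:
            flat.append((r, a))
    return flat


class _EnergyModel:
    """Precomputed term arrays for one structure; evaluates E and dE/dx."""

    def __init__(self, cplx, settings, params):
        self.settings = settings
        flat = _flat_atoms(cplx)
        self.flat = flat
        n = len(flat)
        self.x0 = np.array([a.coords for _, a in flat])
        eps, rmin, q, _ = params.arrays(flat)
        self.eps, self.rmin, self.q = eps, rmin, q

        bonds = templates.build_bond_list(cplx)
        ub = templates.angles_from_bonds(n, bonds)
        self.bonds = np.array(bonds, dtype=int).reshape(-1, 2)
        self.ub = np.array(ub, dtype=int).reshape(-1, 2)
        self.r0_bond = self._reference_lengths(cplx, flat, self.bonds)
        self.r0_ub = self._reference_lengths(cplx, flat, self.ub)

        excluded = {tuple(sorted(b)) for b in bonds}
        excluded.update(tuple(sorted(p)) for p in ub)
        cutoff = settings.nonbonded_cutoff + PAIRLIST_SKIN
        d = np.linalg.norm(self.x0[:, None, :] - self.x0[None, :, :], axis=-1)
        ii, jj = np.nonzero(np.triu(d < cutoff, k=1))
        keep = [k for k, (i, j) in enumerate(zip(ii, jj))
                if (i, j) not in excluded]
        self.nb_i = ii[keep]
        self.nb_j = jj[keep]

        self.backbone = np.array(
            [k for k, (r, a) in enumerate(flat) if not a.is_sidechain],
            dtype=int)

    def _reference_lengths(self, cplx, flat, pairs):
        """Ideal template distance where both atoms sit in one residue's
        template, otherwise the input-structure distance."""
        r0 = np.empty(len(pairs))
        tcoords = {}
        for k, (i, j) in enumerate(pairs):
            ri, ai = flat[i]
            rj, aj = flat[j]
            val = None
            if ri.key == rj.key:
                if ri.name not in tcoords:
                    try:
                        names, xyz, _ = templates.residue_template(ri.name)
                        tcoords[ri.name] = dict(zip(names, xyz))
                    except KeyError:
                        tcoords[ri.name] = {}
                tm = tcoords[ri.name]
                if ai.name in tm and aj.name in tm:
                    val = float(np.linalg.norm(tm[ai.name] - tm[aj.name]))
            if val is None:
                val = float(np.linalg.norm(self.x0[i] - self.x0[j]))
            r0[k] = val
        return r0

    def _pair_terms(self, x, idx_i, idx_j, r0, k):
        if len(idx_i) == 0:
            return 0.0, np.zeros_like(x)
        dx = x[idx_i] - x[idx_j]
        r = np.linalg.norm(dx, axis=1)
        e = k * (r - r0) ** 2
        dEdr = 2.0 * k * (r - r0)
        g = (dEdr / np.maximum(r, 1e-8))[:, None] * dx
        grad = np.zeros_like(x)
        np.add.at(grad, idx_i, g)
        np.add.at(grad, idx_j, -g)
        return float(e.sum()), grad

    def energy_grad(self, xflat):
        x = xflat.reshape(-1, 3)
        s = self.settings
        e_total = 0.0
        grad = np.zeros_like(x)

        e, g = self._pair_terms(x, self.bonds[:, 0], self.bonds[:, 1],
                                self.r0_bond, K_BOND)
        e_total += e
        grad += g
        e, g = self._pair_terms(x, self.ub[:, 0], self.ub[:, 1],
                                self.r0_ub, K_ANGLE)
        e_total += e
        grad += g

        i, j = self.nb_i, self.nb_j
        if len(i):
            dx = x[i] - x[j]
            r = np.linalg.norm(dx, axis=1)
            within = r < s.nonbonded_cutoff
            i, j, dx, r = i[within], j[within], dx[within], r[within]
            r = np.maximum(r, 0.3)  # guard pathological overlaps
            eps_ij = np.sqrt(self.eps[i] * self.eps[j])
            rm_ij = self.rmin[i] + self.rmin[j]
            sr6 = (rm_ij / r) ** 6
            e_lj = eps_ij * (sr6 ** 2 - 2.0 * sr6)
            dEdr_lj = eps_ij * (-12.0 * sr6 ** 2 + 12.0 * sr6) / r
            qq = COULOMB_CONSTANT * self.q[i] * self.q[j]
            e_el = qq / r
            dEdr_el = -qq / r ** 2
            e_total += float(e_lj.sum() + e_el.sum())
            gpair = ((dEdr_lj + dEdr_el) / r)[:, None] * dx
            np.add.at(grad, i, gpair)
            np.add.at(grad, j, -gpair)

        if s.restraint_k > 0 and len(self.backbone):
            dxr = x[self.backbone] - self.x0[self.backbone]
            e_total += float(s.restraint_k * np.sum(dxr ** 2))
            grad[self.backbone] += 2.0 * s.restraint_k * dxr

        return e_total, grad.ravel()


def total_energy(cplx, settings=None, params=None, include_restraints=False):
    """Evaluate the backend potential for a structure (diagnostic)."""
    settings = settings or MinimizationSettings()
    params = params or load_default_params()
    if not include_restraints:
        settings = MinimizationSettings(
            settings.n_steps, 0.0, settings.nonbonded_cutoff)
    model = _EnergyModel(cplx, settings, params)
    e, _ = model.energy_grad(model.x0.ravel())
    return e


def minimize(cplx, settings=None, params=None):
    """Backbone-restrained minimization; returns a new structure.

    The returned structure's (restrained) energy never exceeds the input's;
    with ``n_steps=0`` the coordinates are returned unchanged.
    """
    settings = settings or MinimizationSettings()
    params = params or load_default_params()

    missing = check_atoms_complete(cplx)
    if missing:
        desc = "; ".join(f"{key}: {','.join(names)}" for key, names in missing)
        raise MissingAtomsError(f"incomplete residues: {desc}")

    out = cplx.copy()
    if settings.n_steps == 0:
        out.provenance["minimization"] = {"steps": 0, "e_initial": None,
                                          "e_final": None}
        return out

    model = _EnergyModel(cplx, settings, params)
    x0 = model.x0.ravel()
    e0, _ = model.energy_grad(x0)
    res = _scipy_minimize(
        model.energy_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": settings.n_steps, "maxls": 40},
    )
    xbest, ebest = (res.x, res.fun) if res.fun <= e0 else (x0, e0)

    coords = xbest.reshape(-1, 3)
    k = 0
    for r in out.residues:
        for a in r.atoms:
            a.coords = coords[k].copy()
            k += 1
    out.provenance["minimization"] = {
        "steps": settings.n_steps, "e_initial": float(e0),
        "e_final": float(ebest),
    }
    return out
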