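"""Reduced heavy-atom force-field parameters.

The bundled table maps (residue name, atom name) to Lennard-Jones
``epsilon`` (kcal/mol), ``r_min/2`` (Angstrom) and a partial charge (e).
Charges are integrated onto heavy atoms so that each neutral residue sums to
0 e and charged groups to their neutral-pH formal charge (Asp/Glu -1,
Lys/Arg +1, each ribonucleotide -1 via the phosphate). The file format is
plain TSV so users can substitute their own parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

COULOMB_CONSTANT = 332.0716  # kcal*A/(mol*e^2), CHARMM convention

__all__ = ["ForceFieldParams", "load_default_params", "AtomTypingError",
           "COULOMB_CONSTANT"]


class AtomTypingError(KeyError):
    """An atom has no entry in the parameter table."""


@dataclass(frozen=True)
class ForceFieldParams:
    table: dict  # (resname, atomname) -> (epsilon, rmin_half, charge)

    def lookup(self, resname, atomname):
        try:
            return self.table[(resname, atomname)]
        except KeyError:
            raise AtomTypingError(
                f"no force-field parameters for atom {atomname} of {resname}"
            ) from None

    def arrays(self, residue_atom_pairs):
        """Vectorized parameters for a sequence of (Residue, Atom) pairs:
        returns (epsilon, rmin_half, charge, coords) numpy arrays."""
        eps, rmin, q, xyz = [], [], [], []
        for r, a in residue_atom_pairs:
            e_, rm_, q_ = self.lookup(r.name, a.name)
            eps.append(e_)
            rmin.append(rm_)
            q.append(q_)
            xyz.append(a.coords)
        return (np.array(eps), np.array(rmin), np.array(q),
                np.array(xyz).reshape(-1, 3))

    def residue_charge(self, resname):
        return sum(v[2] for (rn, an), v in self.table.items()
                   if rn == resname and an not in ("OXT", "OP3"))


def _read_table(text):
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, _elem, eps, rmin, charge = line.split("\t")
        table[(res, atom)] = (float(eps), float(rmin), float(charge))
    return table


def load_default_params():
    text = (resources.files("priddg") / "data" / "forcefield.tsv").read_text()
    return ForceFieldParams(_read_table(text))


def load_params(path):
    """Load a user-supplied parameter table (same TSV layout as the bundled one)."""
    with open(path) as fh:
        return ForceFieldParams(_read_table(fh.read()))
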