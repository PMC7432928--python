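"""Deterministic toy structures and synthetic datasets.

Everything the pipeline needs for testing is generated here: idealized
peptide + single-stranded RNA complexes (valid PDB text) and synthetic
mutation datasets with a known linear ground truth. No network access, no
external files; byte-identical output for a fixed seed.

The toy complexes are geometric idealizations, not folded molecules: the
peptide uses canonical backbone dihedrals with template side chains, and the
RNA strand places ideal nucleotides along a helical axis with enough rise to
stay clash-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import templates
from .mutate import _graft_sidechain, _kabsch
from .structure import (AA_1TO3, RNA_BACKBONE, Atom, ComplexStructure,
                        Residue, load_complex, write_pdb)

__all__ = ["make_toy_complex", "make_synthetic_dataset",
           "make_reference_dataset_table", "FEATURE_RANGES"]

# backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

_GEOMETRIES = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}

# helical placement of the toy RNA strand (calibrated once for clash-free
# stacking of rigid ideal nucleotides)
_RNA_TWIST_DEG = 32.7
_RNA_RISE = 6.5
_RNA_RADIUS = 9.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom D from A-B-C with given internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(angle) * bc
                + np.sin(angle) * (np.cos(dihedral) * m + np.sin(dihedral) * n))
    return c + d


def _backbone_trace(phipsi):
    """N/CA/C/O coordinates for a chain with per-residue (phi, psi)."""
    n_res = len(phipsi)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        phi_i = phipsi[i][0]
        psi_prev = phipsi[i - 1][1]
        Nn = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N,
                         psi_prev)
        CAn = _place_atom(CA[i - 1], C[i - 1], Nn, _B_N_CA, _A_C_N_CA, 180.0)
        Cn = _place_atom(C[i - 1], Nn, CAn, _B_CA_C, _A_N_CA_C, phi_i)
        N.append(Nn)
        CA.append(CAn)
        C.append(Cn)
    O = []
    for i in range(n_res):
        psi = phipsi[i][1]
        O.append(_place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O,
                             psi + 180.0))
    return N, CA, C, O


def _hairpin_phipsi(n_res):
    """Dihedrals of a two-stranded antiparallel hairpin: extended strands
    joined by a tight two-residue turn."""
    strand = (-139.0, 135.0)
    turn = [(60.0, -120.0), (-80.0, 0.0)]  # type II' beta turn
    n_strand = (n_res - 2) // 2
    pp = [strand] * n_strand + turn + [strand] * (n_res - 2 - n_strand)
    return pp[:n_res]


def _build_peptide(sequence, geometry, chain_id="A"):
    n_res = len(sequence)
    if geometry == "hairpin":
        phipsi = _hairpin_phipsi(n_res)
    else:
        phipsi = [_GEOMETRIES[geometry]] * n_res
    N, CA, C, O = _backbone_trace(phipsi)
    residues = []
    for i, aa in enumerate(sequence):
        key = (chain_id, i + 1, " ")
        resname = AA_1TO3[aa]
        atoms = [
            Atom("N", "N", N[i], 1.0, False, key),
            Atom("CA", "C", CA[i], 1.0, False, key),
            Atom("C", "C", C[i], 1.0, False, key),
            Atom("O", "O", O[i], 1.0, False, key),
        ]
        res = Residue(key, "amino-acid", aa, resname, atoms)
        if aa != "G":
            side = _graft_sidechain(res, resname)
            for nme, (crd, elem) in sorted(side.items()):
                res.atoms.append(Atom(nme, elem, np.asarray(crd, float),
                                      1.0, True, key))
        residues.append(res)
    return residues


def _build_rna(sequence, chain_id="B"):
    """Rigid ideal nucleotides placed along a helical axis (z)."""
    twist = np.deg2rad(_RNA_TWIST_DEG)
    residues = []
    for i, nt in enumerate(sequence):
        names, coords, elements = templates.residue_template(nt)
        c1_idx = list(names).index("C1'")
        local = coords - coords[c1_idx]
        # deterministic principal-axis orientation: long axis radial (x),
        # flattest axis along the helix (z), so rigid copies stack cleanly
        _, _, Vt = np.linalg.svd(local - local.mean(axis=0))
        axes = Vt.copy()
        for k in range(3):
            if axes[k, np.argmax(np.abs(axes[k]))] < 0:
                axes[k] = -axes[k]
        if np.linalg.det(axes) < 0:
            axes[2] = -axes[2]
        local = local @ axes.T
        th = i * twist
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0],
                       [0, 0, 1.0]])
        origin = np.array([_RNA_RADIUS * np.cos(th),
                           _RNA_RADIUS * np.sin(th),
                           i * _RNA_RISE])
        placed = local @ Rz.T + origin
        key = (chain_id, i + 1, " ")
        atoms = []
        for nme, crd, elem in zip(names, placed, elements):
            if i == 0 and nme in ("P", "OP1", "OP2"):
                continue  # 5' terminal nucleotide has no phosphate
            atoms.append(Atom(nme, elem, crd, 1.0, nme not in RNA_BACKBONE,
                              key))
        residues.append(Residue(key, "nucleotide", nt, nt, atoms))
    return residues


def _min_gap(res_a, res_b):
    xa = np.vstack([r.coords() for r in res_a])
    xb = np.vstack([r.coords() for r in res_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return d.min()


def make_toy_complex(n_res=12, n_nt=6, geometry="helix", separation=4.0,
                     seed=0, peptide_seq=None, rna_seq=None):
    """Generate a toy protein–RNA complex as PDB text.

    The peptide (chain A) is built with ideal dihedrals (``helix``,
    ``extended`` or ``hairpin``); the RNA strand (chain B) is a helical
    stack of ideal nucleotides. The RNA is rigidly translated so that the
    smallest peptide–RNA heavy-atom distance equals ``separation``.
    Deterministic: the same arguments and seed give byte-identical text.
    """
    if n_res < 3 or n_nt < 2:
        raise ValueError("need n_res >= 3 and n_nt >= 2")
    if geometry not in ("helix", "extended", "hairpin"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    aas = "ACDEFHIKLMNQRSTVWY"  # no Gly/Pro in random fills
    if peptide_seq is None:
        peptide_seq = "".join(rng.choice(list(aas), size=n_res))
    if rna_seq is None:
        rna_seq = "".join(rng.choice(list("ACGU"), size=n_nt))
    if len(peptide_seq) != n_res or len(rna_seq) != n_nt:
        raise ValueError("sequence lengths disagree with n_res/n_nt")

    pep = _build_peptide(peptide_seq, geometry)
    rna = _build_rna(rna_seq)

    # center both on the origin, then push the RNA along +x to the gap
    pep_center = np.vstack([r.coords() for r in pep]).mean(axis=0)
    for r in pep:
        for a in r.atoms:
            a.coords = a.coords - pep_center
    rna_center = np.vstack([r.coords() for r in rna]).mean(axis=0)
    for r in rna:
        for a in r.atoms:
            a.coords = a.coords - rna_center

    # move RNA along +x until the minimum heavy-atom gap equals separation
    for r in rna:
        for a in r.atoms:
            a.coords = a.coords + np.array([60.0, 0.0, 0.0])
    for _ in range(12):  # iterate: the closest pair may change as we slide
        gap = _min_gap(pep, rna)
        delta = gap - separation
        if abs(delta) < 0.01:
            break
        for r in rna:
            for a in r.atoms:
                a.coords = a.coords - np.array([delta, 0.0, 0.0])

    cplx = ComplexStructure(
        residues=pep + rna,
        chains=[("A", "protein"), ("B", "RNA")],
        partner1=frozenset("A"),
        partner2=frozenset("B"),
    )
    return write_pdb(cplx, title=f"toy complex seed={seed}")


# plausible marginal ranges for the 11 features in a synthetic dataset
FEATURE_RANGES = {
    "dd_evdw": (-3.0, 3.0),
    "dd_evdw_re": (-2.0, 2.0),
    "dd_eelec": (-5.0, 5.0),
    "n_inter": (2.0, 30.0),
    "r_l_sa": (0.01, 0.04),
    "closeness": (0.05, 0.6),
    "delta_sa": (-80.0, 80.0),
    "p_coil": (0.0, 0.8),
    "delta_omh": (-3.2, 3.2),
    "delta_p_fwy": (-0.02, 0.02),
    "delta_p_krde": (-0.04, 0.04),
}

from .model import FEATURE_NAMES  # noqa: E402  (canonical feature order)

assert list(FEATURE_RANGES) == FEATURE_NAMES


def default_true_model(seed=0):
    """A reference 12-coefficient linear model (intercept + 11 features)
    with effect sizes scaled so each feature contributes comparably."""
    rng = np.random.default_rng(seed)
    coefs = {}
    for name, (lo, hi) in FEATURE_RANGES.items():
        span = (hi - lo) / 2.0
        coefs[name] = float(rng.normal(0.0, 0.5)) / span
    return 0.3, coefs  # intercept, per-feature slopes


def make_synthetic_dataset(true_model=None, n_complexes=50,
                           muts_per_complex=5, noise_sd=0.76, seed=0):
    """Synthetic mutation dataset with a known linear ground truth.

    Feature vectors are drawn uniformly from realistic ranges; the response
    is ``intercept + sum(beta_i * x_i) + N(0, noise_sd)``. Rows are grouped
    into synthetic complexes (``pdb_id``) so leave-one-complex-out
    cross-validation is exercised. Defaults emulate the statistical shape of
    the curated experimental training data: 50 complexes, ~5 mutations each,
    residual spread ~0.76 kcal/mol.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if true_model is None:
        true_model = default_true_model()
    intercept, coefs = true_model
    rng = np.random.default_rng(seed)
    rows = []
    aas = list(AA_1TO3)
    for c in range(n_complexes):
        pdb_id = f"SYN{c:02d}"
        for m in range(muts_per_complex):
            x = {name: float(rng.uniform(lo, hi))
                 for name, (lo, hi) in FEATURE_RANGES.items()}
            y = intercept + sum(coefs[k] * x[k] for k in FEATURE_NAMES)
            y += float(rng.normal(0.0, noise_sd))
            wt, mut = rng.choice(aas, size=2, replace=False)
            rows.append({
                "pdb_id": pdb_id, "protein_chain": "A",
                "position": int(m + 1), "wt_aa": wt, "mut_aa": mut,
                "ddg_exp": y, **x,
            })
    return pd.DataFrame(rows)


def make_reference_dataset_table(seed=0):
    """Synthetic stand-in for the curated experimental training table.

    Reproduces the bookkeeping shape of the curated set: 248 single
    mutations across 50 protein–RNA complexes, of which exactly 124 are
    highly decreasing (ddG_exp >= 1 kcal/mol), with alanine-scanning,
    interface and ssRNA/dsRNA category flags. The ddG values themselves are
    synthetic draws, not experimental measurements.
    """
    rng = np.random.default_rng(seed)
    n_total, n_complexes, n_high = 248, 50, 124
    # mutation counts per complex: at least 1 each, multinomial for the rest
    extra = rng.multinomial(n_total - n_complexes, np.ones(n_complexes) / n_complexes)
    counts = extra + 1
    # exactly 124 highly decreasing mutations
    high = np.zeros(n_total, dtype=bool)
    high[rng.choice(n_total, size=n_high, replace=False)] = True
    rows = []
    aas = list(AA_1TO3)
    k = 0
    for c in range(n_complexes):
        pdb_id = f"TOY{c:02d}"
        ds = bool(rng.random() < 0.3)
        for m in range(counts[c]):
            if high[k]:
                ddg = 1.0 + float(rng.exponential(0.9))
            else:
                ddg = float(rng.normal(0.0, 0.55))
                ddg = min(ddg, 0.99)
            wt = rng.choice(aas)
            is_ala = bool(rng.random() < 0.55)
            mut = "A" if is_ala and wt != "A" else rng.choice(
                [a for a in aas if a != wt])
            rows.append({
                "pdb_id": pdb_id, "protein_chain": "A",
                "position": int(10 + m), "wt_aa": wt, "mut_aa": mut,
                "ddg_exp": round(ddg, 2),
                "alanine_scanning": mut == "A",
                "interface": bool(rng.random() < 0.7),
                "rna_type": "dsRNA" if ds else "ssRNA",
            })
            k += 1
    return pd.DataFrame(rows)
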