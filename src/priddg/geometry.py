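"""SASA-derived structural features.

Interface membership compares a residue's solvent-accessible surface area in
the rigidly extracted unbound partner with its area in the complex: burial
upon binding defines the protein–RNA interface. Derived features: Ninter
(interface amino-acid count), R_L/SA (chain length over unbound-protein
surface area), delta-SA (mutant minus wild-type site area in the unbound
protein), exposure classification (relative area > 0.25) and P_coil (the
fraction of a chain's residues that are both exposed and coil).
"""

from __future__ import annotations

from importlib import resources

from .sasa import compute_sasa
from .secondary import assign_secondary_structure
from .structure import extract_partner

__all__ = ["interface_residues", "n_inter", "ratio_length_sasa", "delta_sa",
           "p_coil", "load_max_asa", "is_exposed", "SASA_TOLERANCE",
           "EXPOSURE_THRESHOLD"]

# > 0.1 A^2 burial counts as interfacial (suppresses lattice noise)
SASA_TOLERANCE = 0.1
EXPOSURE_THRESHOLD = 0.25


def load_max_asa():
    """Per-residue-type maximum ASA (Gly-X-Gly reference), A^2."""
    text = (resources.files("priddg") / "data" / "max_asa.tsv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, v = line.split("\t")
        table[aa] = float(v)
    return table


def interface_residues(cplx, probe=1.4, n_points=960,
                       sasa_complex=None, sasa_p1=None, sasa_p2=None):
    """Residue keys (either partner) buried upon binding.

    A residue is interfacial iff its SASA in the unbound partner exceeds its
    SASA in the complex by more than ``SASA_TOLERANCE``. Precomputed SASA
    results may be passed to avoid recomputation.
    """
    if sasa_complex is None:
        sasa_complex = compute_sasa(cplx, probe, n_points)
    if sasa_p1 is None:
        sasa_p1 = compute_sasa(extract_partner(cplx, 1), probe, n_points)
    if sasa_p2 is None:
        sasa_p2 = compute_sasa(extract_partner(cplx, 2), probe, n_points)
    out = set()
    for r in cplx.residues:
        if r.chain in cplx.partner1:
            unbound = sasa_p1
        elif r.chain in cplx.partner2:
            unbound = sasa_p2
        else:
            continue
        if (unbound.residue_area(r.key)
                > sasa_complex.residue_area(r.key) + SASA_TOLERANCE):
            out.add(r.key)
    return out


def n_inter(cplx, interface=None, **kw):
    """Number of amino acids at the protein–RNA binding interface
    (nucleotides are never counted)."""
    if interface is None:
        interface = interface_residues(cplx, **kw)
    keys = {r.key for r in cplx.residues if r.kind == "amino-acid"}
    return len(interface & keys)


def ratio_length_sasa(protein, sasa=None, probe=1.4, n_points=960):
    """Protein length / unbound-protein SASA (residues per A^2)."""
    if sasa is None:
        sasa = compute_sasa(protein, probe, n_points)
    n_res = sum(1 for r in protein.residues if r.kind == "amino-acid")
    if sasa.total <= 0:
        raise ValueError("degenerate structure: zero surface area")
    return n_res / sasa.total


def delta_sa(wt_protein, mut_protein, site_key, probe=1.4, n_points=960,
             sasa_wt=None, sasa_mut=None):
    """Mutant minus wild-type SASA of the mutated residue, both measured in
    the unbound protein extracted from the corresponding minimized complex."""
    wt_protein.get_residue(site_key)   # raise KeyError if absent
    mut_protein.get_residue(site_key)
    if sasa_wt is None:
        sasa_wt = compute_sasa(wt_protein, probe, n_points)
    if sasa_mut is None:
        sasa_mut = compute_sasa(mut_protein, probe, n_points)
    return sasa_mut.residue_area(site_key) - sasa_wt.residue_area(site_key)


def is_exposed(residue, sasa_complex, max_asa=None):
    """Exposure rule: SASA in the complex over the residue type's maximum
    reference ASA exceeds 0.25."""
    if max_asa is None:
        max_asa = load_max_asa()
    ref = max_asa.get(residue.code)
    if not ref:
        return False
    return sasa_complex.residue_area(residue.key) / ref > EXPOSURE_THRESHOLD


def p_coil(cplx, chain_id, sasa_complex=None, ss=None, probe=1.4,
           n_points=960, max_asa=None):
    """Fraction of the chain's residues that are exposed (in the complex)
    and in coil conformation."""
    if sasa_complex is None:
        sasa_complex = compute_sasa(cplx, probe, n_points)
    if ss is None:
        ss = assign_secondary_structure(cplx)
    if max_asa is None:
        max_asa = load_max_asa()
    chain = [r for r in cplx.chain_residues(chain_id)
             if r.kind == "amino-acid"]
    if not chain:
        return 0.0
    n_ec = sum(
        1 for r in chain
        if ss.labels.get(r.key) == "coil"
        and is_exposed(r, sasa_complex, max_asa)
    )
    return n_ec / len(chain)
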