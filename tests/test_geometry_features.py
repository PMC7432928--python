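import numpy as np
import pytest

from priddg import fixtures
from priddg.geometry import (delta_sa, interface_residues, is_exposed,
                             load_max_asa, n_inter, p_coil, ratio_length_sasa)
from priddg.mutate import MutationSpec, build_mutant
from priddg.sasa import compute_sasa
from priddg.secondary import SecondaryStructureAssignment
from priddg.structure import extract_partner, load_complex

N_PTS = 240  # coarse lattice keeps these tests quick


def _brute_force_interface(cplx):
    sc = compute_sasa(cplx, n_points=N_PTS)
    s1 = compute_sasa(extract_partner(cplx, 1), n_points=N_PTS)
    s2 = compute_sasa(extract_partner(cplx, 2), n_points=N_PTS)
    out = set()
    for r in cplx.residues:
        unbound = s1 if r.chain in cplx.partner1 else s2
        if unbound.residue_area(r.key) > sc.residue_area(r.key) + 0.1:
            out.add(r.key)
    return out


def test_interface_contains_contacting_residues_only(toy_complex):
    iface = interface_residues(toy_complex, n_points=N_PTS)
    assert iface == _brute_force_interface(toy_complex)
    assert iface, "docked toy complex must have an interface"
    # the residue closest to the RNA is interfacial, the farthest is not
    rna = np.vstack([r.coords() for r in toy_complex.residues
                     if r.chain == "B"])
    dists = {}
    for r in toy_complex.chain_residues("A"):
        d = np.linalg.norm(r.coords()[:, None, :] - rna[None, :, :], axis=-1)
        dists[r.key] = d.min()
    assert min(dists, key=dists.get) in iface
    assert max(dists, key=dists.get) not in iface


def test_separated_partners_have_empty_interface(separated_complex):
    assert interface_residues(separated_complex, n_points=N_PTS) == set()
    assert n_inter(separated_complex, n_points=N_PTS) == 0


def test_interface_invariant_to_chain_order(toy_pdb_text):
    lines = toy_pdb_text.splitlines()
    a = [l for l in lines if l.startswith("ATOM") and l[21] == "A"]
    b = [l for l in lines if l.startswith("ATOM") and l[21] == "B"]
    swapped = load_complex("\n".join(b + ["TER"] + a + ["TER", "END"]) + "\n")
    ref = load_complex(toy_pdb_text)
    assert (interface_residues(swapped, n_points=N_PTS)
            == interface_residues(ref, n_points=N_PTS))


def test_n_inter_counts_amino_acids_only(toy_complex):
    iface = interface_residues(toy_complex, n_points=N_PTS)
    protein_keys = {r.key for r in toy_complex.residues
                    if r.kind == "amino-acid"}
    expected = len(iface & protein_keys)
    assert n_inter(toy_complex, interface=iface) == expected
    assert n_inter(toy_complex, interface=iface) <= len(protein_keys)


def test_ratio_length_sasa_value_and_invariances(toy_complex):
    protein = extract_partner(toy_complex, 1)
    s = compute_sasa(protein, n_points=N_PTS)
    ratio = ratio_length_sasa(protein, sasa=s)
    assert ratio == pytest.approx(12.0 / s.total)

    # rigid rotation leaves the ratio unchanged
    rot = protein.copy()
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    for r in rot.residues:
        for a in r.atoms:
            a.coords = R @ a.coords
    assert ratio_length_sasa(rot, n_points=N_PTS) == pytest.approx(
        ratio_length_sasa(protein, n_points=N_PTS), rel=0.01)


def test_duplicating_the_chain_far_away_preserves_the_ratio(toy_complex):
    protein = extract_partner(toy_complex, 1)
    doubled = protein.copy()
    clone = protein.copy()
    for r in clone.residues:
        key = ("C", r.key[1], r.key[2])
        r.key = key
        for a in r.atoms:
            a.coords = a.coords + np.array([200.0, 0.0, 0.0])
            a.residue_key = key
    doubled.residues = doubled.residues + clone.residues
    doubled.chains = doubled.chains + [("C", "protein")]
    r1 = ratio_length_sasa(protein, n_points=N_PTS)
    r2 = ratio_length_sasa(doubled, n_points=N_PTS)
    assert r2 == pytest.approx(r1, rel=0.01)


def test_delta_sa_zero_for_identical_structures(toy_complex):
    protein = extract_partner(toy_complex, 1)
    site = protein.residues[4].key
    assert delta_sa(protein, protein, site, n_points=N_PTS) == 0.0


def test_delta_sa_negative_for_large_to_small_substitution(toy_complex):
    # an exposed bulky residue replaced by alanine exposes less area
    protein = extract_partner(toy_complex, 1)
    res = protein.residues[5]
    spec = MutationSpec("A", res.key[1], res.code,
                        "W" if res.code != "W" else "F")
    big = build_mutant(protein, spec)
    back = MutationSpec("A", res.key[1], spec.mut_aa, "A")
    small = build_mutant(big, back)
    d = delta_sa(big, small, res.key, n_points=N_PTS)
    assert d < 0


def test_delta_sa_missing_site_raises(toy_complex):
    protein = extract_partner(toy_complex, 1)
    with pytest.raises(KeyError):
        delta_sa(protein, protein, ("A", 999, " "), n_points=N_PTS)


def test_p_coil_matches_brute_force_count(toy_complex):
    from priddg.secondary import assign_secondary_structure
    sc = compute_sasa(toy_complex, n_points=N_PTS)
    ss = assign_secondary_structure(toy_complex)
    max_asa = load_max_asa()
    chain = [r for r in toy_complex.chain_residues("A")]
    n_ec = sum(1 for r in chain
               if ss[r.key] == "coil" and is_exposed(r, sc, max_asa))
    expected = n_ec / len(chain)
    assert p_coil(toy_complex, "A", sasa_complex=sc, ss=ss) == \
        pytest.approx(expected)


def test_p_coil_zero_when_nothing_is_coil(toy_complex):
    labels = {r.key: "helix" for r in toy_complex.chain_residues("A")}
    ss = SecondaryStructureAssignment(labels)
    assert p_coil(toy_complex, "A", ss=ss, n_points=N_PTS) == 0.0


def test_p_coil_equals_coil_fraction_when_fully_exposed():
    # a fully extended solvated chain: every residue exposed, so P_coil
    # collapses to the coil fraction
    txt = fixtures.make_toy_complex(10, 2, "extended", 80.0, seed=4)
    c = load_complex(txt)
    from priddg.secondary import assign_secondary_structure
    ss = assign_secondary_structure(c)
    sc = compute_sasa(c, n_points=N_PTS)
    max_asa = load_max_asa()
    chain = c.chain_residues("A")
    assert all(is_exposed(r, sc, max_asa) for r in chain)
    coil_frac = sum(1 for r in chain if ss[r.key] == "coil") / len(chain)
    assert p_coil(c, "A", sasa_complex=sc, ss=ss) == pytest.approx(coil_frac)
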