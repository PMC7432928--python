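import numpy as np
import pytest

from priddg.energy import (CONTACT_CUTOFF, contact_set, dd_eelec, dd_evdw,
                           dd_evdw_rep, elec_energy, lj_energy,
                           lj_repulsive_energy)
from priddg.forcefield import (COULOMB_CONSTANT, AtomTypingError,
                               ForceFieldParams, load_default_params)
from priddg.structure import Atom, Residue

TOL = 1e-8


def _pair_structure(r, eps=0.086, rmin2=2.0, q=0.0):
    """Two single-atom residues separated by r with custom parameters."""
    params = ForceFieldParams({("XXX", "X1"): (eps, rmin2, q),
                               ("XXX", "X2"): (eps, rmin2, q)})
    a = Residue(("A", 1, " "), "other", "X", "XXX",
                [Atom("X1", "C", [0.0, 0.0, 0.0], 1.0, True, ("A", 1, " "))])
    b = Residue(("B", 1, " "), "other", "X", "XXX",
                [Atom("X2", "C", [r, 0.0, 0.0], 1.0, True, ("B", 1, " "))])
    return a, b, params


def _brute_lj(groupA, groupB, params):
    total = 0.0
    for rA, aA in groupA:
        eA, rmA, _ = params.lookup(rA.name, aA.name)
        for rB, aB in groupB:
            eB, rmB, _ = params.lookup(rB.name, aB.name)
            r = float(np.linalg.norm(aA.coords - aB.coords))
            eps = (eA * eB) ** 0.5
            rm = rmA + rmB
            total += eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
    return total


def _brute_coulomb(groupA, groupB, params):
    total = 0.0
    for rA, aA in groupA:
        _, _, qA = params.lookup(rA.name, aA.name)
        for rB, aB in groupB:
            _, _, qB = params.lookup(rB.name, aB.name)
            r = float(np.linalg.norm(aA.coords - aB.coords))
            total += COULOMB_CONSTANT * qA * qB / r
    return total


def _partner_atoms(cplx, partner):
    chains = cplx.partner1 if partner == 1 else cplx.partner2
    return [(r, a) for r, a in cplx.atoms(heavy_only=True)
            if r.chain in chains]


def test_lj_minimum_is_minus_epsilon():
    a, b, params = _pair_structure(r=4.0, eps=0.25, rmin2=2.0)
    e = lj_energy([(a, a.atoms[0])], [(b, b.atoms[0])], params)
    assert e == pytest.approx(-0.25, abs=1e-12)


def test_lj_vanishes_at_large_separation():
    a, b, params = _pair_structure(r=500.0)
    e = lj_energy([(a, a.atoms[0])], [(b, b.atoms[0])], params)
    assert abs(e) < 1e-10


def test_lj_matches_brute_force_on_toy_interface(toy_complex, ff_params):
    p1 = _partner_atoms(toy_complex, 1)
    p2 = _partner_atoms(toy_complex, 2)
    assert len(p1) > 30 and len(p2) > 40
    fast = lj_energy(p1, p2, ff_params)
    slow = _brute_lj(p1, p2, ff_params)
    assert fast == pytest.approx(slow, abs=TOL)


def test_untypeable_atom_raises_naming_it(toy_complex, ff_params):
    r = toy_complex.residues[0]
    bad = Residue(("A", 99, " "), "other", "X", "UNK",
                  [Atom("QQ", "C", [0, 0, 0], 1.0, True, ("A", 99, " "))])
    with pytest.raises(AtomTypingError, match="QQ"):
        lj_energy([(bad, bad.atoms[0])], [(r, r.atoms[0])], ff_params)


def test_repulsive_energy_nonnegative_and_decaying(toy_complex, ff_params):
    site = toy_complex.chain_residues("A")[5]
    rna = _partner_atoms(toy_complex, 2)
    e = lj_repulsive_energy(site, rna, ff_params)
    assert e >= 0
    # push the RNA far away: repulsion goes to ~0
    far = [(r, Atom(a.name, a.element, a.coords + np.array([300.0, 0, 0]),
                    1.0, a.is_sidechain, a.residue_key)) for r, a in rna]
    assert lj_repulsive_energy(site, far, ff_params) < 1e-12


def test_repulsive_energy_matches_brute_force(toy_complex, ff_params):
    site = toy_complex.chain_residues("A")[5]
    rna = _partner_atoms(toy_complex, 2)
    fast = lj_repulsive_energy(site, rna, ff_params)
    slow = 0.0
    for a in site.atoms:
        eA, rmA, _ = ff_params.lookup(site.name, a.name)
        for rB, aB in rna:
            eB, rmB, _ = ff_params.lookup(rB.name, aB.name)
            r = float(np.linalg.norm(a.coords - aB.coords))
            slow += (eA * eB) ** 0.5 * ((rmA + rmB) / r) ** 12
    assert fast == pytest.approx(slow, abs=TOL)


def test_repulsion_increases_as_rna_approaches(toy_complex, ff_params):
    site = min(toy_complex.chain_residues("A"),
               key=lambda r: min(np.linalg.norm(a.coords) for a in r.atoms))
    rna = _partner_atoms(toy_complex, 2)
    e0 = lj_repulsive_energy(site, rna, ff_params)
    # translate RNA 0.5 A toward the protein (along -x in fixture frame)
    closer = [(r, Atom(a.name, a.element, a.coords - np.array([0.5, 0, 0]),
                       1.0, a.is_sidechain, a.residue_key)) for r, a in rna]
    e1 = lj_repulsive_energy(site, closer, ff_params)
    assert e1 > e0


def test_contact_set_empty_for_isolated_residue(separated_complex):
    # in the separated complex no RNA base is near any protein side chain
    site = separated_complex.chain_residues("A")[5].key
    contacts = contact_set(separated_complex, site)
    assert all(k[0] != "B" for k in contacts)


def test_contact_set_symmetric_between_residues(toy_complex):
    keys = [r.key for r in toy_complex.chain_residues("A")]
    for u in keys:
        cu = contact_set(toy_complex, u)
        for v in cu:
            if v in keys:
                assert u in contact_set(toy_complex, v)


def test_contact_set_matches_brute_force(toy_complex):
    site = toy_complex.chain_residues("A")[4]
    got = contact_set(toy_complex, site.key)
    expected = set()
    site_sc = site.sidechain_atoms()
    for r in toy_complex.residues:
        if r.key == site.key:
            continue
        for a in r.sidechain_atoms():
            if any(np.linalg.norm(a.coords - b.coords) < CONTACT_CUTOFF
                   for b in site_sc):
                expected.add(r.key)
                break
    assert got == expected


def test_coulomb_closed_form_unit_charges():
    a, b, params = _pair_structure(r=3.32, q=1.0)
    e = elec_energy(a, [b], params)
    assert e == pytest.approx(COULOMB_CONSTANT / 3.32, abs=1e-9)
    assert e == pytest.approx(100.02, abs=0.01)


def test_coulomb_zero_for_neutral_charges():
    a, b, params = _pair_structure(r=3.0, q=0.0)
    assert elec_energy(a, [b], params) == 0.0


def test_coulomb_matches_brute_force(toy_complex, ff_params):
    site = toy_complex.chain_residues("A")[4]
    contacts = [toy_complex.get_residue(k)
                for k in contact_set(toy_complex, site.key)]
    fast = elec_energy(site, contacts, ff_params)
    site_pairs = [(site, a) for a in site.atoms]
    other = [(r, a) for r in contacts for a in r.atoms]
    slow = _brute_coulomb(site_pairs, other, ff_params)
    assert fast == pytest.approx(slow, abs=TOL)


def test_dd_terms_vanish_for_identical_structures(toy_complex, ff_params):
    site = toy_complex.chain_residues("A")[4].key
    assert dd_evdw(toy_complex, toy_complex, ff_params) == 0.0
    assert dd_evdw_rep(toy_complex, toy_complex, site, ff_params) == 0.0
    assert dd_eelec(toy_complex, toy_complex, site, ff_params) == 0.0


def test_dd_evdw_equals_cross_partner_difference(toy_complex, ff_params):
    from priddg.mutate import MutationSpec, build_mutant
    res = toy_complex.chain_residues("A")[5]
    spec = MutationSpec("A", res.key[1], res.code,
                        "G" if res.code != "G" else "A")
    mut = build_mutant(toy_complex, spec)
    expected = (lj_energy(_partner_atoms(mut, 1), _partner_atoms(mut, 2),
                          ff_params)
                - lj_energy(_partner_atoms(toy_complex, 1),
                            _partner_atoms(toy_complex, 2), ff_params))
    assert dd_evdw(toy_complex, mut, ff_params) == pytest.approx(
        expected, abs=TOL)


def test_energies_invariant_under_rigid_rotation(toy_complex, ff_params):
    theta = 1.1
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    rot = toy_complex.copy()
    for r in rot.residues:
        for a in r.atoms:
            a.coords = R @ a.coords + np.array([3.0, -2.0, 7.0])
    p1a, p2a = _partner_atoms(toy_complex, 1), _partner_atoms(toy_complex, 2)
    p1b, p2b = _partner_atoms(rot, 1), _partner_atoms(rot, 2)
    assert lj_energy(p1a, p2a, ff_params) == pytest.approx(
        lj_energy(p1b, p2b, ff_params), abs=1e-7)
    site = toy_complex.chain_residues("A")[4].key
    assert dd_evdw_rep(toy_complex, rot, site, ff_params) == pytest.approx(
        0.0, abs=1e-7)


def test_glycine_mutation_cannot_increase_site_repulsion(toy_complex,
                                                         ff_params):
    from priddg.mutate import MutationSpec, build_mutant
    iface_res = min(
        toy_complex.chain_residues("A"),
        key=lambda r: min(np.linalg.norm(a.coords - b.coords)
                          for a in r.atoms
                          for rr in toy_complex.chain_residues("B")
                          for b in rr.atoms))
    if iface_res.code == "G":
        pytest.skip("fixture site already glycine")
    spec = MutationSpec("A", iface_res.key[1], iface_res.code, "G")
    mut = build_mutant(toy_complex, spec)
    d = dd_evdw_rep(toy_complex, mut, spec.site_key, ff_params)
    assert d <= 1e-9  # smaller side chain, geometry otherwise fixed


def test_contact_sets_are_recomputed_per_structure():
    # a mutation to a bulky side chain gains contacts the wild type lacks,
    # so per-structure recomputation matters
    from priddg import fixtures
    from priddg.mutate import MutationSpec, build_mutant
    from priddg.structure import load_complex
    txt = fixtures.make_toy_complex(12, 6, "extended", 11.0, seed=1)
    c = load_complex(txt)
    rna = np.vstack([r.coords() for r in c.residues if r.chain == "B"])
    res = min(c.chain_residues("A"),
              key=lambda r: np.linalg.norm(
                  r.coords()[:, None, :] - rna[None, :, :], axis=-1).min())
    spec = MutationSpec("A", res.key[1], res.code,
                        "W" if res.code != "W" else "R")
    mut = build_mutant(c, spec)
    wt_contacts = contact_set(c, spec.site_key)
    mut_contacts = contact_set(mut, spec.site_key)
    assert mut_contacts - wt_contacts
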