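"""Extract the 11 scoring features for one mutation of a toy complex.

Builds a 12-residue helical peptide docked against a 6-nucleotide RNA
strand, mutates one interface residue, relaxes both structures, and prints
each feature with a one-line meaning.
"""

from priddg import fixtures, load_complex
from priddg.minimize import MinimizationSettings
from priddg.model import WildTypeContext, featurize
from priddg.mutate import MutationSpec

MEANING = {
    "dd_evdw": "change in protein-RNA van der Waals energy (kcal/mol)",
    "dd_evdw_re": "change in site-vs-RNA steric repulsion (kcal/mol)",
    "dd_eelec": "change in site-vs-contacts Coulomb energy (kcal/mol)",
    "n_inter": "amino acids at the binding interface (count)",
    "r_l_sa": "protein length over unbound surface area (res/A^2)",
    "closeness": "network centrality of the mutated site (0..1)",
    "delta_sa": "change in the site's exposed area (A^2)",
    "p_coil": "fraction of chain residues exposed and in coil (0..1)",
    "delta_omh": "hydrophobicity change, mutant minus wild type",
    "delta_p_fwy": "change in the chain's aromatic fraction",
    "delta_p_krde": "change in the chain's net-charge fraction",
}

pdb_text = fixtures.make_toy_complex(n_res=12, n_nt=6, geometry="helix",
                                     separation=4.0, seed=1)
cplx = load_complex(pdb_text)
context = WildTypeContext(cplx, MinimizationSettings(n_steps=200))

site = cplx.chain_residues("A")[4]
spec = MutationSpec("A", site.key[1], site.code,
                    "A" if site.code != "A" else "G")
print(f"complex: {len(cplx.chain_residues('A'))}-residue peptide + "
      f"{len(cplx.chain_residues('B'))}-nt RNA")
print(f"mutation: {spec.label()} "
      f"(interface: {'yes' if context.is_interfacial(site.key) else 'no'})\n")

fv = featurize(cplx, spec, context=context)
for name, value in fv.as_dict().items():
    print(f"{name:>13s} = {value:9.4f}   {MEANING[name]}")
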