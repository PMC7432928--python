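# Methods

## Model

`priddg` predicts the change in protein–RNA binding free energy upon a
single amino-acid substitution as a linear function of 11 features,

    ddG_pred = b0 + sum_i b_i x_i ,

with positive values meaning the mutation decreases binding affinity. The
features are computed from the energy-minimized wild-type and mutant
complex structures and from the mutated chain's sequence; the coefficients
are obtained by ordinary least squares against experimentally measured ddG
values. A linear model was chosen deliberately: with only a few hundred
training mutations, interpretable per-feature contributions and low
variance matter more than flexibility, and collinearity is monitored via
variance inflation factors (all < 3 on the synthetic training shape).

## Structure handling

PDB input is parsed with Bio.PDB. Waters are stripped; alternate locations
resolve to the highest occupancy (ties by altloc code); for multi-model
(NMR) files the first model is used unless requested otherwise; for
crystal structures the caller supplies the biological-assembly file. Chains
are typed protein/RNA by majority residue content; partner 1 collects the
protein chains and partner 2 the RNA chains. Complexes without at least one
chain of each type are rejected. A small set of common chemically modified
residues is mapped to parent types with a warning; if a mapped residue
turns out to lie at the binding interface the complex is rejected during
feature extraction, mirroring the curation rule for modified interface
residues. Second partners containing non-RNA nucleic acids are rejected
rather than guessed at. Author (PDB) residue numbering is preserved
throughout and mutation positions are interpreted in it.

Unbound partners are produced by rigid extraction: the bound conformation
is kept and only the other partner's chains are dropped. This makes the
cross-partner energy differences exact algebraic identities and is the
standard convention for structure-based ddG features.

## Mutant construction and minimization

The mutant side chain is grafted from an ideal-geometry residue template
(the chemical component dictionary bundled with biotite): the template is
superimposed on the site's backbone (N, CA, C), and when both wild type and
mutant have a gamma atom the new side chain is rotated about the CA–CB axis
to match the wild-type chi1 direction. No rotamer search is performed — the
scheme is deterministic, and the subsequent minimization relieves local
strain. Missing heavy atoms of incomplete residues are rebuilt from the
same templates.

Both structures are relaxed with the built-in backend: a simplified
molecular-mechanics potential with harmonic bond terms and 1–3 distance
terms (reference values from the ideal templates, inter-residue references
from the input geometry), Lennard-Jones and Coulomb nonbonded terms within
a 12 A cutoff, and harmonic positional restraints (default 5 kcal/mol/A^2)
on backbone atoms of all residues. L-BFGS runs a fixed number of
iterations (default 1000); the output energy never exceeds the input and
`n_steps=0` is an exact identity. The potential operates on heavy atoms
only, with partial charges integrated onto heavy atoms so each neutral
residue sums to 0 e and Asp/Glu/Lys/Arg and each ribonucleotide carry
their neutral-pH formal charge. Ionization states are fixed at neutral-pH
defaults; no pKa calculation is attempted. The backend is a contract —
an external minimization engine can be substituted by providing the same
`minimize(structure, settings)` signature — and the bundled parameter set
is a plain TSV (atom, LJ epsilon, r_min/2, charge) that users can swap.

## Features

*Energies.* LJ and Coulomb sums run over heavy-atom pairs with no cutoff
(the 12 A cutoff applies only inside minimization). Combination rules are
Lorentz–Berthelot; the Coulomb constant is 332.0716 kcal*A/(mol*e^2) with
relative dielectric 1 (gas phase). ddE_vdw is the mutant-minus-wild-type
change of the complex-minus-partners LJ difference; with rigid extraction
this equals the change in the protein–RNA cross term. ddE_vdw.re keeps only
the repulsive r^-12 component between the mutated residue and the RNA.
ddE_elec sums Coulomb terms between the mutated residue and its contact
residues/nucleotides — those with any side-chain (protein) or base (RNA)
atom within 10 A of any side-chain atom of the site. Contact sets are
recomputed independently for wild type and mutant; glycine's side-chain
set is represented by its CA so the set is never empty. Bonded-pair
exclusions are immaterial here because no bonded pair crosses the
partner–partner or site–contact boundaries being summed.

*SASA.* Shrake–Rupley with a deterministic golden-spiral lattice (default
960 points/atom, probe 1.4 A) over heavy atoms, with a bundled
Chothia-style element radius table. Residues are interfacial when their
SASA in the rigidly extracted unbound partner exceeds their SASA in the
complex by more than 0.1 A^2 (the tolerance suppresses lattice noise on a
nominally strict inequality). Exposure divides the residue's SASA in the
complex by a per-residue-type maximum ASA (Gly-X-Gly extended tripeptide
reference, bundled) with threshold 0.25.

*Secondary structure.* A three-class re-implementation of the
hydrogen-bond-pattern assignment: amide hydrogens are rebuilt from the
backbone, the Kabsch–Sander electrostatic H-bond energy is thresholded at
-0.5 kcal/mol, n-turn patterns give helix (3/4/5-turn classes), bridge
patterns give strand, everything else is coil. Only the 3-class collapse
is exposed because only the coil label enters the model.

*Network.* Nodes are Calpha atoms of all protein chains (a configurable
choice; the text definition does not restrict the network to the mutated
chain); edges join pairs closer than 6 A (strict). Closeness is
(n-1)/sum of shortest-path distances, computed with NetworkX; on
disconnected graphs the Wasserman–Faust component scaling applies, which
reduces to the plain formula on connected graphs, and isolated nodes score
0 by convention.

*Sequence.* dOMH uses the bundled optimal-matching hydrophobicity scale;
dP_FWY and dP_KR-DE are mutant-minus-wild-type changes of the aromatic and
net-charge fractions of the mutated chain. The chain length is the number
of residues resolved in the structure, consistent with the other
structure-derived features.

## Fitting and evaluation

OLS is fit with statsmodels; diagnostics are per-coefficient t-test
p-values, |t| importance and variance inflation factors. Features are not
standardized before fitting, so coefficients stay in natural units;
standardized importance is available through |t|. Rank-deficient designs
raise an error naming the collinear columns. Models serialize to a
documented JSON file; none is bundled — a model must be fit to a ddG table
before prediction.

Curation of raw training tables applies, in order: per-row validity,
modified residues at the interface, protein < 20 residues or RNA < 5
nucleotides, metal-coordination sites, RNA structure-vs-assay sequence
identity below 80% (global alignment, matches over the longer length;
the exact similarity method behind the 80% rule is not fixed by the
problem statement, so this choice is configurable), and consolidation of
repeat measurements (averaged when their range is < 1 kcal/mol, rejected
otherwise).

CV1/CV2 repeat random 50/50 and 80/20 mutation splits (default 100
rounds); their aggregate is the arithmetic mean of per-round R and RMSE.
CV3 leaves one complex out per fold and reports metrics on the pooled
out-of-fold predictions, including AUC-ROC (trapezoidal), AUC-PR (step
interpolation) and the maximal MCC over all distinct prediction
thresholds, with positives defined by experimental ddG >= 1 kcal/mol.
RMSE is sqrt(mean squared residual); the slope is from the least-squares
line of experimental on predicted values. Splits are unstratified and all
randomness flows from an explicit seed.

## Synthetic data and what the tests show

The fixture generator produces two kinds of input. Toy complexes are
geometric idealizations — a peptide with canonical dihedrals (helix,
extended, or a type II' beta-hairpin) and template side chains, docked at a
controlled gap against a clash-free helical stack of ideal nucleotides.
They exercise every structural code path (parsing, mutation, minimization,
SASA, secondary structure, networks, energies) deterministically, but they
are not folded molecules: absolute feature values on real complexes will
differ, and passing tests demonstrate correctness of the computations, not
predictive accuracy on real data.

Synthetic datasets draw the 11 features uniformly from plausible ranges
and generate responses from a known linear model plus Gaussian noise with
0.76 kcal/mol standard deviation, grouped into 50 synthetic complexes of
~5 mutations — the statistical shape of the curated experimental training
set (248 mutations / 50 complexes / 124 highly decreasing, which the
reference-shaped table reproduces exactly). Because the features are drawn
independently, the synthetic data lack the inter-feature correlation and
per-complex clustering of real data; they validate the estimator
(parameter recovery, CV machinery, metric formulas), not the biology.

## Numerical choices and limitations

Sphere-lattice SASA is deterministic but orientation-dependent at the ~1%
level at 960 points; tests use coarser lattices with matching tolerances.
Exactly coincident atoms are counted once via an index-ordered tie-break.
The minimizer's pair list is built once from the input geometry with a 2 A
skin. Closed-shell checks (LJ minimum at r_min = -epsilon, Coulomb of unit
charges at 3.32 A = 100.02 kcal/mol) pin the unit conventions.

Known limitations: single substitutions only (effects of multiple
mutations are not additive and are out of scope); no explicit solvent,
ions or pKa shifts; no rotamer search in mutant building; DNA or hybrid
second partners are rejected; mmCIF input and assembly generation from
symmetry operators are not supported (supply the assembly file).
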