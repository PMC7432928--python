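"""Protein–RNA complex structures: PDB parsing, chain typing, partner extraction.

A complex is held as a flat list of residues in file order. Chains are
classified as protein or RNA from their residue content; partner 1 collects
the protein chains and partner 2 the RNA chains, mirroring the convention of
binding-affinity calculations where DG_bind = E(complex) - E(P1) - E(P2).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "StructureFormatError",
    "CompositionError",
    "load_complex",
    "classify_chain",
    "extract_partner",
    "write_pdb",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
RNA_CODES = {"A", "C", "G", "U"}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Common chemically modified residues mapped to their parent type.
MODIFIED_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "HYP": "PRO", "MLY": "LYS", "PCA": "GLU",
    "PSU": "U", "1MA": "A", "5MC": "C", "OMC": "C", "7MG": "G",
    "M2G": "G", "2MG": "G", "OMG": "G", "H2U": "U", "4SU": "U", "5MU": "U",
}

PROTEIN_BACKBONE = {"N", "CA", "C", "O", "OXT"}
# RNA backbone = phosphate + ribose; base atoms count as the "side chain"
RNA_BACKBONE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed as PDB."""


class CompositionError(ValueError):
    """Raised when a complex lacks a protein or an RNA partner."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float
    is_sidechain: bool
    residue_key: tuple

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")


@dataclass
class Residue:
    key: tuple  # (chain id, residue number, insertion code)
    kind: str  # "amino-acid" | "nucleotide" | "other"
    code: str  # 1-letter code ("X" for other)
    name: str  # PDB residue name
    atoms: list = field(default_factory=list)

    @property
    def chain(self):
        return self.key[0]

    def atom(self, name):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self):
        return np.array([a.coords for a in self.atoms])

    def sidechain_atoms(self):
        """Side-chain heavy atoms; for glycine the CA stands in (no side chain)."""
        sc = [a for a in self.atoms if a.is_sidechain and a.element != "H"]
        if not sc and self.kind == "amino-acid":
            ca = self.atom("CA")
            if ca is not None:
                sc = [ca]
        return sc


@dataclass
class ComplexStructure:
    residues: list
    chains: list  # [(chain id, "protein"|"RNA"|"other"), ...] in file order
    partner1: frozenset  # protein chain ids
    partner2: frozenset  # RNA chain ids
    provenance: dict = field(default_factory=dict)

    def chain_ids(self):
        return [c for c, _ in self.chains]

    def chain_type(self, chain_id):
        for c, t in self.chains:
            if c == chain_id:
                return t
        raise KeyError(chain_id)

    def chain_residues(self, chain_id):
        return [r for r in self.residues if r.chain == chain_id]

    def chain_sequence(self, chain_id):
        return "".join(r.code for r in self.chain_residues(chain_id))

    def get_residue(self, key):
        chain, num, icode = key
        for r in self.residues:
            if r.key == (chain, num, icode):
                return r
        raise KeyError(f"no residue {key}")

    def find_residue(self, chain, number, icode=" "):
        try:
            return self.get_residue((chain, number, icode))
        except KeyError:
            return None

    def atoms(self, heavy_only=False):
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.element == "H":
                    continue
                yield r, a

    def n_atoms(self):
        return sum(len(r.atoms) for r in self.residues)

    def copy(self):
        residues = [
            replace(r, atoms=[replace(a, coords=a.coords.copy()) for a in r.atoms])
            for r in self.residues
        ]
        return ComplexStructure(
            residues, list(self.chains), self.partner1, self.partner2,
            dict(self.provenance),
        )


def classify_chain(residues):
    """Classify a chain as ``protein``, ``RNA`` or ``other`` by majority content."""
    if not residues:
        raise ValueError("cannot classify an empty chain")
    n_aa = sum(1 for r in residues if r.kind == "amino-acid")
    n_nt = sum(1 for r in residues if r.kind == "nucleotide")
    n = len(residues)
    if n_aa > n / 2:
        return "protein"
    if n_nt > n / 2:
        return "RNA"
    return "other"


def _residue_kind(resname):
    if resname in AA_3TO1:
        return "amino-acid", AA_3TO1[resname]
    if resname in RNA_CODES:
        return "nucleotide", resname
    return "other", "X"


def _pick_altloc(bio_atom):
    """Resolve a possibly disordered atom to one location: highest occupancy,
    ties broken by altloc code order."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def load_complex(pdb_text, model_index=0, partner1=None, partner2=None):
    """Parse PDB text into a :class:`ComplexStructure`.

    Parameters
    ----------
    pdb_text : str
        PDB-format text (a crystal biological assembly or NMR multi-model
        file; for NMR files the first model is used unless ``model_index``
        says otherwise).
    model_index : int
        Which MODEL to keep (0-based; default first).
    partner1, partner2 : iterable of str, optional
        Explicit chain ids for the protein and RNA partner. By default all
        protein chains form partner 1 and all RNA chains partner 2.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            struct = parser.get_structure("cplx", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureFormatError(f"cannot parse PDB text: {exc}") from exc
    models = list(struct.get_models())
    if not models:
        raise StructureFormatError("no models in PDB text")
    if model_index >= len(models):
        raise StructureFormatError(
            f"model_index {model_index} out of range ({len(models)} models)")
    model = models[model_index]

    residues = []
    chain_order = []
    modified = []
    for bio_chain in model:
        chain_id = bio_chain.id
        for bio_res in bio_chain:
            resname = bio_res.get_resname().strip()
            if resname in WATER_NAMES:
                continue
            if resname in MODIFIED_PARENT:
                parent = MODIFIED_PARENT[resname]
                warnings.warn(
                    f"modified residue {resname} {bio_res.id[1]} in chain "
                    f"{chain_id} mapped to parent {parent}")
                het, num, icode = bio_res.id
                modified.append((chain_id, num, icode))
                resname = parent
            kind, code = _residue_kind(resname)
            het, num, icode = bio_res.id
            key = (chain_id, num, icode)
            backbone = PROTEIN_BACKBONE if kind == "amino-acid" else RNA_BACKBONE
            atoms = []
            for bio_atom in bio_res:
                a = _pick_altloc(bio_atom)
                element = (a.element or "").strip() or a.get_name()[0]
                if element == "H" or element == "D":
                    continue  # heavy-atom model
                name = a.get_name().strip()
                atoms.append(Atom(
                    name=name,
                    element=element,
                    coords=np.asarray(a.get_coord(), dtype=float),
                    occupancy=float(a.get_occupancy() or 1.0),
                    is_sidechain=name not in backbone,
                    residue_key=key,
                ))
            if atoms:
                residues.append(Residue(key, kind, code, resname, atoms))
            if chain_id not in chain_order:
                chain_order.append(chain_id)

    chains = []
    for cid in chain_order:
        rs = [r for r in residues if r.chain == cid]
        if rs:
            chains.append((cid, classify_chain(rs)))

    type_of = dict(chains)
    if partner1 is None:
        partner1 = frozenset(c for c, t in chains if t == "protein")
    else:
        partner1 = frozenset(partner1)
    if partner2 is None:
        partner2 = frozenset(c for c, t in chains if t == "RNA")
    else:
        partner2 = frozenset(partner2)
        bad = [c for c in partner2 if type_of.get(c) != "RNA"]
        if bad:
            raise CompositionError(
                f"partner 2 must contain only RNA chains; got {sorted(bad)}")
    if not partner1:
        raise CompositionError("no protein chain in complex")
    if not partner2:
        raise CompositionError("no RNA chain in complex")
    if partner1 & partner2:
        raise CompositionError("partner chain sets overlap")

    return ComplexStructure(
        residues=residues,
        chains=chains,
        partner1=partner1,
        partner2=partner2,
        provenance={
            "model_index": model_index,
            "n_models": len(models),
            "modified_residues": modified,
        },
    )


def extract_partner(cplx, partner):
    """Rigid extraction of partner 1 (protein) or 2 (RNA): coordinates are
    untouched, only the selected chains are retained (the unbound conformation
    is taken to be the bound one)."""
    if partner not in (1, 2):
        raise ValueError("partner must be 1 or 2")
    keep = cplx.partner1 if partner == 1 else cplx.partner2
    if not keep:
        raise CompositionError(f"partner {partner} is empty")
    residues = [r for r in cplx.residues if r.chain in keep]
    chains = [(c, t) for c, t in cplx.chains if c in keep]
    return ComplexStructure(
        residues=residues,
        chains=chains,
        partner1=cplx.partner1 & keep,
        partner2=cplx.partner2 & keep,
        provenance=dict(cplx.provenance, extracted_partner=partner),
    )


def write_pdb(cplx_or_residues, title=None):
    """Serialize to PDB-format text (ATOM records, 3-decimal coordinates)."""
    residues = getattr(cplx_or_residues, "residues", cplx_or_residues)
    lines = []
    if title:
        lines.append(f"TITLE     {title[:70]}")
    serial = 1
    prev_chain = None
    for r in residues:
        chain, num, icode = r.key
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        for a in r.atoms:
            name = a.name
            # PDB column rules: 1-3 char names start in column 14
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                "ATOM  {:>5d} {:<4s}{:1s}{:>3s} {:1s}{:>4d}{:1s}   "
                "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2s}".format(
                    serial, pad, " ", r.name[:3], str(chain)[:1], int(num),
                    icode if icode.strip() else " ",
                    a.coords[0], a.coords[1], a.coords[2],
                    a.occupancy, 0.0, a.element[:2],
                )
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
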