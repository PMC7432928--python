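"""Sequence-based mutation features.

Three features depend only on the mutated chain's sequence: the change in
optimal-matching hydrophobicity (OMH) between mutant and wild-type residue
types, and the changes in the chain's aromatic fraction P_FWY = N_FWY/N and
net-charge fraction P_KR-DE = (N_KR - N_DE)/N. The chain length N is the
number of residues resolved in the structure.
"""

from __future__ import annotations

from importlib import resources

from .structure import AA_1TO3

__all__ = ["load_omh_scale", "delta_omh", "composition_deltas"]

AROMATIC = set("FWY")
POSITIVE = set("KR")
NEGATIVE = set("DE")


def load_omh_scale():
    """The bundled optimal-matching hydrophobicity scale (20 amino acids)."""
    text = (resources.files("priddg") / "data" / "omh.tsv").read_text()
    scale = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, v = line.split("\t")
        scale[aa] = float(v)
    return scale


def delta_omh(wt_aa, mut_aa, scale=None):
    """OMH(mutant) - OMH(wild type)."""
    if scale is None:
        scale = load_omh_scale()
    for aa in (wt_aa, mut_aa):
        if aa not in scale:
            raise KeyError(f"amino acid {aa!r} not in hydrophobicity scale")
    return scale[mut_aa] - scale[wt_aa]


def composition_deltas(chain_seq, position_index, wt_aa, mut_aa):
    """(dP_FWY, dP_KR-DE) for substituting ``wt_aa``->``mut_aa`` at the
    0-based ``position_index`` of ``chain_seq``.

    Both are mutant-minus-wild-type differences of per-chain fractions; a
    single substitution shifts each numerator by at most 1 (2 for P_KR-DE
    when a positive residue swaps with a negative one).
    """
    n = len(chain_seq)
    if n == 0:
        raise ValueError("empty chain sequence")
    if not 0 <= position_index < n:
        raise ValueError(f"position index {position_index} outside chain")
    if chain_seq[position_index] != wt_aa:
        raise ValueError(
            f"sequence has {chain_seq[position_index]!r} at index "
            f"{position_index}, mutation specifies {wt_aa!r}")
    if mut_aa not in AA_1TO3:
        raise ValueError(f"unknown amino acid {mut_aa!r}")

    d_fwy = ((mut_aa in AROMATIC) - (wt_aa in AROMATIC)) / n
    d_krde = (((mut_aa in POSITIVE) - (mut_aa in NEGATIVE))
              - ((wt_aa in POSITIVE) - (wt_aa in NEGATIVE))) / n
    return d_fwy, d_krde
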