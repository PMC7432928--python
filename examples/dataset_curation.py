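"""Apply the training-set curation filters to a raw mutation table.

Demonstrates every rejection rule: short protein/RNA partners, modified
residues at the interface, metal coordination sites, RNA sequence mismatch
between structure and assay, and consolidation of repeat measurements.
"""

import pandas as pd

from priddg.evaluate import curate_dataset

raw = pd.DataFrame({
    "pdb_id":          ["1AAA", "1BBB", "1CCC", "1DDD", "1EEE", "1EEE"],
    "protein_chain":   ["A"] * 6,
    "position":        [10, 20, 30, 40, 50, 50],
    "wt_aa":           ["T", "K", "S", "R", "Y", "Y"],
    "mut_aa":          ["A", "E", "A", "A", "F", "F"],
    "ddg_exp":         [0.5, 1.2, 2.0, 0.8, 1.4, 1.6],
    "protein_length":  [150, 19, 300, 88, 120, 120],
    "rna_length":      [30, 12, 4, 25, 40, 40],
    "metal_site":      [False, False, False, True, False, False],
    "rna_seq_structure": ["ACGUACGUAC", None, None, None, None, None],
    "rna_seq_assay":     ["ACGUACGAGG", None, None, None, None, None],
})

curated, report = curate_dataset(raw)
print("rejections / consolidations:")
for ident, rule in report:
    print(f"  row {ident}: {rule}")
print(f"\nkept {len(curated)} of {len(raw)} rows:")
print(curated[["pdb_id", "wt_aa", "position", "mut_aa", "ddg_exp"]]
      .to_string(index=False))
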