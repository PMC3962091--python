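"""Measure a molecule's maximal linear dimension from PDB coordinates.

Builds a synthetic structure whose point-set diameter is known exactly
(57.95 A — the size scale of a TNF-alpha monomer), writes it as PDB text,
reads it back through the default atom selection and measures it.
"""

from memflux import (SyntheticStructureSpec, make_structure, max_dimension,
                     read_structure)

spec = SyntheticStructureSpec(diameter=57.95, n_atoms=500, seed=7)
model, pdb_text = make_structure(spec)

parsed = read_structure(pdb_text)          # first model, no H, no waters
result = max_dimension(parsed)

print(f"atoms measured : {result.n_atoms}")
print(f"d_max          : {result.d_max_A:.3f} A = {result.d_max_nm:.4f} nm")
print(f"endpoint atoms : {result.endpoints}")
# d_max is the largest pairwise atom distance — the molecule's maximal
# dimension, the size that governs steric hindrance in a pore.
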