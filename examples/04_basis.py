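"""The vector space of headache diagnosis.

Exact row reduction of the matrix finds the pivot columns: the minimal
set of basis characteristics whose linear combinations span every
phenotype row.  Dropping the "probable" diagnoses (all-but-one-criterion
categories) yields the basis for definitive diagnoses.  Elimination is
done in exact rational arithmetic — rank must never hinge on a floating
point epsilon.
"""

from ichd_matrix import basis_characteristics, bundled_matrix

m = bundled_matrix()
definitive = basis_characteristics(m, include_probable=False)
everything = basis_characteristics(m, include_probable=True)

print(f"matrix: {m.shape[0]} phenotypes x {m.shape[1]} characteristics")
print(f"basis for definitive diagnoses: {len(definitive)} characteristics")
print(f"basis including probable diagnoses: {len(everything)} characteristics "
      f"({m.shape[1] - len(everything)} dependent columns)\n")
print("first 15 basis characteristics (definitive diagnoses):")
for label in definitive[:15]:
    print(f"  {label}")
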