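"""Expand disorder criteria into phenotypes.

Loads the bundled ICHD-3 primary headache encoding and shows how a
disorder's Boolean criteria formula unfolds into its phenotypes — the
conjunctive clauses of its disjunctive normal form, each one a matrix
row.  NDPH, a pure conjunction, yields a single phenotype; migraine
without aura ("at least two of four" pain characteristics, nausea/
vomiting or photophobia+phonophobia) yields twelve.
"""

from ichd_matrix import bundled_criteria
from ichd_matrix.dnf import enumerate_phenotypes

cs = bundled_criteria()
print(f"{len(cs.disorders)} disorders over {len(cs.universe)} characteristics\n")

for disorder_id in ("ndph", "migrainewoaura"):
    d = cs.disorder(disorder_id)
    phenotypes = enumerate_phenotypes(d)
    print(f"{d.name} ({d.id}): {len(phenotypes)} phenotype(s)")
    for p in phenotypes[:3]:
        print(f"  {p.name}: {', '.join(sorted(p.characteristics))}")
    if len(phenotypes) > 3:
        print(f"  ... and {len(phenotypes) - 3} more")
    print()

print("phenotype counts per disorder:")
for d in cs.disorders:
    print(f"  {d.id:26s} {len(enumerate_phenotypes(d)):4d}")
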