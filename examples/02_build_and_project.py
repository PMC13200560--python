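"""Build the biadjacency matrix and compute bipartite projections.

The matrix rows are phenotypes, columns are characteristics.  Projecting
onto one axis links two nodes by the number of neighbors they share on
the other axis: strongly linked characteristics co-occur in many
phenotypes, strongly linked phenotypes share many characteristics.  The
chronicity pair ("greater than 15 days per month" / "more than 3
months") dominates because every chronic migraine and chronic
tension-type phenotype carries both.
"""

from ichd_matrix import bundled_matrix, project, top_weight_pairs

m = bundled_matrix()
print(f"matrix: {m.shape[0]} phenotypes x {m.shape[1]} characteristics, "
      f"{int(m.values.sum())} ones\n")

gc = project(m, "characteristics")
for rank in (1, 2, 3):
    w, pairs = top_weight_pairs(gc, rank)
    print(f"characteristic weight rank {rank}: {w} ({len(pairs)} pair(s))")
    for u, v in pairs[:5]:
        print(f"   {u}  --  {v}")

print()
gp = project(m, "phenotypes")
w, pairs = top_weight_pairs(gp, 1)
print(f"top phenotype-pair weight: {w}; all top pairs are chronic migraine: "
      f"{all(u.startswith('cm') and v.startswith('cm') for u, v in pairs)}")
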