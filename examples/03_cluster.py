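"""Markov clustering of the criteria graph.

Runs MCL on the full bipartite adjacency at a chosen (inflation,
expansion) setting and at the high-expansion sensitivity settings, where
flow overshoots the graph and almost everything merges.  The four
nummular-headache characteristics are joined by a logical AND and share
no edge with the rest of the classification, so no parameter choice can
split them apart — a useful tracer for parameter effects.
"""

from ichd_matrix import bundled_matrix, MCLParams, bipartite_to_adjacency, mcl, modularity

m = bundled_matrix()
labels, adj = bipartite_to_adjacency(m)
print(f"graph: {len(labels)} nodes ({m.shape[0]} phenotypes + {m.shape[1]} "
      f"characteristics)\n")

for expansion, inflation in [(3, 3.3), (2, 2.0), (9, 1.5), (9, 3.3)]:
    clustering = mcl(adj, labels, MCLParams(expansion=expansion, inflation=inflation))
    q = modularity(adj, clustering, labels)
    nummular = [c for c in clustering.clusters
                if "c:sharply contoured" in c]
    intact = len(nummular) == 1 and {
        "c:fixed in size and shape", "c:sharply contoured",
        "c:1 to 6 cm in diameter", "c:round or elliptical",
    } <= nummular[0]
    print(f"expansion={expansion} inflation={inflation}: "
          f"{clustering.n_clusters:3d} clusters, Q={q:+.4f}, "
          f"nummular block intact: {intact}")
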