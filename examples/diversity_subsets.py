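"""Build a Tanimoto diversity subset and expand a hit back into the library.

A clustered synthetic library stands in for a redundant screening library:
sphere exclusion keeps one representative per cluster of near-duplicates,
and a similarity-band query later recovers the neighbors of a promising
representative for a second screening round.
"""

from pgpscreen import diversity_subset, gen_ligand_library, similarity_expand

# 60 molecules in 12 clusters of near-duplicates (~0.9 Tanimoto within)
lib, labels = gen_ligand_library(60, 12, within_cluster_similarity=0.9,
                                 seed=11)

subset = diversity_subset(lib, cutoff=0.85)
print(f"sphere exclusion at cutoff {subset.cutoff}: "
      f"{len(subset.retained_ids)}/{len(lib)} retained")
# every excluded molecule is covered by one retained representative
example_excluded = next(iter(subset.assignment))
print(f"e.g. {example_excluded} is represented by "
      f"{subset.assignment[example_excluded]} at similarity "
      f"{subset.similarities[example_excluded]:.2f}")

# expand one representative back into the full library: the 70–99% band
# pulls in its cluster mates but not the molecule itself (similarity 1.0)
query = lib.get(subset.retained_ids[0])
neighbors = similarity_expand([query], lib, band=(0.70, 0.99))
print(f"\nband [0.70, 0.99] neighbors of {query.ligand_id}:")
for nid, sim in neighbors[query.ligand_id]:
    print(f"  {nid}  similarity {sim:.3f}")
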