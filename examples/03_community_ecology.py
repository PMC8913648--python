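"""Community ecology of simulated fecal cultures: diversity, ordination,
and K-means taxonomic-response clusters.

Generates replicate fecal-culture abundance tables across donors, averages
replicates, computes Shannon diversity and richness per culture, embeds the
Bray-Curtis dissimilarities with non-metric multidimensional scaling, and
clusters glycans by their abundance shifts relative to no-glycan controls.
"""

import numpy as np

import glycoferm as gf

cfg = gf.simulate.SimConfig(seed=3, n_donors=4)
taxa, meta, _ = gf.simulate.generate_taxa_tables(cfg)

shannon = [gf.community.shannon(row) for row in taxa.to_numpy()]
richness = [gf.community.richness(row, threshold=1e-3) for row in taxa.to_numpy()]
print(f"{len(taxa)} cultures: Shannon {np.mean(shannon):.2f} +/- "
      f"{np.std(shannon):.2f} nats, richness {np.mean(richness):.1f} taxa "
      "(> 0.1% abundance)")

mean_tab, mean_meta = gf.community.average_replicates(taxa, meta)
d = gf.community.bray_curtis_matrix(mean_tab)
res = gf.community.nmds(d, restarts=20, seed=0)
print(f"NMDS of Bray-Curtis dissimilarities: Kruskal stress-1 = "
      f"{res.stress:.4f} ({'converged' if res.converged else 'not converged'})")

resp = gf.community.response_matrix(mean_tab, mean_meta).drop(index="none")
assignment, info = gf.community.kmeans_cluster(resp, k="elbow", seed=0, kmax=6)
print(f"taxonomic-response clusters (K-means, elbow): K = {assignment.k}")
for g in sorted(set(assignment.labels)):
    members = [i for i, l in zip(assignment.ids, assignment.labels) if l == g]
    print(f"  cluster {g}: {members}")
print("\nGlycans in the same response cluster shift the same genera in the"
      "\nsame direction relative to the no-glycan control; low NMDS stress"
      "\nmeans the 2-D map preserves the dissimilarity ranking faithfully.")
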