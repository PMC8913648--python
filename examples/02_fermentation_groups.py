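"""Cluster glycans into fermentation groups and test class enrichment.

Simulates 100 glycans drawn from five fermentation-dynamic archetypes,
Z-scores the twelve kinetic descriptors, clusters with Manhattan distance /
complete linkage, picks the number of groups by the elbow of the
within-cluster sum of squares, and checks whether reference glycans are
enriched in particular groups (Fisher exact test).
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import glycoferm as gf

cfg = gf.simulate.SimConfig(seed=1, n_glycans=100)
plate, truth = gf.simulate.generate_plate_timeseries(cfg)
_, per_glycan = gf.pipeline.phenotype_plate(plate, cfg.ph_model)

assignment, tree, wcss = gf.pipeline.cluster_fermentation(per_glycan, k="elbow")
print(f"elbow-selected number of fermentation groups: k = {assignment.k}")
sizes = pd.Series(assignment.labels).value_counts().sort_index()
print("group sizes:", dict(sizes))

truth_labels = truth.set_index("glycan_id")["true_group"].loc[list(assignment.ids)]
print(f"adjusted Rand index vs planted archetypes: "
      f"{adjusted_rand_score(truth_labels, assignment.labels):.3f}")

classes = truth.set_index("glycan_id")["compound_class"].loc[list(assignment.ids)]
enrich = gf.ferm_cluster.class_enrichment(assignment, classes.to_numpy())
ref = enrich[enrich["class"] == "reference"].sort_values("p_value")
print("\nreference-glycan enrichment per group (Fisher exact, two-sided):")
print(ref[["group", "a", "b", "p_value"]].to_string(index=False))
print("\nSmall p-values mark groups dominated by reference glycans, i.e."
      "\nfast fermenters; an ARI of 1.0 means the planted groups were"
      "\nrecovered exactly.")
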