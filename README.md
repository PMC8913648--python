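# glycoferm

Analysis pipeline for ex vivo glycan fermentation screens: calibrated
pH/growth kinetic phenotyping of anaerobic fecal cultures, clustering of
glycans into fermentation groups and taxonomic-response clusters, community
diversity and ordination, cross-donor differential abundance of genera and
CAZyme families, internal-standard SCFA quantification, and the
group-comparison statistics used for intervention experiments.  A
synthetic-data generator with planted ground truth emulates every input the
pipeline consumes, so the whole stack is testable without instrument data.

The package is aimed at microbiome researchers running plate-based
fermentation screens (glycans or other substrates) who want a reproducible,
desk-checkable path from raw kinetic tables and abundance matrices to
fermentation groups, response clusters and statistics.

## The methods in brief

**pH calibration.** Culture pH is read ratiometrically with BCECF: the
pH-sensitive 485/540 signal over the isosbestic 450/540 signal.  A standard
curve of medium at known pH is fit with a four-parameter logistic in pH,

  R(pH) = R_min + (R_max − R_min) / (1 + exp(−s·(pH − pH_mid))),

and sample ratios are inverted analytically (out-of-range ratios are clamped
to the dynamic range and flagged).

**Kinetic phenotyping.** OD600 and pH curves are smoothed with a
Savitzky–Golay filter (window 9, degree 2 by default); derivatives come from
the local polynomial.  Twelve descriptors are extracted per culture — od_max,
t_od_max, μ_max, t_μmax, lag time (tangent construction), OD AUC, pH_start,
pH_min, t_pHmin, max acidification rate −dpH/dt, its time, and ΔpH.

**Fermentation groups.** Descriptors are Z-scored across glycans, clustered
hierarchically (Manhattan distance, complete linkage, deterministic
lowest-index tie rule), the number of groups is picked at the elbow
(maximum chord distance) of the within-cluster sum-of-squares curve over
tree cuts, and compound-class enrichment per group is tested with the
two-sided Fisher exact test.

**Community analysis.** Replicates are averaged per (donor, glycan); each
glycan's species profile is expressed as a difference versus the no-glycan
control; K-means (k-means++, best of 25 restarts) with elbow-selected K
groups glycans by taxonomic response.  Shannon diversity (natural log),
richness, Bray–Curtis dissimilarity BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), and non-metric
multidimensional scaling (isotonic regression alternated with Guttman
updates, Kruskal stress-1) summarize community structure.

**Differential abundance.** Per feature and glycan, log2 fold changes versus
each donor's control (pseudocount 1e-5) are summarized by the cross-donor
median; significance comes from a linear mixed model on rank-transformed
abundances, rank = β₀ + β·treatment + u_donor + ε, with a likelihood-ratio
test for β and Benjamini–Hochberg FDR control; the display filter keeps
features with q < 0.05 and |median log2FC| > 1 on at least one glycan and
clusters their profiles (Euclidean, complete linkage).

**SCFA quantification.** Analyte peak areas are normalized by the internal
standard and calibrated against 2.5–40 mM standards with a 1/x-weighted
(x = detector response) linear fit; concentrations are back-calculated from
the line.

**Statistics.** Self-contained two-sided Fisher exact, Wilcoxon rank-sum
(exact by enumeration for n+m ≤ 20 without ties), Kruskal–Wallis with Dunn's
post-hoc comparisons (Holm-adjusted), two-group log-rank, trapezoid AUC for
body-weight trajectories, and Pearson/Spearman correlation.

## Worked example

`examples/` contains one short script per capability.  Running
`python examples/02_fermentation_groups.py` simulates a 100-glycan screen
from the five default fermentation archetypes and recovers them:

```
elbow-selected number of fermentation groups: k = 5
group sizes: {1: 20, 2: 20, 3: 20, 4: 20, 5: 20}
adjusted Rand index vs planted archetypes: 1.000

reference-glycan enrichment per group (Fisher exact, two-sided):
 group  a  b      p_value
     1 20  0 2.571843e-10
     4 20  0 2.571843e-10
     2  0 20 1.387536e-05
```

The elbow on the within-cluster sum-of-squares curve selects five groups;
the adjusted Rand index of 1.0 means the partition matches the planted
archetype labels exactly; the tiny Fisher p-values show the two
reference-glycan archetypes (fast fermenters) are perfectly enriched in
groups 1 and 4.

There is also a thin CLI over the same library code:

```
glycoferm simulate --seed 1 --out run/
glycoferm calibrate-ph --standards run/ph_standards.tsv --out run/model.txt
glycoferm phenotype --plate run/plate.csv --model run/model.txt --out run/
glycoferm cluster-ferm --profiles run/profiles.tsv --out run/
```

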