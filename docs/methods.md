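# Methods notes

This note records the models, parameter choices, numerical conventions and
known limitations behind each stage of the pipeline, in the spirit of the
model documentation shipped with simulation and statistics packages.

## Synthetic study generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream guarantee is stated.

**Kinetic plates.** Growth is a four-parameter logistic
OD(t) = OD0 + K/(1 + exp(−r(t − tm))) with additive Gaussian noise
(SD 0.01 OD by default, a typical plate-reader noise floor).  Acidification
is a falling logistic from pH_start to pH_floor whose midpoint trails the
growth midpoint by 1 h, with maximum rate `acidification_rate` (the logistic
steepness is 4·rate/span), plus an optional linear rebound ramp toward the
end of the run.  Fluorescence channels are synthesized by pushing the true
pH through a known 4PL ratio model (R_min 0.5, R_max 3.0, midpoint pH 6.8,
slope 1.1 per pH unit) with 1% relative noise per channel; headspace
pressure is a logistic scaled from the carrying capacity with 0.05 psi
noise.  Cultures are sampled every 0.5 h for 45 h in triplicate — the
screen's culture duration and replication — which also gives smooth
derivatives for the phenotyping stage.

**Default archetypes.** Five fermentation-dynamic archetypes mirror the
canonical group shapes: fast acidic reference fermenters, slow large
growers, weak fermenters, fast fermenters with a strong pH rebound, and
moderate fermenters with deep gradual acidification.  Two design constraints
matter and are deliberate:

1. *Decorrelated axes.* The five differ along several independent
   descriptor axes (growth magnitude, timing, pH depth, acidification rate,
   rebound) with scrambled orderings, so no single fast-versus-slow axis
   dominates the between-group geometry.  Near-equidistant groups make the
   within-cluster sum-of-squares curve fall roughly linearly until k equals
   the number of planted groups and flatten after, which is the shape the
   chord-distance elbow rule detects.  With groups strung along one dominant
   axis the elbow genuinely sits at the macro-split (k = 2–3) — that is a
   property of the elbow heuristic, not a defect of the clustering.
2. *Anchored extrema.* Every archetype rebounds at least slightly
   (0.05–0.7 pH), so the time-of-pH-minimum descriptor is well defined; on a
   perfectly flat tail the argmin is noise-driven and the descriptor carries
   pure within-group variance.  The time-of-OD-maximum descriptor still
   jitters for early-saturating curves, and the starting pH is common to all
   archetypes (same medium), so one to two of the twelve Z-scored
   descriptors are uninformative noise dimensions — a realistic property the
   clustering must (and does) tolerate.

Documented separation margin: neighboring archetypes differ by ≥ 0.2 OD in
carrying capacity or ≥ 4 h in midpoint, and by ≥ 0.3 pH in floor; at default
noise this is several within-group SDs in the informative descriptors.

**Abundance tables.** Per donor, a baseline composition is drawn from a
Dirichlet around a shared lognormal profile (precision 50·n_taxa);
treatment multiplies planted taxa by 2^effect before renormalization, and
replicates are Dirichlet draws with precision 500 (tight technical
replicates).  A no-glycan control is always included per donor.  Because
the data are compositional, a planted +2 log2 effect on a taxon at a few
percent abundance realizes as slightly less than +2 after closure, and
unplanted taxa acquire small negative shifts; the display filter
(|log2FC| > 1) is what separates planted responders from closure spillover.
An optional pathogen spike fixes a designated taxon at 8% of the expected
composition, emulating OD-normalized pathogen spike-in cultures.  A
configurable `base_profile` overrides the lognormal profile when a scenario
needs controlled (e.g. uniform) baseline abundances.

**SCFA peaks.** Detector response is linear with zero intercept:
analyte area = slope·conc·IS_area·(1 + noise); standards are generated at
the calibration levels 2.5, 10, 15, 20, 30, 40 mM.  **Survival/weights.**
Exponential event times with constant per-day group hazards, censored at the
horizon (14 d); body weights start at 100% and drift linearly per group.

What the generator does **not** emulate: mechanistic fermentation or
metabolic dynamics, sequencing reads and their error modes (tables arrive as
relative abundances), inter-plate batch effects, non-logistic growth
(diauxie, death phase), or donor-by-treatment interaction in the planted
effects (effects are conserved across donors by construction — which is the
cross-donor conservation scenario the mixed model is meant to detect).
Passing tests therefore certify the pipeline's correctness and calibration
under these idealized conditions, not performance on real screens.

## pH calibration

The 4PL is parameterized as a logistic in pH, not the EC50/Hill
concentration form, because pH is the natural abscissa and the analytic
inverse is needed downstream.  Fitting is Levenberg–Marquardt least squares
initialized from data quantiles (asymptotes near the observed ratio range,
midpoint at the pH closest to half-range, slope sign from the linear trend)
with 5 jittered restarts; the best RSS wins.  A response whose variance is
below 1e-12 raises an "unidentifiable curve" error.  The inverse clamps
ratios outside (R_min+ε, R_max−ε), ε = 1e-9, to the corresponding bound and
flags them rather than extrapolating, since the inverse diverges at the
asymptotes.  Blank subtraction is not performed; the ratio is taken on raw
channel intensities.

## Kinetic phenotyping

Smoothing is Savitzky–Golay with window 9 and polynomial degree 2;
derivatives come from the fitted local polynomial, not raw differences,
which stabilizes rate descriptors at plate-reader noise.  Note the
degree-2 derivative estimator carries an O(h²) bias proportional to the
third derivative: on the steepest screen-like logistic (r ≈ 0.8/h) at the
default 0.5 h grid the bias on μ_max is ≈ 0.04 OD/h.  The bias is common to
all curves of a group and does not affect clustering; closed-form descriptor
checks are therefore stated on dense (0.02–0.05 h) noiseless grids where it
is below 1e-3.

Lag time is the classical tangent construction: the tangent at the point of
maximum smoothed growth rate intersected with the baseline OD level,
truncated to the observed time range (truncating to the observed start
rather than t = 0 keeps the descriptor time-shift equivariant).  The
baseline defaults to the smoothed OD at the first timepoint and can be
supplied explicitly when the pre-growth OD is known.  A flat OD curve
(range below 1e-9) yields μ_max = 0, lag set to the final timepoint, and a
flag.  No parametric growth model (Gompertz, Baranyi) is fitted; the
descriptors are model-free.

## Fermentation clustering

Z-scores use the sample (n−1) SD; a constant column raises an error naming
the column.  Agglomeration is complete linkage on Manhattan distances via
the Lance–Williams max-update; at exactly equal heights the merge with the
lowest (i, j) cluster-id pair wins, making the tree deterministic given row
order (the partition itself is row-order invariant).  Tree cuts label groups
1..k by decreasing size, ties by first occurrence.  The elbow is
operationalized kneedle-style: the k whose (k, WCSS) point lies farthest
from the chord joining the curve's endpoints, ties to the smaller k, so an
exactly linear WCSS decay yields k = 1.  WCSS for tree cuts is computed in
the Z-scored Euclidean space even though merging used Manhattan distances,
matching the sum-of-squares formulation of the selection criterion.  Whether
five groups should come from the elbow or from inspection is genuinely open
in screens of this kind; the pipeline makes elbow-on-cuts the default and
logs the selected k.

## Community analysis

Shannon diversity uses natural log (the convention of the standard ecology
packages); richness counts strictly positive abundance by default (inputs
are relative abundances, so rarefaction is out of scope).  K-means runs
Lloyd's algorithm with k-means++ seeding, best of 25 restarts by WCSS, on
the raw response differences (not re-standardized — the procedure operates
on abundance differences directly).  NMDS alternates isotonic regression of
configuration distances on dissimilarity ranks (primary tie approach) with
Guttman-transform updates; only improving steps are accepted, so the
recorded Kruskal stress-1 sequence is non-increasing by construction;
20 random restarts, tolerance 1e-6 on stress, 2 dimensions by default — the
restart count and dimensionality are configuration, as they would be in any
ordination run.  Bray–Curtis is not a metric; no triangle inequality is
asserted anywhere.

## Differential abundance

Each glycan is tested against the no-glycan control in its own model rather
than one multi-level treatment factor (recorded in configuration); ranks are
computed per feature across all samples entering that model, q-values are
BH-adjusted across features within each glycan.  The mixed model has a
single random intercept per donor, fitted by profiling the likelihood over
the variance ratio σᵤ²/σₑ² — a bounded 1-D optimization with closed-form GLS
(Woodbury block inverse) at each ratio, REML for reported estimates, full ML
for the likelihood-ratio test of the treatment effect (χ², 1 df, variance
components constrained ≥ 0).  The LRT is chosen over Satterthwaite or
Kenward–Roger approximations because it is self-contained and desk-testable;
its mild anti-conservatism at small subject counts is covered by the
Monte-Carlo calibration test at 10 subjects × 6 observations (the screen's
donor scale), which lands near 0.05–0.065.  In balanced designs the GLS
treatment estimate coincides with OLS for every variance ratio, which the
σᵤ² = 0 consistency check exploits.  The log2FC pseudocount is 1e-5 relative
abundance, below typical detection resolution, and configurable.  No
compositional transforms (CLR) or zero-inflated models are used.

## SCFA quantification

The "x" in 1/x weighting is the detector response (the normalized area),
per the quantification convention this stage implements; a
1/concentration variant is available by flag.  Weighted least squares is
solved by the normal equations.  Negative back-calculated concentrations are
floored at zero and flagged (concentrations are physical); responses above
the top standard are flagged as extrapolated.  Exact affine-rescale
invariance of quantified concentrations holds for unweighted fits; with 1/x
weights it holds for pure gain changes (the weights themselves are
scale-dependent only through the offset).

## Comparison statistics

Fisher's exact test is two-sided by the "sum of tables no more probable than
observed" convention with a 1e-12 relative tolerance for floating-point
ties; no mid-p.  Wilcoxon rank-sum switches from exact enumeration to the
tie-corrected normal approximation with continuity correction at
n+m > 20 or in the presence of ties (a deterministic, logged rule).
Kruskal–Wallis uses the tie-corrected H with a χ² reference; Dunn's pairwise
z statistics use pooled ranks with tie-corrected variance and Holm
adjustment by default (the adjustment is configurable; Holm is the
conservative choice where no convention is fixed).  The log-rank test is the
standard (O−E)²/V χ²(1) over distinct event times.  Body-mass comparisons
integrate each animal's trajectory by the trapezoid rule over the observed
span before a rank-sum comparison.

## Problem sizes in tests

The verification suite states its guarantees at these scales: 100-glycan
screens (5 archetypes × 20) over 50 seeds for pipeline label recovery;
2000-replicate Monte-Carlo null for the rank LMM (10 donors × 6
observations) and the log-rank test (12 + 12 animals); exhaustive
enumeration up to margins of 12 (Fisher), n+m ≤ 12 (Wilcoxon), n ≤ 10
(agglomeration oracle) and n ≤ 8 (K-means 2-partitions).  These sizes were
chosen to make the brute-force oracles exact while keeping the suite quick
to run.
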