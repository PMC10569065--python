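# Methods

## The mosaic-locus model

A locus of length L bp is modelled as an ordered set of segments, each
evolving along one of two trees that share a strain set:

* the **species tree** — an unrooted binary tree describing vertical
  descent; simulated as a pure-birth (Yule) genealogy rescaled to a mean
  root-to-tip depth of 0.1 substitutions/site (a typical core-genome
  divergence scale for a closely related species group);
* the **donor tree** — the same strains, but with the deepest split
  separating two allele groups A and B regardless of their species
  relationships. It is built by restricting the species tree to each
  allele group (preserving the restricted topologies and path lengths) and
  joining the two restrictions by a single internal edge whose length,
  the *donor divergence*, defaults to 0.3 substitutions/site. This is the
  simplest tree consistent with a one-time horizontal transfer of a
  diverged allele followed by spread within each group.

Sequences evolve site-independently under Jukes–Cantor: the root sequence
is uniform over {A,C,G,T} and a branch of length t substitutes each site
with probability (3/4)(1 − e^(−4t/3)), choosing uniformly among the three
alternative bases. Segments are concatenated in layout order; the default
layout is a six-gene operon analog (appD 1000, appF 900, appC 900,
appA 1600, appB 900, yjbA 500 bp) with the contiguous appA+appB block
(2800–5300) on the donor tree. Gene lengths are illustrative defaults and
fully configurable; boundaries are sharp (no intra-segment mixing). The
simulator emits gapless pre-aligned sequences: no indels, no rate
heterogeneity, no codon structure. Real alignments have gaps, ambiguous
bases, rate variation across sites and uncertain alignment columns, so
passing tests on this generator demonstrates correctness of the scan
machinery, not robustness to alignment error.

All generators take a mandatory integer seed, use one numpy Generator per
call, and are bit-reproducible.

## The incongruence scan

Windows of width 500 bp advance in steps of 50 bp (0-based, half-open
coordinates; the trailing partial window is dropped, giving
⌊(L−500)/50⌋+1 windows). Per window:

* **Distances.** Jukes–Cantor with pairwise deletion: sites where either
  sequence is not A/C/G/T are dropped per pair; d = −(3/4)ln(1 − 4p/3).
  The correction diverges at p = 3/4, so pairs with p ≥ 0.74999 are capped
  at d = 5.0 and flagged saturated. A window in which any pair retains
  under 50% usable sites is skipped with a recorded reason, not silently
  dropped.
* **Trees.** Neighbor joining with the Q-matrix criterion. Ties in Q are
  broken toward the lexicographically smallest pair of cluster labels (a
  cluster is labelled by its smallest member), and negative limb estimates
  are clamped to zero with a count kept on the tree, so output is
  bit-identical across platforms. Distance-based NJ was chosen over
  likelihood methods because the downstream metric needs only consistent
  branch-length trees per window and the scan runs thousands of windows.

**Tree comparison.** The K tree score between a reference and a comparison
tree matches branches by bipartition (terminal branches by leaf label),
assigns length 0 to missing branches, rescales the comparison tree by the
closed-form optimum K* = Σ(b_ref·b_comp)/Σ(b_comp²) and reports
√Σ(K*·b_comp − b_ref)². It is zero iff the trees agree up to a global
scale; it does not satisfy the triangle inequality. The accompanying
Robinson–Foulds distance counts internal bipartitions unique to either
tree, excluding zero-length internal branches (treated as polytomies).
The all-pairs window matrix stores the mean of the two score directions,
since the score is asymmetric but the heatmap wants one value per pair.

**Congruence profile.** Each window tree is compared to the reference
tree. A window is flagged incongruent only when two independent signals
agree: a branch-length signal (robust z of its K score above 2.0) and a
topological signal (RF distance above 0.4 of the maximum 2(n−3)).
Requiring both avoids flagging windows that differ from the reference by
rate variation alone (length signal without topology) or by sparse-window
noise (topology signal without length). The robust z is computed as
(k − median)/(1.4826·MAD) with median and MAD taken over the **lower half**
of the window score distribution rather than all windows: incongruence can
only increase the distance to the reference, so the congruent population
is the low mode, and a baseline over all windows breaks down as soon as
divergent plus boundary-straddling windows approach half the locus — which
they do already for a 2500 bp transferred block in a 5800 bp locus scanned
at 500/50.

**Segmentation and calls.** Windows are segmented by contiguity-constrained
agglomerative merging: repeatedly merge the adjacent segment pair with the
smallest mean between-segment K score, stopping when the next merge's
score exceeds mean + 2 SD of the scores already merged (at most 8 segments
are allowed; merging continues past the stop rule until that cap is met).
Segments are voted congruent (< 20% of windows flagged), incongruent
(> 80%) or mixed; adjacent segments of equal status coalesce into regions,
and each transition into or out of an incongruent region yields a
breakpoint at the midpoint between the flanking window centers, in
alignment bp. Because windows are 10 steps wide, boundary windows blend
both histories and breakpoint estimates carry an intrinsic uncertainty of
roughly half a window; on the default simulation they land within ±250 bp
of the truth.

**Allele clustering.** Strains are clustered on the whole incongruent
region (more signal per pair than any single window) by average-linkage
hierarchical clustering of the JC distance matrix. The dendrogram is cut
at the largest gap between successive merge heights provided that gap
exceeds twice the median gap; otherwise one cluster is reported. Clusters
are numbered by decreasing size. Two caveats are documented deliberately:
the 2×-median-gap rule is liberal on structureless data (the largest of
~n random spacings exceeds twice their median quite often), and a species
tree with a genuinely deep basal split will legitimately be reported as
two groups — the rule detects *discrete depth structure*, not horizontal
transfer per se; transfer is established by the window scan, clustering
only names the groups. Regions shorter than 100 bp are rejected as
carrying too little signal (configurable).

With both signals required, a locus simulated entirely on the species tree
produces no incongruent region calls (0 across 20 seeds in the test
suite). Sensitivity falls with strain count: with few strains a random
allele partition can be nearly concordant with the species tree, leaving
too few conflicting bipartitions to clear the RF threshold (observed at
n = 12; solid from n = 16 up at donor divergence 0.3).

## The dose-response model

Reporter output as a function of peptide concentration c (µM) is

    Y(c) = Emin + (Emax − Emin) · (1 + erf(log10(c/K)/n)) / 2

with floor Emin and plateau Emax in arbitrary units, half-maximal
concentration K (µM) — Y(K) = (Emin+Emax)/2 by construction — and log10
transition width n (dimensionless, default 1; the width is never a
reported quantity). A second, "literal" convention
Y = Emin + (Emax−Emin)·erf(log10(c/K)/n) is first-class: it traces the
same curve family with remapped plateaus (its floor sits at 2Emin−Emax and
its K marks the lower knee rather than the midpoint), and both conventions
fit identical residuals on data sampling both plateaus. The halfmax form
is the default because K is used throughout as *the half-maximal
concentration*. c = 0 is evaluated at the analytic c→0 limit rather than
dropped.

Fitting is least squares on per-concentration replicate means (what a
mean±sem dose plot displays), parameterized as (Emin, Emax−Emin, log10 K,
ln n) so the invariants Emax ≥ Emin ≥ 0, K > 0, n > 0 hold by
construction, with 5 starts on a log10 K grid spanning the positive
concentration range and optimizer tolerances of 1e-8. Standard errors
come from the Jacobian at the optimum; a fit is flagged when K falls
outside the sampled concentration range, when SE(log10 K) exceeds 1, or
when the optimizer stalls on a flat ridge (typical when no upper plateau
was sampled). An inverse-sem² weighted objective is available but off by
default. K values from two fits are compared as a ratio with log10-scale
error propagation √(SE_a² + SE_b²) and a geometric ±1 SE interval.

The synthetic assay multiplies the model value by (1+ε), ε ~ N(0, CV)
with CV = 0.1, floored at 0 — flow-cytometry population means are
scale-noisy. Simulated truth uses Emin = 1 AU (expression is normalized
so autofluorescence ≈ 1) and 8 log-spaced concentrations bracketing K
with 3 replicates, mirroring a realistic assay design.

## Fold-change statistics

Replicate efficiencies are treated as log-normal; groups are compared by
the ratio of geometric means with logarithmic standard error
√(s_a²/n_a + s_b²/n_b) on log10 values, a geometric ±1 SE interval
ratio·10^(±SE), and a Welch t-test on the log10 replicates (variances are
not assumed equal across genotypes). At n = 4 per group the ±1 SE
geometric interval covers the true ratio ~64–65% of the time (slightly
below the 68% normal nominal because the SE is estimated from 3 degrees
of freedom per group). The generator draws log10 efficiencies as
N(−0.3, 0.2) for the baseline group (≈50% efficiency) and shifts the
second group down by log10 of the true ratio; values are unbounded
positive, as plate-count ratios are.

## Problem sizes and numerics

Simulated studies use 24 strains × 5800 bp (107 windows) for the scan, 20
seeds per condition; 200 refits per dose-response operating point; 500
simulations for fold-change calibration — sizes at which every quantity
of interest is stable to well within its tolerance while the full suite
runs in minutes. Determinism everywhere: mandatory integer seeds,
lexicographic tie-breaks in NJ and in cluster relabelling, fixed optimizer
tolerances, and canonical bipartition keys (the side not containing the
lexicographically first leaf).

Known limitations: no indel/gap-aware simulation; no support values or
tree uncertainty per window; the K score mixes terminal and internal
branches, so very unbalanced terminal-length noise can dilute topological
signal; segmentation assumes one shared history per window and sharp
transitions; no inference of transfer direction or donor identity.
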