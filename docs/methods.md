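# Methods

## Overview

`rewirenet` analyses staged (e.g. disease-progression) expression data by
comparing **co-expression network wiring** rather than expression levels
alone. The premise: a gene can drive a disease state by changing who it is
co-expressed with — gaining and losing network neighbours — without ever
being differentially expressed. The pipeline builds one thresholded
correlation network per stage, quantifies each gene's degree change and
edge turnover against the control stage, assembles per-stage disease gene
sets, and ranks pathways by how much their disease genes' sub-network
tightens relative to control.

## Stage networks

For a stage with n samples, the network is defined on the gene-pair
Pearson correlation matrix r_ij. Each pair is tested against the null of
zero correlation with the exact t reference,

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2, two-sided,

which is the standard test of no correlation and well behaved for
n > 10 (a precondition the builder enforces). The N(N-1)/2 upper-triangle
p-values are Benjamini–Hochberg adjusted and an edge is kept iff

    r_ij >= r_min (default 0.5)  and  adj.p_ij <= fdr_max (default 0.05).

Only positive correlations form edges by default (the threshold is on r,
not |r|); `absolute=True` switches to |r|. Comparisons are inclusive at
the boundary; ties at the exact boundary are measure-zero in practice.
Self-loops are removed (A_ii = 0) and zero-variance genes get r = 0,
p = 1 with a log message. BH runs over the upper triangle only — counting
each unordered pair twice would bias the FDR denominator.

**Fast path.** The permutation test below rebuilds networks thousands of
times but needs only degrees. Because the p-value is a monotone function
of |r| at fixed n, BH step-up is equivalent to a rank cutoff on |r|: the
critical |r| at every BH rank is precomputed once per (n, number of
pairs, fdr_max) and each rebuild reduces to one correlation matrix plus
one sort. A test asserts bit-identical adjacency between the fast path
and the full p/FDR-matrix route.

## Topology diagnostics

Per network: edge count, number of degree-0 nodes, global transitivity
(3 x triangles / connected triples), density 2E/(N(N-1)) and Freeman
degree centralization sum(k_max - k_i) / ((N-1)(N-2)). Erdős–Rényi
references use G(N, p) with p = ⟨d⟩/N and a two-sample Kolmogorov–
Smirnov comparison of the real degree distribution against degrees
pooled over replicates. Scale-free plausibility is assessed by a
discrete power-law fit to the positive degrees: per candidate x_min the
exponent is the zeta-function MLE, x_min minimizes the KS distance, and
a semi-parametric bootstrap (body resampled empirically, tail from the
fitted model, full refit per replicate) yields a goodness-of-fit p;
p < 0.1 is read as rejecting the power law. The exponent search is
bounded at alpha <= 8: observed scale-free exponents are far smaller,
and without the bound an ultra-steep power law can mimic a Poisson tail
well enough to erase the bootstrap's power to reject ER-like networks
(measured: 1/10 vs 9/10 rejections).

## Differential connectivity and rewiring

For a disease stage d versus control c, each gene's differential
connectivity is dK_i = K_i^d - K_i^c over the binarized adjacencies
(union gene universe; a gene absent from one network has degree 0).
Significance comes from a label-permutation null: sample labels are
shuffled between the two groups with group sizes preserved, both
networks are rebuilt with the identical edge rule, and

    perm_p_i = #{ |dK#_i| > |dK_i| } / t        (t = 1000 by default),

with BH across genes; "DC genes" use adj.p < 0.01. The inequality is
strict, exactly as defined; consequently perm_p can be exactly 0, and
for a gene whose degree is *identically* stable under permutation (e.g.
a pure-noise gene in an otherwise sparse network, where every dK# = 0
and dK = 0) the p-value degenerates to 0 rather than 1. In data where
degrees fluctuate at all this does not arise (then dK = 0 gives a large
p), and the rewiring flag below is robust to it because its EG gate
excludes such genes anyway; an add-one smoothed estimate
(1 + count)/(1 + t), which cannot be 0, is available behind
`smoothed=True` but is off by default to keep the printed definition.
Shuffling is global per sample (whole expression vectors move between
groups), the only scheme that preserves gene–gene structure and hence
exchangeability under the null.

Edge rewiring refines dK by neighbour-set algebra: EG = edges unique to
the disease network, EL = edges unique to control, common = shared;
dK = EG - EL is an identity asserted on every fixture. A gene is flagged
**rewired** when its DC adj.p <= 0.05 (a looser gate than the DC-gene
call, both exposed) and EG strictly exceeds a novel-connectivity
threshold. The default threshold 70 is calibrated to ~17k-gene networks;
at other scales pass a number (tests use module_size/2) or `"fit"`,
which fits a power law to the positive EG distribution and takes the
smallest EG with estimated unconditional tail probability < 0.05,
falling back to 70 with a warning when the EG support is too small or
degenerate to fit.

The per-stage disease gene set is

    zeta = (rewired ∪ significantly up-regulated) \ significantly down-regulated,

with up/down defined as |logFC| > 1 and adj.p < 0.05 from a per-gene
Welch t-test versus control (BH across genes). Welch's t is a documented
stand-in for array-era moderated-t pipelines; at the sample sizes this
package targets (>= 30 per group) variance moderation changes nothing
material, and the choice is recorded in the output metadata. The
fraction of rewired genes that are not DE at all is reported — the
headline observation this style of analysis exists to make. For edges
between disease genes the differential correlation strength r_d - r_c is
reported (control r read from the correlation matrix whether or not the
pair passes control thresholds), histogrammed at bin width 0.1.

## Pathway scoring

Disease genes are tested against a GMT collection by one-sided
hypergeometric over-representation with the expression gene universe as
background (not the GMT union — the analysis domain is the network), BH
across sets, retaining adj.p < 0.05. For each enriched pathway the
*enriched disease genes* (set ∩ zeta) are mapped into the disease and
control networks; the induced sub-graph gives the per-gene connectivity
phi (mean induced degree) and density delta in each condition, plus the
disease sub-graph transitivity. The reporting filter n > 5, delta_d > 0,
clustering > 0 marks pathways with a non-trivial disease sub-network.

Pathways sharing a statistically significant number of member genes
(one-sided Fisher's exact test over the universe; BH by default, raw
p behind `multiplicity="raw"`) are joined in the co-membership
(cross-talk) graph; PC is a pathway's degree there, and connected
components form integrated pathway clusters (IPCs). The relevance score

    R = log10(PC) + (phi_d - phi_c)/phi_d + (delta_d - delta_c)/delta_d

is defined only when PC >= 1, phi_d > 0 and delta_d > 0; otherwise it is
reported as undefined with a reason code rather than imputed. The log
base is configurable; base 10 is the default, consistent with reported
score ranges at PC in the hundreds (the two fractional terms are each
bounded above by +1). Per gene, the cross-talk frequency cf counts the
retained pathways containing it; by default the count runs over
signalling-tagged pathways (case-insensitive name match on "signal", or
an explicit tag list) when any are tagged. Each pathway's hub gene is
the maximal-induced-degree disease gene, ties broken by total network
degree then lexicographic id.

## Synthetic data generator

The generator plants three orthogonal mechanisms on one gene universe:

* **Modules.** Blocks of `module_size` genes follow a per-stage,
  per-module latent factor f ~ N(0,1): expression = lambda * f + eps,
  eps ~ N(0, noise_sd^2), lambda = sqrt(c/(1-c)) * noise_sd, so two
  same-module genes have expected correlation exactly c
  (default c = 0.8).
* **Rewiring.** Rewired genes are unattached noise in the control stage
  and join a fixed target module in every disease stage — edge gain
  with no mean change. Targets are assigned round-robin so every module
  receives the same number of arrivals; an arriving gene gains the
  module's members plus its co-arrivals as neighbours (EG ~ module_size
  - 1 + arrivals), while resident genes gain only the arrivals and stay
  below a module_size/2 threshold.
* **Differential expression.** DE genes are noise genes whose mean
  shifts by ±de_log_fc in every disease stage (25% down by default) —
  mean change with no wiring change.

Defaults (1200 genes, 10 modules x 20, 60 rewired, 40 DE at
logFC 1.5, 100 samples per stage, stages N → CnM → CM → LN) emulate a
stratified multi-stage expression study at desk scale; sample sizes
satisfy the correlation test's n > 10 requirement with margin, and the
problem size keeps a full permutation run (t = 200) near 15 s per stage
on one core. Everything is deterministic given the seed.

Matched GMT files contain one *planted* set per module — its
disease-stage membership plus a 10-gene slice of the next module, so
adjacent planted sets share genes and the co-membership graph (hence PC
and R) is non-degenerate — and *decoy* sets drawn from genes carrying no
planted signal. A baseline intensity of 8.0 (typical log2 microarray
scale) is added throughout.

What the generator does **not** emulate: cross-platform probe effects,
batch structure, intensity-dependent variance, correlated noise between
modules, partial module membership, or realistic (heavy-tailed) degree
distributions — planted networks are near-regular within modules, which
is precisely why the power-law helpers refuse to fit them. Passing
recovery tests therefore demonstrate correctness of the machinery under
the planted model, not performance guarantees on real microarray
compendia.

## Numerical and design notes

* All randomness flows from a single root seed; per-purpose child seeds
  are derived by hashing stable token strings (stage names, step names)
  into a `SeedSequence`, so adding a stage never perturbs another
  stage's stream.
* Dense float64 matrices are used up to ~20k genes; edge lists are
  emitted sorted (gene_a < gene_b) for byte-stable output.
* Degenerate inputs: zero-variance genes (r = 0, p = 1, logged),
  constant genes in DE (p = 1, neutral), empty disease gene sets
  (empty result + warning), sub-graphs with < 2 mapped genes (all
  properties 0, filter fails), co-membership with < 2 pathways (empty
  graph).
* The outlier QC step scores each sample by its standardized
  connectivity Z.K in a signed sample-similarity network with adjacency
  ((1 + cor)/2)^2, per stage, and removes samples with Z.K < -2.5 in a
  single pass (no iteration); the adjacency power and cut are
  configurable.
* Known limitations: no edge-wise differential-correlation test (only
  the degree/neighbour-set level), no soft-threshold (WGCNA-power)
  adjacency, no probe/batch handling, and the permutation test's strict
  p-value degeneracy for identically-stable genes discussed above.
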