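# Methods

This note documents the model, the numerical choices, and what the
synthetic data does and does not establish.

## Niche categorization

**Image mode.** Immediate neighbors are taken from a Delaunay
triangulation of the cell centroids (alternatives: symmetrized or mutual
k-nearest neighbors, radial cutoff; Delaunay edges can be pruned at a
radius, default the 95th percentile of edge lengths, to remove spurious
long convex-hull edges). A cell of type X whose neighbors are all X is a
member of the homotypic group X/X. A cell of type X touching one or more
foreign types joins the heterotypic group X+Y for *every* distinct foreign
neighbor type Y. This multi-membership choice maximizes group sizes and
keeps each comparison conditioned on a specific partner type; the
alternative (assign only to the nearest foreign neighbor's group) is
available via `exclusive_nearest`. Homotypic membership is strict — any
foreign contact excludes a cell from the reference group — so the
reference is uncontaminated by partial contact effects. Groups smaller
than `min_group` (default 10; rank tests below that size carry little
information) are dropped and logged.

**NGS mode.** The unit is the deconvolved bead: singlets of type A form
the homotypic group A/A, doublets of types {A, B} form the heterotypic
group A+B (unordered; canonicalized lexicographically, and all reported
proportions refer to the lexicographically first type). Spots with more
than two types are outside the model and rejected by the reader; the
doublet regime is the stated operating domain of bead data near cellular
resolution. Heterotypic annotations can be sanity-checked two ways:
(1) marker check — a spot should express at least one marker of each
constituent type; (2) correlation check — the annotated pair should be
the arg-max, over all candidate type pairs, of the mean Pearson
correlation between the spot and artificial mixtures built at the spot's
own weight. Correlation is computed per replicate and averaged
(`aggregate="corr_of_mean"` correlates against the replicate-mean profile
instead; on well-separated synthetic data the two agree).

## Preprocessing

Units detecting fewer than `min_features` genes (default 200; set 0 to
disable for tissues where low-complexity beads are a large share) are
removed, then counts are library-size log-normalized:
`log(1 + scale * count / total)` with scale 10,000 and the natural log —
the convention of the mainstream single-cell toolchains; both scale and
log base are configurable since the log-ratio threshold is defined on this
scale. Feature selection keeps the `top_n` genes by variance of the
normalized values plus all supplied marker genes. Variance of the
log-normalized values is used rather than a mean-dispersion fit: it is
deterministic, transparent, and adequate at these problem sizes.

## Test selection and the tests

Group sizes drive the choice: both n > 30 (strictly; n = 30 routes to the
rank test) means parametric testing, with a two-sided F test on the
variance ratio at α = 0.05 deciding between Student's pooled-variance t
and Welch's t with Satterthwaite degrees of freedom. Smaller groups get
the Mann–Whitney U test with mid-ranks for ties. An optional Shapiro–Wilk
gate (off by default) forces the rank test when either group fails
normality at α = 0.05.

Numerical details worth knowing:

* Mann–Whitney p-values are exact (full enumeration of the rank-sum null
  distribution) when there are no ties, min(n) < 8 and n₁+n₂ ≤ 25; beyond
  that the normal approximation with tie and continuity correction is
  used. Full enumeration with one very large group is quadratic in memory
  and was deliberately capped.
* Zero-variance edge cases: two identical constant groups give p = 1;
  constant-but-different groups are an error for the t tests (the model
  cannot quantify evidence there) and fall through to the rank test in
  practice.
* Genes detected (normalized value > 0) in less than `min_detect_frac`
  (default 10%) of *both* groups are not tested. Near-silent genes
  produce all-zero groups whose t statistics have wildly heavy tails (an
  all-zero heterotypic group against a 7%-detected reference yields
  spuriously tiny Welch p-values); the detection floor is the standard
  guard against this, analogous to the min.pct filter of mainstream DE
  tools. Skipped genes are counted in the log.

Effect size is log₂((mean(het)+ε)/(mean(homo)+ε)) with ε = 1e-9, means
taken on the normalized scale; 0.4 therefore means ≈ 1.32-fold. Base and
pseudo-count are configurable and materially affect calls — they are
reported in every output. FDR control is Benjamini–Hochberg within each
category comparison (one volcano plot = one family); a flag pools
globally instead.

Call criteria: |log ratio| > 0.4 and p < 0.01, with FDR < 0.05 as an
additional criterion in image mode. Down-regulation uses the symmetric
−0.4 threshold. In NGS mode the heterotypic group A+B is compared against
A/A and B/B *separately* and a gene is called only if it passes both, with
the reported row carrying the weaker evidence (max p, min |log ratio|,
consistent sign required). A pooled-reference alternative
(`pooled_homotypic`) exists; the separate-references default is the
stricter reading of comparing "with the respective homotypic spots".

## The artificial-spot null model

A doublet's elevated expression can be a trivial consequence of mixing two
transcriptomes. The null model makes that explicit: for each heterotypic
spot with weight w, `n_reps` (default 100) artificial spots are built as
w·a + (1−w)·b from homotypic spots a, b of the two constituent types drawn
uniformly with replacement. Each replicate is exactly the weighted mix,
element-wise — this conservation is asserted in the tests to 1e-12.

The merge scale matters. Merging on the *counts* scale and then
log-normalizing each merged pseudo-spot (`null_merge_scale="counts"`, the
default) reproduces exactly how a passive mixture of two cells would be
measured, so the null is unbiased. Merging log-normalized profiles
directly (`"normalized"`, available for data without raw counts) is
biased low: log1p is concave, so a real mixture sits systematically above
the mix of logs (Jensen's inequality), and for strongly asymmetric genes
that gap alone can approach the 0.4 log-ratio call threshold — pushing
pure-mixing genes toward false survival of the null model. The
correlation-based annotation check is unaffected by this choice (it ranks
candidate pairs, all subject to the same bias) and uses normalized-scale
mixtures.

Called genes are retested heterotypic vs pooled artificial spots with the
same test-selection machinery; survival requires log ratio > 0.4,
p < 0.01, FDR < 0.01 (BH across the retested genes).

## Origin regression

For gene g in pair A+B, OLS of normalized expression on x = proportion of
the canonical first type, over the heterotypic spots *expressing* g
(normalized value > 0, mirroring the definition of n; configurable to
include zeros). Closed-form normal equations; slope p-value from the t
distribution with n−2 df. Origin is the first type if β̂ > 0 and p < 0.05,
the second if β̂ < 0 and p < 0.05, otherwise undetermined. Fits are
attempted only with at least `min_spots` expressing spots (default 20 —
"large enough" is not otherwise quantified) and a non-degenerate design
(x not constant). Swapping the roles of the two types (x → 1−x) negates β̂
exactly and swaps the call. A dissociated single-cell/nucleus reference
can be cross-checked with `cross_check_reference`: the reference-favored
type is the arg-max of mean expression over the pair.

Note a composition caveat: origin inference rests on y tracking the
expressing type's proportion *after* library-size normalization. If a
large fraction of the library is specific to one type, normalization
partially cancels the proportion signal. The synthetic origin benchmark
therefore embeds the 200 type-specific genes among 800 background genes,
as in real panels where any one type's signature is a minority of the
library.

## RGB niche maps

Up to three neighbor-dependent genes of one center type are bound to the
red/green/blue channels. A unit's channel value is its normalized
expression divided by the maximum over that gene's heterotypic group,
clipped to [0, 1]; with two genes the blue channel is identically zero;
units outside all displayed groups are gray at reduced opacity, and
boundary colors encode the niche categories in image mode. Max
normalization makes each channel invariant to rescaling its gene. SVG
output is byte-deterministic (fixed hash salt, no timestamp metadata) so
maps can be hashed in the run manifest.

## Synthetic data generator

The generator is the package's test bed and defines the conditions under
which every quantitative claim is measured.

* **Counts** are negative binomial with variance m + m²/θ, θ = 10 by
  default (moderate overdispersion typical of both FISH panels and bead
  data); a Poisson switch exists for closed-form checks. Per-gene baseline
  means are lognormal around `base_mean` = 2 counts — the regime of the
  *selected* feature set (top variable genes plus markers), which in real
  data consists of moderately-to-well expressed genes, not the silent
  tail. Each type has a signature block (10% of genes, 8× elevated) that
  doubles as its marker set and separates type profiles.
* **Image mode** places cells uniformly in the unit square cut into
  vertical stripes, two stripes per type, so every adjacent type pair has
  two contact borders and heterotypic groups reach ~100 cells at 2,000
  cells total. Planted contact genes are multiplied by 2^FC (default FC =
  1.5) in cells of the center type whose *true* Delaunay neighbors include
  the partner type; ground truth is derived from the realized graph, so
  planted FC is exactly the estimand.
* **NGS mode** draws singlets per type and doublets as count samples
  around w·μ_A + (1−w)·μ_B with w ~ Beta(2, 2) (centered mixtures, which
  also stress the origin regression). Contact genes are elevated beyond
  the mixture by 2^FC; *mixing-only* genes are 4× asymmetric between their
  two types and receive no contact effect — they are elevated in doublets
  against the low type's reference purely by mixing, which is exactly the
  signal the artificial-spot null model must absorb.

What the synthetic data does **not** emulate: real tissue morphology,
segmentation errors, deconvolution noise in the reported proportions,
platform dropout structure, and spatial autocorrelation of expression
beyond the planted niche effects. Passing benchmarks therefore demonstrate
correctness of the machinery under the stated model, not performance on
any particular tissue.

## Benchmark sizes and observed behavior

The standard verification run (also `scripts/acceptance.py`) uses: 1,000
random sample pairs for the t-statistic oracles and an exhaustive sweep of
n₁, n₂ ≤ 12 for the U oracle; 50 Delaunay instances of 60 points against
the empty-circumcircle enumeration; a 2,000-gene null simulation at 1,500
cells for per-branch type-I calibration (each branch applied
unconditionally to the null groups — conditioning on the F-test routing
would select genes by their mean–variance coupling and is not a test of
calibration); 2,000 cells / 48 planted genes for image-mode recovery;
2,000 spots for the mixing/contact discrimination; 100 doublets / 200
type-specific genes for origin recovery. These sizes keep a full run in
tens of seconds while leaving the binomial uncertainty of each reported
percentage a few points at most.

One measurement convention: the correlation-validation accuracy is
reported over doublets whose minor type contributes at least 20% of
transcripts. Below that a doublet is statistically near-indistinguishable
from a singlet and no correlation rule can recover the pair reliably; the
cutoff marks the identifiable regime rather than hiding failures (the
all-doublet accuracy is a few points lower).

## Known limitations

* The t tests assume approximate normality of group means; at group sizes
  just above 30 with very sparse genes the extreme tail of the p
  distribution is heavier than nominal. The detection floor mitigates
  this; the Shapiro–Wilk gate is the stricter option.
* Heterotypic assignment in image mode conditions on the partner type but
  not on the number of contacting partner cells; dose effects are not
  modelled.
* The artificial-spot model inherits the deconvolution's proportion
  estimates; systematic proportion bias propagates into the null.
* No covariate adjustment, no mixed models, no spatial autocorrelation
  correction.
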