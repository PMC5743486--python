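# Methods notes

This note records the statistical conventions, numerical choices, and
synthetic-data assumptions behind `phyloturn`, at the level of detail a
user auditing results would want.

## Turnover statistics

All quantities derive from the cophenetic distance matrix `d_ij` of a dated
ultrametric phylogeny (branch lengths in Myr; on such a tree
`d_ij = 2 × age(MRCA(i,j))`). The matrix is computed by a single postorder
sweep (`d_ij = depth_i + depth_j − 2 depth_v` for tips in different child
subtrees of node `v`) and cached; the test suite verifies it against
dendropy's independent distance machinery and against MRCA enumeration.

**Pair exclusion.** "Distinct species" is taken literally: same-species
pairs are excluded from numerator *and* denominator in both modes, within
plots (where `i = j` cannot occur) and across plots (where it can). A
shared species therefore pulls `Δ_a` toward within-plot values only through
its pairings with other species.

**Pairwise vs pooled aggregation.** The framework defines stage-level
statistics; regressions on pairwise environmental distance need a per-pair
statistic. Both are provided:

- *pairwise*: `1 − ½(Δ_w(k) + Δ_w(l)) / Δ_a(k,l)` per unordered plot pair —
  the symmetric form; group means over these values come with a descriptive
  SE (pairs are not independent — inference is left to the null model);
- *pooled*: `1 − mean_k Δ_w / mean_{(k,l)} Δ_a` over a group's plots and
  pairs — the original ratio-of-means estimator.

Undefined quantities (plots with fewer than two distinct species, plot
pairs with no valid species pair under a depth mask, `Δ_a = 0`) propagate
as NaN with a `defined` flag and are excluded from means with a logged
count; they are never silently zero.

**Engine.** With plot-weight matrix `W` (binary presence rows or relative
abundance rows) and pair mask `M` (off-diagonal, optionally
depth-restricted), every `Δ` is the ratio of the quadratic forms
`W (D∘M) Wᵀ` and `W M Wᵀ`; a full 27-plot pairwise table costs two small
matrix products, which is what makes 10⁵-replicate experiments cheap.
Small-instance brute-force enumeration (O(S²P²) loops, written
independently in the test suite) agrees to 1e-12.

**Shannon evenness** is `H/ln S` over species with positive counts; a
single-species plot is *defined* as 0 (flagged) rather than 0/0.

## Null models and significance

The "1p" randomization is a uniform permutation of the pool's tip names,
implemented as an index permutation applied to the pool cophenetic matrix;
the community matrix is untouched, so per-plot richness, occurrence
frequencies, abundance structure, and species turnover are preserved
exactly. The shuffle spans the *whole regional pool* (410 species by
default), not just the community species — relatedness of plot species to
unrecorded pool members informs the null. The test is exact (correct
type-I error) when species frequencies are phylogenetically unstructured;
the acceptance suite verifies the rejection rate at α = .05 over 500
neutral datasets.

p-values are rank-based with the add-one convention and strict
more-extreme counting: `p_high = (#{replicates > obs} + 1)/(R + 1)`,
`p_low` symmetric, two-sided = `min(1, 2·min(p_low, p_high))`. For the
continuous turnover statistics ties have probability zero; the discrete
node-count tests (below) use tie-inclusive counting instead, which is the
conservative direction there. SES is `(obs − mean)/sd` with `sd` the
R−1-denominator standard deviation; `sd = 0` (e.g. a star-tree pool) flags
SES as undefined. The 95% null interval uses type-7 linear-interpolation
quantiles. One `numpy` generator drives all replicates of a run; a master
seed makes entire analyses bit-reproducible.

## Phylogenetic depth

`restricted_turnover` keeps species pairs with MRCA age strictly `< T`
(`d_ij < 2T`); ties at exactly `T` are excluded by default (an
`inclusive` flag flips this). The partial null shuffles tip names
independently within each *maximal* clade younger than `T` (depth-first
from the root, stopping at the first qualifying node); `T` above the root
age reduces to the full 1p shuffle, and the retained-pair sets are nested
in `T`. Age thresholds default to an arithmetic grid from 30 Myr by 10-Myr
steps with 128 Myr appended (11 thresholds). SES profiles are reported
raw; any curve smoothing is presentation, not inference.

## Clade enrichment (nodesig)

For each internal node of the pool tree and each plot, the observed number
of the plot's species descending from the node is compared to the same 1p
shuffle. Under that shuffle the count is exactly hypergeometric
(pool size N, clade size c, plot richness m), so an analytic mode is
offered next to the default randomization mode; the acceptance suite
checks the equivalence by χ² goodness of fit. No multiple-testing
correction is applied by default (each node × plot test is reported
marginally); a Benjamini–Hochberg column is available as an explicitly
labelled extension.

## Environment association

Environmental variables are log-transformed where strictly positive
(signed variables such as northness pass through, recorded in metadata —
no offset guessing), z-scored, and reduced by PCA to the smallest
component set reaching 90% of variance; environmental distance is
Euclidean in that score space. Note that duplicating a variable slightly
reweights its axis — the PCA controls correlated-variable dominance but is
not a whitening. Pairwise turnover is first residualized on the Euclidean
geographic distance (OLS; zero-variance distances degrade to centering
with a warning), then regressed on environmental distance. Significance
permutes the response across *pairs* (5000 permutations by default,
fixed count, no sequential stopping); pairs are non-independent, which this
permutation scheme shares with permutation-ANOVA practice on distance
tables — a plot-level Mantel permutation would be the stricter
alternative and the residual-vector machinery accepts any pair subset, so
it can be layered on. The 4-plot resampling enumerates all C(n,4) subsets
per stage, refits residualization and regression within each subset, and
reports the mean R² and the significant fraction — the equal-sample-size
robustness check.

## Trait signal

- **Blomberg's K** uses the phylogenetic GLS mean and the Brownian
  covariance `C` (shared root-to-MRCA path lengths):
  `K = (MSE₀/MSE) / [(tr C − n/𝟙ᵀC⁻¹𝟙)/(n−1)]`. The permutation test
  shuffles trait values across tips and compares K itself (one-sided).
- **Pagel's λ** scales off-diagonal `C` entries; the profile log-likelihood
  (analytic GLS mean and σ²) is maximized by bounded 1-D optimization on
  `[0, λ_max]`, with `λ_max` the largest value keeping the matrix positive
  definite (found by bisection, capped at 2). The test is a 1-df
  likelihood-ratio test against λ = 0 — i.e. against *no* signal, not
  against Brownian motion. Near-singular covariances (effectively
  zero-length terminal pairs) get a minimal diagonal jitter, logged.
- **Abouheif/Moran's I** uses the Abouheif proximity — the product of
  inverse direct-descendant counts over the internal nodes on the path
  between two tips (MRCA counted once), diagonal zero, row-normalized —
  and the one-sided tip-permutation test for positive autocorrelation.

K and the GLS machinery were cross-checked against `phytools::phylosig`
(agreement to ≤1e-5 for K, ≤1e-3 for λ̂ on a shared fixture); the Abouheif
proximity is verified against closed-form 3-tip values and an independent
path-walking implementation.

## Synthetic data: what it emulates, and what it does not

Defaults encode the chronosequence design the package targets: 27 plots in
five successional stages of 5/4/5/6/7 plots; a regional pool of 410
species on a pure-birth tree rescaled to root age 128 Myr; 143 species
occurring in the plots (the community table is, by construction, the set
of recorded species — community-pool species never drawn receive one
individual in a random plot, a phylogeny-blind padding that preserves
exchangeability); per-plot richness Poisson with mean 30; individuals per
plot declining with stage age (350→170); lognormal abundance weights whose
σ decreases with stage (1.6→0.7), so Shannon evenness rises through
succession.

Tree simulation uses dendropy's birth–death sampler conditioned on tip
count; because that sampler stops at the instant of the n-th speciation
(zero-length final sister pair), every tip branch is extended by an
Exp(n(b+d)) sojourn interval — for pure birth this is exactly the
conditioned distribution of the final internode, and the γ-statistic of
the resulting trees is centered on zero.

Scenarios plant known effects: `filtering_conserved` assembles plots by a
Gaussian niche kernel (width 0.5 gradient units) on a Brownian niche
trait; `overdispersion` adds a 30-Myr minimum-distance repulsion among
co-occurring species (relaxed only if the candidate pool runs dry);
`dominance_shift` holds composition fixed while the evenness parameter
climbs; `deep_filtering_late` assembles stages 1–3 neutrally and sorts the
two sides of an old clade split (the non-root node nearest 100 Myr with
≥15% of the pool and ≥5 tips per side; its age is recorded in the
manifest) to opposite gradient ends in stages 4–5. The observed
environment is 10 noisy indicator variables with unit-magnitude
random-sign loadings on the latent gradient (noise SD 0.25) plus x/y
coordinates independent of the gradient by default; these settings were
fixed so that the planted late-stage turnover–environment association has
R² ≈ 0.2 per stage — the magnitude such chronosequence studies report —
which caps per-stage significance power near 0.5–0.6 at ≤21 pairs, and is
why pattern checks aggregate over many datasets.

What the generator does *not* emulate: spatial autocorrelation of
communities (coordinates are independent of composition unless
`spatial_autocorr` is set), non-ultrametric rate variation, observational
error in counts, trait–environment feedbacks, and temporal autocorrelation
between stages beyond shared pool membership. Passing tests therefore show
the *estimators and tests* behave correctly under the design's sampling
structure; they cannot certify conclusions about any particular field
system.

## Problem sizes

The calibration experiment runs 500 neutral datasets at R = 199 replicates;
the pattern-recovery experiment 100 deep-filtering datasets (30 of them
profiled over a 4-threshold grid); signal recovery 200 Brownian traits on
128 tips plus 100 white-noise and 100 λ = 0.5 traits; the nodesig GOF
4000 shuffle draws. These sizes give Monte-Carlo standard errors well below
the decision margins of every check while keeping a full run in minutes on
one CPU.

## Known limitations

- Polytomies are handled throughout (the engine and Abouheif proximity are
  defined for arbitrary multifurcations), but Blomberg-K permutation power
  on heavily polytomous trees has not been characterized.
- The λ optimizer profiles a single trait; no multivariate or
  measurement-error extensions.
- The pooled turnover convention weights plots equally regardless of
  richness; alternative weightings are not implemented.
- `nodesig`'s randomization mode shares shuffles across nodes within a
  replicate (as the underlying null prescribes), so node-level p-values
  are correlated across nodes by construction.
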