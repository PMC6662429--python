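# Methods

This note documents the statistical models implemented in `nestkin`, the
conventions and defaults chosen where several are defensible, what the
synthetic-data generator does and does not emulate, and the package's known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spatial statistics

**Ripley's K.** For a point pattern of n events in a rectangular window of
area A, the estimator is

    K̂(r) = A / (n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ r]

with `w_ij` an edge-correction weight. Three corrections are available:
`none` (w = 1, used by the exactness tests), `translate`, and `isotropic`
(Ripley's correction; the default). The isotropic weight is the reciprocal of
the fraction of the circle of radius `d_ij` centred on point *i* lying inside
the window, computed in closed form for a rectangle (per-edge exterior arcs
`2·arccos(d_k/r)` minus corner overlaps `arccos(d_i/r)+arccos(d_j/r)−π/2`
where positive). The closed form is exact for `r` up to half the shorter
window side, and the estimator refuses larger `r` under this correction. The
variance-stabilized transform is `L(r) − r = √(K̂(r)/π) − r`: positive values
indicate clustering, negative values regularity.

**CSR envelopes.** Significance uses pointwise rank-1 (min/max) envelopes
from `s` binomial CSR simulations conditioned on the observed n in the same
window. The attained two-sided level is exactly `2/(s+1)`; the default
`s = 95` gives 2/96 ≈ 0.0208. Caveats that matter in practice:

- the envelope is *pointwise*; reading it across many distances inflates the
  family-wise error (global envelopes are out of scope);
- with the uncorrected estimator at small n, K̂ lives on a lattice of scaled
  pair counts, and rank ties with the simulated extremes make the *strict*
  exceedance rate fall below the nominal level. The calibration test
  therefore measures the level under the isotropic correction, whose
  position-dependent weights make K̂ effectively continuous.

**Edge thinning.** Points within link distance r form an undirected graph;
connected components are counted on the grid `{0, step, 2·step, …}` (default
step 5 m) by an incremental union-find over distance-sorted pairs. Ties at
exactly `d = r` are linked. Plateaus are maximal constant-count runs of at
least `min_run` grid steps (default 2; the all-singleton prefix at r = 0 is
never a plateau), and their onset radii are the threshold distances used to
assign cluster labels. Cluster means count singleton nests.

## Population genetics

**Diversity.** Expected heterozygosity uses Nei's unbiased correction
`h_exp = (2n/(2n−1))(1 − Σ p_k²)`. The Hardy–Weinberg exact test is Monte
Carlo: the observed genotype table's conditional probability under Levene's
distribution (random pairing of the observed allele counts) is compared with
tables generated by shuffling the allele vector; the reported p is the
fraction of tables at most as probable, with its binomial standard error.
Monomorphic loci return p = 1.

**F-statistics.** F_IS is Weir & Cockerham's (1984) small-sample f, with
variance components summed over alleles and loci; the one-sided permutation
test shuffles alleles among individuals within the group (`p = P(rand f ≥
obs f)`, never exactly 0 under the `(exceed+1)/(perms+1)` convention used
throughout). Pairwise F_ST is Weir–Cockerham θ with individuals permuted
between the two groups.

**Hierarchical AMOVA.** Allele copies are treated as one-hot vectors, so the
identity-distance sums of squares equal half the Euclidean ANOVA sums; the
four-level nested decomposition (clusters / nests / individuals / copies) is
solved with exact unbalanced-design coefficients (Searle-type expected sums
of squares; the individual level always carries coefficient 2 because every
individual contributes two copies). Negative variance components are
retained, so slightly negative F_CT values are representable, and
`(1−F_IT) = (1−F_IS)(1−F_SC)(1−F_CT)` holds identically. Missing genotypes
are excluded per locus: components are estimated per locus over the typed
individuals and summed across loci. Permutation nulls follow the standard
per-level schemes: whole nests among clusters (F_CT), individuals among
nests within clusters (F_SC), alleles within nests (F_IS), alleles across
the sample (F_IT).

**Null alleles.** A single non-amplifying allele of frequency p₀ is fitted
by EM under Hardy–Weinberg proportions. Apparent homozygotes k/k split into
true k/k and k/null in the E step with weight `2p₀/(p_k + 2p₀)`. Because
null/null homozygotes are indistinguishable from failed amplifications, the
default treats them as unobserved and imputes their expected count from the
truncated-multinomial likelihood (`n_typed · p₀²/(1−p₀²)`), which keeps the
estimate robust to unrelated technical missingness; `use_blanks=True`
instead counts every blank genotype as a putative null homozygote. Loci with
estimates strictly above 0.20 are dropped by the QC stage.

**Nei distance and Mantel.** Nei's standard distance is `D = −ln I` with the
identity `I` formed as a ratio of sums across loci (the `dist.genpop`
convention); loci untyped in either group are dropped pairwise, and disjoint
allele sets give D = ∞ (excluded pairwise by the Mantel stage, with a
count). The Mantel statistic is the Pearson correlation of upper-triangle
entries, with simultaneous row/column permutations and a one-sided
alternative of positive association. Because a population-level genetic
distance has no unique individual-level pairing, the pipeline computes the
test at the **nest** level: nest allele-frequency vectors against
nest-centroid distances, in two modes (all hatchlings; one hatchling per
nest, chosen as the first by sorted id so reduced datasets are
reproducible). An `individual` grouping mode exists in the library for
experimentation; neither mode claims to reproduce any one historical
choice of matrix pairing.

**Gene flow and effective size.**

- *Private alleles:* mean frequency p(1) of alleles seen in exactly one
  group; `ln Nm` solved from the Barton–Slatkin regressions at reference
  sample sizes 10/25/50 and interpolated linearly in the harmonic-mean
  per-group sample size (clamped to [10, 50]). No private alleles → an error
  flagging effectively unbounded gene flow.
- *LD method:* Burrows' composite Δ (with the S/(S−1) factor) over all
  allele pairs of all locus pairs, screened at `pcrit` (default 0.05);
  `r̄²` weighted by comparisons per pair; Waples' (2006) random-mating
  sample-size expectation subtracted (`1/S + 3.19/S²` for S ≥ 30, the
  small-S variant otherwise) and the quadratic inverted for Ne. Non-positive
  residual r² → ∞. The 95% CI uses a **delete-one-locus** jackknife — locus
  pairs sharing a locus are strongly dependent, and grouping by locus is
  what makes the interval honest (the delete-one-pair variant measured ~60%
  coverage of a nominal 95% interval in the package's own recovery
  simulations; the locus grouping measured ~90%).
- *Heterozygote excess:* per-allele `D = (H_O − H_E)/H_E` averaged with
  sample-size weights; `Nb = 1/(2D̄) + 1/(2(D̄+1))`, ∞ when D̄ ≤ 0.
- *Molecular coancestry:* pairwise allele-sharing kinship (Li-type,
  sample-frequency reference, ratio of sums across loci), negative pair
  values truncated to zero per Nomura's convention, `Nb = 1/(2 f̄)`;
  individual-jackknife CI. With an internal frequency reference the
  *untruncated* mean kinship is ≈ 0 for any sample, so truncation is what
  makes the estimator informative; the cost is that unrelated samples yield
  large-but-finite values (the positive half of noise) rather than ∞, and
  the estimator saturates near ~7 when only two families are present. These
  are properties of the published method, not implementation choices.

## The synthetic-data generator

The generator emulates the field conditions the analyses were designed for:

- **Window and intensity:** default 476 × 170 m per nesting site (the scale
  of a small communal nesting ground), two sites separated by a 1,000 m gap
  in the combined coarse-scale window.
- **Point process:** Thomas clusters by default (expected 6 parents/site,
  mean 4 nests each, σ = 12 m — chosen to put threshold distances in the
  tens of meters, where the plateau analysis operates) or CSR. Displacements
  are truncated to the window by redraw, so the large-σ limit tends to CSR
  rather than piling points on the boundary. Thomas parents define the
  *latent* clusters.
- **Genetics:** 13 microsatellite loci with 8 possible alleles each;
  ancestral frequencies Dirichlet-uniform; two populations at
  Balding–Nichols divergence F = 0.15 (the adults-only population and the
  nesting population that carries both sites).
- **Families:** each site holds 20 founder pairs (matrilines — enough that
  full philopatry is realizable for any plausible latent-cluster draw). A
  nest's mother is a daughter of the matriline tied to the nest's latent
  cluster with probability φ, otherwise of a random matriline; fathers are
  drawn site-wide; clutches are full sibs with truncated-Poisson size
  (mean 12.5, clipped to [2, 23]). φ = 0 leaves full-sib clutches (strong
  F_SC) but no cluster signal; φ = 1 makes the mothers within a cluster
  full sisters (positive F_CT).
- **Missing data:** uniform at random, default 2%.

What it does **not** emulate: multi-generation pedigrees (one generation
suffices to create the testable kin signal), mutation, nest-site fidelity
dynamics over years, sex-biased sampling, null alleles (added separately by
the recovery tests), or non-uniform missingness. Passing tests on this
generator therefore demonstrate that the estimators detect or reject the
philopatry signal under the stated model — not that any field dataset is
free of the confounders the generator omits.

## Problem sizes and numerical choices

Defaults follow the settings conventional for this analysis chain: 16,000 permutations for
F_IS/F_ST, 10,000 for hierarchical AMOVA and Mantel, 95 envelope
simulations, 5 m thinning step, 0.20 null-allele threshold, pcrit 0.05, r
grids of 512 steps to site-specific maxima. The test suite and the
acceptance script run the same machinery at smaller problem sizes chosen as
a deliberate compromise between Monte Carlo resolution and runtime —
99–999 permutations, 600–2,000 calibration replicates, 50–100 end-to-end
replicates, sites of ~24 nests — with tolerances set by binomial/Monte Carlo
error at those sizes. Permutation p-values use `(exceed+1)/(perms+1)`;
permutation and simulation seeds derive from a master seed plus a stable
stage tag (CRC32), so adding or disabling stages never shifts another
stage's stream. Degenerate inputs (monomorphic loci, single-unit levels,
constant distance matrices) are reported as NaN/∞ with flags or raised as
errors, never silently truncated — except that variance components may be
negative by design.

## Known limitations

- Envelope inference is pointwise, not simultaneous.
- The AMOVA permutation engine recomputes components per scheme; at very
  large n with 10,000 permutations a run takes minutes, not seconds.
- The LD-Ne estimator assumes random mating and unlinked loci; its CI relies
  on the locus jackknife's normal approximation.
- The coancestry-Nb estimator saturates for very few families and is bounded
  for unrelated samples (see above).
- Only rectangular observation windows and planar-meter coordinates are
  supported; geographic coordinates are rejected, not reprojected.
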