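# Methods

## The scientific setting

The package analyses experimentally assembled grassland plots that were sown
at controlled species richness from a defined pool and then left open to
natural colonization and extinction, with a final census and aboveground
biomass measured at the end. Three questions drive the design:

1. Did plots converge in phylogenetic structure as they gained colonists and
   lost sown species?
2. Were colonists (and extinctions) phylogenetically non-random with respect
   to the species already in a plot?
3. Did changes in phylogenetic diversity track changes in productivity, and
   how much of that association is attributable to nitrogen-fixing legumes?

## Metrics

All metrics are computed on a rooted phylogeny with branch lengths in
whatever units the tree carries (for an ML tree, expected substitutions per
site); no normalisation is applied.

- **PD** of a community is the sum of branch lengths of the minimal subtree
  connecting the community's tips, rooted at their most recent common
  ancestor. The path from the MRCA up to the tree root is *not* counted, so
  this differs from Faith's classical PD and a monoculture has PD = 0. This
  definition is forced once monocultures are admitted: a single tip's MRCA is
  itself.
- **MNND** is the mean over members of the patristic distance to the nearest
  other member; **MPD** the mean over all unordered pairs. Both are undefined
  for communities of fewer than two species and raise an explicit
  `UndefinedStatisticError` rather than returning a sentinel; downstream
  analyses drop such plots and report the exclusion.
- **Cross-group MNND** (colonists vs residents, extinct vs survivors) is the
  mean over focal species of the distance to the nearest reference species.

Implementation: the engine precomputes an edge-by-tip descendant incidence
matrix. PD of a community of size k is then the sum of branch lengths over
edges whose descendant tip count c satisfies 1 <= c < k (edges with c = k
are exactly the MRCA-to-root path), and the patristic matrix follows from
the same incidence matrix by linear algebra. Batch variants evaluate many
equal-sized communities per matrix operation; this is what keeps
1000-randomization tests over dozens of plots in the low milliseconds.

## Null models and inference

Null communities are uniform draws without replacement from a declared
species pool, matched to the observed richness, optionally conditioned on
containing at least one member of a required clade (at least one grass, the
rule of the emulated sowing design) and/or excluding a clade entirely.
Conditioning is by rejection sampling, which preserves uniformity on the
feasible subsets; a chi-square audit over an enumerable pool is part of the
test suite. The grass constraint applies only to communities of two or more
species: all singleton draws would otherwise be forced to be grasses, which
is not what the sowing rule means.

The two-tailed p-value is rank-based:

    p = min(1, 2 * min(n_le + 1, n_ge + 1) / (n_rand + 1))

with ties counted on both sides. The standardized effect size
SES = (obs − null mean)/null sd and its normal-reference p are also
reported, but the rank-based p is authoritative: with 999 randomizations the
smallest attainable p is 0.002 and the test is slightly conservative
(attainable rejection probability 0.048 at alpha = 0.05), which the
calibration checks reflect. A null standard deviation that is zero up to
float summation order (degenerate pools) sets `sd_zero`, reports SES = 0 and
p = 1, and never raises, so batch runs complete.

Per-plot tests are reported unadjusted and summarized as counts of
clustered/overdispersed plots against the count expected by chance
(`round(n_tests * alpha)`, half away from zero); a Benjamini–Hochberg column
is emitted for reference but does not feed the headline counts.

### Colonist test

Observed statistic: cross-group MNND from the plot's colonists to its sown
(resident) species. Null: equally many pseudo-colonists drawn uniformly from
the regional pool minus the plot's sown species, same statistic. Options:

- `residents="sown_plus_colonists"` — each colonist is judged against the
  sown species plus the *other* colonists (leave-one-out), for the
  colonists-as-established-species rerun; the within-window order of
  colonizations is unobserved, so both readings are legitimate.
- clade exclusions (e.g. the legume clade) remove the clade from the focal
  set *and* the null pool; residents keep their full composition, since the
  question is about who arrives, not who was planted. Every result carries
  an audit count of null draws containing grasses/legumes so exclusion runs
  are verifiable after the fact.
- a restricted pool (only species observed to colonize anywhere) is
  available as an option; using an incomplete colonist pool is a known
  caveat of this class of null model, so the default is the full regional
  pool.

### Extinction test

Observed statistic: cross-group MNND from the plot's extinct species to its
survivors. The null *relabels which of the sown species went extinct*,
holding the extinct count fixed (a hypergeometric relabelling within the
plot), rather than resampling from the regional pool — the question is
whether extinction depended on the plot's internal phylogenetic structure,
so the null conditions on the sown composition. With two sown species the
statistic is invariant under relabelling and the test is degenerate by
construction (flagged, p = 1). Options mirror the colonist test
(colonists-as-residents, clade removal).

### Pool-level tests

Whether the species that colonized (or went extinct in) at least one plot
are clustered across the regional pool: observed MNND of the focal set
against equal-sized uniform draws from the pool, unconstrained — the grass
rule is a property of the sowing design, not of the regional flora.

## Change and productivity analyses

Per-plot change records hold sown/final/delta richness, PD, MNND and
biomass, plus a three-way legume status: initiated-with, colonized-by, or
never. Compositional convergence is measured by the mean pairwise Jaccard
index within a census; the between-census comparison uses a permutation test
that swaps the two census memberships within each plot independently (the
original analysis reports a p-value without naming a test; the within-plot
permutation is this package's documented choice).

Diversity-change regressions (delta metric on sown metric) share one OLS
code path across metrics; plots with an undefined sown MNND (monocultures)
are dropped and the n used is reported. In the limiting case where every
plot converges to one common final composition, delta-PD on sown PD is
exactly slope −1 with R² = 1; this analytic limit is a test anchor.

The ANCOVA fits `d_biomass ~ d_pd + legume_initiated` on the plots that ever
contained a legume; plots never containing one are excluded and counted. The
covariate is 1 for plots initiated with a legume and 0 for plots initiated
without but colonized by one. Under the generator's biomass model the
expected covariate coefficient is *minus* the legume biomass bonus: plots
that gained a legume (coded 0) gain the bonus in their biomass change, plots
that started with one (coded 1) do not. A near-singular design (PD change
perfectly confounded with the covariate) emits a condition-number warning
rather than failing.

## The synthetic generator

The generator emulates the emulated experiment's *design*, with known ground
truth, so every analysis stage is testable without the unpublished field
data:

- **Tree**: three pure-birth (Yule) clades — grasses, legumes, forbs —
  joined at the root, giving contiguous tagged clades by construction; the
  legume stem is scaled (default ×4) to impose the long branch that makes
  legume colonization dominate PD change. Branch lengths are rescaled so the
  deepest tip is at height 1. Defaults: 60 tips = 48 internal + 12 external,
  14 grasses, 6 legumes.
- **Pools**: 12 external (colonist-only) species drawn uniformly, conditioned
  on the internal pool keeping at least two grasses and one legume and the
  external pool containing a legume, so all three legume statuses can arise.
- **Design**: richness levels 1/2/4/8/32 with replication 11/12/12/12/12
  (59 plots); polycultures are uniform draws from the internal pool
  conditioned on at least one grass; monocultures unconstrained.
- **Dynamics** (one collapsed transition for the post-maintenance window):
  each sown species goes extinct independently with probability 0.15 (×1.8
  for grasses, matching the observed grass-biased extinction and an overall
  loss rate near the reported ~10%/yr over two years); each absent pool
  species colonizes with probability
  `0.12 * (0.25 + exp(-d/0.3)) * (4 if legume)`, capped at 1, where d is the
  patristic distance to the nearest sown resident. The affinity term
  produces the close-relative colonization mode; the legume bonus plus the
  long legume stem produces the distant second mode.
- **Biomass**: `150 + 45*PD + 130*[legume present] + N(0, 45)` g/m²,
  truncated at zero. These constants were chosen once so that a 59-plot run
  spans realistic grassland productivity (roughly 50–850 g/m²).

What the generator does **not** emulate: spatial arrangement and dispersal
limitation, multi-year census sequences (the two open years are collapsed to
one transition), density dependence in extinction, rank abundance, and the
real pool's topology (a random Yule tree stands in; only the legume
long-branch structure is imposed because it is the feature that drives the
analyses). Passing tests therefore demonstrate correctness of the machinery
and calibration of the inference under a faithful *design*, not
reproduction of the original field results, whose plot-level data are
unpublished. The per-richness-level colonist counts of the generator are
flatter than in the field (a distance-kernel model cannot simultaneously
favour close relatives and make species-poor plots the biggest gainers);
none of the analyses depend on that gradient.

## Numerical and design choices

- Missing branch lengths are a load error by default (`missing_length=
  "zero"` opts into imputation); negative lengths and duplicate tips always
  reject. Outgroups are assumed pruned; the loader offers prune-by-label.
- Stage seeding: every randomized stage (and every plot within a stage)
  draws from a generator derived from the master seed by a stable text
  label, so results are independent of plot processing order and
  bit-reproducible per stage.
- Relative tolerance 1e-12 on the degenerate-null detection absorbs float
  summation-order noise when all null draws are the same set.
- Report bundles are byte-deterministic given config + seed; a `FAILED`
  marker file distinguishes aborted from complete bundles.
- Problem sizes used by the verification suite: type-I calibration uses 500
  simulated plots at 999 randomizations per test; parameter recovery uses
  200 replicates of the 59-plot preset; oracle equivalence uses 100 random
  trees of up to 12 tips; the constraint audit uses 1e5 constrained draws
  plus a 10,000-draw uniformity check on an enumerable pool.

## Known limitations

- The rank p is discrete; for very small combinatorial null spaces (few
  relabellings) small p-values are unattainable and tests are conservative.
- The colonist null pool treats all non-sown regional species as equally
  available propagules; dispersal differences are not modelled.
- MNND convergence regressions exclude monocultures (sown MNND undefined),
  so their n differs from the PD regressions on the same plots.
- The uniformity audit's chi-square p-value is itself a random variate; at
  alpha = 0.01 one run in a hundred fails by construction.
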