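# Methods

## Distance layers

**Functional distances (Gower).** Each of the eight traits contributes a
partial distance in [0, 1]: numeric and ordinal traits contribute
|a−b|/range with the range taken over the whole table (a zero range
contributes 0), categorical traits contribute 0/1. The pair's distance is
the mean over traits observed in both species; traits missing in either
member are dropped from that pair only, and a pair sharing no observed
trait is an error. Ordinal traits (habitat preference with its four
saprobity levels, tolerance 1–5) are scored as numeric ranks — the classic
Gower treatment; `ordinal_as_categorical=True` switches to 0/1 scoring.
Body size enters on the raw µm scale: the range normalization makes the
matrix invariant to translation, and no transform is applied.

**Phylogenetic distances (K2P → NJ → patristic).** Pairwise K2P distances
use pairwise deletion: a site counts only where both sequences carry an
unambiguous A/C/G/T; transitions are A↔G and C↔T. The distance
`-½ ln[(1−2P−Q)√(1−2Q)]` is undefined when either log argument is ≤ 0
("saturation"); the matrix builder names the offending pair. The
neighbour-joining implementation is the standard Saitou–Nei agglomeration
with two determinism rules: pairs tied on the Q criterion are resolved
toward the lexicographically smallest label pair, and negative limb
lengths are clamped to zero with the deficit moved to the sibling limb so
the joined pair's path length is preserved. The Q matrix is explicitly
symmetrized before the argmin because the two summation orders of
`(m−2)·d_ij − r_i − r_j` can differ by one ulp, which would make the tie
set asymmetric. Bootstrap support resamples alignment columns with
replacement; replicates whose K2P computation fails are skipped (and
counted in the log) rather than aborting the run.

`PDist` is, by default, the unit-standardized patristic distance matrix of
the NJ tree — the tree-mediated route, consistent with standardizing
*branch lengths*. Standardizing the raw K2P matrix directly is available
via `pdist_route="direct"`. Standardization divides by the maximum
off-diagonal entry (not min–max), preserving zero self-distances and all
ratios; it is idempotent and scale-invariant, and an all-zero matrix is an
error rather than silently degenerate.

## Blend, null model, effect size

`FPDist_ij = (α·PDist^ρ + (1−α)·FDist^ρ)^{1/ρ}` with integer ρ ≥ 1
(default 2). α = 0 and α = 1 return the functional and phylogenetic
matrices *exactly* (special-cased, no floating-point round trip).

The community statistic is the abundance-weighted mean pairwise distance
MPD = Σ_{i<j} d_ij a_i a_j / Σ_{i<j} a_i a_j over species with positive
abundance; samples with fewer than two species yield NA, never an
exception, and are carried through all reports as NA.

The null model draws richness-many species uniformly without replacement
from the regional pool (default: the union of all species observed
anywhere in the community matrix; a per-season pool is a config option)
and assigns the sample's observed abundance values to them in random
order: the abundance vector is preserved, identities are randomized. The
effect size is the probit of the mid-p quantile of the observed MPD in the
null, p = (k + (t+1)/2)/(n+1) with k the nulls strictly below and t the
ties; this keeps p strictly inside (0, 1) (|ES| ≤ 3.29 at n = 999), is
symmetric, and under the null gives ES that is standard normal up to the
discreteness of the grid.

## α sweep and summaries

For every α in the grid (41 levels, step 0.025, by default) and every
sample, the ES is recomputed against the blended matrix; per season, an
OLS of ES on sampling position (metres from the source by default, site
rank via `position_as_rank`) is fit over all dates pooled, and the optimal
α maximizes the adjusted R² (ties go to the smallest α — the more
functional, more parsimonious explanation). Seasons with fewer than three
ES-defined samples get no fit and an NA optimum with a warning.

Two numerical choices matter here. First, the null draws are *paired
across the grid*: each sample's identity permutations are generated once
(from a per-sample substream of the master seed) and reused for every α,
so the argmax over 41 correlated curves is not perturbed by independent
Monte-Carlo jitter. Second, every stochastic stage (tree bootstrap,
Mantel, per-sample nulls, per-site bootstrap CIs) seeds its own named
substream of the master seed, which is what makes whole-pipeline reruns
byte-identical.

Per site and season, the mean ES carries a percentile bootstrap 95% CI
(999 resamples; a single date returns the degenerate interval). Rao's
quadratic entropy Q = Σ_ij d_ij p_i p_j (relative abundances, full double
sum) is reported per sample at the season's optimal α; the operation
itself returns 0 for a single-species community and NA only when empty,
but the pipeline reports NA for any sample with fewer than two species,
alongside its NA effect size.

Mantel concordance between FDist and PDist is Pearson correlation of the
lower-triangle vectors with a simultaneous row/column permutation null
(9999 permutations by default), one-tailed "greater" to match the trait
conservatism hypothesis; the computation is delegated to scikit-bio with a
fixed seed.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design so that degenerate cases (few
samples per season, sparse autumn sites) are exercised at realistic sizes:
24 species, five sites at 0/500/2500/3000/3500 m, three dates in each of
three seasons, 621 bp sequences, κ = 2, Yule tree scaled to 0.2
substitutions/site root-to-tip (the tree is then derooted, so it has
2n−3 edges like any unrooted binary tree).

Trait conservatism: log body size evolves by an Ornstein–Uhlenbeck process
(stationary variance 1, θ = 1 per unit tree depth) and is mapped to
50–1500 µm; ordinal traits evolve by a ±1 random walk with reflecting
bounds (rate 1.5 per depth); categoricals by equal-rates Markov jumps
(rate 1 per depth). These rates give a clearly positive FDist–PDist Mantel
correlation at the default `trait_scale=1`; multiplying the trait branch
lengths by a large `trait_scale` (100 in the decoupling experiments)
saturates the jump processes and decorrelates the OU, severing traits from
the phylogeny while leaving the sequences untouched.

Assembly rules:

- *neutral* — richness uniform on 5..n_species, species uniform without
  replacement.
- *filtering* — inclusion weight exp(−s·δ²), δ the species' distance on
  the chosen axis (functional by default) to the most pollution-tolerant
  "optimum" species; s = `filter_strength`·(1 − d/d_max)² so filtering is
  strong at the source, negligible past mid-gradient and zero at the far
  site. The quadratic relaxation is deliberate: a linear one leaves the
  2500–3000 m sites substantially filtered and flattens the ES gradient
  the study design is meant to produce. Default `filter_strength=25`
  drops the inclusion weight to ~0.1 at axis distance 0.3. Richness is
  capped at 12 of the 24 species: filtering depresses local richness, and
  a sample containing nearly the whole pool cannot carry a composition
  signal.
- *limiting* — sequential assembly rejecting candidates closer than a
  threshold (the 0.10 quantile of the pooled blended distances) to any
  resident, richness capped at 8. The threshold/cap pair was chosen for
  feasibility: greedy packing of a 24-species pool supports ~9–13 species
  at the 0.10 quantile, and an infeasible draw raises an error rather than
  silently relaxing the rule.

Abundances are log-normal (log-mean 3, log-sd 1 → median ≈ 20
individuals/sample) in every scenario. `sparse_autumn=True` thins two
sites' autumn samples to 0–1 species to exercise the NA reporting path.

What the generator does *not* emulate: real rotifer population dynamics,
seasonal succession, detection error, spatial autocorrelation between
sites, or any water-chemistry covariate. Passing the scenario-recovery
tests therefore shows the *inference machinery* recovers planted assembly
signals under idealized sampling — not that field data of this shape would
yield equally clean gradients.

## Problem sizes used in validation

The automated checks run the closed-form oracles at 1000 random parameter
draws (K2P) and 100 random tables/inputs (Gower, Rao, NJ); null-model
calibration uses 1000 draws × 999 nulls on a 12-species pool; Mantel
calibration uses 500 replicates of 10-label matrices at 99 permutations;
scenario recovery uses 20 seeded full-size runs per scenario (10 in the
standalone reproduction script) and ≥1000 pooled neutral samples
(450 in the script). These sizes keep every Monte-Carlo assertion's
sampling error well inside its tolerance band.

## Known limitations

- Surrogate substitution for species missing a sequence is not
  implemented: the alignment must cover every community species exactly
  (by label), and mismatches are hard errors.
- The NJ implementation targets the ≤ a-few-hundred-species regime
  (dense O(n³) agglomeration); it is not meant for large phylogenies.
- K2P saturation aborts the matrix rather than imputing; highly diverged
  pools need a different substitution model upstream.
- The seasonal OLS uses ≤ 15 points; its adjusted R² is accordingly noisy,
  which is why the α sweep is paired and why per-season optima on real
  data should be read alongside the full `alpha_scan.csv` curve rather
  than as point estimates.
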