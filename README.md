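# fpdiv

Functional–phylogenetic diversity analysis of species communities along an
environmental gradient.

`fpdiv` is built for the situation a community ecologist faces when asking
*which process assembles communities along a pollution (or any other)
gradient*: species differ both in their functional traits and in their
evolutionary history, and neither axis alone captures how "different" two
co-occurring species really are. The package was shaped around a concrete
study design — rotifer communities sampled at five stations along an oxbow
lake receiving aquaculture effluent — but every stage is generic: it needs
only a trait table, an aligned set of sequences (one per species) and a
sample × species abundance table.

## The method

1. **Functional distances.** Species × trait tables (eight rotifer traits:
   body size, trophi type, feeding type, protection, lorica type, corona
   type, habitat preference, tolerance) are turned into a Gower distance
   matrix `FDist ∈ [0, 1]`, mixing numeric, ordinal and categorical traits.
2. **Phylogenetic distances.** Aligned COI-like sequences give Kimura
   two-parameter distances, `d = -½ ln[(1-2P-Q)√(1-2Q)]`; a
   neighbour-joining tree (with column-bootstrap support) is built from
   them and its patristic distances are standardized to `[0, 1]` to give
   `PDist`.
3. **Blending.** The two are combined as

   `FPDist_ij = (α·PDist_ij^ρ + (1-α)·FDist_ij^ρ)^{1/ρ}`,  ρ = 2,

   with the weight α swept over 41 levels (0 to 1, step 0.025). FDist–PDist
   concordance (trait conservatism) is quantified by a Mantel test.
4. **Assembly inference.** For every sample, the abundance-weighted mean
   pairwise FPDist (MFPD) is compared against 999 randomizations that hold
   richness and the abundance vector fixed while drawing species identities
   from the regional pool. The effect size is the probit of the observed
   value's mid-p quantile in the null: ES < 0 means co-occurring species
   are more similar than chance (environmental filtering), ES > 0 means
   they are over-dispersed (limiting similarity).
5. **α selection and diversity.** Per season, α is chosen where the
   adjusted R² of `ES ~ distance from the source` peaks; diversity is then
   summarized per sample by Rao's quadratic entropy `Q = Σ d_ij p_i p_j` at
   that α.

A fully seeded synthetic-data generator (`fpdiv.simulate`) produces
study-shaped bundles — Yule tree, K2P-evolved alignment, conservatively
evolved traits, and communities assembled under *neutral*, *filtering* or
*limiting* rules — so the whole inference chain can be validated against
known ground truth.

## Worked example

```bash
python examples/03_assembly_inference.py
```

simulates a filtering gradient (24 species, 5 sites at 0–3500 m, 3 dates ×
3 seasons, seed 42) and runs the full pipeline. It prints, among other
things:

```
Mantel r (FDist vs PDist) = 0.6678, p = 0.0010

per-site mean effect size with 95% bootstrap CI:
season site  distance_m  mean_es   ci_lo   ci_hi  n_dates
summer   K1       0.000   -1.923  -1.986  -1.832        3
summer   K2     500.000   -1.712  -2.183  -1.273        3
summer   K3    2500.000    0.622  -0.520   1.296        3
summer   K4    3000.000    0.994   0.497   1.296        3
summer   K5    3500.000    1.133   0.419   1.711        3

mean Rao's quadratic entropy per site:
K1   0.269
K2   0.318
K3   0.458
```

The Mantel r shows the simulated traits are phylogenetically conserved.
The near-source sites (K1, K2) have significantly negative mean ES — the
filtering signature the scenario planted — and their Rao's Q is depressed
relative to the unfiltered far sites. `examples/01_species_distances.py`
and `examples/02_blend_and_concordance.py` demonstrate the distance and
blending layers in isolation.

The same analysis is available from the shell:

```bash
fpdiv simulate --scenario filtering --seed 42 --out data/
fpdiv run --traits data/traits.csv --alignment data/alignment.fasta \
          --abundance data/abundance.csv --seed 42 --out results/
```

`fpdiv run` writes tidy CSVs (`alpha_scan.csv`, `optimal_alpha.csv`,
`site_es.csv`, `sample_es.csv`, `rao_q.csv`, `mantel.csv`), the NJ tree
with bootstrap supports (`tree.nwk`) and the serialized configuration;
reruns with the same seed are byte-identical.

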