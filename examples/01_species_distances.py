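"""Trait-based and sequence-based species distances.

Simulates a small species pool (tree -> COI-like alignment + trait table),
then computes the two distance matrices the analysis blends: Gower
functional distances (FDist) and unit-standardized patristic distances
from a K2P/neighbour-joining tree (PDist).
"""

import numpy as np

from fpdiv import (
    gower_matrix,
    k2p_matrix,
    nj_tree,
    patristic_matrix,
    simulate_sequences,
    simulate_traits,
    simulate_tree,
    standardize_unit,
)

tree = simulate_tree(n_species=8, seed=4)
alignment = simulate_sequences(tree, length=621, kappa=2.0, seed=4)
traits = simulate_traits(tree, seed=4)
species = sorted(traits.species)

fdist = gower_matrix(traits).filter(species)
k2p = k2p_matrix(alignment).filter(species)
nj = nj_tree(k2p)
pdist = standardize_unit(patristic_matrix(nj, labels=species))

np.set_printoptions(precision=3, suppress=True)
print("species:", ", ".join(species))
print("\nGower functional distances (FDist, 0..1):")
print(fdist.data)
print("\nK2P distances (substitutions/site):")
print(k2p.data)
print("\nstandardized NJ patristic distances (PDist, max = 1):")
print(pdist.data)
print(
    "\nEach FDist entry is the mean per-trait dissimilarity of a species"
    "\npair; each PDist entry is their path length on the NJ tree, scaled"
    "\nso the most divergent pair sits at 1."
)
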