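"""Sequence-based phylogenetic distances.

K2P (Kimura two-parameter) pairwise distances from an aligned set of COI
sequences, neighbour-joining tree construction with nonparametric bootstrap
support, patristic distances, and unit standardization of a distance matrix.

The phylogenetic distance matrix PDist used by the blending step is, by
default, the unit-standardized patristic distance matrix of the NJ tree
built from the K2P matrix; standardizing the raw K2P matrix directly is
available via ``PipelineConfig.pdist_route = "direct"``.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .io import AlignedSequences

__all__ = [
    "SitePairCounts",
    "SaturationError",
    "count_site_pairs",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "patristic_matrix",
    "standardize_unit",
    "bootstrap_support",
    "pdist_from_alignment",
    "tree_to_newick",
]

logger = logging.getLogger(__name__)

# nucleotide codes; >=4 means ambiguous/gap, excluded pairwise.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _base in enumerate("ACGT"):
    _CODE[ord(_base)] = _i


class SitePairCounts(NamedTuple):
    """Comparable-site counts for one sequence pair (pairwise deletion)."""

    n_compared: int
    n_transitions: int
    n_transversions: int


class SaturationError(ValueError):
    """K2P distance undefined: substitutions too saturated (log of <= 0)."""


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_site_pairs(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> SitePairCounts:
    """Count comparable sites, transitions (A<->G, C<->T) and transversions.

    Sites where either symbol is not an unambiguous A/C/G/T are excluded
    (pairwise deletion).
    """
    a = _encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = _encode(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no overlap: zero comparable sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    # with A=0,C=1,G=2,T=3 purines are even codes, so a substitution is a
    # transition iff both codes share parity
    ts = int((diff & ((av & 1) == (bv & 1))).sum())
    tv = int(diff.sum()) - ts
    return SitePairCounts(n, ts, tv)


def k2p_distance(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance, substitutions/site.

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)] with P, Q the transition and
    transversion proportions over compared sites.
    """
    n, ts, tv = counts
    if n <= 0:
        raise ValueError("n_compared must be positive")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (saturation): P={p:.4f}, Q={q:.4f}"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return 0.0 if d == 0.0 else d  # avoid -0.0 for identical sequences


def _k2p_matrix_encoded(enc: Sequence[np.ndarray], labels: Sequence[str]) -> DistanceMatrix:
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(count_site_pairs(enc[i], enc[j]))
            except ValueError as exc:
                raise type(exc)(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from None
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=list(labels))


def k2p_matrix(alignment: AlignedSequences) -> DistanceMatrix:
    """Pairwise K2P distance matrix over all species of the alignment."""
    labels = alignment.species
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    enc = [_encode(alignment.sequences[s]) for s in labels]
    return _k2p_matrix_encoded(enc, labels)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining (Saitou & Nei) tree from a distance matrix.

    Deterministic: among pairs tied on the Q criterion the lexicographically
    smallest label pair is joined.  Negative limb lengths are clamped to zero
    with the deficit transferred to the sibling limb, preserving the joined
    pair's path length.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour-joining needs at least 3 labels")
    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
        keys.append(lab)
    D = dm.data.astype(float).copy()
    active = list(range(n))

    def _attach(parent: dendropy.Node, child_idx: int, length: float) -> None:
        child = nodes[child_idx]
        parent.add_child(child)
        child.edge.length = length

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        q = 0.5 * (q + q.T)  # kill 1-ULP float asymmetry from summation order
        iu = np.triu_indices(m, k=1)
        tri = q[iu]
        qmin = tri.min()
        best = None
        for flat in np.flatnonzero(tri == qmin):
            ii, jj = int(iu[0][flat]), int(iu[1][flat])
            pair = tuple(sorted((keys[active[ii]], keys[active[jj]])))
            if best is None or pair < best[0]:
                best = (pair, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            logger.debug("clamping negative limb %.3g at %s", li, keys[i])
            lj += li
            li = 0.0
        if lj < 0.0:
            logger.debug("clamping negative limb %.3g at %s", lj, keys[j])
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        _attach(parent, i, li)
        _attach(parent, j, lj)
        new = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (i, j):
                continue
            D[new, kk] = D[kk, new] = 0.5 * (D[i, kk] + D[j, kk] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final unresolved trichotomy
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        if length < 0.0:
            logger.debug("clamping negative terminal limb %.3g", length)
            length = 0.0
        _attach(root, idx, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_matrix(
    tree: dendropy.Tree, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise sums of branch lengths along leaf-to-leaf paths."""
    pdm = tree.phylogenetic_distance_matrix()
    if labels is None:
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=list(labels))


def standardize_unit(dm: DistanceMatrix) -> DistanceMatrix:
    """Scale a distance matrix so the maximum off-diagonal entry equals 1.

    Division by the maximum (rather than min-max scaling) preserves zero
    self-distances and all distance ratios; the operation is idempotent and
    scale-invariant.
    """
    data = dm.data
    mx = data.max()
    if mx <= 0.0:
        raise ValueError("degenerate distances: all entries are zero")
    return DistanceMatrix(data / mx, ids=list(dm.ids))


def _internal_splits(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Map id(node) -> normalized leaf-label split for internal edges."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_labels)
    splits: dict[int, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_labels - below
        if 2 <= len(side) <= len(all_labels) - 2:
            splits[id(node)] = side
    return splits


def bootstrap_support(
    alignment: AlignedSequences, n_reps: int, seed: int
) -> dendropy.Tree:
    """NJ tree with bootstrap support on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate is run through K2P + NJ and the support of an internal edge of
    the original tree is the fraction of successful replicates containing
    its bipartition.  Replicates whose K2P computation fails (saturation or
    no overlap) are skipped and logged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(k2p_matrix(alignment))
    target = _internal_splits(tree)
    counts = {key: 0 for key in target}
    labels = alignment.species
    enc = np.array([_encode(alignment.sequences[s]) for s in labels])
    length = enc.shape[1]
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        sub = enc[:, cols]
        try:
            rep_tree = nj_tree(_k2p_matrix_encoded(list(sub), labels))
        except ValueError:
            logger.debug("bootstrap replicate skipped (K2P failure)")
            continue
        n_ok += 1
        rep_splits = set(_internal_splits(rep_tree).values())
        for key, side in target.items():
            if side in rep_splits:
                counts[key] += 1
    if n_ok == 0:
        raise ValueError("all bootstrap replicates failed")
    if n_ok < n_reps:
        logger.info("bootstrap: %d/%d replicates usable", n_ok, n_reps)
    for node in tree.preorder_node_iter():
        if id(node) in counts:
            node.label = f"{counts[id(node)] / n_ok:.3f}"
    return tree


def pdist_from_alignment(
    alignment: AlignedSequences, route: str = "tree"
) -> tuple[DistanceMatrix, dendropy.Tree]:
    """Unit-standardized phylogenetic distance matrix PDist plus the NJ tree.

    route="tree": standardized patristic distances of the NJ tree (default);
    route="direct": standardized raw K2P matrix (tree still returned).
    """
    k2p = k2p_matrix(alignment)
    tree = nj_tree(k2p)
    if route == "tree":
        pdist = standardize_unit(patristic_matrix(tree, labels=alignment.species))
    elif route == "direct":
        pdist = standardize_unit(k2p)
    else:
        raise ValueError("route must be 'tree' or 'direct'")
    return pdist, tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths and any internal-node labels."""
    return tree.as_string(schema="newick", suppress_rooting=True)
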