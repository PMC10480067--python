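"""Functional-phylogenetic distance blending and matrix concordance.

FPDist_ij = (alpha * PDist_ij^rho + (1 - alpha) * FDist_ij^rho)^(1/rho)

alpha = 0 gives the purely functional distance, alpha = 1 the purely
phylogenetic one; rho (an integer >= 1) controls the nonlinearity of the
blend, rho = 2 being the conventional choice.  Both inputs must be unit
scaled so the blend stays in [0, 1].

Concordance between the functional and phylogenetic matrices is quantified
with a Mantel test (Pearson correlation of the off-diagonal distance
vectors, permutation null, one-tailed "greater" by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

__all__ = ["MantelResult", "fp_distance", "mantel_test"]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


def fp_distance(
    pd_dm: DistanceMatrix, fd_dm: DistanceMatrix, alpha: float, rho: int = 2
) -> DistanceMatrix:
    """Blend phylogenetic and functional distances with weight ``alpha``."""
    if list(pd_dm.ids) != list(fd_dm.ids):
        raise ValueError("PDist and FDist must share identical label order")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if rho < 1 or int(rho) != rho:
        raise ValueError("rho must be an integer >= 1")
    if alpha == 0.0:
        return DistanceMatrix(fd_dm.data.copy(), ids=list(fd_dm.ids))
    if alpha == 1.0:
        return DistanceMatrix(pd_dm.data.copy(), ids=list(pd_dm.ids))
    blended = (alpha * pd_dm.data ** rho + (1.0 - alpha) * fd_dm.data ** rho) ** (1.0 / rho)
    np.fill_diagonal(blended, 0.0)
    return DistanceMatrix(blended, ids=list(pd_dm.ids))


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix concordance.

    Pearson correlation of the strictly-lower-triangle vectors; the null is
    generated by simultaneous row/column permutation of ``d2``;
    p = (#{null r >= observed} + 1) / (n_perm + 1) for the one-tailed
    "greater" alternative (a "two-sided" alternative is also accepted).
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("matrices must share the same label set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for name, dm in (("d1", d1), ("d2", d2)):
        if np.isclose(dm.condensed_form().std(), 0.0):
            raise ValueError(f"{name} has a constant off-diagonal vector")
    d2 = d2.filter(d1.ids)
    r, p, _ = _skbio_mantel(
        d1, d2, method="pearson", permutations=n_perm,
        alternative=alternative, seed=seed,
    )
    return MantelResult(r=float(r), p=float(p), n_perm=n_perm)
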