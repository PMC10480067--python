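"""Functional distances from the trait table (Gower's distance).

Each of the eight traits contributes a partial distance in [0, 1]:
numeric and ordinal traits contribute |a - b| / range (range computed over
the whole table; a zero range contributes 0), categorical traits contribute
0/1 on mismatch.  The Gower distance of a species pair is the mean of the
partial distances over the traits observed in both species; traits missing
in either member of the pair are dropped from that pair's mean.

Ordinal traits (habitat preference, tolerance) are scored as numeric ranks
with range normalization — the classic Gower treatment; set
``ordinal_as_categorical=True`` for the 0/1 alternative.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import TRAIT_SCHEMA, TraitTable

__all__ = ["trait_values", "trait_ranges", "gower_pair", "gower_matrix"]


def trait_values(tt: TraitTable, ordinal_as_categorical: bool = False) -> pd.DataFrame:
    """Traits encoded for Gower: numeric columns as floats (ordinals as
    their rank), categoricals as pandas category codes; missing as NaN."""
    del ordinal_as_categorical  # encoding is identical; only the kind differs
    out = {}
    for trait, (kind, vocab) in TRAIT_SCHEMA.items():
        col = tt.data[trait]
        if kind == "numeric":
            out[trait] = col.astype(float)
        elif kind == "ordinal":
            ranks = {level: float(i) for i, level in enumerate(vocab)}
            out[trait] = col.map(ranks).astype(float)
        else:
            codes = pd.Categorical(col, categories=list(vocab)).codes.astype(float)
            out[trait] = pd.Series(codes, index=col.index).replace(-1.0, np.nan)
    return pd.DataFrame(out, index=tt.data.index)


def _trait_kind(trait: str, ordinal_as_categorical: bool) -> str:
    kind = TRAIT_SCHEMA[trait][0]
    if kind == "ordinal" and ordinal_as_categorical:
        return "categorical"
    return "numeric" if kind in ("numeric", "ordinal") else "categorical"


def trait_ranges(tt: TraitTable, ordinal_as_categorical: bool = False) -> dict[str, float]:
    """Per-trait ranges over the full table (0 for categorical traits)."""
    vals = trait_values(tt, ordinal_as_categorical)
    ranges: dict[str, float] = {}
    for trait in TRAIT_SCHEMA:
        if _trait_kind(trait, ordinal_as_categorical) == "numeric":
            col = vals[trait].dropna()
            ranges[trait] = float(col.max() - col.min()) if len(col) else 0.0
        else:
            ranges[trait] = 0.0
    return ranges


def gower_pair(
    a: Mapping[str, float],
    b: Mapping[str, float],
    ranges: Mapping[str, float],
    ordinal_as_categorical: bool = False,
) -> float:
    """Gower distance between two encoded trait records.

    ``a`` and ``b`` map trait name -> encoded value (as produced by
    :func:`trait_values`); ``ranges`` holds the table-wide numeric ranges.
    """
    total = 0.0
    count = 0
    for trait in TRAIT_SCHEMA:
        va, vb = a.get(trait, np.nan), b.get(trait, np.nan)
        if pd.isna(va) or pd.isna(vb):
            continue
        count += 1
        if _trait_kind(trait, ordinal_as_categorical) == "numeric":
            rng = ranges[trait]
            total += abs(va - vb) / rng if rng > 0 else 0.0
        else:
            total += 0.0 if va == vb else 1.0
    if count == 0:
        raise ValueError("no shared non-missing traits between the pair")
    return total / count


def gower_matrix(tt: TraitTable, ordinal_as_categorical: bool = False) -> DistanceMatrix:
    """Functional distance matrix FDist over all species of the table."""
    species = tt.species
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    vals = trait_values(tt, ordinal_as_categorical)
    n = len(species)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for trait in TRAIT_SCHEMA:
        x = vals[trait].to_numpy(dtype=float)
        present = ~np.isnan(x)
        both = present[:, None] & present[None, :]
        if _trait_kind(trait, ordinal_as_categorical) == "numeric":
            col = x[present]
            rng = col.max() - col.min() if col.size else 0.0
            part = np.abs(x[:, None] - x[None, :]) / rng if rng > 0 else np.zeros((n, n))
        else:
            part = (x[:, None] != x[None, :]).astype(float)
        part = np.where(both, part, 0.0)
        num += np.nan_to_num(part)
        cnt += both
    if (cnt[~np.eye(n, dtype=bool)] == 0).any():
        ii, jj = np.argwhere((cnt == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no shared non-missing traits for pair ({species[ii]!r}, {species[jj]!r})"
        )
    mat = num / cnt
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)  # exact symmetry against float noise
    return DistanceMatrix(mat, ids=species)
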