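"""Domain types and file I/O.

The pipeline consumes three inputs: an aligned set of nucleotide sequences
(one per species, FASTA), a species x trait table (CSV, eight rotifer
functional traits with a fixed schema), and a sample x species abundance
table (CSV, samples being site x date with season and distance-from-source
metadata).  All three are validated eagerly so that schema violations fail
loudly at read time rather than surfacing as NaNs mid-analysis.

Species matching across the three inputs is by exact label string.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix

__all__ = [
    "TRAIT_SCHEMA",
    "HABITAT_LEVELS",
    "SEASONS",
    "SchemaError",
    "TraitTable",
    "AlignedSequences",
    "CommunityMatrix",
    "PipelineConfig",
    "DistanceMatrix",
    "read_trait_table",
    "read_alignment",
    "read_community_matrix",
    "write_alignment",
]


class SchemaError(ValueError):
    """An input violates the fixed trait/community schema."""


#: Ordered saprobity (organic-pollution) preference levels, clean -> polluted.
HABITAT_LEVELS = (
    "oligosaprobic",
    "oligo_beta_mesosaprobic",
    "beta_mesosaprobic",
    "beta_alpha_mesosaprobic",
)

#: Trait schema: name -> (kind, closed vocabulary or None).
#: kind is one of "numeric", "ordinal", "categorical".  Ordinal traits carry
#: their level order; tolerance is an ordinal integer 1 (narrow) .. 5 (wide).
TRAIT_SCHEMA: dict[str, tuple[str, tuple | None]] = {
    "body_size_um": ("numeric", None),
    "trophi_type": (
        "categorical",
        ("malleate", "virgate", "ramate", "incudate", "malleoramate", "forcipate"),
    ),
    "feeding_type": (
        "categorical",
        (
            "microphagous",
            "polyphagous",
            "macrophagous_algivore",
            "macrophagous_predator",
        ),
    ),
    "protection": ("categorical", ("active", "passive")),
    "lorica_type": ("categorical", ("illoricate", "loricate_ridged", "loricate_spined")),
    "corona_type": (
        "categorical",
        (
            "asplanchna",
            "philodina",
            "euchlanis_brachionus",
            "notommata",
            "dichranophorus",
            "conochilus",
            "hexarthra_testudinella",
            "collotheca",
        ),
    ),
    "habitat_preference": ("ordinal", HABITAT_LEVELS),
    "tolerance": ("ordinal", (1, 2, 3, 4, 5)),
}

TRAIT_NAMES = tuple(TRAIT_SCHEMA)

SEASONS = ("spring", "summer", "autumn")


@dataclass(frozen=True)
class TraitTable:
    """Species x trait records under the fixed eight-trait schema.

    ``data`` is indexed by species label with exactly the eight schema
    columns; missing trait values are NaN and are handled pairwise by the
    Gower distance.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRAIT_NAMES if c not in df.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise SchemaError(f"duplicate species labels: {dups}")
        for species, row in df.iterrows():
            for trait, (kind, vocab) in TRAIT_SCHEMA.items():
                value = row[trait]
                if _is_missing(value):
                    continue
                if trait == "body_size_um":
                    if not float(value) > 0:
                        raise SchemaError(
                            f"species {species!r}: body_size_um must be > 0, got {value!r}"
                        )
                elif trait == "tolerance":
                    if int(value) != value or not (1 <= int(value) <= 5):
                        raise SchemaError(
                            f"species {species!r}: tolerance must be an integer in 1..5, "
                            f"got {value!r}"
                        )
                elif value not in vocab:
                    raise SchemaError(
                        f"species {species!r}, trait {trait!r}: value {value!r} not in "
                        f"allowed vocabulary {vocab}"
                    )
        object.__setattr__(self, "data", df[list(TRAIT_NAMES)])

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def subset(self, species: Sequence[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[list(species)])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="species")


@dataclass(frozen=True)
class AlignedSequences:
    """Equal-length nucleotide sequences keyed by species label."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {label: len(s) for label, s in self.sequences.items()}
        distinct = set(lengths.values())
        if len(distinct) != 1:
            offender = max(lengths, key=lambda k: abs(lengths[k] - np.median(list(lengths.values()))))
            raise ValueError(
                f"aligned sequences must have equal length; got lengths {sorted(distinct)} "
                f"(e.g. record {offender!r} has length {lengths[offender]})"
            )
        upper = {k: v.upper() for k, v in self.sequences.items()}
        bad = {
            k: sorted(set(v) - set("ACGTN-"))
            for k, v in upper.items()
            if set(v) - set("ACGTN-")
        }
        # IUPAC ambiguity codes are tolerated and treated as missing downstream.
        iupac = set("RYSWKMBDHV")
        bad = {k: [c for c in v if c not in iupac] for k, v in bad.items()}
        bad = {k: v for k, v in bad.items() if v}
        if bad:
            raise ValueError(f"non-nucleotide symbols in alignment: {bad}")
        object.__setattr__(self, "sequences", upper)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def subset(self, species: Sequence[str]) -> "AlignedSequences":
        missing = [s for s in species if s not in self.sequences]
        if missing:
            raise KeyError(f"species not in alignment: {missing}")
        return AlignedSequences({s: self.sequences[s] for s in species})


@dataclass(frozen=True)
class CommunityMatrix:
    """Sample x species abundances with per-sample metadata.

    ``abundance`` is indexed by sample id (``"<site>|<date>"``); ``meta``
    shares that index and carries ``site``, ``date`` (ISO-8601), ``season``
    and ``distance_m`` (distance from the effluent source, metres).
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.meta.index):
            raise ValueError("abundance and meta must share the sample index")
        for col in ("site", "date", "season", "distance_m"):
            if col not in self.meta.columns:
                raise ValueError(f"meta missing column {col!r}")
        bad_season = sorted(set(self.meta["season"]) - set(SEASONS))
        if bad_season:
            raise SchemaError(f"unknown season labels: {bad_season} (allowed: {SEASONS})")
        abund = self.abundance.astype(float)
        if (abund.to_numpy() < 0).any():
            loc = np.argwhere(abund.to_numpy() < 0)[0]
            raise SchemaError(
                f"negative abundance at sample {abund.index[loc[0]]!r}, "
                f"species {abund.columns[loc[1]]!r}"
            )
        if (self.meta["distance_m"].astype(float) < 0).any():
            raise SchemaError("distance_m must be nonnegative")
        per_site = self.meta.groupby("site")["distance_m"].nunique()
        inconsistent = sorted(per_site[per_site > 1].index)
        if inconsistent:
            raise SchemaError(
                f"distance_m must be constant within a site; inconsistent sites: {inconsistent}"
            )
        object.__setattr__(self, "abundance", abund)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    def richness(self) -> pd.Series:
        """Number of species with positive abundance, per sample."""
        return (self.abundance > 0).sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        wide = pd.concat([self.meta, self.abundance], axis=1)
        wide.to_csv(path, index=False)


def _default_alpha_grid() -> tuple[float, ...]:
    # 41 levels, 0 to 1 in steps of 0.025
    return tuple(np.round(np.linspace(0.0, 1.0, 41), 6))


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full analysis.

    Defaults follow the study design: FPDist exponent rho=2, a 41-level
    alpha grid (step 0.025), 999 null randomizations, 999 bootstrap
    resamples, 9999 Mantel permutations, 3000 tree-bootstrap replicates.
    """

    seed: int
    rho: int = 2
    alpha_grid: tuple[float, ...] = field(default_factory=_default_alpha_grid)
    n_null: int = 999
    n_boot: int = 999
    n_mantel: int = 9999
    n_tree_boot: int = 3000
    pdist_route: str = "tree"  # "tree" (patristic) or "direct" (raw K2P matrix)
    ordinal_as_categorical: bool = False
    position_as_rank: bool = False  # regress ES on site rank instead of metres
    pool: str = "global"  # null-model species pool: "global" or "per_season"

    def __post_init__(self) -> None:
        if self.rho < 1 or int(self.rho) != self.rho:
            raise ValueError("rho must be an integer >= 1")
        for name in ("n_null", "n_boot", "n_mantel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_tree_boot < 0:
            raise ValueError("n_tree_boot must be >= 0")
        grid = tuple(float(a) for a in self.alpha_grid)
        if not grid:
            raise ValueError("alpha_grid must be non-empty")
        if any(not (0.0 <= a <= 1.0) for a in grid):
            raise ValueError("alpha_grid values must lie in [0, 1]")
        if list(grid) != sorted(grid):
            raise ValueError("alpha_grid must be sorted ascending")
        if self.pdist_route not in ("tree", "direct"):
            raise ValueError("pdist_route must be 'tree' or 'direct'")
        if self.pool not in ("global", "per_season"):
            raise ValueError("pool must be 'global' or 'per_season'")
        object.__setattr__(self, "alpha_grid", grid)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        payload["alpha_grid"] = tuple(payload["alpha_grid"])
        return cls(**payload)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a species x trait CSV (``species`` column plus the 8 traits)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise SchemaError("trait CSV must have a 'species' column")
    df = df.set_index("species")
    # surface row numbers in schema errors
    try:
        return TraitTable(df)
    except SchemaError:
        for i, (species, row) in enumerate(df.iterrows(), start=2):  # header is line 1
            try:
                TraitTable(pd.DataFrame([row], index=[species]))
            except SchemaError as exc:
                raise SchemaError(f"line {i}: {exc}") from None
        raise


def read_alignment(path: str | Path) -> AlignedSequences:
    """Read a FASTA alignment with unique headers."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return AlignedSequences(sequences)


def write_alignment(aln: AlignedSequences, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.sequences.items():
            fh.write(f">{label}\n{seq}\n")


def read_community_matrix(path: str | Path) -> CommunityMatrix:
    """Read a wide sample x species CSV with leading metadata columns."""
    df = pd.read_csv(path, dtype={"site": str, "date": str, "season": str})
    meta_cols = ["site", "date", "season", "distance_m"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"community CSV missing metadata columns: {missing}")
    species_cols = [c for c in df.columns if c not in meta_cols]
    if not species_cols:
        raise SchemaError("community CSV has no species columns")
    sample_ids = df["site"].astype(str) + "|" + df["date"].astype(str)
    if sample_ids.duplicated().any():
        raise SchemaError(
            f"duplicate samples: {sorted(sample_ids[sample_ids.duplicated()])}"
        )
    meta = df[meta_cols].copy()
    meta.index = pd.Index(sample_ids, name="sample")
    abund = df[species_cols].copy()
    abund.index = meta.index
    try:
        abund = abund.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric abundance value: {exc}") from None
    return CommunityMatrix(abund, meta)
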