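"""Synthetic study-shaped data with known assembly rules.

Generates an internally consistent bundle — a Yule phylogeny, a K2P-evolved
nucleotide alignment, a conservatively evolved eight-trait table, and
site x date community samples assembled under a known rule — so every
pipeline stage can be exercised without field data.  The default dimensions
mirror the study design: a 24-species rotifer pool, five sites at
0/500/2500/3000/3500 m from an effluent source, three sampling dates in
each of three seasons, 621 bp sequences.

Assembly scenarios:

neutral
    species drawn uniformly without replacement; community structure
    carries no signal, so effect sizes should centre on zero.
filtering
    inclusion probability proportional to exp(-strength * delta^2) where
    delta is the species' distance (functional or phylogenetic axis) to a
    tolerant "optimum" species; the strength decays linearly with distance
    from the source, emulating an effluent gradient.  Near-source
    communities are trait-compressed, so effect sizes should go negative
    there.
limiting
    sequential assembly rejecting candidates closer than a minimum blended
    distance to any resident; communities are overdispersed, so effect
    sizes should go positive.

Trait conservatism: log body size evolves by an Ornstein-Uhlenbeck process
(stationary variance 1), ordinal traits by a +-1 random walk with
reflecting bounds, categorical traits by an equal-rates Markov jump
process, all on the same tree as the sequences.  Scaling the trait branch
lengths up (``trait_scale``) saturates these processes and decouples the
traits from the phylogeny.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .blend import fp_distance
from .io import (
    SEASONS,
    TRAIT_SCHEMA,
    AlignedSequences,
    CommunityMatrix,
    TraitTable,
    write_alignment,
)
from .phylo import patristic_matrix, standardize_unit
from .traits import gower_matrix

__all__ = [
    "ScenarioSpec",
    "simulate_tree",
    "simulate_sequences",
    "simulate_traits",
    "assemble_communities",
    "simulate_bundle",
    "write_bundle",
]

_SEASON_MONTHS = {"spring": (3, 4, 5), "summer": (6, 7, 8), "autumn": (9, 10, 11)}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study."""

    scenario: str = "neutral"  # neutral | filtering | limiting
    n_species: int = 24
    distances_m: tuple[float, ...] = (0.0, 500.0, 2500.0, 3000.0, 3500.0)
    n_dates_per_season: int = 3
    filter_strength: float = 25.0
    filter_axis: str = "functional"  # functional | phylogenetic
    limiting_quantile: float = 0.10
    richness_range: tuple[int, int] | None = None
    abundance_mu: float = 3.0  # lognormal log-mean of ind./sample counts
    abundance_sigma: float = 1.0
    alpha: float = 0.5  # blend used by the limiting rule
    rho: int = 2
    seq_length: int = 621
    kappa: float = 2.0
    trait_scale: float = 1.0
    sparse_autumn: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("neutral", "filtering", "limiting"):
            raise ValueError("scenario must be neutral, filtering or limiting")
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        d = list(self.distances_m)
        if any(x < 0 for x in d) or d != sorted(d) or len(set(d)) != len(d):
            raise ValueError("distances_m must be nonnegative and strictly increasing")
        if self.filter_axis not in ("functional", "phylogenetic"):
            raise ValueError("filter_axis must be functional or phylogenetic")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")

    @property
    def n_sites(self) -> int:
        return len(self.distances_m)

    def default_richness_range(self) -> tuple[int, int]:
        if self.richness_range is not None:
            return self.richness_range
        if self.scenario == "limiting":
            return (5, min(8, self.n_species))
        if self.scenario == "filtering":
            # filtering depresses local richness; a filtered site never
            # hosts the whole regional pool
            return (5, min(12, self.n_species))
        return (5, self.n_species)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def simulate_tree(n_species: int, seed: int, depth: float = 0.2) -> dendropy.Tree:
    """Yule (pure-birth) tree with ``n_species`` leaves, scaled so the
    maximum root-to-tip depth equals ``depth`` substitutions/site."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    max_depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = depth / max_depth if max_depth > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.deroot()  # basal trifurcation; 2n-3 edges, as for an unrooted tree
    tree.seed_node.edge.length = None
    tree.is_rooted = False
    return tree


def _k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """4x4 base substitution probabilities for a branch of ``d``
    expected substitutions/site under K2P."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e_tv = np.exp(-4.0 * bt)
    e_ts = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv  # each of the two transversion targets
    m = np.full((4, 4), p_tv)
    for s in range(4):
        m[s, s ^ 2] = p_ts  # transition partner: A<->G, C<->T
        m[s, s] = 1.0 - p_ts - 2.0 * p_tv
    return m


def simulate_sequences(
    tree: dendropy.Tree, length: int = 621, kappa: float = 2.0, seed: int = 0
) -> AlignedSequences:
    """Evolve equal-length sequences along the tree under the K2P model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rng = _rng(seed, 11)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, 4, size=length)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        if t <= 0:
            child = parent_seq.copy()
        else:
            m = _k2p_transition_matrix(t, kappa)
            cum = m.cumsum(axis=1)
            u = rng.random(length)
            child = (u[:, None] > cum[parent_seq]).sum(axis=1).astype(np.int64)
        states[id(node)] = child
    bases = np.array(list("ACGT"))
    seqs = {
        leaf.taxon.label: "".join(bases[states[id(leaf)]])
        for leaf in tree.leaf_node_iter()
    }
    return AlignedSequences(dict(sorted(seqs.items())))


def _evolve_markov(tree, n_states: int, rate: float, rng) -> dict[str, int]:
    """Equal-rates Markov jump process; returns leaf label -> state."""
    k = n_states
    states: dict[int, int] = {id(tree.seed_node): int(rng.integers(0, k))}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        t = (node.edge.length or 0.0) * rate
        # P(stay) for the k-state equal-rates chain
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k * t / (k - 1.0))
        if rng.random() < p_same:
            states[id(node)] = parent
        else:
            other = int(rng.integers(0, k - 1))
            states[id(node)] = other if other < parent else other + 1
    return {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}


def _evolve_walk(tree, n_states: int, rate: float, rng) -> dict[str, int]:
    """+-1 random walk with reflecting bounds (ordinal trait evolution)."""
    states: dict[int, int] = {id(tree.seed_node): int(rng.integers(0, n_states))}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = states[id(node.parent_node)]
        t = (node.edge.length or 0.0) * rate
        for _ in range(rng.poisson(t)):
            step = 1 if rng.random() < 0.5 else -1
            s = min(max(s + step, 0), n_states - 1)
        states[id(node)] = s
    return {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}


def _evolve_ou(tree, theta: float, rng) -> dict[str, float]:
    """Ornstein-Uhlenbeck with stationary variance 1, mean 0."""
    states: dict[int, float] = {id(tree.seed_node): float(rng.normal())}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        x = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        decay = np.exp(-theta * t)
        states[id(node)] = float(
            x * decay + np.sqrt(max(1.0 - decay**2, 0.0)) * rng.normal()
        )
    return {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}


def simulate_traits(
    tree: dendropy.Tree, seed: int = 0, trait_scale: float = 1.0
) -> TraitTable:
    """Evolve the eight-trait table on the tree (trait conservatism).

    Branch lengths are first rescaled so the tree depth is 1 "trait time"
    unit, then multiplied by ``trait_scale``; large values saturate the
    processes and decouple traits from the phylogeny.
    """
    rng = _rng(seed, 13)
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    unit = (trait_scale / depth) if depth > 0 else 0.0
    scaled = dendropy.Tree(tree)  # deep clone; rescale the copy only
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= unit

    leaves = sorted(lf.taxon.label for lf in scaled.leaf_node_iter())
    size_raw = _evolve_ou(scaled, theta=1.0, rng=rng)
    vals = np.array([size_raw[s] for s in leaves])
    span = vals.max() - vals.min()
    lo, hi = np.log(50.0), np.log(1500.0)
    if span > 0:
        log_size = lo + (vals - vals.min()) / span * (hi - lo)
    else:
        log_size = np.full(len(leaves), (lo + hi) / 2.0)
    body_size = np.round(np.exp(log_size), 1)

    records: dict[str, dict] = {s: {"body_size_um": body_size[i]} for i, s in enumerate(leaves)}
    for trait, (kind, vocab) in TRAIT_SCHEMA.items():
        if trait == "body_size_um":
            continue
        k = len(vocab)
        if kind == "categorical":
            leaf_states = _evolve_markov(scaled, k, rate=1.0, rng=rng)
        else:  # ordinal: ordered random walk keeps neighbours similar
            leaf_states = _evolve_walk(scaled, k, rate=1.5, rng=rng)
        for s in leaves:
            records[s][trait] = vocab[leaf_states[s]]
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "species"
    return TraitTable(df)


def _dates_for(season: str, n_dates: int) -> list[str]:
    months = _SEASON_MONTHS[season]
    return [
        f"2019-{months[i % 3]:02d}-{10 + 5 * (i // 3):02d}" for i in range(n_dates)
    ]


def _weighted_draw_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    chosen = []
    w = weights.astype(float).copy()
    for _ in range(k):
        total = w.sum()
        if total <= 0:
            # all remaining weights numerically zero: fall back to uniform
            w = np.where(w >= 0, 1.0, 0.0)
            w[chosen] = 0.0
            total = w.sum()
        idx = rng.choice(len(w), p=w / total)
        chosen.append(int(idx))
        w[idx] = 0.0
    return np.array(chosen)


def assemble_communities(
    tree: dendropy.Tree, traits: TraitTable, spec: ScenarioSpec
) -> CommunityMatrix:
    """Assemble site x date communities under the scenario's rule."""
    species = sorted(traits.species)
    tree_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if species != tree_labels:
        raise ValueError("traits and tree must cover the same species")
    n = len(species)

    fd = gower_matrix(traits).filter(species)
    pdist = standardize_unit(patristic_matrix(tree, labels=species))
    blended = fp_distance(pdist, fd, spec.alpha, spec.rho)
    axis = fd if spec.filter_axis == "functional" else pdist

    tol = traits.data["tolerance"].reindex(species)
    optimum = int(np.argmax(tol.to_numpy()))  # most pollution-tolerant species
    delta = axis.data[:, optimum]

    tau = float(np.quantile(blended.condensed_form(), spec.limiting_quantile))
    lo, hi = spec.default_richness_range()
    max_dist = max(spec.distances_m) or 1.0

    rows, meta_rows = [], []
    sample_idx = 0
    for s_i, dist in enumerate(spec.distances_m):
        site = f"K{s_i + 1}"
        for season in SEASONS:
            for date in _dates_for(season, spec.n_dates_per_season):
                rng = _rng(spec.seed, 17, sample_idx)
                sample_idx += 1
                k = int(rng.integers(lo, hi + 1))
                if (
                    spec.sparse_autumn
                    and season == "autumn"
                    and s_i in (2, spec.n_sites - 1)
                ):
                    k = int(rng.integers(0, 2))
                if spec.scenario == "neutral" or spec.filter_strength == 0.0 and spec.scenario == "filtering":
                    chosen = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
                elif spec.scenario == "filtering":
                    # quadratic relaxation: strong at the source, negligible
                    # beyond mid-gradient, zero at the far site
                    strength = spec.filter_strength * (1.0 - dist / max_dist) ** 2
                    w = np.exp(-strength * delta**2)
                    chosen = _weighted_draw_without_replacement(rng, w, k)
                else:  # limiting
                    chosen_list: list[int] = []
                    candidates = list(range(n))
                    rng.shuffle(candidates)
                    for cand in list(candidates):
                        if len(chosen_list) >= k:
                            break
                        if all(blended.data[cand, r] >= tau for r in chosen_list):
                            chosen_list.append(cand)
                    if len(chosen_list) < k:
                        raise ValueError(
                            f"limiting assembly infeasible: reached richness "
                            f"{len(chosen_list)} < {k} at threshold {tau:.3f}; "
                            "use a smaller limiting_quantile or richness"
                        )
                    chosen = np.array(chosen_list)
                abund = np.zeros(n)
                if k:
                    abund[chosen] = np.round(
                        np.exp(rng.normal(spec.abundance_mu, spec.abundance_sigma, size=k)), 2
                    )
                rows.append(abund)
                meta_rows.append(
                    dict(site=site, date=date, season=season, distance_m=float(dist))
                )
    meta = pd.DataFrame(meta_rows)
    index = pd.Index(meta["site"] + "|" + meta["date"], name="sample")
    meta.index = index
    abundance = pd.DataFrame(rows, index=index, columns=species)
    return CommunityMatrix(abundance, meta)


def simulate_bundle(spec: ScenarioSpec) -> dict:
    """Full internally consistent dataset for one scenario."""
    tree = simulate_tree(spec.n_species, spec.seed)
    alignment = simulate_sequences(tree, spec.seq_length, spec.kappa, spec.seed)
    traits = simulate_traits(tree, spec.seed, spec.trait_scale)
    communities = assemble_communities(tree, traits, spec)
    truth = asdict(spec)
    truth["sites"] = {
        f"K{i + 1}": d for i, d in enumerate(spec.distances_m)
    }
    return {
        "tree": tree,
        "alignment": alignment,
        "traits": traits,
        "communities": communities,
        "truth": truth,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["traits"].to_csv(out / "traits.csv")
    write_alignment(bundle["alignment"], out / "alignment.fasta")
    bundle["communities"].to_csv(out / "abundance.csv")
    (out / "tree_true.nwk").write_text(
        bundle["tree"].as_string(schema="newick")
    )
    (out / "truth.json").write_text(json.dumps(bundle["truth"], indent=2) + "\n")
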