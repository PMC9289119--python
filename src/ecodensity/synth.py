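"""Synthetic landscapes, bird communities, traits and phylogenies.

The generator emulates a national point-count monitoring design: census
points of 100 m radius strung along transects of 20 points, each point
described by the proportions of seven aggregated habitat classes within
its radius, and each visited twice in a breeding season.  Every species
has a binary habitat-preference (niche) vector; its within-suitable-
habitat intensity is

    intensity_s = base_intensity * exp(gamma * SSI_s)

so that ``gamma = 0`` is an exact null (all species equally dense inside
their habitat) and positive ``gamma`` makes habitat specialists denser
within their habitat.  Counts per visit are independent Poisson draws
with mean intensity x suitable area at the point.

Trees come from a Yule (pure-birth) process; a sample of perturbed trees
(lognormal branch-length jitter, optional NNI moves) stands in for a
posterior sample from a phylogeny database.  Continuous traits evolve by
Brownian motion along the base tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .density import suitable_area_matrix
from .habitats import AGGREGATED_CLASSES, DIET_CLASSES, NEST_TYPES, POINT_AREA_HA
from .ssi import compute_ssi
from .traits import MORPHOLOGY_TRAITS, REPRODUCTIVE_TRAITS


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic census.

    Defaults describe the study conditions the package is tested under: a
    thousand census points, 150 species, a moderately patchy landscape
    (Dirichlet concentration 0.5 makes most points dominated by one or two
    biotopes, as field census points are), half an individual per hectare
    of suitable habitat for a complete generalist, and a specialization
    effect of 0.2 on the log intensity scale.
    """

    n_points: int = 1000
    n_species: int = 150
    habitat_classes: tuple[str, ...] = tuple(AGGREGATED_CLASSES)
    dirichlet_concentration: float = 0.5
    niche_breadth_probs: tuple[float, ...] | None = None
    base_intensity: float = 0.5
    ssi_effect: float = 0.2
    tree_birth_rate: float = 1.0
    trait_sigma2: float = 1.0
    n_trees: int = 100
    branch_jitter_sd: float = 0.1
    nni_moves: int = 0
    points_per_transect: int = 20
    nest_type_probs: tuple[float, ...] = (0.25, 0.15, 0.30, 0.30)
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 1:
            raise ConfigurationError("n_points must be >= 1")
        if self.n_species < 3:
            raise ConfigurationError("n_species must be >= 3")
        if not (self.dirichlet_concentration > 0):
            raise ConfigurationError("dirichlet_concentration must be > 0")
        if self.base_intensity <= 0:
            raise ConfigurationError("base_intensity must be > 0")
        if self.tree_birth_rate <= 0:
            raise ConfigurationError("tree_birth_rate must be > 0")
        if self.trait_sigma2 < 0:
            raise ConfigurationError("trait_sigma2 must be >= 0")
        if self.n_trees < 0:
            raise ConfigurationError("n_trees must be >= 0")
        if len(self.habitat_classes) < 1:
            raise ConfigurationError("at least one habitat class required")
        H = len(self.habitat_classes)
        if self.niche_breadth_probs is not None:
            probs = np.asarray(self.niche_breadth_probs, dtype=float)
            if probs.size != H or (probs < 0).any() or probs.sum() <= 0:
                raise ConfigurationError(
                    f"niche_breadth_probs must be {H} non-negative weights"
                )
        if abs(sum(self.nest_type_probs) - 1.0) > 1e-9:
            raise ConfigurationError("nest_type_probs must sum to 1")

    @property
    def breadth_probs(self) -> np.ndarray:
        H = len(self.habitat_classes)
        if self.niche_breadth_probs is None:
            return np.full(H, 1.0 / H)
        p = np.asarray(self.niche_breadth_probs, dtype=float)
        return p / p.sum()

    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{i:0{width}d}" for i in range(1, self.n_species + 1)]


@dataclass
class Landscape:
    composition: pd.DataFrame          # point x habitat class proportions
    transect: pd.Series                # point -> transect id
    point_area_ha: float = POINT_AREA_HA


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    niche: pd.DataFrame                # species x habitat class, binary
    diet: pd.DataFrame                 # species x diet class, binary
    ssi_habitat: pd.Series
    ssi_diet: pd.Series
    intensity: pd.Series               # individuals / ha of suitable habitat
    config: SimConfig
    tree: dendropy.Tree | None = None
    traits: pd.DataFrame | None = None

    def validate(self):
        cfg = self.config
        expected = cfg.base_intensity * np.exp(cfg.ssi_effect * self.ssi_habitat)
        assert np.allclose(self.intensity, expected)
        assert set(np.unique(self.niche.to_numpy())) <= {0, 1}
        assert (self.niche.sum(axis=1) >= 1).all()


def simulate_landscape(cfg: SimConfig, rng: np.random.Generator | None = None) -> Landscape:
    """Dirichlet habitat mosaics at census points along transects.

    An infinite concentration is the exactly-uniform limit (every class in
    equal proportion at every point).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    H = len(cfg.habitat_classes)
    point_ids = [f"p{i:05d}" for i in range(1, cfg.n_points + 1)]
    if np.isinf(cfg.dirichlet_concentration):
        comps = np.full((cfg.n_points, H), 1.0 / H)
    else:
        comps = rng.dirichlet(
            np.full(H, cfg.dirichlet_concentration), size=cfg.n_points
        )
    composition = pd.DataFrame(
        comps, index=pd.Index(point_ids, name="point"),
        columns=list(cfg.habitat_classes),
    )
    transect = pd.Series(
        [f"t{i // cfg.points_per_transect + 1:03d}" for i in range(cfg.n_points)],
        index=composition.index, name="transect",
    )
    return Landscape(composition=composition, transect=transect)


def _binary_prefs(
    rng: np.random.Generator, species: list[str], classes: list[str],
    breadth_probs: np.ndarray,
) -> pd.DataFrame:
    H = len(classes)
    mat = np.zeros((len(species), H), dtype=int)
    breadths = rng.choice(np.arange(1, H + 1), size=len(species), p=breadth_probs)
    for i, h in enumerate(breadths):
        mat[i, rng.choice(H, size=h, replace=False)] = 1
    return pd.DataFrame(mat, index=pd.Index(species, name="species"), columns=classes)


def simulate_community(
    cfg: SimConfig, landscape: Landscape, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Poisson point counts for two visits plus the generating truth.

    The returned count table is sparse-long (zero counts omitted) with
    columns ``point, transect, visit, species, count``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    species = cfg.species_ids()
    H = len(cfg.habitat_classes)

    niche = _binary_prefs(rng, species, list(cfg.habitat_classes), cfg.breadth_probs)
    diet = _binary_prefs(
        rng, species, DIET_CLASSES, np.full(len(DIET_CLASSES), 1.0 / len(DIET_CLASSES))
    )
    ssi_hab = pd.Series(
        [compute_ssi(int(h), H) for h in niche.sum(axis=1)],
        index=niche.index, name="ssi_habitat",
    )
    ssi_diet = pd.Series(
        [compute_ssi(int(h), len(DIET_CLASSES)) for h in diet.sum(axis=1)],
        index=diet.index, name="ssi_diet",
    )
    intensity = cfg.base_intensity * np.exp(cfg.ssi_effect * ssi_hab)
    intensity.name = "intensity"

    identity_map = {c: c for c in cfg.habitat_classes}
    suitable = suitable_area_matrix(
        landscape.composition, niche, identity_map, landscape.point_area_ha
    )  # point x species, ha

    mean = suitable.to_numpy() * intensity.to_numpy()[None, :]
    frames = []
    for visit in (1, 2):
        counts = rng.poisson(mean)
        pts, sps = np.nonzero(counts)
        frames.append(
            pd.DataFrame(
                {
                    "point": landscape.composition.index.to_numpy()[pts],
                    "visit": visit,
                    "species": np.asarray(species)[sps],
                    "count": counts[pts, sps],
                }
            )
        )
    counts_long = pd.concat(frames, ignore_index=True)
    counts_long.insert(
        1, "transect", landscape.transect.loc[counts_long["point"]].to_numpy()
    )
    truth = GroundTruth(
        niche=niche, diet=diet, ssi_habitat=ssi_hab, ssi_diet=ssi_diet,
        intensity=intensity, config=cfg,
    )
    truth.validate()
    return counts_long, truth


# ---------------------------------------------------------------------------
# Trees


def yule_tree(
    n_tips: int, birth_rate: float, rng: np.random.Generator,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Sample an ultrametric pure-birth tree with ``n_tips`` extant tips.

    Lineages split at exponential waiting times (rate = k * birth_rate
    with k lineages alive); after the last split the n surviving lineages
    run for one more exponential wait, so terminal edges have strictly
    positive length.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = labels or [f"sp{i}" for i in range(1, n_tips + 1)]
    if len(labels) != n_tips:
        raise ValueError("label count must equal n_tips")
    nodes = [{"start": 0.0, "children": None, "split": None} for _ in range(2)]
    active = [0, 1]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = active.pop(rng.integers(len(active)))
        nodes[i]["split"] = t
        for _ in range(2):
            nodes.append({"start": t, "children": None, "split": None})
            active.append(len(nodes) - 1)
        nodes[i]["children"] = (len(nodes) - 2, len(nodes) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    order = rng.permutation(n_tips)
    label_iter = iter([labels[i] for i in order])

    def newick(i: int) -> str:
        nd = nodes[i]
        if nd["children"] is None:
            return f"{next(label_iter)}:{t_end - nd['start']!r}"
        a, b = nd["children"]
        return f"({newick(a)},{newick(b)}):{nd['split'] - nd['start']!r}"

    nwk = f"({newick(0)},{newick(1)});"
    return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        preserve_underscores=True,
    )


def _jitter_branch_lengths(tree: dendropy.Tree, sd: float, rng) -> None:
    if sd <= 0:
        return
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * np.exp(rng.normal(0.0, sd)))


def _nni_move(tree: dendropy.Tree, rng) -> None:
    candidates = [
        nd for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    if not candidates:
        return
    x = candidates[rng.integers(len(candidates))]
    p = x.parent_node
    siblings = [c for c in p.child_nodes() if c is not x]
    s = siblings[rng.integers(len(siblings))]
    kids = x.child_nodes()
    c = kids[rng.integers(len(kids))]
    x.remove_child(c)
    p.remove_child(s)
    x.add_child(s)
    p.add_child(c)


@dataclass
class TreeSet:
    base: dendropy.Tree
    variants: list[dendropy.Tree] = field(default_factory=list)

    def all_trees(self) -> list[dendropy.Tree]:
        return [self.base] + self.variants


def simulate_tree_set(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> TreeSet:
    """One Yule base tree plus jittered / NNI-perturbed variants."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    base = yule_tree(
        cfg.n_species, cfg.tree_birth_rate, rng, labels=cfg.species_ids()
    )
    variants = []
    for _ in range(cfg.n_trees):
        v = _clone(base)
        _jitter_branch_lengths(v, cfg.branch_jitter_sd, rng)
        for _ in range(cfg.nni_moves):
            _nni_move(v, rng)
        variants.append(v)
    return TreeSet(base=base, variants=variants)


# ---------------------------------------------------------------------------
# Traits


def brownian_trait(
    tree: dendropy.Tree, sigma2: float, rng: np.random.Generator,
    root_value: float = 0.0,
) -> pd.Series:
    """One Brownian-motion trait on a tree: tip values, root at ``root_value``."""
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    value: dict = {}
    tips = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = root_value
        else:
            bl = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            tips[node.taxon.label] = value[node]
    return pd.Series(tips, name="trait")


def simulate_traits(
    tree: dendropy.Tree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Brownian continuous traits plus categorical nest type.

    Morphological and reproductive traits are independent Brownian motions
    (root 0, rate ``trait_sigma2``); body mass is a lognormal transform of
    its own Brownian trait (grams); breeding range is lognormal i.i.d.
    (km^2); nest type is drawn from ``nest_type_probs``.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    out = pd.DataFrame(index=pd.Index(sorted(species), name="species"))
    for trait in MORPHOLOGY_TRAITS + REPRODUCTIVE_TRAITS:
        out[trait] = brownian_trait(tree, cfg.trait_sigma2, rng).reindex(out.index)
    out["body_mass"] = 30.0 * np.exp(
        0.5 * brownian_trait(tree, cfg.trait_sigma2, rng).reindex(out.index)
    )
    out["breeding_range"] = np.exp(rng.normal(14.0, 1.0, size=len(out)))
    out["nest_type"] = rng.choice(
        NEST_TYPES, size=len(out), p=np.asarray(cfg.nest_type_probs)
    )
    return out


# ---------------------------------------------------------------------------
# Bundled simulation + disk round-trip


@dataclass
class SimResult:
    config: SimConfig
    landscape: Landscape
    counts: pd.DataFrame
    truth: GroundTruth
    trees: TreeSet


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator with per-stage independent substreams."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_land, rng_comm, rng_tree, rng_trait = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    landscape = simulate_landscape(cfg, rng_land)
    counts, truth = simulate_community(cfg, landscape, rng_comm)
    trees = simulate_tree_set(cfg, rng_tree)
    truth.tree = trees.base
    truth.traits = simulate_traits(trees.base, cfg, rng_trait)
    return SimResult(
        config=cfg, landscape=landscape, counts=counts, truth=truth, trees=trees
    )


def write_outputs(sim: SimResult, outdir) -> None:
    """Write the generator outputs as plain CSV / Newick / JSON files."""
    from pathlib import Path
    from .phylo import write_trees

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.counts.to_csv(outdir / "counts.csv", index=False)
    habitat = sim.landscape.composition.copy()
    habitat.insert(0, "transect", sim.landscape.transect)
    habitat.to_csv(outdir / "habitat.csv")
    sim.truth.niche.to_csv(outdir / "prefs_habitat.csv")
    sim.truth.diet.to_csv(outdir / "prefs_diet.csv")
    if sim.truth.traits is not None:
        sim.truth.traits.to_csv(outdir / "traits.csv")
    write_trees(sim.trees.all_trees(), outdir / "trees.nwk")
    cfg = asdict(sim.config)
    cfg["habitat_classes"] = list(cfg["habitat_classes"])
    truth_payload = {
        "config": cfg,
        "ssi_habitat": sim.truth.ssi_habitat.round(6).to_dict(),
        "ssi_diet": sim.truth.ssi_diet.round(6).to_dict(),
        "intensity": sim.truth.intensity.round(6).to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, default=str)
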