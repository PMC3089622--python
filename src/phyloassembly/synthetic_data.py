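"""Synthetic grassland-assembly experiment generator.

Emulates the structure of a European grassland biodiversity experiment in
which plots were sown at controlled richness from an internal species pool,
then left open to natural colonization and extinction for a final census:

* a regional pool of 60 species (48 internal + 12 external colonist-only
  species) on a pure-birth phylogeny with contiguous grass and legume clades,
  the legume clade sitting on a long stem branch so that legume colonization
  dominates gains in phylogenetic diversity;
* sown designs at richness 1/2/4/8/32 in which every polyculture must
  contain at least one grass;
* one collapsed colonization/extinction transition with grass-biased
  extinction and a colonization kernel combining a close-relative affinity
  term with a legume colonization bonus;
* aboveground biomass (g/m^2) increasing with plot PD plus a legume bonus,
  with Gaussian noise, truncated at zero.

All generator parameters live in the three config dataclasses; the defaults
constitute the package's paper-like preset. Every simulate_* function is
deterministic given its generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import InfeasibleConstraintError
from .phylo_core import Phylogeny, read_newick
from .tables import CommunityTable, write_composition

__all__ = [
    "SimTreeConfig",
    "SimExperimentConfig",
    "SimDynamicsParams",
    "SyntheticExperiment",
    "simulate_tree",
    "assign_pools",
    "simulate_sown_design",
    "simulate_dynamics",
    "simulate_biomass",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimTreeConfig:
    """Shape of the regional-pool phylogeny.

    The tree is assembled from three pure-birth (Yule) clades — grasses,
    legumes and forbs — joined at the root; the legume stem is scaled by
    ``legume_stem_multiplier`` to give that clade its characteristic long
    branch. All branch lengths are rescaled so the deepest tip sits at
    ``height`` (arbitrary branch-length units).
    """

    n_internal: int = 48
    n_external: int = 12
    n_grass: int = 14
    n_legume: int = 6
    legume_stem_multiplier: float = 4.0
    birth_rate: float = 1.0
    height: float = 1.0
    seed: Optional[int] = None

    @property
    def n_tips(self) -> int:
        return self.n_internal + self.n_external

    def __post_init__(self):
        if self.n_grass + self.n_legume > self.n_tips:
            raise InfeasibleConstraintError("grass + legume tips exceed total tips")
        if self.legume_stem_multiplier < 1:
            raise ValueError("legume_stem_multiplier must be >= 1")
        if min(self.n_grass, self.n_legume) < 1 or self.n_tips - self.n_grass - self.n_legume < 1:
            raise InfeasibleConstraintError("each clade needs at least one tip")


@dataclass(frozen=True)
class SimExperimentConfig:
    """Sown-design layout: richness levels, replication, grass rule.

    The default replication (11 monocultures, 12 plots at each higher level)
    gives the 59 usable plots of the emulated design.
    """

    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 32)
    plots_per_level: tuple[int, ...] = (11, 12, 12, 12, 12)
    grass_required: bool = True
    seed: Optional[int] = None

    @property
    def n_plots(self) -> int:
        return int(sum(self.plots_per_level))

    def __post_init__(self):
        if len(self.richness_levels) != len(self.plots_per_level):
            raise ValueError("richness_levels and plots_per_level must align")


@dataclass(frozen=True)
class SimDynamicsParams:
    """Colonization/extinction/biomass ground truth.

    Colonization probability of an absent pool species is
    ``baseline * (kernel_floor + kernel_affinity * exp(-d / kernel_scale))``
    times ``legume_colonization_bonus`` for legumes, where ``d`` is the
    patristic distance to the nearest sown resident; capped at 1. Extinction
    is independent per sown species at ``extinction_baseline`` (times
    ``grass_extinction_multiplier`` for grasses). Biomass (g/m^2) is
    ``intercept + pd_slope * PD + legume_bonus * [legume present] + noise``.
    """

    colonization_baseline: float = 0.12
    kernel_affinity: float = 1.0
    kernel_floor: float = 0.25
    kernel_scale: float = 0.3
    legume_colonization_bonus: float = 4.0
    extinction_baseline: float = 0.15
    grass_extinction_multiplier: float = 1.8
    biomass_intercept: float = 150.0
    biomass_pd_slope: float = 45.0
    biomass_legume_bonus: float = 130.0
    biomass_noise_sd: float = 45.0
    seed: Optional[int] = None

    def __post_init__(self):
        for name in (
            "colonization_baseline",
            "extinction_baseline",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.biomass_noise_sd < 0:
            raise ValueError("biomass_noise_sd must be >= 0")


# -- tree ------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, length=0.0, label=None):
        self.children = []
        self.length = length
        self.label = label

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10f}"


def _yule_clade(n_tips: int, rate: float, rng: np.random.Generator, prefix: str) -> _Node:
    """A pure-birth clade of ``n_tips``; the returned node's length is the
    stem (waiting time to the first split)."""
    root = _Node(length=float(rng.exponential(1.0 / rate)))
    if n_tips == 1:
        root.label = f"{prefix}01"
        return root
    t = 0.0
    birth: dict[int, float] = {}
    active: list[_Node] = []
    for _ in range(2):
        child = _Node()
        birth[id(child)] = 0.0
        root.children.append(child)
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        t += float(rng.exponential(1.0 / (rate * k)))
        node = active.pop(int(rng.integers(k)))
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = _Node()
            birth[id(child)] = t
            node.children.append(child)
            active.append(child)
    t += float(rng.exponential(1.0 / (rate * n_tips)))
    for j, leaf in enumerate(active):
        leaf.length = t - birth[id(leaf)]
        leaf.label = f"{prefix}{j + 1:02d}"
    return root


def _depths(node: _Node, acc=0.0):
    d = acc + node.length
    if not node.children:
        yield d
    for c in node.children:
        yield from _depths(c, d)


def _scale(node: _Node, factor: float):
    node.length *= factor
    for c in node.children:
        _scale(c, factor)


def simulate_tree(config: SimTreeConfig, rng: Optional[np.random.Generator] = None) -> Phylogeny:
    """Simulate the tagged regional-pool phylogeny."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_other = config.n_tips - config.n_grass - config.n_legume
    grass = _yule_clade(config.n_grass, config.birth_rate, rng, "grass_")
    legume = _yule_clade(config.n_legume, config.birth_rate, rng, "legume_")
    other = _yule_clade(n_other, config.birth_rate, rng, "forb_")
    legume.length *= config.legume_stem_multiplier
    root = _Node(length=0.0)
    root.children = [grass, legume, other]
    max_depth = max(_depths(root))
    _scale(root, config.height / max_depth)
    root.length = 0.0
    newick = f"({grass.newick()},{legume.newick()},{other.newick()});"
    tags = {}
    phy = read_newick(newick)
    for tip in phy.tip_labels:
        if tip.startswith("grass_"):
            tags[tip] = {"grass"}
        elif tip.startswith("legume_"):
            tags[tip] = {"legume"}
        else:
            tags[tip] = {"other"}
    return phy.with_clade_tags(tags)


def assign_pools(
    tree: Phylogeny, config: SimTreeConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Split the regional pool into internal (sowable) and external
    (colonist-only) species.

    Externals are a uniform draw conditioned on the internal pool keeping at
    least two grasses and one legume, and the external pool containing at
    least one legume — so legume-initiated, legume-colonized and
    never-legume plots can all arise.
    """
    tips = np.array(tree.tip_labels)
    grasses = tree.tips_with_tag("grass")
    legumes = tree.tips_with_tag("legume")
    for _ in range(10_000):
        ext = set(rng.choice(tips, size=config.n_external, replace=False))
        internal = set(tips) - ext
        if (
            len(internal & grasses) >= 2
            and len(internal & legumes) >= 1
            and len(ext & legumes) >= 1
        ):
            break
    else:
        raise InfeasibleConstraintError("could not find a feasible pool split")
    rows = []
    for tip in sorted(tips):
        tag = next(iter(tree.clade_tags[tip]))
        rows.append(
            {
                "species_id": tip,
                "clade_tag": tag,
                "pool": "external" if tip in ext else "internal",
            }
        )
    return pd.DataFrame(rows)


# -- sown design -----------------------------------------------------------


def simulate_sown_design(
    tree: Phylogeny,
    config: SimExperimentConfig,
    rng: np.random.Generator,
    internal_pool: frozenset[str],
) -> CommunityTable:
    """Draw the sown plot compositions from the internal pool.

    Polycultures are uniform draws conditioned on containing at least one
    grass (when ``grass_required``); monocultures are unconstrained, so
    legume monocultures can occur as in the emulated design.
    """
    internal = np.array(sorted(internal_pool))
    grasses = tree.tips_with_tag("grass") & internal_pool
    if config.grass_required and not grasses:
        raise InfeasibleConstraintError("grass constraint active but no internal grasses")
    max_level = max(config.richness_levels)
    if max_level > internal.size:
        raise InfeasibleConstraintError(
            f"richness level {max_level} exceeds internal pool ({internal.size})"
        )
    plot_rows = {}
    pid = 0
    for level, n_plots in zip(config.richness_levels, config.plots_per_level):
        for _ in range(n_plots):
            pid += 1
            while True:
                draw = set(rng.choice(internal, size=level, replace=False))
                if level == 1 or not config.grass_required or draw & grasses:
                    break
            plot_rows[f"P{pid:02d}"] = draw
    matrix = pd.DataFrame(
        {sp: [sp in plot_rows[p] for p in plot_rows] for sp in tree.tip_labels},
        index=list(plot_rows),
    )
    sown_richness = matrix.sum(axis=1)
    return CommunityTable("sown", matrix, sown_richness=sown_richness)


# -- dynamics --------------------------------------------------------------


def simulate_dynamics(
    sown: CommunityTable,
    tree: Phylogeny,
    params: SimDynamicsParams,
    rng: np.random.Generator,
    regional_pool: Optional[frozenset[str]] = None,
) -> CommunityTable:
    """One colonization/extinction transition from the sown census.

    Each sown species survives independently; each absent regional-pool
    species colonizes with a probability set by the distance kernel (nearest
    sown resident) and the legume bonus.
    """
    engine = tree.metrics
    pool = sorted(regional_pool if regional_pool is not None else tree.tip_labels)
    pool_idx = {sp: engine.index[sp] for sp in pool}
    grasses = tree.tips_with_tag("grass")
    legumes = tree.tips_with_tag("legume")
    final_rows = {}
    for plot in sown.plot_ids:
        residents = sorted(sown.members(plot))
        res_idx = np.array([engine.index[sp] for sp in residents], dtype=np.intp)
        # extinction
        p_ext = np.array(
            [
                min(
                    1.0,
                    params.extinction_baseline
                    * (params.grass_extinction_multiplier if sp in grasses else 1.0),
                )
                for sp in residents
            ]
        )
        survive = rng.random(len(residents)) >= p_ext
        survivors = {sp for sp, ok in zip(residents, survive) if ok}
        # colonization (candidates: regional-pool species absent from the plot)
        candidates = [sp for sp in pool if sp not in sown.members(plot)]
        if candidates and res_idx.size:
            cand_idx = np.array([pool_idx[sp] for sp in candidates], dtype=np.intp)
            d_nn = engine.dist[np.ix_(cand_idx, res_idx)].min(axis=1)
        else:
            d_nn = np.full(len(candidates), np.inf)
        kernel = params.kernel_floor + params.kernel_affinity * np.exp(
            -d_nn / params.kernel_scale
        )
        bonus = np.array(
            [params.legume_colonization_bonus if sp in legumes else 1.0 for sp in candidates]
        )
        p_col = np.minimum(1.0, params.colonization_baseline * kernel * bonus)
        arrive = rng.random(len(candidates)) < p_col
        colonists = {sp for sp, ok in zip(candidates, arrive) if ok}
        final_rows[plot] = survivors | colonists
    matrix = pd.DataFrame(
        {sp: [sp in final_rows[p] for p in sown.plot_ids] for sp in tree.tip_labels},
        index=sown.plot_ids,
    )
    return CommunityTable("final", matrix, sown_richness=sown.sown_richness)


def simulate_biomass(
    census: CommunityTable,
    tree: Phylogeny,
    params: SimDynamicsParams,
    rng: np.random.Generator,
) -> pd.Series:
    """Aboveground biomass (g/m^2) per plot under the linear PD model."""
    engine = tree.metrics
    legumes = tree.tips_with_tag("legume")
    values = {}
    for plot in census.plot_ids:
        members = census.members(plot)
        pd_val = engine.pd(members) if members else 0.0
        has_legume = bool(members & legumes)
        mu = (
            params.biomass_intercept
            + params.biomass_pd_slope * pd_val
            + (params.biomass_legume_bonus if has_legume else 0.0)
        )
        values[plot] = max(0.0, mu + rng.normal(0.0, params.biomass_noise_sd))
    return pd.Series(values, name=f"biomass_{census.census}")


# -- full experiment -------------------------------------------------------


@dataclass
class SyntheticExperiment:
    """A complete synthetic input bundle plus its generating ground truth."""

    tree: Phylogeny
    species: pd.DataFrame
    sown: CommunityTable
    final: CommunityTable
    plots: pd.DataFrame
    ground_truth: dict

    def write_bundle(self, out_dir) -> dict:
        """Write tree.nwk, composition.csv, plots.csv, species.csv and
        ground_truth.json; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "composition": out / "composition.csv",
            "plots": out / "plots.csv",
            "species": out / "species.csv",
            "ground_truth": out / "ground_truth.json",
        }
        paths["tree"].write_text(self.tree.write_newick())
        write_composition(paths["composition"], [self.sown, self.final])
        self.plots.to_csv(paths["plots"], index=False)
        self.species.to_csv(paths["species"], index=False)
        paths["ground_truth"].write_text(json.dumps(self.ground_truth, indent=2))
        return {k: str(v) for k, v in paths.items()}


def simulate_experiment(
    seed: int,
    tree_config: SimTreeConfig = SimTreeConfig(),
    experiment_config: SimExperimentConfig = SimExperimentConfig(),
    dynamics_params: SimDynamicsParams = SimDynamicsParams(),
) -> SyntheticExperiment:
    """Generate the full paper-like bundle: tree, pools, sown design, final
    census, two years of biomass, and the ground-truth record.

    Each stage draws from its own generator derived from ``seed`` by a stable
    label, so outputs are reproducible stage by stage.
    """
    tree = simulate_tree(tree_config, derive_rng(seed, "tree"))
    species = assign_pools(tree, tree_config, derive_rng(seed, "pools"))
    internal = frozenset(species.loc[species["pool"] == "internal", "species_id"])
    sown = simulate_sown_design(tree, experiment_config, derive_rng(seed, "design"), internal)
    final = simulate_dynamics(sown, tree, dynamics_params, derive_rng(seed, "dynamics"))
    b1 = simulate_biomass(sown, tree, dynamics_params, derive_rng(seed, "biomass-year1"))
    b2 = simulate_biomass(final, tree, dynamics_params, derive_rng(seed, "biomass-year2"))
    sown.biomass = b1.reindex(sown.plot_ids)
    final.biomass = b2.reindex(final.plot_ids)
    plots = pd.DataFrame(
        {
            "plot_id": sown.plot_ids,
            "sown_richness": sown.richness().to_numpy(),
            "biomass_year1": sown.biomass.to_numpy(),
            "biomass_year2": final.biomass.to_numpy(),
        }
    )
    ground_truth = {
        "seed": int(seed),
        "tree_config": asdict(tree_config),
        "experiment_config": asdict(experiment_config),
        "dynamics_params": asdict(dynamics_params),
    }
    return SyntheticExperiment(tree, species, sown, final, plots, ground_truth)
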