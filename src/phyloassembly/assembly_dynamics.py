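"""Colonization/extinction partitions and relatedness tests.

Between the sown census and the final census each plot's species fall into
three classes: *persist* (sown and still present), *extinct* (sown but gone)
and *colonize* (not sown but present at the end). The tests here ask whether
colonists were more or less closely related to plot residents than random
arrivals from the species pool would be, and whether extinctions tracked the
plot's phylogenetic structure:

* colonist test — observed statistic is the mean nearest-neighbour patristic
  distance from each colonist to the resident (sown) species; the null draws
  equally many pseudo-colonists from the regional pool minus the plot's sown
  species.
* extinction test — observed statistic is the mean nearest-neighbour distance
  from each extinct species to the survivors; the null relabels *which* of the
  sown species went extinct, holding the extinct count fixed (a hypergeometric
  relabelling within the plot), so it conditions on plot composition.

Both tests support clade exclusions (e.g. dropping the legume clade from the
colonist side, or grasses from the extinction analysis) and a
"colonists as established species" rerun in which colonists count as
residents, since the within-window order of events is unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import as_rng
from .errors import InfeasibleConstraintError, UndefinedStatisticError
from .null_models import (
    DispersionResult,
    NullConstraintSpec,
    draw_null_indices,
    expected_false_positives,
    summarize_null,
)
from .phylo_core import PatristicMatrix, Phylogeny

__all__ = [
    "PlotPartition",
    "RelatednessTestResult",
    "ColonistTestOptions",
    "ExtinctionTestOptions",
    "SignificanceSummary",
    "partition_plot",
    "cross_group_mnnd",
    "colonist_relatedness_test",
    "extinction_relatedness_test",
    "pool_colonizer_test",
    "count_significant",
    "results_to_dataframe",
]


@dataclass(frozen=True)
class PlotPartition:
    """Three-way species partition of one plot across the two censuses."""

    plot_id: str
    sown: frozenset[str]
    final: frozenset[str]

    @property
    def persist(self) -> frozenset[str]:
        return self.sown & self.final

    @property
    def extinct(self) -> frozenset[str]:
        return self.sown - self.final

    @property
    def colonize(self) -> frozenset[str]:
        return self.final - self.sown


def partition_plot(
    sown: Iterable[str], final: Iterable[str], plot_id: str = ""
) -> PlotPartition:
    return PlotPartition(plot_id, frozenset(sown), frozenset(final))


def cross_group_mnnd(
    focal: Iterable[str], reference: Iterable[str], dist: PatristicMatrix
) -> float:
    """Mean over focal species of the patristic distance to the nearest
    reference species. Focal and reference must be non-empty and disjoint."""
    focal, reference = set(focal), set(reference)
    if not focal or not reference:
        raise UndefinedStatisticError("focal and reference sets must be non-empty")
    if focal & reference:
        raise ValueError(f"focal and reference overlap: {sorted(focal & reference)}")
    fi = dist.indices(focal)
    ri = dist.indices(reference)
    return float(dist.values[np.ix_(fi, ri)].min(axis=1).mean())


@dataclass(frozen=True)
class ColonistTestOptions:
    """Options for the colonist relatedness test.

    ``residents`` is ``"sown"`` (default: colonists are judged against the
    species planted in the plot) or ``"sown_plus_colonists"`` (each colonist
    is judged against the sown species plus the *other* colonists — the
    colonists-as-established-species rerun). ``pool`` defaults to the full
    regional pool (all tree tips); pass a restricted pool (e.g. only species
    observed to colonize anywhere) to condition on colonizing ability.
    """

    residents: str = "sown"
    excluded_tags: frozenset[str] = field(default_factory=frozenset)
    pool: Optional[frozenset[str]] = None
    n_randomizations: int = 1000
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "residents": self.residents,
            "excluded_tags": sorted(self.excluded_tags),
            "pool": None if self.pool is None else sorted(self.pool),
            "n_randomizations": self.n_randomizations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ExtinctionTestOptions:
    """Options for the extinction relatedness test. ``colonists_as_residents``
    adds the plot's colonists to the survivor side (observed and null)."""

    colonists_as_residents: bool = False
    excluded_tags: frozenset[str] = field(default_factory=frozenset)
    n_randomizations: int = 1000
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "colonists_as_residents": self.colonists_as_residents,
            "excluded_tags": sorted(self.excluded_tags),
            "n_randomizations": self.n_randomizations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class RelatednessTestResult:
    """Per-plot result of a colonist or extinction relatedness test."""

    plot_id: str
    focal_group: str  # "colonize" | "extinct"
    n_focal: int
    n_reference: int
    dispersion: DispersionResult
    options: dict
    null_tag_counts: dict  # tag -> number of null draws containing that clade

    @property
    def p_value(self) -> float:
        return self.dispersion.p_value

    @property
    def direction(self) -> str:
        return self.dispersion.direction


def _drop_tags(species: frozenset[str], tags: frozenset[str], tree: Phylogeny) -> frozenset[str]:
    out = set(species)
    for tag in tags:
        out -= tree.tips_with_tag(tag)
    return frozenset(out)


def _tag_draw_counts(draws: np.ndarray, tree: Phylogeny) -> dict:
    engine = tree.metrics
    counts = {}
    for tag in ("grass", "legume"):
        tagged = tree.tips_with_tag(tag)
        if not tagged:
            counts[tag] = 0
            continue
        tag_idx = engine.indices(tagged)
        counts[tag] = int(np.isin(draws, tag_idx).any(axis=1).sum())
    return counts


def _loo_mnnd(engine, focal_idx: np.ndarray, base_idx: np.ndarray) -> float:
    """Mean over focal tips of min distance to base tips or *other* focal tips."""
    to_base = engine.dist[np.ix_(focal_idx, base_idx)].min(axis=1)
    if focal_idx.size > 1:
        within = engine.dist[np.ix_(focal_idx, focal_idx)].copy()
        np.fill_diagonal(within, np.inf)
        to_base = np.minimum(to_base, within.min(axis=1))
    return float(to_base.mean())


def _loo_mnnd_batch(engine, draws: np.ndarray, base_idx: np.ndarray) -> np.ndarray:
    to_base = engine.dist[draws[:, :, None], base_idx[None, None, :]].min(axis=2)
    k = draws.shape[1]
    if k > 1:
        within = engine.dist[draws[:, :, None], draws[:, None, :]]
        within[:, np.arange(k), np.arange(k)] = np.inf
        to_base = np.minimum(to_base, within.min(axis=2))
    return to_base.mean(axis=1)


def colonist_relatedness_test(
    part: PlotPartition,
    spec: Optional[NullConstraintSpec],
    tree: Phylogeny,
    options: ColonistTestOptions = ColonistTestOptions(),
    *,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> RelatednessTestResult:
    """Are this plot's colonists closer to (or farther from) the residents
    than random arrivals from the pool would be?

    ``spec``, when given, supplies the null pool, clade exclusions, number of
    randomizations and seed; ``options`` adds the residents definition and
    any further exclusions. With ``spec=None`` everything comes from
    ``options`` (pool default: all tree tips).
    """
    engine = tree.metrics
    excluded = frozenset(options.excluded_tags)
    if spec is not None:
        excluded |= spec.excluded_tags
    focal = _drop_tags(part.colonize, excluded, tree)
    if not focal:
        raise UndefinedStatisticError(
            f"plot {part.plot_id!r}: no colonists after exclusions"
        )
    residents = frozenset(part.sown)
    if not residents:
        raise UndefinedStatisticError(f"plot {part.plot_id!r}: empty resident set")

    if spec is not None:
        pool = frozenset(spec.pool)
        n_rand = spec.n_randomizations
        default_seed = spec.seed if spec.seed is not None else options.seed
    else:
        pool = options.pool if options.pool is not None else frozenset(tree.tip_labels)
        n_rand = options.n_randomizations
        default_seed = options.seed
    null_pool = _drop_tags(pool - part.sown, excluded, tree)
    k = len(focal)
    if len(null_pool) < k:
        raise InfeasibleConstraintError(
            f"plot {part.plot_id!r}: null pool ({len(null_pool)}) smaller than "
            f"colonist count ({k}) after exclusions"
        )

    rng = as_rng(rng if rng is not None else default_seed)
    pool_idx = engine.indices(null_pool)
    draws = draw_null_indices(rng, pool_idx, k, n_rand)

    res_idx = engine.indices(residents)
    focal_idx = engine.indices(focal)
    if options.residents == "sown":
        observed = engine.cross_mnnd(focal_idx, res_idx)
        null_values = engine.cross_mnnd_batch(draws, res_idx)
        n_reference = len(residents)
    elif options.residents == "sown_plus_colonists":
        observed = _loo_mnnd(engine, focal_idx, res_idx)
        null_values = _loo_mnnd_batch(engine, draws, res_idx)
        n_reference = len(residents) + k - 1
    else:
        raise ValueError("residents must be 'sown' or 'sown_plus_colonists'")

    disp = summarize_null("cross-MNND", observed, null_values, alpha=alpha)
    return RelatednessTestResult(
        plot_id=part.plot_id,
        focal_group="colonize",
        n_focal=k,
        n_reference=n_reference,
        dispersion=disp,
        options=options.as_dict(),
        null_tag_counts=_tag_draw_counts(draws, tree),
    )


def extinction_relatedness_test(
    part: PlotPartition,
    tree: Phylogeny,
    options: ExtinctionTestOptions = ExtinctionTestOptions(),
    *,
    n_randomizations: Optional[int] = None,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> RelatednessTestResult:
    """Did extinctions track the plot's phylogenetic structure?

    The null holds the plot's sown composition and extinct count fixed and
    relabels which sown species went extinct.
    """
    engine = tree.metrics
    sown = _drop_tags(part.sown, options.excluded_tags, tree)
    extinct = _drop_tags(part.extinct, options.excluded_tags, tree) & sown
    colonize = (
        _drop_tags(part.colonize, options.excluded_tags, tree)
        if options.colonists_as_residents
        else frozenset()
    )
    if not extinct:
        raise UndefinedStatisticError(
            f"plot {part.plot_id!r}: no extinctions after exclusions"
        )
    survivors = (sown - extinct) | colonize
    if not survivors:
        raise UndefinedStatisticError(
            f"plot {part.plot_id!r}: every sown species went extinct; no survivors"
        )

    dist = engine.patristic
    observed = cross_group_mnnd(extinct, survivors, dist)

    n_rand = n_randomizations or options.n_randomizations
    rng = as_rng(rng if rng is not None else (seed if seed is not None else options.seed))

    s_idx = engine.indices(sown)
    s = s_idx.size
    e = len(extinct)
    if e >= s:
        raise UndefinedStatisticError(
            f"plot {part.plot_id!r}: extinct count must be below sown count"
        )
    # relabel within the plot: which e of the s sown species are "extinct"
    positions = draw_null_indices(rng, np.arange(s, dtype=np.intp), e, n_rand)
    ext_mask = np.zeros((n_rand, s), dtype=bool)
    np.put_along_axis(ext_mask, positions, True, axis=1)
    d_ss = engine.dist[np.ix_(s_idx, s_idx)]
    masked = np.where(ext_mask[:, None, :], np.inf, d_ss[None, :, :])
    nn = masked.min(axis=2)  # (n_rand, s): each sown species' nearest pseudo-survivor
    if colonize:
        c_idx = engine.indices(colonize)
        d_sc = engine.dist[np.ix_(s_idx, c_idx)].min(axis=1)  # (s,)
        nn = np.minimum(nn, d_sc[None, :])
    null_values = (nn * ext_mask).sum(axis=1) / e

    disp = summarize_null("cross-MNND", observed, null_values, alpha=alpha)
    # audit: which clades appear among pseudo-extinct draws
    label_arr = s_idx[positions]
    return RelatednessTestResult(
        plot_id=part.plot_id,
        focal_group="extinct",
        n_focal=e,
        n_reference=len(survivors),
        dispersion=disp,
        options=options.as_dict(),
        null_tag_counts=_tag_draw_counts(label_arr, tree),
    )


def pool_colonizer_test(
    colonizers: Iterable[str],
    regional_pool: Iterable[str],
    tree: Phylogeny,
    n_randomizations: int = 1000,
    seed: Optional[int] = None,
    *,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> DispersionResult:
    """Pool-level test: is the set of species that colonized (or went extinct)
    anywhere phylogenetically clustered across the regional pool?

    Observed statistic is the MNND of the focal set; nulls are equal-sized
    uniform draws from the regional pool (no clade constraint at pool level).
    """
    engine = tree.metrics
    colonizers = frozenset(colonizers)
    regional_pool = frozenset(regional_pool)
    if not colonizers <= regional_pool:
        raise ValueError("focal species must all belong to the regional pool")
    k = len(colonizers)
    if k < 2:
        raise UndefinedStatisticError("pool-level MNND needs at least 2 focal species")
    rng = as_rng(rng if rng is not None else seed)
    observed = engine.mnnd(colonizers)
    pool_idx = engine.indices(regional_pool)
    draws = draw_null_indices(rng, pool_idx, k, n_randomizations)
    null_values = engine.mnnd_batch(draws)
    return summarize_null("MNND", observed, null_values, alpha=alpha)


@dataclass(frozen=True)
class SignificanceSummary:
    n_tested: int
    n_clustered: int
    n_overdispersed: int
    n_expected_by_chance: int
    alpha: float

    def as_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_clustered": self.n_clustered,
            "n_overdispersed": self.n_overdispersed,
            "n_expected_by_chance": self.n_expected_by_chance,
            "alpha": self.alpha,
        }


def count_significant(
    results: Sequence[RelatednessTestResult | DispersionResult],
    alpha: float = 0.05,
) -> SignificanceSummary:
    """Tally clustered/overdispersed plots at ``alpha`` against the count
    expected by chance alone."""
    if not results:
        raise ValueError("no results to summarize")
    n_clu = n_over = 0
    for r in results:
        disp = r.dispersion if isinstance(r, RelatednessTestResult) else r
        if disp.p_value < alpha:
            if disp.observed < disp.null_mean:
                n_clu += 1
            elif disp.observed > disp.null_mean:
                n_over += 1
    return SignificanceSummary(
        n_tested=len(results),
        n_clustered=n_clu,
        n_overdispersed=n_over,
        n_expected_by_chance=expected_false_positives(len(results), alpha),
        alpha=alpha,
    )


def results_to_dataframe(results: Sequence[RelatednessTestResult]) -> pd.DataFrame:
    """Per-plot results table; adds a Benjamini-Hochberg adjusted p column
    (reported for reference, headline counts use unadjusted p)."""
    rows = []
    for r in results:
        d = r.dispersion
        rows.append(
            {
                "plot_id": r.plot_id,
                "focal_group": r.focal_group,
                "n_focal": r.n_focal,
                "n_reference": r.n_reference,
                "observed": d.observed,
                "null_mean": d.null_mean,
                "null_sd": d.null_sd,
                "ses": d.ses,
                "p_value": d.p_value,
                "p_normal": d.p_normal,
                "direction": d.direction,
                "sd_zero": d.sd_zero,
                "null_draws_with_grass": r.null_tag_counts.get("grass", 0),
                "null_draws_with_legume": r.null_tag_counts.get("legume", 0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
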