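"""Constrained richness-preserving null communities and dispersion tests.

The null model resamples plot *membership* from a defined species pool:
each null community has the same richness as the observed plot and is a
uniform draw (without replacement) from the pool, optionally conditioned on
containing at least one species of a required clade (in grassland designs,
at least one grass) and/or excluding a clade entirely.

Significance is judged by the rank of the observed statistic within the null
distribution; the two-tailed p-value is

    p = min(1, 2 * min(n_le + 1, n_ge + 1) / (n_rand + 1))

where ``n_le``/``n_ge`` count null values <= / >= the observed value (ties
count on both sides). A normal-reference p-value computed from the
standardized effect size SES = (obs - mean_null) / sd_null is also reported,
but the rank-based p is authoritative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from ._rng import as_rng
from .errors import InfeasibleConstraintError, UndefinedStatisticError
from .phylo_core import CommunityMetrics, Phylogeny

__all__ = [
    "NullConstraintSpec",
    "DispersionResult",
    "sample_null_community",
    "null_test",
    "summarize_null",
    "expected_false_positives",
]

METRICS = ("PD", "MNND", "MPD")


@dataclass(frozen=True)
class NullConstraintSpec:
    """Defines the pool and constraints for null-community draws.

    ``required_tag`` imposes a minimum count (default 1) of species carrying
    that clade tag in every draw; ``excluded_tags`` removes whole clades from
    the pool before drawing.
    """

    pool: frozenset[str]
    required_tag: Optional[str] = None
    required_min: int = 1
    excluded_tags: frozenset[str] = field(default_factory=frozenset)
    n_randomizations: int = 1000
    seed: Optional[int] = None

    def effective_pool(self, tree: Phylogeny) -> frozenset[str]:
        pool = set(self.pool)
        for tag in self.excluded_tags:
            pool -= tree.tips_with_tag(tag)
        return frozenset(pool)

    def required_species(self, tree: Phylogeny) -> frozenset[str]:
        if self.required_tag is None:
            return frozenset()
        return tree.tips_with_tag(self.required_tag) & self.effective_pool(tree)


@dataclass(frozen=True)
class DispersionResult:
    """Observed statistic against its randomization null."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float          # rank-based, two-tailed (authoritative)
    p_normal: float         # SES against a standard normal reference
    n_at_or_below: int
    n_at_or_above: int
    n_randomizations: int
    direction: str          # clustered | overdispersed | random
    sd_zero: bool = False
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "p_value": self.p_value,
            "p_normal": self.p_normal,
            "n_at_or_below": self.n_at_or_below,
            "n_at_or_above": self.n_at_or_above,
            "n_randomizations": self.n_randomizations,
            "direction": self.direction,
            "sd_zero": self.sd_zero,
        }


def expected_false_positives(n_tests: int, alpha: float) -> int:
    """Number of tests expected to cross ``alpha`` by chance alone, rounded
    to the nearest integer (half away from zero)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return int(math.floor(n_tests * alpha + 0.5))


# -- sampling --------------------------------------------------------------


def draw_null_indices(
    rng: np.random.Generator,
    pool_idx: np.ndarray,
    richness: int,
    n_draws: int,
    required_idx: Optional[np.ndarray] = None,
    required_min: int = 1,
) -> np.ndarray:
    """Uniform ``richness``-subsets of ``pool_idx`` conditioned on containing
    at least ``required_min`` members of ``required_idx``; (n_draws, richness)
    index matrix. Rejection sampling preserves uniformity on the feasible set.
    """
    pool = np.asarray(pool_idx, dtype=np.intp)
    p = pool.size
    if richness > p:
        raise InfeasibleConstraintError(
            f"richness {richness} exceeds effective pool size {p}"
        )
    if required_idx is not None and required_idx.size == 0:
        raise InfeasibleConstraintError("required clade has no species in the pool")
    out = np.empty((n_draws, richness), dtype=np.intp)
    todo = np.arange(n_draws)
    req = None if required_idx is None else np.asarray(required_idx)
    guard = 0
    while todo.size:
        # k smallest of iid uniforms = uniform random k-subset
        keys = rng.random((todo.size, p))
        picks = pool[np.argpartition(keys, richness - 1, axis=1)[:, :richness]]
        out[todo] = picks
        if req is None:
            break
        ok = np.isin(out[todo], req).sum(axis=1) >= required_min
        todo = todo[~ok]
        guard += 1
        if guard > 10_000:
            raise InfeasibleConstraintError(
                "constraint rejection did not converge; constraint may be infeasible"
            )
    return out


def sample_null_community(
    spec: NullConstraintSpec,
    richness: int,
    rng: np.random.Generator,
    tree: Phylogeny,
) -> frozenset[str]:
    """One uniform constrained draw of ``richness`` species from the pool."""
    engine = tree.metrics
    pool = spec.effective_pool(tree)
    pool_idx = engine.indices(pool)
    req = spec.required_species(tree)
    req_idx = engine.indices(req) if spec.required_tag is not None else None
    draw = draw_null_indices(rng, pool_idx, richness, 1, req_idx, spec.required_min)[0]
    return frozenset(engine.labels[i] for i in draw)


# -- dispersion testing -----------------------------------------------------


def summarize_null(
    metric: str,
    observed: float,
    null_values: np.ndarray,
    alpha: float = 0.05,
) -> DispersionResult:
    """Rank the observed statistic within its null distribution."""
    null_values = np.asarray(null_values, dtype=float)
    if not np.all(np.isfinite(null_values)):
        raise ValueError("null distribution contains non-finite values")
    n = null_values.size
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1)) if n > 1 else 0.0
    n_le = int(np.sum(null_values <= observed))
    n_ge = int(np.sum(null_values >= observed))
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n + 1))
    # degenerate null: identical draws up to float summation order
    sd_zero = sd <= 1e-12 * max(1.0, abs(mean))
    if sd_zero:
        sd = 0.0
    ses = 0.0 if sd_zero else (observed - mean) / sd
    p_normal = 1.0 if sd_zero else float(2.0 * stats.norm.sf(abs(ses)))
    if p < alpha and observed < mean:
        direction = "clustered"
    elif p < alpha and observed > mean:
        direction = "overdispersed"
    else:
        direction = "random"
    return DispersionResult(
        metric=metric,
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=ses,
        p_value=p,
        p_normal=p_normal,
        n_at_or_below=n_le,
        n_at_or_above=n_ge,
        n_randomizations=n,
        direction=direction,
        sd_zero=sd_zero,
        alpha=alpha,
    )


def null_test(
    metric: str,
    community: Iterable[str],
    spec: NullConstraintSpec,
    tree: Phylogeny,
    *,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> DispersionResult:
    """Test a community's PD / MNND / MPD against constrained null draws.

    Null communities match the observed richness. The required-clade
    constraint is applied only for communities of two or more species:
    monoculture nulls are unconstrained singletons.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    engine: CommunityMetrics = tree.metrics
    community = set(community)
    tree.validate_species(community)
    richness = len(community)
    if metric in ("MNND", "MPD") and richness < 2:
        raise UndefinedStatisticError(f"{metric} undefined for richness {richness}")
    if richness == 0:
        raise UndefinedStatisticError("empty community")
    rng = as_rng(rng if rng is not None else spec.seed)

    pool_idx = engine.indices(spec.effective_pool(tree))
    req_idx = None
    if spec.required_tag is not None and richness >= 2:
        req_idx = engine.indices(spec.required_species(tree))
    draws = draw_null_indices(
        rng, pool_idx, richness, spec.n_randomizations, req_idx, spec.required_min
    )

    if metric == "PD":
        observed = engine.pd(community)
        masks = np.zeros((draws.shape[0], len(engine.labels)), dtype=bool)
        np.put_along_axis(masks, draws, True, axis=1)
        null_values = engine.pd_batch(masks)
    elif metric == "MNND":
        observed = engine.mnnd(community)
        null_values = engine.mnnd_batch(draws)
    else:
        observed = engine.mpd(community)
        null_values = engine.mpd_batch(draws)
    return summarize_null(metric, observed, null_values, alpha=alpha)
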