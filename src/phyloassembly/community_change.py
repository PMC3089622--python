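"""Turnover, convergence and productivity analyses.

Covers three strands of the plot-level story:

* compositional similarity — Jaccard index between plots within a census and
  a permutation test for whether plots became more similar between censuses;
* diversity convergence — per-plot change records (richness, PD, MNND,
  biomass) and regressions of metric change on the sown value, whose limiting
  case (all plots converging to one common value) has slope -1 and R^2 = 1;
* productivity — OLS regressions of biomass on diversity and an ANCOVA of
  biomass change on PD change with a binary legume covariate, which separates
  the phylogenetic-diversity signal from the nitrogen-fixer effect it is
  confounded with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._rng import as_rng
from .errors import UndefinedStatisticError
from .phylo_core import Phylogeny
from .tables import CommunityTable

__all__ = [
    "RegressionResult",
    "AncovaResult",
    "jaccard",
    "mean_pairwise_jaccard",
    "compare_jaccard_years",
    "build_change_records",
    "ols_fit",
    "diversity_change_regression",
    "ancova_biomass",
]


# -- Jaccard ---------------------------------------------------------------


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|. Defined whenever the union is non-empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise UndefinedStatisticError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def _pairwise_jaccards(matrix: np.ndarray) -> np.ndarray:
    """Jaccard over all unordered row pairs of a boolean plot x species matrix."""
    m = matrix.astype(float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    iu = np.triu_indices(m.shape[0], k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = inter[iu] / union[iu]
    return np.where(union[iu] > 0, vals, 0.0)


def mean_pairwise_jaccard(census: CommunityTable) -> tuple[float, float, int]:
    """Mean, standard error and pair count of Jaccard similarity over all
    unordered plot pairs of one census."""
    n = len(census.plot_ids)
    if n < 2:
        raise UndefinedStatisticError("need at least 2 plots")
    vals = _pairwise_jaccards(census.matrix.to_numpy())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), se, int(vals.size)


def compare_jaccard_years(
    census1: CommunityTable,
    census2: CommunityTable,
    n_perm: int = 999,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Did mean between-plot similarity change between the two censuses?

    Returns (delta_mean, p). delta_mean = mean pairwise Jaccard of census2
    minus census1. The permutation null swaps the two census memberships
    within each plot independently and recomputes the difference; p is the
    two-tailed rank p-value on |delta|.
    """
    if list(census1.plot_ids) != list(census2.plot_ids):
        raise ValueError("the two censuses must cover the same plots in the same order")
    cols = sorted(set(census1.matrix.columns) | set(census2.matrix.columns))
    m1 = census1.matrix.reindex(columns=cols, fill_value=False).to_numpy()
    m2 = census2.matrix.reindex(columns=cols, fill_value=False).to_numpy()
    obs = float(_pairwise_jaccards(m2).mean() - _pairwise_jaccards(m1).mean())
    rng = as_rng(rng if rng is not None else seed)
    n_plots = m1.shape[0]
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        flip = rng.random(n_plots) < 0.5
        a = np.where(flip[:, None], m2, m1)
        b = np.where(flip[:, None], m1, m2)
        perm_stats[i] = _pairwise_jaccards(b).mean() - _pairwise_jaccards(a).mean()
    n_extreme = int(np.sum(np.abs(perm_stats) >= abs(obs)))
    p = (n_extreme + 1) / (n_perm + 1)
    return obs, float(p)


# -- change records --------------------------------------------------------

CHANGE_COLUMNS = [
    "plot_id",
    "sown_richness",
    "final_richness",
    "d_richness",
    "sown_pd",
    "final_pd",
    "d_pd",
    "sown_mnnd",
    "final_mnnd",
    "d_mnnd",
    "biomass_year1",
    "biomass_year2",
    "d_biomass",
    "legume_status",
]


def build_change_records(
    sown: CommunityTable,
    final: CommunityTable,
    tree: Phylogeny,
) -> pd.DataFrame:
    """One row per plot with sown/final/delta richness, PD, MNND, biomass and
    the plot's legume status (initiated-with / colonized-by / never).

    MNND is NaN for monocultures (undefined for fewer than 2 species);
    regressions downstream drop and report such plots.
    """
    if set(sown.plot_ids) != set(final.plot_ids):
        raise ValueError("sown and final censuses must cover the same plots")
    engine = tree.metrics
    legumes = tree.tips_with_tag("legume")
    rows = []
    for pid in sown.plot_ids:
        s = sown.members(pid)
        f = final.members(pid)
        tree.validate_species(s | f)
        sown_pd = engine.pd(s) if s else np.nan
        final_pd = engine.pd(f) if f else np.nan
        sown_mnnd = engine.mnnd(s) if len(s) >= 2 else np.nan
        final_mnnd = engine.mnnd(f) if len(f) >= 2 else np.nan
        if s & legumes:
            legume_status = "initiated-with"
        elif f & legumes:
            legume_status = "colonized-by"
        else:
            legume_status = "never"
        b1 = float(sown.biomass.loc[pid]) if sown.biomass is not None else np.nan
        b2 = float(final.biomass.loc[pid]) if final.biomass is not None else np.nan
        rows.append(
            {
                "plot_id": pid,
                "sown_richness": len(s),
                "final_richness": len(f),
                "d_richness": len(f) - len(s),
                "sown_pd": sown_pd,
                "final_pd": final_pd,
                "d_pd": final_pd - sown_pd,
                "sown_mnnd": sown_mnnd,
                "final_mnnd": final_mnnd,
                "d_mnnd": final_mnnd - sown_mnnd,
                "biomass_year1": b1,
                "biomass_year2": b2,
                "d_biomass": b2 - b1,
                "legume_status": legume_status,
            }
        )
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


# -- regression / ANCOVA ---------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    r_squared: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "f_statistic": self.f_statistic,
            "df_model": self.df[0],
            "df_resid": self.df[1],
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class AncovaResult:
    coef_predictor: float
    t_predictor: float
    p_predictor: float
    coef_covariate: float
    t_covariate: float
    p_covariate: float
    ci_covariate: tuple[float, float]
    n_used: int
    n_excluded: int
    condition_number: float

    def as_dict(self) -> dict:
        return {
            "coef_predictor": self.coef_predictor,
            "t_predictor": self.t_predictor,
            "p_predictor": self.p_predictor,
            "coef_covariate": self.coef_covariate,
            "t_covariate": self.t_covariate,
            "p_covariate": self.p_covariate,
            "ci_covariate_low": self.ci_covariate[0],
            "ci_covariate_high": self.ci_covariate[1],
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "condition_number": self.condition_number,
        }


def ols_fit(x, y) -> RegressionResult:
    """Simple least-squares regression of y on x with the model F test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_statistic=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=n,
    )


def diversity_change_regression(
    records: pd.DataFrame, metric: str
) -> tuple[RegressionResult, int]:
    """Regress change in a metric on its sown value; metric is one of
    ``richness``, ``pd``, ``mnnd``. Plots with an undefined sown value
    (monoculture MNND) are dropped; the count of plots used is returned."""
    if metric not in ("richness", "pd", "mnnd"):
        raise ValueError("metric must be richness, pd or mnnd")
    sub = records[[f"sown_{metric}", f"d_{metric}"]].dropna()
    res = ols_fit(sub[f"sown_{metric}"], sub[f"d_{metric}"])
    return res, len(sub)


def ancova_biomass(records: pd.DataFrame, n_min: int = 2) -> AncovaResult:
    """ANCOVA: d_biomass ~ d_pd + legume covariate.

    The covariate is binary over the two legume exposure routes: 1 for plots
    initiated with a legume, 0 for plots initiated without one but colonized
    by one. Plots never containing a legume are excluded.
    """
    sub = records[records["legume_status"] != "never"].dropna(
        subset=["d_biomass", "d_pd"]
    )
    n_excluded = len(records) - len(sub)
    initiated = (sub["legume_status"] == "initiated-with").astype(float)
    for level, cnt in (("initiated-with", int(initiated.sum())), ("colonized-by", int((1 - initiated).sum()))):
        if cnt < n_min:
            raise ValueError(
                f"covariate level {level!r} has {cnt} plots (< {n_min}) after exclusion"
            )
    X = pd.DataFrame({"d_pd": sub["d_pd"].to_numpy(), "legume_initiated": initiated.to_numpy()})
    model = sm.OLS(sub["d_biomass"].to_numpy(), sm.add_constant(X)).fit()
    cond = float(np.linalg.cond(sm.add_constant(X).to_numpy()))
    if cond > 1e8:
        warnings.warn(
            f"ANCOVA design matrix is near-singular (condition number {cond:.3g}); "
            "PD change and legume covariate may be confounded",
            stacklevel=2,
        )
    ci = model.conf_int()
    return AncovaResult(
        coef_predictor=float(model.params["d_pd"]),
        t_predictor=float(model.tvalues["d_pd"]),
        p_predictor=float(model.pvalues["d_pd"]),
        coef_covariate=float(model.params["legume_initiated"]),
        t_covariate=float(model.tvalues["legume_initiated"]),
        p_covariate=float(model.pvalues["legume_initiated"]),
        ci_covariate=(float(ci.loc["legume_initiated", 0]), float(ci.loc["legume_initiated", 1])),
        n_used=len(sub),
        n_excluded=n_excluded,
        condition_number=cond,
    )
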