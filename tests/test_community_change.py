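"""Jaccard turnover, change records, OLS and ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phyloassembly import (
    ancova_biomass,
    build_change_records,
    community_pd,
    compare_jaccard_years,
    diversity_change_regression,
    jaccard,
    mean_pairwise_jaccard,
    ols_fit,
    read_newick,
)
from phyloassembly.community_change import CHANGE_COLUMNS
from phyloassembly.errors import UndefinedStatisticError
from phyloassembly.tables import CommunityTable


def make_table(census, plots: dict, species):
    matrix = pd.DataFrame(
        {sp: [sp in plots[p] for p in plots] for sp in species}, index=list(plots)
    )
    return CommunityTable(census, matrix)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            jaccard(set(), set())

    @given(
        a=st.sets(st.sampled_from("ABCDEF")),
        b=st.sets(st.sampled_from("ABCDEF")),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0

    def test_mean_pairwise_identical_plots(self):
        t = make_table("sown", {"p1": {"A", "B"}, "p2": {"A", "B"}, "p3": {"A", "B"}}, "AB")
        mean, se, n = mean_pairwise_jaccard(t)
        assert (mean, se, n) == (1.0, 0.0, 3)

    def test_mean_pairwise_disjoint_plots(self):
        t = make_table("sown", {"p1": {"A"}, "p2": {"B"}, "p3": {"C"}}, "ABC")
        mean, se, n = mean_pairwise_jaccard(t)
        assert mean == 0.0 and se == 0.0

    def test_mean_pairwise_hand_computed(self):
        t = make_table(
            "sown",
            {"p1": {"A", "B"}, "p2": {"B", "C"}, "p3": {"A", "B", "C"}},
            "ABC",
        )
        mean, _, n = mean_pairwise_jaccard(t)
        assert n == 3
        assert mean == pytest.approx((1 / 3 + 2 / 3 + 2 / 3) / 3)

    def test_compare_years_identity(self):
        t1 = make_table("sown", {"p1": {"A"}, "p2": {"B"}, "p3": {"A", "B"}}, "AB")
        t2 = make_table("final", {"p1": {"A"}, "p2": {"B"}, "p3": {"A", "B"}}, "AB")
        d, p = compare_jaccard_years(t1, t2, n_perm=99, seed=1)
        assert d == 0.0 and p == 1.0

    def test_compare_years_antisymmetric(self):
        t1 = make_table("sown", {"p1": {"A"}, "p2": {"B"}, "p3": {"C"}}, "ABCD")
        t2 = make_table("final", {"p1": {"A", "B"}, "p2": {"A", "B"}, "p3": {"A", "C"}}, "ABCD")
        d12, _ = compare_jaccard_years(t1, t2, n_perm=49, seed=1)
        d21, _ = compare_jaccard_years(t2, t1, n_perm=49, seed=1)
        assert d12 == pytest.approx(-d21)

    def test_strong_convergence_hits_permutation_floor(self):
        plots1 = {f"p{i}": {f"s{i}"} for i in range(10)}
        plots2 = {f"p{i}": {"x", "y"} for i in range(10)}
        species = [f"s{i}" for i in range(10)] + ["x", "y"]
        t1 = make_table("sown", plots1, species)
        t2 = make_table("final", plots2, species)
        d, p = compare_jaccard_years(t1, t2, n_perm=199, seed=1)
        assert d == pytest.approx(1.0)
        # identity and full-flip permutations tie with the observed |delta|,
        # so p sits within a few ties of the attainable floor 1/(n_perm+1)
        assert 1 / 200 <= p <= 5 / 200


LEGUME_TREE = "(((A:1,B:1):1,(C:1,D:1):1):1,L:6);"


def legume_tree():
    tags = {s: {"other"} for s in "ABCD"}
    tags["L"] = {"legume"}
    return read_newick(LEGUME_TREE, clade_tags=tags)


class TestChangeRecords:
    def test_no_change_plot(self):
        tree = legume_tree()
        t1 = make_table("sown", {"p1": {"A", "B"}}, tree.tip_labels)
        t2 = make_table("final", {"p1": {"A", "B"}}, tree.tip_labels)
        rec = build_change_records(t1, t2, tree).iloc[0]
        assert rec.d_richness == 0 and rec.d_pd == 0.0 and rec.d_mnnd == 0.0

    def test_monoculture_mnnd_flagged(self):
        tree = legume_tree()
        t1 = make_table("sown", {"p1": {"A"}}, tree.tip_labels)
        t2 = make_table("final", {"p1": {"A", "B"}}, tree.tip_labels)
        rec = build_change_records(t1, t2, tree).iloc[0]
        assert rec.d_richness == 1
        assert np.isnan(rec.sown_mnnd) and not np.isnan(rec.final_mnnd)

    def test_d_pd_matches_recomputation(self, experiment):
        rec = build_change_records(experiment.sown, experiment.final, experiment.tree)
        row = rec.iloc[20]
        sown = experiment.sown.members(row.plot_id)
        final = experiment.final.members(row.plot_id)
        expected = community_pd(experiment.tree, final) - community_pd(
            experiment.tree, sown
        )
        assert row.d_pd == pytest.approx(expected, rel=1e-12)
        assert list(rec.columns) == CHANGE_COLUMNS

    def test_legume_status_rule(self):
        tree = legume_tree()
        t1 = make_table(
            "sown", {"p1": {"L", "A"}, "p2": {"A", "B"}, "p3": {"C", "D"}}, tree.tip_labels
        )
        t2 = make_table(
            "final", {"p1": {"L", "A"}, "p2": {"A", "L"}, "p3": {"C", "D"}}, tree.tip_labels
        )
        rec = build_change_records(t1, t2, tree).set_index("plot_id")
        assert rec.loc["p1", "legume_status"] == "initiated-with"
        assert rec.loc["p2", "legume_status"] == "colonized-by"
        assert rec.loc["p3", "legume_status"] == "never"


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_fit(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=40)
        y = 1.5 + 0.7 * x + rng.normal(scale=0.5, size=40)
        res = ols_fit(x, y)
        # closed-form normal equations
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        # F = (n-2) R^2 / (1 - R^2)
        f = (40 - 2) * res.r_squared / (1 - res.r_squared)
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.df == (1, 38)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones(5), np.arange(5.0))

    def test_null_slope_p_uniform(self):
        rng = np.random.default_rng(3)
        pvals = [
            ols_fit(rng.normal(size=30), rng.normal(size=30)).p_value
            for _ in range(200)
        ]
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue >= 0.01


class TestConvergenceRegression:
    def test_exact_convergence_limit(self, experiment):
        """If every plot ends at one common composition, d_PD regressed on
        sown PD has slope -1 and R^2 = 1 (all residuals vanish)."""
        tree = experiment.tree
        target = experiment.final.members(experiment.final.plot_ids[0])
        matrix = pd.DataFrame(
            {sp: [sp in target] * len(experiment.sown.plot_ids) for sp in tree.tip_labels},
            index=experiment.sown.plot_ids,
        )
        forced = CommunityTable("final", matrix)
        rec = build_change_records(experiment.sown, forced, tree)
        res, n = diversity_change_regression(rec, "pd")
        assert res.slope == pytest.approx(-1.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-8)

    def test_mnnd_regression_drops_monocultures(self, experiment):
        rec = build_change_records(experiment.sown, experiment.final, experiment.tree)
        res, n = diversity_change_regression(rec, "mnnd")
        n_mono = int((rec["sown_richness"] == 1).sum())
        assert n == len(rec) - n_mono


def records_frame(d_pd, d_biomass, status):
    n = len(d_pd)
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(n)],
            "d_pd": d_pd,
            "d_biomass": d_biomass,
            "legume_status": status,
        }
    )


class TestAncova:
    def test_noise_free_recovery(self):
        """d_biomass = 5 + 0*d_pd + 30*initiated is recovered exactly."""
        rng = np.random.default_rng(1)
        n = 30
        d_pd = rng.normal(size=n)
        initiated = np.repeat([1.0, 0.0], n // 2)
        status = np.where(initiated == 1, "initiated-with", "colonized-by")
        y = 5 + 0 * d_pd + 30 * initiated
        res = ancova_biomass(records_frame(d_pd, y, status))
        assert res.coef_predictor == pytest.approx(0.0, abs=1e-10)
        assert res.coef_covariate == pytest.approx(30.0, abs=1e-8)
        assert res.n_used == n and res.n_excluded == 0

    def test_never_legume_plots_excluded(self):
        rng = np.random.default_rng(2)
        d_pd = rng.normal(size=12)
        status = ["initiated-with"] * 5 + ["colonized-by"] * 5 + ["never"] * 2
        res = ancova_biomass(records_frame(d_pd, rng.normal(size=12), status))
        assert res.n_used == 10 and res.n_excluded == 2

    def test_confounded_design_warns(self):
        initiated = np.repeat([1.0, 0.0], 10)
        d_pd = 10 * initiated  # perfectly collinear with the covariate
        status = np.where(initiated == 1, "initiated-with", "colonized-by")
        with pytest.warns(UserWarning, match="confounded"):
            ancova_biomass(records_frame(d_pd, initiated * 3, status))

    def test_level_too_small_rejected(self):
        d_pd = np.arange(4.0)
        status = ["initiated-with"] * 3 + ["colonized-by"]
        with pytest.raises(ValueError):
            ancova_biomass(records_frame(d_pd, d_pd, status))

    def test_ci_coverage(self):
        """95% CI for the covariate effect covers the truth ~95% of the time."""
        rng = np.random.default_rng(5)
        true = 25.0
        hits = 0
        for _ in range(200)[:200]:
            n = 40
            d_pd = rng.normal(size=n)
            initiated = (rng.random(n) < 0.5).astype(float)
            status = np.where(initiated == 1, "initiated-with", "colonized-by")
            if min(initiated.sum(), n - initiated.sum()) < 2:
                continue
            y = 5 + 2 * d_pd + true * initiated + rng.normal(scale=10, size=n)
            res = ancova_biomass(records_frame(d_pd, y, status))
            lo, hi = res.ci_covariate
            hits += lo <= true <= hi
        assert hits / 200 >= 0.90
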