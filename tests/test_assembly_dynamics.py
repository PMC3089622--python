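"""Plot partitions, cross-group MNND, colonist/extinction relatedness tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloassembly import (
    ColonistTestOptions,
    ExtinctionTestOptions,
    colonist_relatedness_test,
    count_significant,
    cross_group_mnnd,
    extinction_relatedness_test,
    partition_plot,
    patristic_matrix,
    pool_colonizer_test,
    read_newick,
)
from phyloassembly.errors import UndefinedStatisticError
from phyloassembly.null_models import NullConstraintSpec, summarize_null

from oracles import cross_mnnd_bruteforce, random_newick


class TestPartition:
    @pytest.mark.parametrize(
        "sown, final, persist, extinct, colonize",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"}, {"A"}, {"D"}),
            ({"A", "B"}, {"A", "B"}, {"A", "B"}, set(), set()),
            ({"A"}, {"B"}, set(), {"A"}, {"B"}),
        ],
    )
    def test_examples(self, sown, final, persist, extinct, colonize):
        part = partition_plot(sown, final, "p")
        assert part.persist == persist
        assert part.extinct == extinct
        assert part.colonize == colonize

    @given(
        sown=st.sets(st.sampled_from("ABCDEFGH")),
        final=st.sets(st.sampled_from("ABCDEFGH")),
    )
    @settings(deadline=None, max_examples=100)
    def test_partition_identities(self, sown, final):
        part = partition_plot(sown, final)
        assert part.persist | part.extinct == part.sown
        assert part.persist | part.colonize == part.final
        assert not part.persist & part.extinct
        assert not part.persist & part.colonize
        assert not part.extinct & part.colonize


class TestCrossGroupMNND:
    def test_singleton_focal(self, cherry_tree):
        m = patristic_matrix(cherry_tree)
        assert cross_group_mnnd({"C"}, {"A", "B"}, m) == pytest.approx(4.0)

    def test_overlap_rejected(self, cherry_tree):
        m = patristic_matrix(cherry_tree)
        with pytest.raises(ValueError):
            cross_group_mnnd({"A", "C"}, {"A", "B"}, m)

    def test_empty_rejected(self, cherry_tree):
        m = patristic_matrix(cherry_tree)
        with pytest.raises(UndefinedStatisticError):
            cross_group_mnnd(set(), {"A"}, m)

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            tree = read_newick(random_newick(rng, 8))
            labels = list(tree.tip_labels)
            rng.shuffle(labels)
            focal, reference = set(labels[:3]), set(labels[3:7])
            m = patristic_matrix(tree)
            assert cross_group_mnnd(focal, reference, m) == pytest.approx(
                cross_mnnd_bruteforce(tree.dendropy_tree, focal, reference), rel=1e-10
            )


def two_clade_tree():
    """Residents and near-colonists in one tight clade; the rest of the pool
    mutually distant (long pendant edges)."""
    near = "(" + ",".join(f"n{i}:0.1" for i in range(1, 7)) + "):5.0"
    far = "(" + ",".join(f"d{i}:5.0" for i in range(1, 13)) + "):1.0"
    return read_newick(f"({near},{far});")


class TestColonistTest:
    def test_clustered_colonists_detected(self):
        """Colonists that are sister to the residents, against a pool
        dominated by a distant clade, test clustered."""
        tree = two_clade_tree()
        part = partition_plot({"n1", "n2", "n3"}, {"n1", "n2", "n3", "n4", "n5"}, "p")
        res = colonist_relatedness_test(
            part, None, tree, ColonistTestOptions(n_randomizations=999, seed=1)
        )
        assert res.direction == "clustered"
        assert res.p_value < 0.05
        assert res.dispersion.observed < res.dispersion.null_mean

    def test_degenerate_pool_flagged(self):
        """Null pool exactly the colonist count -> every draw identical."""
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        part = partition_plot({"A", "B"}, {"A", "B", "C", "D"}, "p")
        res = colonist_relatedness_test(
            part, None, tree, ColonistTestOptions(n_randomizations=99, seed=1)
        )
        assert res.dispersion.sd_zero

    def test_no_colonists_rejected(self, cherry_tree):
        part = partition_plot({"A", "B"}, {"A", "B"}, "p")
        with pytest.raises(UndefinedStatisticError):
            colonist_relatedness_test(part, None, cherry_tree)

    def test_legume_exclusion_audit(self, experiment):
        """With the legume clade excluded, no legume may appear in the focal
        set or in any null draw."""
        tree = experiment.tree
        legumes = tree.tips_with_tag("legume")
        part = next(
            partition_plot(experiment.sown.members(p), experiment.final.members(p), p)
            for p in experiment.sown.plot_ids
            if (experiment.final.members(p) - experiment.sown.members(p)) - legumes
        )
        res = colonist_relatedness_test(
            part,
            None,
            tree,
            ColonistTestOptions(
                excluded_tags=frozenset({"legume"}), n_randomizations=499, seed=3
            ),
        )
        assert res.null_tag_counts["legume"] == 0

    def test_spec_overrides_pool_and_n(self, experiment, internal_pool):
        tree = experiment.tree
        part = next(
            partition_plot(experiment.sown.members(p), experiment.final.members(p), p)
            for p in experiment.sown.plot_ids
            if experiment.final.members(p) - experiment.sown.members(p)
        )
        spec = NullConstraintSpec(
            pool=frozenset(tree.tip_labels), n_randomizations=77, seed=4
        )
        res = colonist_relatedness_test(part, spec, tree)
        assert res.dispersion.n_randomizations == 77

    def test_invariant_to_input_ordering(self, experiment):
        tree = experiment.tree
        pid = next(
            p
            for p in experiment.sown.plot_ids
            if experiment.final.members(p) - experiment.sown.members(p)
        )
        sown = list(experiment.sown.members(pid))
        final = list(experiment.final.members(pid))
        opts = ColonistTestOptions(n_randomizations=199, seed=8)
        r1 = colonist_relatedness_test(partition_plot(sown, final, pid), None, tree, opts)
        rev = colonist_relatedness_test(
            partition_plot(sown[::-1], final[::-1], pid), None, tree, opts
        )
        assert r1.dispersion == rev.dispersion

    def test_neutral_colonists_calibrated(self, experiment, internal_pool):
        """Uniformly drawn pseudo-colonists yield ~uniform p-values."""
        from scipy import stats

        tree = experiment.tree
        pool = frozenset(tree.tip_labels)
        rng = np.random.default_rng(17)
        labels = np.array(sorted(internal_pool))
        pvals = []
        for _ in range(200):
            sown = frozenset(rng.choice(labels, size=8, replace=False))
            outside = np.array(sorted(pool - sown))
            colonists = frozenset(rng.choice(outside, size=3, replace=False))
            part = partition_plot(sown, sown | colonists, "sim")
            res = colonist_relatedness_test(
                part, None, tree,
                ColonistTestOptions(n_randomizations=199), rng=rng,
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue >= 0.01


class TestExtinctionTest:
    def test_two_sown_one_extinct_is_degenerate(self, cherry_tree):
        """With two sown species the statistic is the same under both
        relabelings, so p = 1 and the zero-sd flag is raised."""
        part = partition_plot({"A", "B"}, {"B"}, "p")
        res = extinction_relatedness_test(
            part, cherry_tree, ExtinctionTestOptions(n_randomizations=199, seed=1)
        )
        assert res.dispersion.sd_zero and res.p_value == 1.0

    def test_enumerated_null_three_sown(self, cherry_tree):
        """Sown {A,B,C}, extinct {C}: relabelings give statistic 2 (A or B
        extinct) or 4 (C extinct); the rank p follows from those counts."""
        part = partition_plot({"A", "B", "C"}, {"A", "B"}, "p")
        res = extinction_relatedness_test(
            part, cherry_tree, ExtinctionTestOptions(n_randomizations=999, seed=2)
        )
        assert res.dispersion.observed == pytest.approx(4.0)
        d = res.dispersion
        n_four = d.n_at_or_above  # draws with statistic 4
        assert d.p_value == pytest.approx(min(1.0, 2 * (n_four + 1) / 1000))
        # relabeling C is picked about 1/3 of the time
        assert 0.2 < n_four / 999 < 0.47

    def test_isolated_extinction_overdispersed(self):
        """On a star tree with one long tip, losing exactly that tip is
        overdispersed relative to the relabeling null."""
        tips = ",".join(f"s{i}:1" for i in range(1, 60))
        tree = read_newick(f"({tips},long:25);")
        sown = set(tree.tip_labels)
        part = partition_plot(sown, sown - {"long"}, "p")
        res = extinction_relatedness_test(
            part, tree, ExtinctionTestOptions(n_randomizations=1999, seed=3)
        )
        assert res.direction == "overdispersed"
        assert res.dispersion.observed > res.dispersion.null_mean

    def test_all_extinct_rejected(self, cherry_tree):
        part = partition_plot({"A", "B"}, set(), "p")
        with pytest.raises(UndefinedStatisticError):
            extinction_relatedness_test(part, cherry_tree)

    def test_colonists_as_residents_changes_reference(self, experiment):
        tree = experiment.tree
        pid = next(
            p
            for p in experiment.sown.plot_ids
            if (experiment.sown.members(p) - experiment.final.members(p))
            and (experiment.final.members(p) - experiment.sown.members(p))
            and (experiment.sown.members(p) & experiment.final.members(p))
        )
        part = partition_plot(experiment.sown.members(pid), experiment.final.members(pid), pid)
        base = extinction_relatedness_test(
            part, tree, ExtinctionTestOptions(n_randomizations=99, seed=5)
        )
        with_col = extinction_relatedness_test(
            part,
            tree,
            ExtinctionTestOptions(colonists_as_residents=True, n_randomizations=99, seed=5),
        )
        assert with_col.n_reference == base.n_reference + len(part.colonize)
        assert with_col.dispersion.observed <= base.dispersion.observed + 1e-12


class TestPoolLevelAndCounting:
    def test_whole_clade_clustered(self):
        tree = two_clade_tree()
        focal = {f"n{i}" for i in range(1, 7)}
        res = pool_colonizer_test(focal, frozenset(tree.tip_labels), tree, 999, seed=1)
        assert res.direction == "clustered" and res.p_value < 0.05

    def test_focal_equals_pool_degenerate(self, cherry_tree):
        pool = frozenset(cherry_tree.tip_labels)
        res = pool_colonizer_test(pool, pool, cherry_tree, 99, seed=1)
        assert res.sd_zero and res.ses == 0.0

    def test_count_significant(self):
        import numpy as np

        results = [
            summarize_null("MNND", obs, nulls)
            for obs, nulls in [
                (0.0, np.linspace(1, 2, 999)),   # clustered
                (3.0, np.linspace(1, 2, 999)),   # overdispersed
                (1.5, np.linspace(1, 2, 999)),   # random
            ]
        ] + [summarize_null("MNND", 1.5, np.linspace(1, 2, 999)) for _ in range(38)]
        summary = count_significant(results, alpha=0.05)
        assert summary.n_tested == 41
        assert summary.n_clustered == 1
        assert summary.n_overdispersed == 1
        assert summary.n_expected_by_chance == 2

    def test_count_significant_empty(self):
        with pytest.raises(ValueError):
            count_significant([])
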