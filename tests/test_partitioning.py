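import numpy as np
import pytest

import lymphoref as lr
from lymphoref.partitioning import (
    DegenerateDataError,
    GroupSummary,
    omnibus_groups,
    summarize,
)


class TestZStar:
    def test_combined_938_gives_printed_value(self):
        assert round(lr.z_star(469, 469), 1) == 5.9

    def test_reference_sample_sizes(self):
        assert lr.z_star(120, 120) == pytest.approx(3.0)
        assert lr.z_star(476, 337) == pytest.approx(5.52, abs=0.005)

    def test_monotone_in_total_n(self):
        values = [lr.z_star(n, n) for n in range(10, 500, 17)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_positive_n_required(self):
        with pytest.raises(ValueError):
            lr.z_star(0, 10)


class TestHarrisBoydZ:
    def test_identical_summaries_give_zero(self):
        a = GroupSummary("a", 50, 3.0, 1.0)
        assert lr.harris_boyd_z(a, a) == 0.0

    def test_hand_computed_value(self):
        a = GroupSummary("a", 64, 10.0, 4.0)
        b = GroupSummary("b", 64, 12.0, 4.0)
        assert lr.harris_boyd_z(a, b) == pytest.approx(2.0 / np.sqrt(0.5), abs=1e-3)

    def test_symmetric_in_group_order(self):
        a = GroupSummary("a", 30, 1.0, 2.0)
        b = GroupSummary("b", 45, 4.0, 1.0)
        assert lr.harris_boyd_z(a, b) == lr.harris_boyd_z(b, a)

    def test_zero_variance_error(self):
        a = GroupSummary("a", 10, 1.0, 0.0)
        with pytest.raises(DegenerateDataError):
            lr.harris_boyd_z(a, a)

    def test_null_z_stays_under_z_star(self):
        """Two same-distribution groups of 406/407: z rarely approaches the
        Harris-Boyd threshold."""
        ok = 0
        for s in range(500):
            rng = np.random.default_rng(s)
            x, y = rng.standard_normal(406), rng.standard_normal(407)
            z = lr.harris_boyd_z(summarize("x", x), summarize("y", y))
            ok += z < lr.z_star(406, 407)
        assert ok >= 475  # >= 95% of seeds


class TestOmnibus:
    def test_power_on_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        b = rng.standard_normal(100) + 3.0
        assert omnibus_groups([a, b], "anova") < 1e-3
        assert omnibus_groups([a, b], "kruskal_wallis") < 1e-3

    def test_constant_groups_error(self):
        with pytest.raises(DegenerateDataError):
            omnibus_groups([np.full(5, 1.0), np.full(5, 1.0)], "anova")

    def test_label_interface_matches_group_interface(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(60)
        labels = np.repeat(["a", "b", "c"], 20)
        assert lr.omnibus_test(v, labels) == pytest.approx(
            omnibus_groups([v[:20], v[20:40], v[40:]])
        )

    def test_kruskal_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [np.exp(rng.standard_normal(40)) for _ in range(3)]
        p_raw = omnibus_groups(groups, "kruskal_wallis")
        p_log = omnibus_groups([np.log(g) for g in groups], "kruskal_wallis")
        assert p_raw == pytest.approx(p_log)


class TestDecideMerge:
    @pytest.mark.parametrize(
        "p,z,zs,expected",
        [
            (0.40, 7.0, 5.9, "merge"),   # non-significant omnibus dominates
            (0.01, 6.5, 5.9, "split"),   # both gates fire
            (0.01, 4.0, 5.9, "merge"),   # z under z*
            (0.049, 5.91, 5.9, "split"),
        ],
    )
    def test_rule(self, p, z, zs, expected):
        assert lr.decide_merge(p, z, zs) == expected


def _bins_from(dists, n=160, seed=0):
    rng = np.random.default_rng(seed)
    return {f"bin{i+1}": d + rng.standard_normal(n) for i, d in enumerate(dists)}


class TestAgeMerging:
    def test_null_collapses_to_single_bin(self):
        hist = lr.merge_adjacent_age_groups(_bins_from([0, 0, 0, 0, 0], seed=5))
        assert hist.final_bins == [["bin1", "bin2", "bin3", "bin4", "bin5"]]

    def test_shifted_first_bin_kept_separate(self):
        hist = lr.merge_adjacent_age_groups(_bins_from([5, 0, 0, 0, 0], seed=5))
        assert hist.final_bins == [["bin1"], ["bin2", "bin3", "bin4", "bin5"]]

    def test_bins_stay_adjacent_and_ordered(self):
        for s in range(10):
            hist = lr.merge_adjacent_age_groups(_bins_from([0, 0.2, 0, 0.4, 0], seed=s))
            flat = [b for grp in hist.final_bins for b in grp]
            assert flat == ["bin1", "bin2", "bin3", "bin4", "bin5"]

    def test_small_bin_warning(self):
        bins = _bins_from([0, 0], n=10)
        hist = lr.merge_adjacent_age_groups(bins)
        assert any("n=10" in w for w in hist.warnings)

    def test_printed_total_t_pattern(self, default_spec):
        """Neonatal %T differs sharply (median 80.6 vs 69.1 elsewhere): the
        first bin stays separate and the rest pool, matching the published
        partition for this analyte."""
        ok = 0
        for s in range(10):
            vals = {
                b: np.log(default_spec.params["pct_T"][b].sample(np.random.default_rng((s, i)), n))
                for i, (b, n) in enumerate(default_spec.group_sizes.items())
            }
            hist = lr.merge_adjacent_age_groups(vals, analyte="pct_T")
            ok += hist.final_bins == [["0-1 month"], ["2-12 months", "1-3 years", "4-6 years", "7-18 years"]]
        assert ok >= 9


class TestSexPartition:
    def test_identical_distributions_merge(self):
        merged = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            res = lr.test_sex_partition(rng.standard_normal(476), rng.standard_normal(337))
            merged += res.decision == "merge"
        assert merged >= 45  # >= 90% of seeds

    def test_engineered_sex_effect_splits(self):
        rng = np.random.default_rng(0)
        m = rng.normal(15.0, 1.0, 476)
        f = rng.normal(10.0, 1.0, 337)
        res = lr.test_sex_partition(m, f)
        assert res.decision == "split" and res.pair == ("M", "F")

    def test_z_star_wired_from_group_sizes(self):
        rng = np.random.default_rng(3)
        res = lr.test_sex_partition(rng.standard_normal(476), rng.standard_normal(337))
        assert res.z_star == pytest.approx(lr.z_star(476, 337))
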