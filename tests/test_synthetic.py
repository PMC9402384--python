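import numpy as np
import pandas as pd
import pytest

import lymphoref as lr
from lymphoref.synthetic import Z975


class TestFitSplitLognormal:
    def test_symmetric_on_log_scale(self):
        p = lr.fit_split_lognormal(100.0, 25.0, 400.0)
        assert p.sigma_low == pytest.approx(p.sigma_high)
        assert p.sigma_low == pytest.approx(np.log(4) / Z975, abs=1e-4)  # ~0.7073

    def test_published_total_t_cell_neonatal_params(self):
        p = lr.fit_split_lognormal(80.59, 52.26, 89.74)
        assert p.sigma_low == pytest.approx(0.2211, abs=5e-4)
        assert p.sigma_high == pytest.approx(0.0549, abs=5e-4)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            lr.fit_split_lognormal(10.0, 12.0, 20.0)

    def test_round_trip_quantiles(self):
        """1e5 draws reproduce the three input quantiles within 2%."""
        p = lr.fit_split_lognormal(62.0, 23.0, 170.0)
        draws = p.sample(np.random.default_rng(0), 100_000)
        for prob, target in [(0.5, 62.0), (0.025, 23.0), (0.975, 170.0)]:
            assert np.quantile(draws, prob) == pytest.approx(target, rel=0.02)

    def test_closed_form_quantile_matches_empirical(self):
        p = lr.fit_split_lognormal(10.0, 2.0, 15.0)
        draws = p.sample(np.random.default_rng(1), 200_000)
        for prob in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert np.quantile(draws, prob) == pytest.approx(p.quantile(prob), rel=0.02)

    def test_central_coverage_by_construction(self):
        p = lr.fit_split_lognormal(35.0, 9.0, 119.0)
        draws = p.sample(np.random.default_rng(2), 100_000)
        inside = np.mean((draws >= 9.0) & (draws <= 119.0))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestDefaultSpec:
    def test_panel_complete_across_all_bins(self, default_spec):
        assert len(default_spec.analytes) == 16
        for a in default_spec.analytes:
            assert set(default_spec.params[a]) == set(default_spec.scheme.labels)

    def test_printed_group_sizes_and_sex_ratio(self, default_spec):
        assert list(default_spec.group_sizes.values()) == [187, 154, 197, 155, 120]
        assert default_spec.total_size == 813
        assert default_spec.sex_counts == {"M": 476, "F": 337}

    def test_selected_published_cells(self, default_spec):
        assert default_spec.params["pct_CD4"]["0-1 month"].median == pytest.approx(56.06)
        p = default_spec.params["cnt_NKT"]["7-18 years"]
        assert p.median == pytest.approx(35.0)
        assert p.quantile(0.025) == pytest.approx(9.0, rel=1e-6)
        assert p.quantile(0.975) == pytest.approx(119.0, rel=1e-6)

    def test_dnt_percentage_median_increases_with_age(self, default_spec):
        meds = [default_spec.params["pct_DNT"][b].median for b in default_spec.scheme.labels]
        assert all(a <= b for a, b in zip(meds, meds[1:]))


class TestGenerateCohort:
    def test_empty_spec_gives_empty_cohort(self, default_spec):
        from dataclasses import replace

        spec = replace(default_spec, group_sizes={b: 0 for b in default_spec.scheme.labels})
        cohort, ledger = lr.generate_cohort(spec, seed=0)
        assert cohort.empty and ledger.empty

    def test_same_seed_is_byte_identical(self, default_spec, tmp_path):
        a, _ = lr.generate_cohort(default_spec, seed=9)
        b, _ = lr.generate_cohort(default_spec, seed=9)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self, default_spec):
        a, _ = lr.generate_cohort(default_spec, seed=1)
        b, _ = lr.generate_cohort(default_spec, seed=2)
        assert not a["pct_T"].equals(b["pct_T"])

    def test_group_sizes_and_schema(self, clean_cohort, default_spec):
        assert len(clean_cohort) == 813
        loaded = lr.load_cohort(clean_cohort)
        assert not loaded.rejected
        counts = loaded.frame["age_group"].value_counts()
        for b, n in default_spec.group_sizes.items():
            assert counts[b] == n

    def test_empirical_medians_near_spec(self, clean_cohort, default_spec):
        """Per-group sample medians track the generating medians within 4
        asymptotic standard errors. On the log scale the sample median's SE
        is ~ 1.25 * sigma_eff / sqrt(n) with sigma_eff the harmonic mean of
        the two tail sigmas (the density has different slopes each side);
        for the tight percentage analytes this bound is ~2-5%, for the
        dispersed NK/B counts at n ~ 120-200 it reaches ~25%."""
        frame = lr.load_cohort(clean_cohort).frame
        for a in default_spec.analytes:
            for b, sub in frame.groupby("age_group", observed=True):
                p = default_spec.params[a][b]
                sigma_eff = 2.0 / (1.0 / p.sigma_low + 1.0 / p.sigma_high)
                se_log = 1.2533 * sigma_eff / np.sqrt(len(sub))
                log_err = abs(np.log(np.median(sub[a]) / p.median))
                assert log_err <= 4 * se_log, (a, b, log_err, se_log)

    def test_injection_ledger_records_contamination(self, default_spec):
        spec = default_spec.with_contamination(0.02, 10.0)
        cohort, ledger = lr.generate_cohort(spec, seed=4)
        assert len(ledger) > 0
        # ledger rows are consistent with the cohort values
        for _, row in ledger.head(20).iterrows():
            v = cohort.loc[cohort["subject_id"] == row["subject_id"], row["analyte"]].iloc[0]
            assert v == pytest.approx(row["value"])
            assert row["value"] == pytest.approx(10.0 * row["clean_value"])

    def test_adding_an_analyte_does_not_perturb_others(self, default_spec):
        from dataclasses import replace

        reduced = replace(
            default_spec,
            params={k: v for k, v in default_spec.params.items() if k != "cnt_NKT"},
        )
        full, _ = lr.generate_cohort(default_spec, seed=11)
        part, _ = lr.generate_cohort(reduced, seed=11)
        assert full["pct_T"].tolist() == part["pct_T"].tolist()
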