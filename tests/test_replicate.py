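"""Anderson-Darling k-sample test, SNR, and the dual replicate filter."""

import numpy as np
import pytest

from topoqc.replicate import (
    DualReplicateFilter,
    ad_ksample,
    ad_permutation_pvalue,
    dual_filter,
    removal_report,
    snr,
)


class TestADKSample:
    def test_identical_samples_not_significant(self):
        res = ad_ksample([np.arange(1, 21), np.arange(1, 21)])
        assert res.p_value > 0.25
        assert res.total_n == 40 and res.n_samples == 2

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        res = ad_ksample([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        assert res.p_value < 0.001

    def test_separated_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(0, 1, 30), rng.normal(1.0, 1, 30)]
        p_perm = ad_permutation_pvalue(samples, n_permutations=10_000,
                                       seed=2)
        p_approx = ad_ksample(samples).p_value
        # Monte-Carlo error on 10k permutations is ~0.005 at these p levels
        assert p_approx == pytest.approx(p_perm, abs=0.02)

    def test_small_case_tracks_exact_enumeration(self):
        """Two samples of size 4: the exact distribution has C(8,4) = 70
        assignments; in the decision region the tabulated approximation
        tracks the exact p within +/-0.05."""
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(40):
            a = rng.normal(0, 1, 4)
            b = rng.normal(2.0, 1, 4)
            p_exact = ad_permutation_pvalue([a, b])
            p_approx = ad_ksample([a, b]).p_value
            if p_exact <= 0.2:  # the region where the filter decides
                assert p_approx == pytest.approx(p_exact, abs=0.05)
                checked += 1
        assert checked >= 10

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        base = ad_ksample([a, b]).statistic
        for f in (np.exp, lambda x: x**3, lambda x: 2 * x + 7):
            assert ad_ksample([f(a), f(b)]).statistic == \
                pytest.approx(base, abs=1e-10)

    def test_sample_order_symmetry(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(i, 1, 15) for i in range(3)]
        base = ad_ksample(groups).statistic
        assert ad_ksample(groups[::-1]).statistic == \
            pytest.approx(base, abs=1e-10)

    def test_matches_independent_reference_implementation(self):
        """Cross-check of the normalized statistic against scipy's
        independent midrank implementation."""
        import warnings

        from scipy.stats import anderson_ksamp

        rng = np.random.default_rng(7)
        for k in (2, 3):
            groups = [rng.normal(0.3 * i, 1, 25) for i in range(k)]
            mine = ad_ksample(groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = anderson_ksamp(groups)
            assert mine.normalized == pytest.approx(ref.statistic,
                                                    abs=1e-8)

    def test_ties_handled_by_midrank(self):
        res = ad_ksample([[1, 1, 2, 2, 3], [1, 2, 2, 3, 3]])
        assert np.isfinite(res.statistic)
        assert res.p_value > 0.25

    def test_degenerate_pooled_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ad_ksample([[5.0, 5.0], [5.0, 5.0]])

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            ad_ksample([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            ad_ksample([[1.0, 2.0]])


class TestSNR:
    def test_arithmetic(self):
        values = [5, 15]  # mean 10, sd ~7.07
        r = snr(values)
        assert r.snr == pytest.approx(10 / np.std(values, ddof=1))

    def test_mean_ten_sd_five(self):
        values = np.array([5.0, 10.0, 15.0])
        r = snr(values)
        assert r.mean == pytest.approx(10.0)
        assert r.sd == pytest.approx(5.0)
        assert r.snr == pytest.approx(2.0)

    def test_constant_sample_infinite(self):
        assert snr([3.0, 3.0, 3.0]).snr == float("inf")

    def test_count_style_snr_near_three(self):
        """Counts drawn 39 +/- 13 give SNR ~= 39/13 = 3."""
        rng = np.random.default_rng(8)
        r = snr(rng.normal(39, 13, 20_000))
        assert r.snr == pytest.approx(3.0, rel=0.05)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            snr([1.0])


class TestDualFilter:
    def test_type_one_error_near_alpha(self):
        """Under the null (all replicates i.i.d.), the AD arm removes
        ~alpha of designs: binomial 3-sigma band around 5% of 600."""
        rng = np.random.default_rng(9)
        designs = {
            f"D{i}": [rng.normal(39, 13, 30), rng.normal(39, 13, 30)]
            for i in range(600)
        }
        _, report = dual_filter(designs, snr_band=(0.001, 1e9))
        n_ad = len(report.removed_by_ad)
        expect = 0.05 * 600
        sigma = np.sqrt(600 * 0.05 * 0.95)
        assert abs(n_ad - expect) <= 3 * sigma

    def test_planted_shift_recall_perfect(self):
        """Shifts of 3 pooled SDs are always caught (recall 1.0)."""
        rng = np.random.default_rng(10)
        designs, planted = {}, []
        for i in range(200):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            if i % 10 == 0:
                b = b + 3.0
                planted.append(f"D{i}")
            designs[f"D{i}"] = [a + 10, b + 10]
        _, report = dual_filter(designs, snr_band=(0.001, 1e9))
        assert set(planted) <= set(report.removed_by_ad)

    def test_constant_values_removed_by_snr(self):
        designs = {"D1": [np.array([5.0, 5.0]), np.array([5.0, 5.0])]}
        retained, report = dual_filter(designs)
        assert retained == []
        assert report.removed_by_snr == ["D1"]
        assert report.removed_by_ad == []  # degenerate AD treated as p=1

    def test_single_group_flagged_untestable(self):
        designs = {"D1": [np.array([1.0, 2.0, 3.0])]}
        retained, report = dual_filter(designs)
        assert retained == []
        assert report.untestable == ["D1"]
        assert report.removed_union == []

    def test_generator_replicate_recall(self, small_screen):
        """Planted inconsistent replicate pairs in a generated screen are
        all removed by the AD arm at default thresholds."""
        from topoqc.replicate import replicate_groups_from_cells
        from topoqc.synth import plant_artifacts

        planted_screen = plant_artifacts(
            small_screen, {"replicate_inconsistent": 0.05}, seed=5)
        reg = set(planted_screen.truth_units(
            "replicate_inconsistent")["design_id"])
        groups = replicate_groups_from_cells(
            planted_screen.cells, planted_screen.layout, "nuclear_area")
        _, report = dual_filter(groups, "nuclear_area")
        recall = np.mean([d in set(report.removed_by_ad) for d in reg])
        assert recall >= 0.9


class TestRemovalReport:
    def test_zero_removal_row(self):
        f = DualReplicateFilter(feature="cell_count").fit(
            {"D1": [np.array([1.0, 2.0, 3.0]), np.array([1.5, 2.5, 3.1])]})
        frame = removal_report([f.report_])
        row = frame.iloc[0]
        assert row["feature"] == "cell_count"
        assert row["removed_by_ad"] == 0 and row["removed_by_snr"] == 0

    def test_union_consistency(self):
        rng = np.random.default_rng(11)
        designs = {f"D{i}": [rng.normal(0, 1, 20) + 10,
                             rng.normal(0.1 * i, 1, 20) + 10]
                   for i in range(60)}
        f = DualReplicateFilter().fit(designs)
        r = f.report_
        assert len(r.removed_by_ad) + len(r.removed_by_snr) >= \
            len(r.removed_union)
        assert set(f.retained_).isdisjoint(r.removed_union)
        assert len(f.retained_) + len(r.removed_union) \
            + len(r.untestable) == len(designs)

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            removal_report([])
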