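"""Tiered QC: object filters, IQR/count-band/NtoC filters, ledger."""

import numpy as np
import pandas as pd
import pytest

from topoqc.features import CVCurve
from topoqc.qc import (
    CountBand,
    NtoCPercentileFilter,
    QCLedger,
    build_ledger,
    count_band_filter,
    filter_objects,
    iqr_bounds,
    ntoc_percentile_filter,
    select_count_band,
)


def _cells(diams, border=None, wall=None):
    n = len(diams)
    return pd.DataFrame({
        "chip_id": "chip1", "row": 0, "col": range(n),
        "cell_id": [f"c{i}" for i in range(n)],
        "nucleus_diameter": diams,
        "touches_border": border if border is not None else [False] * n,
        "touches_wall": wall if wall is not None else [False] * n,
    })


class TestObjectFilter:
    def test_diameter_band_inclusive(self):
        cells = _cells([10, 15, 40, 65, 70])
        kept, log = filter_objects(cells)
        assert list(kept["nucleus_diameter"]) == [15, 40, 65]
        assert list(log["rule"]) == ["diameter", "diameter"]

    def test_identity_when_all_pass(self):
        cells = _cells([20, 30, 40])
        kept, log = filter_objects(cells)
        assert len(kept) == 3 and log.empty

    def test_wall_contact_linkage_rule(self):
        rng = np.random.default_rng(0)
        wall = np.zeros(100, dtype=bool)
        wall[rng.choice(100, 17, replace=False)] = True
        cells = _cells([30.0] * 100, wall=wall)
        kept, log = filter_objects(cells)
        assert len(kept) == 83
        assert (log["rule"] == "wall-contact").sum() == 17

    def test_first_failing_rule_reported(self):
        cells = _cells([5.0], border=[True], wall=[True])
        _, log = filter_objects(cells)
        assert log["rule"].iloc[0] == "diameter"

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            filter_objects(_cells([30.0]), diam_min=65, diam_max=15)


class TestIQRBounds:
    def test_constant_sample(self):
        b = iqr_bounds([7.0] * 10)
        assert b.lower == b.upper == 7.0

    def test_outlier_detected_under_type7_quartiles(self):
        """Brute-force check of the linear-interpolation quartile rule:
        for 1..10 plus 100, q1 = 3.5 and q3 = 8.5, so the upper fence is
        8.5 + 1.5 * 5 = 16."""
        values = list(range(1, 11)) + [100]
        b = iqr_bounds(values, k=1.5)
        assert b.q1 == pytest.approx(3.5)
        assert b.q3 == pytest.approx(8.5)
        assert b.upper == pytest.approx(16.0)
        outside = [v for v in values if not b.contains([v])[0]]
        assert outside == [100]

    def test_symmetric_sample_symmetric_bounds(self):
        values = [-3, -2, -1, 0, 1, 2, 3]
        b = iqr_bounds(values)
        assert b.lower == pytest.approx(-b.upper)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="4"):
            iqr_bounds([1.0, 2.0, 3.0])


def _curve(counts, cvs):
    return CVCurve(feature="f", table=pd.DataFrame({
        "cell_count": counts, "n_units": 50, "cv": cvs}))


class TestSelectCountBand:
    def test_flat_curves_full_range(self):
        band = select_count_band([_curve(range(5, 70), [0.1] * 65)],
                                 cv_ceiling=1.5)
        assert (band.lower, band.upper) == (5, 69)
        assert band.provenance == "derived_from_cv"

    def test_u_shaped_curves_against_exhaustive_oracle(self):
        """Independent oracle: brute-force scan over all contiguous count
        ranges, keeping the widest range with every cv under the ceiling."""
        counts = list(range(5, 71))
        cvs = [0.3 if c < 12 or c > 60 else 0.1 for c in counts]
        curve = _curve(counts, cvs)
        band = select_count_band([curve], cv_ceiling=1.5)

        floor = min(cvs)
        ok = {c: cv <= 1.5 * floor for c, cv in zip(counts, cvs)}
        best = None
        for s in counts:
            for e in counts:
                if e < s or not all(ok.get(c, True)
                                    for c in range(s, e + 1)):
                    continue
                n = sum(1 for c in range(s, e + 1) if c in ok and ok[c])
                if best is None or n > best[0]:
                    best = (n, s, e)
        assert (band.lower, band.upper) == (best[1], best[2])
        assert (band.lower, band.upper) == (12, 60)

    def test_no_qualifying_range_falls_back_to_fixed(self):
        # a curve with no populated bins offers no qualifying counts
        empty = _curve([], [])
        band = select_count_band([empty], cv_ceiling=1.5)
        assert (band.lower, band.upper) == (11, 64)
        assert band.provenance == "fixed"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_count_band([], cv_ceiling=1.5)


def _units(counts, ntoc=None):
    n = len(counts)
    frame = pd.DataFrame({
        "chip_id": "chip1", "row": np.arange(n) // 66,
        "col": np.arange(n) % 66,
        "design_id": [f"D{i}" for i in range(n)],
        "cell_count": counts,
    })
    frame["mean_ntoc"] = ntoc if ntoc is not None else 0.15
    return frame


class TestCountBandFilter:
    def test_band_boundaries_inclusive_retain(self):
        units = _units([10, 11, 64, 65])
        kept, removed, tier = count_band_filter(units, CountBand(11, 64))
        assert list(kept["cell_count"]) == [11, 64]
        assert list(removed["cell_count"]) == [10, 65]
        assert tier.images_removed == 2
        assert tier.objects_removed == 75

    def test_wide_band_identity(self):
        units = _units([1, 50, 500])
        kept, removed, _ = count_band_filter(units, CountBand(1, 10**9))
        assert len(kept) == 3 and removed.empty

    def test_idempotent(self):
        units = _units(list(range(1, 100)))
        kept, _, _ = count_band_filter(units, CountBand(11, 64))
        again, removed, _ = count_band_filter(kept, CountBand(11, 64))
        assert removed.empty
        pd.testing.assert_frame_equal(again, kept)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            CountBand(64, 11)


class TestNtoCPercentileFilter:
    def test_degenerate_distribution_removes_none(self):
        units = _units([30] * 20, ntoc=[0.15] * 20)
        kept, removed, _ = ntoc_percentile_filter(units)
        assert removed.empty and len(kept) == 20

    def test_uniform_tail_mass_binomial(self):
        rng = np.random.default_rng(5)
        units = _units([30] * 1000, ntoc=rng.uniform(0, 1, 1000))
        kept, removed, _ = ntoc_percentile_filter(units, 2.5, 97.5)
        # ~5% expected strictly outside; binomial(1000, .05) 4-sigma band
        assert 22 <= len(removed) <= 78

    def test_invalid_sentinel_always_removed(self):
        ntoc = [0.15] * 10 + [float("nan")]
        units = _units([30] * 11, ntoc=ntoc)
        f = NtoCPercentileFilter().fit(units)
        kept = f.transform(units)
        assert len(kept) == 10
        assert f.n_invalid_ == 1
        assert "ntoc-invalid" in set(f.removed_["rule"])

    def test_frozen_thresholds_do_not_cascade(self):
        rng = np.random.default_rng(6)
        units = _units([30] * 500, ntoc=rng.lognormal(-1.9, 0.3, 500))
        f = NtoCPercentileFilter().fit(units)
        once = f.transform(units)
        twice = f.transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_invalid_rejected(self):
        units = _units([30] * 5, ntoc=[float("nan")] * 5)
        with pytest.raises(ValueError, match="invalid"):
            NtoCPercentileFilter().fit(units)


class TestLedger:
    def test_curation_worked_example(self):
        """Screen-scale arithmetic: 39,204 images / 1,213,838 objects minus
        the count-band tier (5278; 63,789) and the NtoC tier (2006; 27,804)
        leaves 31,920 images and 1,122,245 objects."""
        ledger = build_ledger(
            [("count_band", 5278, 63789), ("ntoc", 2006, 27804)],
            images_in=39204, objects_in=1213838)
        assert ledger.images_retained == 31920
        assert ledger.objects_retained == 1122245
        assert ledger.total_removed == (7284, 91593)

    def test_zero_removal_identity(self):
        ledger = build_ledger([("a", 0, 0), ("b", 0, 0)], 100, 1000)
        assert ledger.retained == (100, 1000)

    def test_overdraw_rejected(self):
        ledger = QCLedger(images_in=10, objects_in=100)
        ledger.add_tier("ok", 5, 50)
        with pytest.raises(ValueError, match="remain"):
            ledger.add_tier("too-much", 6, 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            QCLedger(10, 100).add_tier("neg", -1, 0)

    def test_frame_chain_is_conserved(self):
        ledger = build_ledger([("a", 3, 30), ("b", 2, 20)], 10, 100)
        frame = ledger.to_frame()
        assert (frame["images_in"] - frame["images_removed"]
                == frame["images_out"]).all()
        assert frame["images_out"].iloc[-1] == ledger.images_retained
        assert frame["objects_out"].iloc[-1] == ledger.objects_retained
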