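"""Synthetic screen generator: calibration, artifacts, images, z-stacks."""

import math

import numpy as np
import pandas as pd
import pytest

from topoqc.layout import build_layout
from topoqc.synth import (
    SyntheticScreenConfig,
    generate_screen,
    generate_stitched_image,
    generate_zstack,
    plant_artifacts,
)


class TestConfig:
    def test_variance_decomposition_solves(self):
        cfg = SyntheticScreenConfig()
        sigma_b, sigma_w = cfg.variance_components()
        total = math.hypot(sigma_b, sigma_w)
        assert total == pytest.approx(161.0, rel=1e-9)
        einv = cfg.expected_inverse_count()
        assert sigma_b**2 + sigma_w**2 * einv == pytest.approx(65.0**2,
                                                               rel=1e-9)

    def test_unsatisfiable_decomposition_rejected(self):
        # unit-mean SD below the sampling floor sigma/sqrt(n) forces
        # sigma_b^2 < 0
        with pytest.raises(ValueError, match="sigma_b"):
            SyntheticScreenConfig(unit_mean_sd=5.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            SyntheticScreenConfig(artifact_rates={"underpopulated": 0.7})
        with pytest.raises(ValueError, match="unknown"):
            SyntheticScreenConfig(artifact_rates={"bogus": 0.1})


class TestGenerateScreen:
    def test_density_classes(self, default_screen):
        stats = default_screen.units.groupby("chip_id")["cell_count"] \
            .agg(["mean", "std"])
        low = {"chip4", "chip7", "chip8"}
        for chip, row in stats.iterrows():
            if chip in low:
                assert row["mean"] == pytest.approx(15, abs=2.5)
                assert row["std"] == pytest.approx(11, abs=1.5)
            else:
                assert row["mean"] == pytest.approx(39, abs=1.5)
                assert row["std"] == pytest.approx(13, abs=1.0)

    def test_nuclear_area_calibration(self, default_screen):
        """Headline parameter-recovery check: estimating the nuclear-area
        moments from a generated screen returns the configured targets."""
        cells = default_screen.cells
        units = default_screen.units
        assert len(cells) >= 30_000
        assert cells["nuclear_area"].std(ddof=1) == pytest.approx(
            161.0, rel=0.03)
        assert units["nuclear_area_mean"].std(ddof=1) == pytest.approx(
            65.0, rel=0.10)
        assert cells["nuclear_area"].mean() == pytest.approx(737.0, rel=0.01)

    def test_planted_correlations_recovered(self, default_screen):
        cells = default_screen.cells
        r_dp = np.corrcoef(cells["mean_dapi"],
                           cells["mean_phalloidin"])[0, 1]
        assert r_dp == pytest.approx(0.83, abs=0.02)
        r_sp = np.corrcoef(cells["solidity"],
                           cells["peripheral_actin_fraction"])[0, 1]
        assert r_sp == pytest.approx(-0.87, abs=0.02)

    def test_zero_between_unit_component(self):
        """With unit_mean_sd^2 = sigma^2 * E[1/n], sigma_b = 0 and unit
        means vary only through sampling noise."""
        base = SyntheticScreenConfig(n_chips=2, high_density_chips=2,
                                     n_designs=126, n_rows=16, n_cols=16,
                                     seed=11)
        einv = base.expected_inverse_count()
        cfg = SyntheticScreenConfig(
            n_chips=2, high_density_chips=2, n_designs=126,
            n_rows=16, n_cols=16, seed=11,
            unit_mean_sd=161.0 * math.sqrt(einv))
        sigma_b, sigma_w = cfg.variance_components()
        assert sigma_b == pytest.approx(0.0, abs=1e-6)
        screen = generate_screen(cfg)
        expected = 161.0 * math.sqrt(einv)
        assert screen.units["nuclear_area_mean"].std(ddof=1) == \
            pytest.approx(expected, rel=0.15)

    def test_determinism(self, small_screen_config):
        a = generate_screen(small_screen_config)
        b = generate_screen(small_screen_config)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.units, b.units)

    def test_every_cell_maps_into_layout(self, small_screen):
        layout_positions = set(small_screen.layout.design_at)
        cell_positions = set(map(tuple,
                                 small_screen.cells[["row", "col"]].values))
        assert cell_positions <= layout_positions


class TestPlantArtifacts:
    def test_zero_rates_identity(self, small_screen):
        planted = plant_artifacts(small_screen, {}, seed=1)
        pd.testing.assert_frame_equal(planted.cells, small_screen.cells)
        assert planted.truth.empty

    def test_underpopulated_exact_count_single_chip(self):
        """floor(0.02 * 4356) = 87 units recorded and all below the band."""
        cfg = SyntheticScreenConfig(n_chips=1, high_density_chips=1,
                                    seed=13)
        screen = generate_screen(cfg)
        planted = plant_artifacts(screen, {"underpopulated": 0.02}, seed=5)
        under = planted.truth_units("underpopulated")
        assert len(under) == 87
        counts = planted.units.set_index(["chip_id", "row", "col"])
        for _, u in under.iterrows():
            assert counts.loc[(u["chip_id"], u["row"], u["col"]),
                              "cell_count"] < 11

    def test_replicate_shift_by_construction(self, small_screen):
        planted = plant_artifacts(small_screen,
                                  {"replicate_inconsistent": 0.05}, seed=5)
        reg = planted.truth_units("replicate_inconsistent")
        assert len(reg) > 0
        for design in reg["design_id"].unique():
            pos = planted.layout.positions_of(design)
            means = []
            for r, c in pos:
                sub = planted.cells[(planted.cells["row"] == r)
                                    & (planted.cells["col"] == c)]
                means.append(sub["nuclear_area"].mean())
            # one replicate shifted by 3 pooled SDs = 483
            assert abs(means[0] - means[1]) > 300

    def test_truth_registry_references_existing_units(self, small_screen):
        rates = {k: 0.02 for k in ("underpopulated", "out_of_focus",
                                   "ntoc_extreme")}
        planted = plant_artifacts(small_screen, rates, seed=5)
        unit_keys = set(map(tuple,
                            small_screen.units[["chip_id", "row",
                                                "col"]].values))
        for _, row in planted.truth.iterrows():
            assert (row["chip_id"], row["row"], row["col"]) in unit_keys

    def test_excessive_rate_rejected(self, small_screen):
        with pytest.raises(ValueError, match="0.5"):
            plant_artifacts(small_screen, {"underpopulated": 0.9}, seed=1)


class TestImages:
    def test_stitched_image_countable(self, small_layout):
        cells = pd.DataFrame({"row": [0, 0], "col": [0, 1],
                              "nuclear_area": [737.0, 737.0]})
        image, mask = generate_stitched_image(small_layout, 32, cells,
                                              seed=3)
        assert image.shape == (128, 128)
        assert mask.max() == 2
        assert len(np.unique(mask)) == 3  # background + 2 labels

    def test_empty_cells_only_walls(self, small_layout):
        image, mask = generate_stitched_image(small_layout, 32, None, seed=3)
        assert (mask == 0).all()
        assert image.max() == 20000  # wall intensity

    def test_out_of_grid_cells_rejected(self, small_layout):
        cells = pd.DataFrame({"row": [9], "col": [0],
                              "nuclear_area": [737.0]})
        with pytest.raises(ValueError, match="outside"):
            generate_stitched_image(small_layout, 32, cells, seed=3)

    def test_zstack_identity_and_protocol(self):
        base = np.arange(64, dtype=np.uint16).reshape(8, 8)
        stack = generate_zstack(base, 1, [0], seed=0, noise_sd=0)
        assert np.array_equal(stack[0], base)
        # 16 um range / 4 um step -> 5 planes
        stack5 = generate_zstack(base, 5, [4, 2, 0, 2, 4], seed=0)
        assert len(stack5) == 5
        assert np.array_equal(stack5[2], base)

    def test_zstack_validation(self):
        base = np.zeros((4, 4), dtype=np.uint16)
        with pytest.raises(ValueError, match="blur_profile"):
            generate_zstack(base, 3, [0, 1], seed=0)
        with pytest.raises(ValueError, match="non-negative"):
            generate_zstack(base, 2, [0, -1], seed=0)
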