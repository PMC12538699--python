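"""Synthetic TopoChip screen generator with planted artifacts.

Emulates the statistical structure of a 9-chip podocyte TopoChip screen so
that every downstream stage (tiling, feature aggregation, tiered QC,
replicate-consistency filtering, ranking) can be exercised offline:

* 66x66 units per chip, 2176 designs in duplicate plus 4 flat units;
* two chip density classes: 6 chips at 39 +/- 13 cells/unit, 3 at 15 +/- 11;
* single-cell nuclear area N(737, 161^2) decomposed into a between-unit
  component (SD sigma_b) and a within-unit component (SD sigma_w) so that the
  per-unit mean area has SD 65 at the mean cell count;
* cell-level feature correlations: r(DAPI, phalloidin) = 0.83 and
  r(solidity, peripheral actin fraction) = -0.87;
* per-design additive effects (nested inside the between-unit variance) so
  replicate units of one design share a real signal;
* plantable artifacts with a ground-truth registry: under/overpopulated
  units, out-of-focus units, NtoC-extreme units, inconsistent replicate pairs.

The generator also renders toy stitched chip images (ellipse nuclei on a
walled grid, flat units texture-free so the orientation landmark is
detectable) and synthetic z-stacks with a per-plane blur profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import aggregate_units
from .layout import FLAT, ChipLayout, build_layout

__all__ = [
    "SyntheticScreenConfig",
    "SyntheticScreen",
    "generate_screen",
    "plant_artifacts",
    "generate_stitched_image",
    "generate_zstack",
    "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = (
    "underpopulated",
    "overpopulated",
    "out_of_focus",
    "ntoc_extreme",
    "replicate_inconsistent",
)

TRUTH_COLUMNS = ["kind", "chip_id", "row", "col", "design_id", "detail"]


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Study conditions of the emulated screen (defaults = the real screen).

    ``unit_mean_sd`` is the SD of per-unit mean nuclear area; together with
    the single-cell SD ``nuc_area_sd_total`` it fixes the between/within-unit
    variance split (solved in :meth:`variance_components`).
    """

    n_chips: int = 9
    high_density_chips: int = 6
    count_mean_high: float = 39.0
    count_sd_high: float = 13.0
    count_mean_low: float = 15.0
    count_sd_low: float = 11.0
    n_designs: int = 2176
    n_rows: int = 66
    n_cols: int = 66
    flat_count: int = 4
    nuc_area_mean: float = 737.0
    nuc_area_sd_total: float = 161.0
    unit_mean_sd: float = 65.0
    r_dapi_phalloidin: float = 0.83
    r_solidity_peripheral: float = -0.87
    dapi_mean: float = 500.0
    dapi_sd: float = 100.0
    phalloidin_mean: float = 300.0
    phalloidin_sd: float = 80.0
    solidity_mean: float = 0.85
    solidity_sd: float = 0.05
    peripheral_mean: float = 0.30
    peripheral_sd: float = 0.08
    ntoc_log_mean: float = math.log(0.15)
    ntoc_log_sd: float = 0.25
    focus_mean: float = 1.0
    focus_sd: float = 0.05
    #: fraction of sigma_b^2 carried by the per-design effect (shared by
    #: replicate units of one design); the rest is unit-level noise.
    design_variance_fraction: float = 0.25
    border_flag_rate: float = 0.02
    wall_flag_rate: float = 0.02
    lognormal_tail_weight: float = 0.0
    artifact_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.high_density_chips <= self.n_chips):
            raise ValueError("high_density_chips must be in (0, n_chips]")
        for name in ("count_sd_high", "count_sd_low", "nuc_area_sd_total",
                     "unit_mean_sd", "dapi_sd", "phalloidin_sd",
                     "solidity_sd", "peripheral_sd", "focus_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("r_dapi_phalloidin", "r_solidity_peripheral"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if not 0 <= self.design_variance_fraction <= 1:
            raise ValueError("design_variance_fraction must lie in [0, 1]")
        if not 0 <= self.lognormal_tail_weight <= 1:
            raise ValueError("lognormal_tail_weight must lie in [0, 1]")
        for kind, rate in self.artifact_rates.items():
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")
            if not 0 <= rate <= 0.5:
                raise ValueError(f"artifact rate for {kind!r} must be in [0, 0.5]")
        self.variance_components()  # fail fast if unsatisfiable

    @property
    def mean_count(self) -> float:
        """Mixture mean cells/unit across the two chip density classes."""
        h, n = self.high_density_chips, self.n_chips
        return (h * self.count_mean_high
                + (n - h) * self.count_mean_low) / n

    def expected_inverse_count(self) -> float:
        """E[1/n] under the count model (class normals, rounded, floored
        at 1), mixed over the chip density classes.

        The per-unit mean of n cells has variance sigma_b^2 + sigma_w^2 / n,
        so across units the unit-mean variance involves E[1/n], not 1/n_bar;
        with a low-density chip class the two differ substantially.
        """
        from scipy.stats import norm

        total = 0.0
        n_low = self.n_chips - self.high_density_chips
        for weight, mean_c, sd_c in (
            (self.high_density_chips / self.n_chips,
             self.count_mean_high, self.count_sd_high),
            (n_low / self.n_chips, self.count_mean_low, self.count_sd_low),
        ):
            if weight == 0:
                continue
            hi = int(math.ceil(mean_c + 8 * sd_c))
            j = np.arange(1, hi + 1)
            upper = norm.cdf((j + 0.5 - mean_c) / sd_c)
            lower = norm.cdf((j - 0.5 - mean_c) / sd_c)
            p = upper - lower
            p[0] = upper[0]  # counts are floored at 1
            p = p / p.sum()
            total += weight * float(np.sum(p / j))
        return total

    def variance_components(self) -> tuple[float, float]:
        """Solve (sigma_b, sigma_w) from the variance decomposition.

        sigma_b^2 + sigma_w^2 = total^2 (single-cell variance) and
        sigma_b^2 + sigma_w^2 * E[1/n] = unit_mean_sd^2 (variance of the
        per-unit mean), with E[1/n] taken under the actual count model so a
        generated screen reproduces both target SDs.
        """
        total2 = self.nuc_area_sd_total**2
        unit2 = self.unit_mean_sd**2
        if self.mean_count <= 1:
            raise ValueError("mean cell count must exceed 1")
        einv = self.expected_inverse_count()
        sigma_w2 = (total2 - unit2) / (1.0 - einv)
        sigma_b2 = total2 - sigma_w2
        if sigma_w2 < 0 or sigma_b2 < 0:
            raise ValueError(
                "unsatisfiable variance decomposition: "
                f"sigma_b^2 = {sigma_b2:.2f}, sigma_w^2 = {sigma_w2:.2f} "
                f"(total SD {self.nuc_area_sd_total}, unit-mean SD "
                f"{self.unit_mean_sd}, E[1/n] = {einv:.4f})"
            )
        return math.sqrt(sigma_b2), math.sqrt(sigma_w2)

    def chip_ids(self) -> list:
        return [f"chip{i + 1}" for i in range(self.n_chips)]

    def low_density_chip_ids(self) -> set:
        """Low-density chips: the study's chips 4, 7 and 8 when the default
        9-chip/6-high configuration is used, otherwise the last chips."""
        ids = self.chip_ids()
        n_low = self.n_chips - self.high_density_chips
        if self.n_chips == 9 and n_low == 3:
            return {"chip4", "chip7", "chip8"}
        return set(ids[self.n_chips - n_low:])


@dataclass
class SyntheticScreen:
    """A generated screen: layout, cell table, unit table, truth registry."""

    config: SyntheticScreenConfig
    layout: ChipLayout
    cells: pd.DataFrame
    units: pd.DataFrame
    truth: pd.DataFrame

    def truth_units(self, kind: str) -> pd.DataFrame:
        return self.truth[self.truth["kind"] == kind]


def _correlated_pair(rng, n, mean1, sd1, mean2, sd2, r):
    """Bivariate normal draws with Pearson correlation r."""
    z = rng.standard_normal((2, n))
    x = mean1 + sd1 * z[0]
    y = mean2 + sd2 * (r * z[0] + math.sqrt(1 - r * r) * z[1])
    return x, y


def generate_screen(cfg: SyntheticScreenConfig | None = None,
                    layout: ChipLayout | None = None) -> SyntheticScreen:
    """Generate a full synthetic screen (deterministic under ``cfg.seed``)."""
    if cfg is None:
        cfg = SyntheticScreenConfig()
    if layout is None:
        layout = build_layout(cfg.n_designs, cfg.n_rows, cfg.n_cols,
                              cfg.flat_count, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    sigma_b, sigma_w = cfg.variance_components()
    sigma_design = math.sqrt(cfg.design_variance_fraction) * sigma_b
    sigma_unit = math.sqrt(max(sigma_b**2 - sigma_design**2, 0.0))

    # per-design additive effects shared by replicate units (flat gets 0)
    design_ids = layout.design_ids
    area_offset = dict(zip(design_ids,
                           rng.normal(0, sigma_design, len(design_ids))))
    area_offset[FLAT] = 0.0
    sigma_count_design = min(cfg.count_sd_high, cfg.count_sd_low) / 2.0
    count_offset = dict(zip(design_ids,
                            rng.normal(0, sigma_count_design,
                                       len(design_ids))))
    count_offset[FLAT] = 0.0
    resid_high = math.sqrt(cfg.count_sd_high**2 - sigma_count_design**2)
    resid_low = math.sqrt(cfg.count_sd_low**2 - sigma_count_design**2)

    positions = sorted(layout.design_at)
    unit_design = np.array([layout.design_at[p] for p in positions])
    unit_rows = np.array([p[0] for p in positions])
    unit_cols = np.array([p[1] for p in positions])
    unit_area_off = np.array([area_offset[d] for d in unit_design])
    unit_count_off = np.array([count_offset[d] for d in unit_design])
    n_units = len(positions)

    low_ids = cfg.low_density_chip_ids()
    chip_frames = []
    for chip_id in cfg.chip_ids():
        low = chip_id in low_ids
        mean_c = cfg.count_mean_low if low else cfg.count_mean_high
        resid = resid_low if low else resid_high
        counts = np.rint(
            rng.normal(mean_c + unit_count_off, resid)
        ).astype(int)
        counts = np.maximum(counts, 1)
        n_cells = int(counts.sum())

        unit_idx = np.repeat(np.arange(n_units), counts)
        b_unit = rng.normal(0, sigma_unit, n_units)
        area = (cfg.nuc_area_mean
                + unit_area_off[unit_idx]
                + b_unit[unit_idx]
                + rng.normal(0, sigma_w, n_cells))
        if cfg.lognormal_tail_weight > 0:
            tail = rng.random(n_cells) < cfg.lognormal_tail_weight
            area[tail] = cfg.nuc_area_mean * rng.lognormal(
                0.0, 0.4, int(tail.sum()))
        area = np.maximum(area, 1.0)

        dapi, phal = _correlated_pair(
            rng, n_cells, cfg.dapi_mean, cfg.dapi_sd,
            cfg.phalloidin_mean, cfg.phalloidin_sd, cfg.r_dapi_phalloidin)
        dapi = np.maximum(dapi, 1.0)
        phal = np.maximum(phal, 1.0)
        solidity, peripheral = _correlated_pair(
            rng, n_cells, cfg.solidity_mean, cfg.solidity_sd,
            cfg.peripheral_mean, cfg.peripheral_sd,
            cfg.r_solidity_peripheral)
        solidity = np.clip(solidity, 1e-6, 1.0)
        peripheral = np.clip(peripheral, 0.0, 1.0)

        ntoc = rng.lognormal(cfg.ntoc_log_mean, cfg.ntoc_log_sd, n_cells)
        cell_area = area * (1.0 + 1.0 / ntoc)
        nuc_ff = np.clip(rng.normal(0.85, 0.05, n_cells), 0.2, 0.999)
        nuc_perim = np.sqrt(4 * np.pi * area / nuc_ff)
        cell_ff = np.clip(rng.normal(0.55, 0.12, n_cells), 0.1, 0.999)
        cell_perim = np.sqrt(4 * np.pi * cell_area / cell_ff)

        unit_focus = rng.normal(cfg.focus_mean, cfg.focus_sd, n_units)
        focus = unit_focus[unit_idx] + rng.normal(0, 0.01, n_cells)

        chip_frames.append(pd.DataFrame({
            "chip_id": chip_id,
            "row": unit_rows[unit_idx],
            "col": unit_cols[unit_idx],
            "design_id": unit_design[unit_idx],
            "cell_id": np.arange(n_cells),
            "nuclear_area": area,
            "cell_area": cell_area,
            "nuclear_perimeter": nuc_perim,
            "cell_perimeter": cell_perim,
            "mean_dapi": dapi,
            "mean_phalloidin": phal,
            "solidity": solidity,
            "peripheral_actin_fraction": peripheral,
            "focus_score": focus,
            "touches_border": rng.random(n_cells) < cfg.border_flag_rate,
            "touches_wall": rng.random(n_cells) < cfg.wall_flag_rate,
            "nucleus_diameter": 2.0 * np.sqrt(area / np.pi),
        }))

    cells = pd.concat(chip_frames, ignore_index=True)
    cells["cell_id"] = (cells["chip_id"].astype(str) + "_c"
                        + cells["cell_id"].astype(str))
    units = aggregate_units(cells)
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    screen = SyntheticScreen(config=cfg, layout=layout, cells=cells,
                             units=units, truth=truth)
    if cfg.artifact_rates:
        screen = plant_artifacts(screen, cfg.artifact_rates,
                                 seed=cfg.seed + 1)
    return screen


def plant_artifacts(screen: SyntheticScreen, rates: dict | None = None,
                    seed: int = 0, *,
                    count_band: tuple = (11, 64),
                    focus_shift: float = 0.5,
                    replicate_shift_sds: float = 3.0) -> SyntheticScreen:
    """Corrupt selected units/designs and record them in the truth registry.

    Per unit-level kind, ``floor(rate * total_units)`` distinct non-flat,
    not-yet-corrupted units are drawn (so corruption is idempotent per unit
    and kinds never overlap); for ``replicate_inconsistent``,
    ``floor(rate * n_designs)`` designs have one replicate position shifted
    by ``replicate_shift_sds`` pooled SDs of nuclear area.
    """
    if rates is None:
        rates = screen.config.artifact_rates
    for kind, rate in rates.items():
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        if not 0 <= rate <= 0.5:
            raise ValueError(
                f"artifact rate for {kind!r} is {rate}; rates above 0.5 break "
                "the QC assumptions")
    if not any(rate > 0 for rate in rates.values()):
        return SyntheticScreen(config=screen.config, layout=screen.layout,
                               cells=screen.cells.copy(),
                               units=screen.units.copy(),
                               truth=screen.truth.copy())
    cfg = screen.config
    rng = np.random.default_rng(seed)
    cells = screen.cells.copy()
    truth_rows = [screen.truth] if len(screen.truth) else []

    total_units = cfg.n_chips * cfg.n_rows * cfg.n_cols
    unit_index = cells[["chip_id", "row", "col", "design_id"]].drop_duplicates()
    eligible = unit_index[unit_index["design_id"] != FLAT]
    already = screen.truth
    if len(already):
        key = eligible["chip_id"].astype(str) + "|" + eligible["row"].astype(str) + "|" + eligible["col"].astype(str)
        done = set(already["chip_id"].astype(str) + "|" + already["row"].astype(str) + "|" + already["col"].astype(str))
        eligible = eligible[~key.isin(done)]
    pool = eligible.reset_index(drop=True)
    pool_order = rng.permutation(len(pool))
    pool = pool.iloc[pool_order].reset_index(drop=True)
    cursor = 0

    def take_units(n):
        nonlocal cursor
        sel = pool.iloc[cursor:cursor + n]
        cursor += n
        if len(sel) < n:
            raise ValueError("not enough uncorrupted units to plant artifacts")
        return sel

    cells.set_index(pd.MultiIndex.from_frame(cells[["chip_id", "row", "col"]]),
                    inplace=True)
    cells.sort_index(inplace=True)

    drop_rows = []
    extra_frames = []

    def unit_mask(u):
        return (u["chip_id"], u["row"], u["col"])

    for kind in ("underpopulated", "overpopulated", "out_of_focus",
                 "ntoc_extreme"):
        rate = rates.get(kind, 0.0)
        n_sel = int(math.floor(rate * total_units))
        if n_sel == 0:
            continue
        selected = take_units(n_sel)
        for i, (_, u) in enumerate(selected.iterrows()):
            key = unit_mask(u)
            block = cells.loc[[key]]
            detail = ""
            if kind == "underpopulated":
                target = int(rng.integers(1, max(2, count_band[0] - 1)))
                ids = block["cell_id"].to_numpy()
                drop_ids = ids[target:]
                drop_rows.append((key, set(drop_ids)))
                detail = f"count={target}"
            elif kind == "overpopulated":
                target = int(rng.integers(count_band[1] + 1,
                                          count_band[1] + 60))
                n_extra = max(target - len(block), 1)
                picks = block.sample(n=n_extra, replace=True,
                                     random_state=int(rng.integers(2**31)))
                picks = picks.copy()
                picks["cell_id"] = [
                    f"{cid}_dup{j}" for j, cid in enumerate(picks["cell_id"])]
                extra_frames.append(picks)
                detail = f"count={len(block) + n_extra}"
            elif kind == "out_of_focus":
                cells.loc[[key], "focus_score"] -= focus_shift
                detail = f"focus_shift={focus_shift}"
            elif kind == "ntoc_extreme":
                if i % 2 == 0:  # high-NtoC tail: cytoplasm barely > nucleus
                    cells.loc[[key], "cell_area"] = (
                        cells.loc[[key], "nuclear_area"] * 1.2)
                    detail = "ntoc=high"
                else:  # low-NtoC tail: cytoplasm vastly dominates
                    cells.loc[[key], "cell_area"] = (
                        cells.loc[[key], "nuclear_area"] * 150.0)
                    detail = "ntoc=low"
            truth_rows.append(pd.DataFrame([{
                "kind": kind, "chip_id": u["chip_id"], "row": u["row"],
                "col": u["col"], "design_id": u["design_id"],
                "detail": detail}]))

    # replicate inconsistency: shift one replicate position of chosen designs
    rate = rates.get("replicate_inconsistent", 0.0)
    if rate > 0:
        layout = screen.layout
        shift = replicate_shift_sds * cfg.nuc_area_sd_total
        corrupted_designs = set(screen.truth.get("design_id", pd.Series([])))
        corrupted_designs |= set(pool.iloc[:cursor]["design_id"])
        candidates = [d for d in layout.design_ids
                      if d not in corrupted_designs]
        n_sel = int(math.floor(rate * layout.n_designs))
        picks = rng.choice(len(candidates), size=min(n_sel, len(candidates)),
                           replace=False)
        for idx in picks:
            did = candidates[idx]
            pos = layout.positions_of(did)
            r, c = pos[int(rng.integers(len(pos)))]
            mask = (cells["design_id"] == did) & (cells["row"] == r) \
                & (cells["col"] == c)
            cells.loc[mask, "nuclear_area"] += shift
            cells.loc[mask, "nucleus_diameter"] = 2.0 * np.sqrt(
                cells.loc[mask, "nuclear_area"] / np.pi)
            for chip_id in cells.loc[mask, "chip_id"].unique():
                truth_rows.append(pd.DataFrame([{
                    "kind": "replicate_inconsistent", "chip_id": chip_id,
                    "row": r, "col": c, "design_id": did,
                    "detail": f"area_shift={shift:.1f}"}]))

    cells = cells.reset_index(drop=True)
    for key, drop_ids in drop_rows:
        chip, r, c = key
        mask = ((cells["chip_id"] == chip) & (cells["row"] == r)
                & (cells["col"] == c) & cells["cell_id"].isin(drop_ids))
        cells = cells[~mask]
    if extra_frames:
        cells = pd.concat([cells] + [f.reset_index(drop=True)
                                     for f in extra_frames],
                          ignore_index=True)
    cells = cells.sort_values(["chip_id", "row", "col", "cell_id"],
                              kind="mergesort").reset_index(drop=True)
    truth = (pd.concat(truth_rows, ignore_index=True)
             if truth_rows else pd.DataFrame(columns=TRUTH_COLUMNS))
    units = aggregate_units(cells)
    return SyntheticScreen(config=cfg, layout=screen.layout, cells=cells,
                           units=units, truth=truth)


# ---------------------------------------------------------------------------
# toy images
# ---------------------------------------------------------------------------

def generate_stitched_image(layout: ChipLayout, px_per_unit: int,
                            cells: pd.DataFrame | None = None,
                            seed: int = 0):
    """Render a grayscale stitched-chip image and its ground-truth label mask.

    Walls between units are drawn as bright 1-px borders; non-flat units get
    a faint periodic pillar texture (flat units stay texture-free, making the
    lower-right flat block detectable as the orientation landmark); each cell
    becomes an ellipse "nucleus" at a seeded random position inside its unit.

    Returns ``(image, mask)``: ``image`` is uint16 of shape
    ``(n_rows * px_per_unit, n_cols * px_per_unit)``; ``mask`` is int32 with
    one positive label per cell.
    """
    from skimage.draw import ellipse as draw_ellipse

    if px_per_unit < 16:
        raise ValueError("px_per_unit must be >= 16")
    rng = np.random.default_rng(seed)
    h = layout.n_rows * px_per_unit
    w = layout.n_cols * px_per_unit
    image = np.full((h, w), 100, dtype=np.uint16)
    mask = np.zeros((h, w), dtype=np.int32)

    # walls
    for r in range(layout.n_rows + 1):
        y = min(r * px_per_unit, h - 1)
        image[y, :] = 20000
    for c in range(layout.n_cols + 1):
        x = min(c * px_per_unit, w - 1)
        image[:, x] = 20000

    # pillar texture in non-flat units
    period = max(4, px_per_unit // 6)
    for (r, c), did in layout.design_at.items():
        if did == FLAT:
            continue
        y0, x0 = r * px_per_unit, c * px_per_unit
        sub = image[y0 + 2:y0 + px_per_unit - 2:period,
                    x0 + 2:x0 + px_per_unit - 2:period]
        sub += 3000

    if cells is not None and len(cells):
        for col in ("row", "col"):
            bad = ~cells[col].between(0, getattr(
                layout, "n_rows" if col == "row" else "n_cols") - 1)
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} cells reference {col} values outside "
                    "the layout grid")
        label = 0
        margin = max(3, px_per_unit // 8)
        for _, cell in cells.iterrows():
            label += 1
            r, c = int(cell["row"]), int(cell["col"])
            cy = r * px_per_unit + rng.integers(margin, px_per_unit - margin)
            cx = c * px_per_unit + rng.integers(margin, px_per_unit - margin)
            r_eq = math.sqrt(float(cell.get("nuclear_area", 737.0)) / math.pi)
            r_px = max(1.0, r_eq * px_per_unit / 128.0)
            rr, cc = draw_ellipse(cy, cx, r_px * 1.2, r_px / 1.2,
                                  shape=image.shape,
                                  rotation=float(rng.uniform(0, np.pi)))
            image[rr, cc] = 30000
            mask[rr, cc] = label
    return image, mask


def generate_zstack(base: np.ndarray, n_planes: int, blur_profile,
                    seed: int = 0, noise_sd: float = 0.0) -> list:
    """Synthesize a z-stack: plane i = base blurred by ``blur_profile[i]``
    plus seeded Gaussian noise. A blur radius of 0 reproduces the base plane
    exactly (the in-focus plane) when ``noise_sd`` is 0.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    blur_profile = list(blur_profile)
    if len(blur_profile) != n_planes:
        raise ValueError(
            f"blur_profile has {len(blur_profile)} radii for {n_planes} planes")
    if any(b < 0 for b in blur_profile):
        raise ValueError("blur radii must be non-negative")
    rng = np.random.default_rng(seed)
    info = np.iinfo(base.dtype) if np.issubdtype(base.dtype, np.integer) \
        else None
    planes = []
    for blur in blur_profile:
        plane = base.astype(float)
        if blur > 0:
            plane = gaussian_filter(plane, sigma=blur)
        if noise_sd > 0:
            plane = plane + rng.normal(0, noise_sd, plane.shape)
        if info is not None:
            plane = np.clip(np.rint(plane), info.min, info.max)
        planes.append(plane.astype(base.dtype))
    return planes
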