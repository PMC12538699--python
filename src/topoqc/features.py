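"""Derived per-cell features and per-TopoUnit aggregates.

The per-cell derived quantities used for QC and profiling:

* form factor ``4*pi*A / P**2`` (1 for a circle, lower for irregular shapes);
* nucleus-to-cytoplasm area ratio NtoC ``A_nuc / (A_cell - A_nuc)``
  (1 when nucleus and cytoplasm occupy equal areas; the invalid sentinel
  ``nan`` marks mis-segmentations with ``A_cell <= A_nuc``);
* peripheral actin fraction: share of phalloidin signal in the outermost of
  four radial shells.

Unit-level aggregation produces one summary row per (chip, row, col) with
cell count and per-feature mean/SD (n-1 denominator), plus coefficient-of-
variation curves across units grouped by shared cell count — the basis for
choosing the stable cell-count band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NTOC_INVALID",
    "form_factor",
    "nto_c",
    "radial_fraction",
    "aggregate_units",
    "cv_by_count",
    "CVCurve",
    "UNIT_KEY",
    "DEFAULT_UNIT_FEATURES",
]

#: Sentinel for NtoC of a mis-segmented cell (cell area <= nuclear area).
NTOC_INVALID = float("nan")

#: Columns identifying one TopoUnit.
UNIT_KEY = ["chip_id", "row", "col"]

#: Cell-level features aggregated into unit summaries by default.
DEFAULT_UNIT_FEATURES = (
    "nuclear_area",
    "cell_area",
    "mean_dapi",
    "mean_phalloidin",
    "solidity",
    "peripheral_actin_fraction",
    "focus_score",
    "ntoc",
    "form_factor",
)


def form_factor(area, perimeter):
    """Circularity ``4*pi*A / P**2``; exactly 1 for an ideal circle.

    Accepts scalars or arrays. On rasterized masks the value can exceed 1
    (digitization shortens the measured perimeter); such values are returned
    as computed, not clamped.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("form_factor requires area > 0 and perimeter > 0")
    out = 4.0 * np.pi * area / perimeter**2
    return float(out) if out.ndim == 0 else out


def nto_c(nuclear_area, cell_area):
    """Nucleus-to-cytoplasm area ratio ``A_nuc / (A_cell - A_nuc)``.

    Returns the ``nan`` sentinel (never raises) where ``cell_area <=
    nuclear_area`` — exactly the mis-segmentations the NtoC filter targets.
    Both areas must be positive.
    """
    nuc = np.asarray(nuclear_area, dtype=float)
    cell = np.asarray(cell_area, dtype=float)
    if np.any(nuc <= 0) or np.any(cell <= 0):
        raise ValueError("nto_c requires positive areas")
    cyto = cell - nuc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(cyto > 0, nuc / np.where(cyto > 0, cyto, 1.0),
                       NTOC_INVALID)
    return float(out) if out.ndim == 0 else out


def radial_fraction(radial_bin_intensities):
    """Fraction of signal in the outermost of 4 radial bins (the 4/4 bin).

    ``radial_bin_intensities`` is a length-4 sequence of non-negative totals
    ordered inner to outer, or an (n, 4) array. All-zero bins yield the
    ``nan`` sentinel.
    """
    bins = np.asarray(radial_bin_intensities, dtype=float)
    if bins.shape[-1] != 4:
        raise ValueError("expected 4 radial bins")
    if np.any(bins < 0):
        raise ValueError("radial bin intensities must be non-negative")
    total = bins.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, bins[..., 3] / np.where(total > 0, total, 1.0),
                       np.nan)
    return float(out) if np.ndim(out) == 0 else out


def aggregate_units(cells: pd.DataFrame, features=None) -> pd.DataFrame:
    """Aggregate a cell table into one summary row per TopoUnit.

    Returns a DataFrame with the unit key, ``design_id``, ``cell_count``,
    ``<feature>_mean`` / ``<feature>_sd`` per aggregated feature (SD with the
    n-1 denominator, NaN-flagged when fewer than 2 contributing cells), and
    ``<feature>_n_excluded`` counting sentinel values left out of the mean.
    ``mean_ntoc``, ``mean_form_factor`` and ``mean_focus`` aliases are added
    for the QC tiers.

    Conservation: ``cell_count`` sums to the number of input rows carrying a
    valid unit key; rows with missing keys are dropped and reported in the
    ``attrs['n_dropped_no_key']`` attribute.
    """
    if features is None:
        derivable = {
            "ntoc": {"nuclear_area", "cell_area"},
            "form_factor": {"nuclear_area", "nuclear_perimeter"},
        }
        features = [
            f for f in DEFAULT_UNIT_FEATURES
            if f in cells.columns
            or derivable.get(f, {None}) <= set(cells.columns)
        ]
    if cells.empty:
        out = pd.DataFrame(columns=UNIT_KEY + ["design_id", "cell_count"])
        out.attrs["n_dropped_no_key"] = 0
        return out
    missing = [k for k in UNIT_KEY if k not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing unit-key columns {missing}")

    valid = cells.dropna(subset=UNIT_KEY)
    n_dropped = len(cells) - len(valid)

    work = valid.copy()
    if "ntoc" in features and "ntoc" not in work.columns:
        work["ntoc"] = nto_c(work["nuclear_area"], work["cell_area"])
    if "form_factor" in features and "form_factor" not in work.columns:
        work["form_factor"] = form_factor(work["nuclear_area"],
                                          work["nuclear_perimeter"])

    grouped = work.groupby(UNIT_KEY, sort=True)
    out = grouped.size().rename("cell_count").reset_index()
    if "design_id" in work.columns:
        out = out.merge(
            grouped["design_id"].first().reset_index(), on=UNIT_KEY
        )
    for feat in features:
        out[f"{feat}_mean"] = grouped[feat].mean().to_numpy()
        out[f"{feat}_sd"] = grouped[feat].std(ddof=1).to_numpy()
        na = work[feat].isna()
        out[f"{feat}_n_excluded"] = (
            na.groupby([work[k] for k in UNIT_KEY], sort=True).sum().to_numpy()
        )
    # aliases used by the unit-level QC tiers
    if "ntoc_mean" in out.columns:
        out["mean_ntoc"] = out["ntoc_mean"]
    if "form_factor_mean" in out.columns:
        out["mean_form_factor"] = out["form_factor_mean"]
    if "focus_score_mean" in out.columns:
        out["mean_focus"] = out["focus_score_mean"]
    out.attrs["n_dropped_no_key"] = int(n_dropped)
    return out


@dataclass
class CVCurve:
    """Coefficient of variation of a unit-level feature per cell-count bin."""

    feature: str
    table: pd.DataFrame  # columns: cell_count, n_units, cv

    @property
    def counts(self) -> np.ndarray:
        return self.table["cell_count"].to_numpy()

    @property
    def cv(self) -> np.ndarray:
        return self.table["cv"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "feature", self.feature)
        out.to_csv(path, index=False)


def cv_by_count(units: pd.DataFrame, feature: str,
                min_units: int = 5) -> CVCurve:
    """CV (SD/mean, n-1 denominator) of ``feature`` across units that share
    the same cell count, for counts represented by at least ``min_units``
    units. Bins whose mean is 0 are flagged and excluded.
    """
    col = feature if feature in units.columns else f"{feature}_mean"
    if col not in units.columns:
        raise ValueError(f"feature {feature!r} not present in unit summaries")
    rows = []
    for count, grp in units.groupby("cell_count"):
        vals = grp[col].dropna()
        if len(vals) < min_units:
            continue
        mean = vals.mean()
        if mean == 0:
            continue  # flagged: CV undefined at zero mean
        rows.append({
            "cell_count": int(count),
            "n_units": int(len(vals)),
            "cv": float(vals.std(ddof=1) / abs(mean)),
        })
    return CVCurve(feature=feature,
                   table=pd.DataFrame(rows, columns=["cell_count", "n_units",
                                                     "cv"]))
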