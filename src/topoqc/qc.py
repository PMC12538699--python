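"""Three-tier quality control with full ledger accounting.

Tier 1 (object level): nucleus-diameter band, image-border contact, and the
wall-contact linkage rule (a discarded secondary removes its primary).

Tier 2 (unit level, counts): either IQR bounds on cell count / focus score,
or the cell-count stability band (default 11-64 cells/unit, derivable from
coefficient-of-variation curves).

Tier 3 (unit level, NtoC): percentile bounds (default 2.5th / 97.5th) on the
per-unit mean nucleus-to-cytoplasm ratio.

Unit-level filters follow the sklearn fit/transform contract: ``fit`` freezes
thresholds on the supplied distribution, ``transform`` applies them — so
re-applying a fitted filter to its own output never cascades removals. The
:class:`QCLedger` chains image/object counts across tiers with exact
conservation at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import CVCurve

__all__ = [
    "filter_objects",
    "IQRBounds",
    "iqr_bounds",
    "CountBand",
    "select_count_band",
    "count_band_filter",
    "ntoc_percentile_filter",
    "ObjectFilter",
    "IQRUnitFilter",
    "CountBandFilter",
    "NtoCPercentileFilter",
    "QCLedger",
    "build_ledger",
    "feature_matrix_entries",
]


# ---------------------------------------------------------------------------
# tier 1: object-level filters
# ---------------------------------------------------------------------------

class ObjectFilter(BaseEstimator):
    """Object-level exclusion rules applied to a cell table.

    Removes cells whose nucleus diameter falls outside ``[diam_min,
    diam_max]`` (inclusive), cells touching the image border, and cells whose
    cell body touches a TopoUnit wall (the linkage rule: wall contact of the
    secondary object removes the whole cell record). Stateless: ``fit`` is a
    no-op kept for pipeline compatibility.
    """

    def __init__(self, diam_min: float = 15.0, diam_max: float = 65.0):
        self.diam_min = diam_min
        self.diam_max = diam_max

    def fit(self, cells: pd.DataFrame, y=None):
        if self.diam_min >= self.diam_max:
            raise ValueError("diam_min must be < diam_max")
        self.n_features_in_ = cells.shape[1]
        return self

    def transform(self, cells: pd.DataFrame) -> pd.DataFrame:
        retained, self.removal_log_ = filter_objects(
            cells, self.diam_min, self.diam_max)
        return retained

    def fit_transform(self, cells: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(cells).transform(cells)


def filter_objects(cells: pd.DataFrame, diam_min: float = 15.0,
                   diam_max: float = 65.0):
    """Apply the object-level exclusion rules.

    Returns ``(retained, removal_log)`` where the log has one row per
    removed cell naming its first failing rule (checked in order:
    diameter, border-contact, wall-contact).
    """
    if diam_min >= diam_max:
        raise ValueError("diam_min must be < diam_max")
    if cells.empty:
        return cells, pd.DataFrame(columns=list(cells.columns) + ["rule"])
    diam_bad = ~cells["nucleus_diameter"].between(diam_min, diam_max)
    border_bad = cells["touches_border"].astype(bool)
    wall_bad = cells["touches_wall"].astype(bool)
    rule = np.select(
        [diam_bad, border_bad, wall_bad],
        ["diameter", "border-contact", "wall-contact"],
        default="",
    )
    removed = rule != ""
    log = cells.loc[removed, ["chip_id", "row", "col", "cell_id"]].copy() \
        if {"chip_id", "row", "col", "cell_id"} <= set(cells.columns) \
        else cells.loc[removed].copy()
    log["rule"] = rule[removed]
    return cells.loc[~removed].copy(), log


# ---------------------------------------------------------------------------
# tier 2: unit-level count filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IQRBounds:
    """Tukey-style acceptance bounds ``[q1 - k*iqr, q3 + k*iqr]``."""

    q1: float
    q3: float
    k: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - self.k * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + self.k * self.iqr

    def contains(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


def iqr_bounds(values, k: float = 1.5) -> IQRBounds:
    """Quartiles by linear interpolation (the common 'type 7' rule)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError(f"need at least 4 values for IQR bounds, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])  # numpy default = linear / type 7
    return IQRBounds(q1=float(q1), q3=float(q3), k=float(k))


class IQRUnitFilter(BaseEstimator):
    """Unit-level IQR outlier filter on one or more summary columns.

    ``fit`` freezes per-column :class:`IQRBounds` on the supplied unit table;
    ``transform`` retains units inside every column's bounds. The curation
    configuration of the screen applied this to cell count and focus score.
    """

    def __init__(self, columns=("cell_count", "mean_focus"), k: float = 1.5):
        self.columns = columns
        self.k = k

    def fit(self, units: pd.DataFrame, y=None):
        self.bounds_ = {
            col: iqr_bounds(units[col], k=self.k) for col in self.columns
        }
        return self

    def transform(self, units: pd.DataFrame) -> pd.DataFrame:
        keep = np.ones(len(units), dtype=bool)
        rules = np.full(len(units), "", dtype=object)
        for col, b in self.bounds_.items():
            bad = ~b.contains(units[col]) & (rules == "")
            rules[bad.to_numpy() if hasattr(bad, "to_numpy") else bad] = col
            keep &= b.contains(units[col])
        self.removed_ = units.loc[~keep].copy()
        self.removed_["rule"] = rules[~keep]
        return units.loc[keep].copy()

    def fit_transform(self, units: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(units).transform(units)


@dataclass(frozen=True)
class CountBand:
    """Inclusive cell-count acceptance band for TopoUnits."""

    lower: int
    upper: int
    provenance: str = "fixed"  # or "derived_from_cv"

    def __post_init__(self):
        if not 1 <= self.lower <= self.upper:
            raise ValueError(
                f"invalid count band ({self.lower}, {self.upper}): "
                "need 1 <= lower <= upper")


DEFAULT_COUNT_BAND = CountBand(11, 64, provenance="fixed")


def select_count_band(curves, cv_ceiling: float = 1.5,
                      fallback: CountBand = DEFAULT_COUNT_BAND) -> CountBand:
    """Derive the stable cell-count band from CV-vs-count curves.

    A count qualifies when every curve observed at that count has
    ``cv <= cv_ceiling * (that curve's minimum cv)``. The band is the
    contiguous integer interval, free of violating counts and bounded by
    qualifying observed counts, that contains the most qualifying counts.
    If no count qualifies, the fixed default band is returned (with a
    ``fixed`` provenance) — the screen's empirical 11-64 range.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one CV curve")
    if cv_ceiling <= 0:
        raise ValueError("cv_ceiling must be > 0")
    good: dict[int, bool] = {}
    for curve in curves:
        table = curve.table if isinstance(curve, CVCurve) else curve
        if not len(table):
            continue
        floor = table["cv"].min()
        for count, cv in zip(table["cell_count"], table["cv"]):
            ok = cv <= cv_ceiling * floor
            good[int(count)] = good.get(int(count), True) and bool(ok)
    qualifying = sorted(c for c, ok in good.items() if ok)
    if not qualifying:
        return CountBand(fallback.lower, fallback.upper, provenance="fixed")
    bad = sorted(c for c, ok in good.items() if not ok)
    # maximal contiguous runs between violating counts
    best = None
    for start in qualifying:
        for end in qualifying:
            if end < start:
                continue
            if any(start <= b <= end for b in bad):
                continue
            n_inside = sum(1 for q in qualifying if start <= q <= end)
            key = (n_inside, -start)
            if best is None or key > best[0]:
                best = (key, (start, end))
    start, end = best[1]
    return CountBand(start, end, provenance="derived_from_cv")


class CountBandFilter(BaseEstimator):
    """Retain units with ``lower <= cell_count <= upper``.

    With ``band=None`` and CV curves passed to ``fit``, the band is derived
    from the curves; otherwise the configured fixed band is frozen at fit.
    """

    def __init__(self, band: CountBand | None = None, lower: int = 11,
                 upper: int = 64, cv_ceiling: float = 1.5):
        self.band = band
        self.lower = lower
        self.upper = upper
        self.cv_ceiling = cv_ceiling

    def fit(self, units: pd.DataFrame, y=None, curves=None):
        if self.band is not None:
            self.band_ = self.band
        elif curves is not None:
            self.band_ = select_count_band(curves, self.cv_ceiling)
        else:
            self.band_ = CountBand(self.lower, self.upper)
        return self

    def transform(self, units: pd.DataFrame) -> pd.DataFrame:
        keep = units["cell_count"].between(self.band_.lower, self.band_.upper)
        self.removed_ = units.loc[~keep].copy()
        self.removed_["rule"] = np.where(
            self.removed_["cell_count"] < self.band_.lower,
            "count-low", "count-high")
        return units.loc[keep].copy()

    def fit_transform(self, units: pd.DataFrame, y=None, curves=None):
        return self.fit(units, curves=curves).transform(units)


def count_band_filter(units: pd.DataFrame,
                      band: CountBand = DEFAULT_COUNT_BAND):
    """Functional form: returns ``(retained, removed, tier_record)``.

    The tier record counts removed images (units) and the objects they carry.
    """
    f = CountBandFilter(band=band).fit(units)
    retained = f.transform(units)
    removed = f.removed_
    tier = TierRecord(
        name=f"count_band[{band.lower},{band.upper}]",
        images_removed=int(len(removed)),
        objects_removed=int(removed["cell_count"].sum()),
    )
    return retained, removed, tier


# ---------------------------------------------------------------------------
# tier 3: NtoC percentile filter
# ---------------------------------------------------------------------------

class NtoCPercentileFilter(BaseEstimator):
    """Percentile filter on per-unit mean NtoC.

    ``fit`` freezes the ``p_low``/``p_high`` percentile thresholds (linear
    interpolation) of the valid ``mean_ntoc`` distribution; ``transform``
    removes units strictly outside them. Units whose mean NtoC is the
    invalid sentinel (NaN) are always removed and counted separately in
    ``n_invalid_``.
    """

    def __init__(self, p_low: float = 2.5, p_high: float = 97.5):
        self.p_low = p_low
        self.p_high = p_high

    def fit(self, units: pd.DataFrame, y=None):
        if not 0 <= self.p_low < self.p_high <= 100:
            raise ValueError("need 0 <= p_low < p_high <= 100")
        vals = units["mean_ntoc"].to_numpy(dtype=float)
        valid = vals[np.isfinite(vals)]
        if valid.size == 0:
            raise ValueError("all unit NtoC values are invalid; cannot fit "
                             "percentile thresholds")
        self.threshold_low_, self.threshold_high_ = (
            float(t) for t in np.percentile(valid, [self.p_low, self.p_high]))
        return self

    def transform(self, units: pd.DataFrame) -> pd.DataFrame:
        vals = units["mean_ntoc"].to_numpy(dtype=float)
        invalid = ~np.isfinite(vals)
        outside = (vals < self.threshold_low_) | (vals > self.threshold_high_)
        remove = invalid | outside
        self.n_invalid_ = int(invalid.sum())
        self.removed_ = units.loc[remove].copy()
        self.removed_["rule"] = np.where(
            invalid[remove], "ntoc-invalid",
            np.where(vals[remove] < self.threshold_low_, "ntoc-low",
                     "ntoc-high"))
        return units.loc[~remove].copy()

    def fit_transform(self, units: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(units).transform(units)


def ntoc_percentile_filter(units: pd.DataFrame, p_low: float = 2.5,
                           p_high: float = 97.5):
    """Functional form: returns ``(retained, removed, tier_record)``."""
    f = NtoCPercentileFilter(p_low=p_low, p_high=p_high).fit(units)
    retained = f.transform(units)
    removed = f.removed_
    tier = TierRecord(
        name=f"ntoc_percentile[{p_low},{p_high}]",
        images_removed=int(len(removed)),
        objects_removed=int(removed["cell_count"].sum()),
    )
    return retained, removed, tier


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierRecord:
    """Removal counts of one QC tier."""

    name: str
    images_removed: int
    objects_removed: int


@dataclass
class QCLedger:
    """Chained image/object accounting across QC tiers.

    Conservation holds independently for images and objects at every tier:
    each tier's input minus its removals equals the next tier's input, and
    no running total may go negative.
    """

    images_in: int
    objects_in: int
    tiers: list = field(default_factory=list)

    def add_tier(self, name: str, images_removed: int, objects_removed: int):
        if images_removed < 0 or objects_removed < 0:
            raise ValueError("removal counts must be non-negative")
        img_left, obj_left = self.retained
        if images_removed > img_left or objects_removed > obj_left:
            raise ValueError(
                f"tier {name!r} removes ({images_removed} images, "
                f"{objects_removed} objects) but only ({img_left}, "
                f"{obj_left}) remain")
        self.tiers.append(TierRecord(name, int(images_removed),
                                     int(objects_removed)))
        return self

    @property
    def retained(self) -> tuple:
        img = self.images_in - sum(t.images_removed for t in self.tiers)
        obj = self.objects_in - sum(t.objects_removed for t in self.tiers)
        return img, obj

    @property
    def images_retained(self) -> int:
        return self.retained[0]

    @property
    def objects_retained(self) -> int:
        return self.retained[1]

    @property
    def total_removed(self) -> tuple:
        return (sum(t.images_removed for t in self.tiers),
                sum(t.objects_removed for t in self.tiers))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        img, obj = self.images_in, self.objects_in
        for t in self.tiers:
            rows.append({
                "tier": t.name,
                "images_in": img, "images_removed": t.images_removed,
                "images_out": img - t.images_removed,
                "objects_in": obj, "objects_removed": t.objects_removed,
                "objects_out": obj - t.objects_removed,
            })
            img -= t.images_removed
            obj -= t.objects_removed
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"QC ledger: {self.images_in} images, "
                 f"{self.objects_in} objects in"]
        img, obj = self.images_in, self.objects_in
        for t in self.tiers:
            img -= t.images_removed
            obj -= t.objects_removed
            lines.append(
                f"  - {t.name}: removed {t.images_removed} images / "
                f"{t.objects_removed} objects -> {img} / {obj} remain")
        lines.append(f"retained: {img} images, {obj} objects")
        return "\n".join(lines)

    def validate(self) -> None:
        img, obj = self.images_in, self.objects_in
        for t in self.tiers:
            img -= t.images_removed
            obj -= t.objects_removed
            if img < 0 or obj < 0:
                raise ValueError(
                    f"ledger conservation violated at tier {t.name!r}")


def build_ledger(tiers, images_in: int, objects_in: int) -> QCLedger:
    """Assemble a ledger from ordered ``(name, images_removed,
    objects_removed)`` records (or :class:`TierRecord` instances), validating
    conservation as each tier is appended."""
    ledger = QCLedger(images_in=int(images_in), objects_in=int(objects_in))
    for t in tiers:
        if isinstance(t, TierRecord):
            ledger.add_tier(t.name, t.images_removed, t.objects_removed)
        else:
            name, ir, orr = t
            ledger.add_tier(name, ir, orr)
    return ledger


def feature_matrix_entries(n_cells: int, n_features: int) -> int:
    """Total entry count of the cells x features matrix (dataset accounting
    for provenance reports)."""
    if n_cells < 0 or n_features < 0:
        raise ValueError("counts must be non-negative")
    return int(n_cells) * int(n_features)
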