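"""Screen storage (CSV / HDF5), pipeline configuration, and orchestration.

A :class:`ScreenStore` bundles the cell table, unit table, design table,
chip layout, optional QC ledger and a provenance block (tool version, config
hash, seed). Both serializations are deterministic (stable row ordering) and
round-trip exactly; the HDF5 layout is columnar (one group per table) with a
schema-version attribute at the root.

:func:`run_pipeline` ties the stages together: synthesize -> object QC ->
unit aggregation -> count filter (band- or IQR-based) -> NtoC percentile
filter -> replicate-consistency filter -> ranking/split, writing tables,
ledgers, reports and a structured log into a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import aggregate_units
from .layout import ChipLayout, layout_from_frame, layout_to_frame, make_design_table
from .qc import (
    CountBand,
    IQRUnitFilter,
    NtoCPercentileFilter,
    ObjectFilter,
    QCLedger,
    count_band_filter,
    ntoc_percentile_filter,
)
from .ranking import RankConfig, SplitSpec, nested_split, rank_select
from .replicate import (
    DualReplicateFilter,
    removal_report,
    replicate_groups_from_cells,
)
from .synth import SyntheticScreenConfig, generate_screen

__all__ = [
    "SCHEMA_VERSION",
    "ScreenStore",
    "read_features",
    "write_features",
    "PipelineConfig",
    "run_pipeline",
]

SCHEMA_VERSION = "1"

REQUIRED_CELL_COLUMNS = [
    "chip_id", "row", "col", "design_id", "cell_id",
    "nuclear_area", "cell_area", "nucleus_diameter",
    "focus_score", "touches_border", "touches_wall",
]


@dataclass
class ScreenStore:
    """In-memory screen: tables + layout + ledger + provenance."""

    cells: pd.DataFrame
    units: pd.DataFrame
    designs: pd.DataFrame
    layout: ChipLayout
    ledger: QCLedger | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_CELL_COLUMNS
                   if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing required column(s): "
                             f"{', '.join(missing)}")
        if len(self.cells):
            cell_units = set(map(tuple,
                                 self.cells[["row", "col"]].values.tolist()))
            layout_units = set(self.layout.design_at)
            orphans = cell_units - layout_units
            if orphans:
                raise ValueError(
                    f"cells reference units outside the layout: "
                    f"{sorted(orphans)[:5]}")
            known = set(self.designs["design_id"].astype(str)) | {"FLAT"}
            bad = set(self.cells["design_id"].astype(str)) - known
            if bad:
                raise ValueError(
                    f"cells reference unknown designs: {sorted(bad)[:5]}")


def _canonical(frame: pd.DataFrame, kind: str) -> pd.DataFrame:
    order = {
        "cells": ["chip_id", "row", "col", "cell_id"],
        "units": ["chip_id", "row", "col"],
        "designs": ["design_id"],
    }[kind]
    cols = [c for c in order if c in frame.columns]
    if cols:
        frame = frame.sort_values(cols, kind="mergesort")
    return frame.reset_index(drop=True)


def _config_hash(provenance: dict) -> str:
    blob = json.dumps(provenance.get("config", {}), sort_keys=True,
                      default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(provenance: dict) -> dict:
    out = dict(provenance)
    out.setdefault("tool", "topoqc")
    out.setdefault("version", __version__)
    out.setdefault("schema_version", SCHEMA_VERSION)
    out["config_hash"] = _config_hash(out)
    return out


def write_features(store: ScreenStore, path, format: str = "csv") -> dict:
    """Serialize a screen deterministically; returns a manifest with row
    counts and the config hash."""
    store.validate()
    path = Path(path)
    provenance = _stamp(store.provenance)
    cells = _canonical(store.cells, "cells")
    units = _canonical(store.units, "units")
    designs = _canonical(store.designs, "designs")
    layout_frame = layout_to_frame(store.layout)

    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        cells.to_csv(path / "cells.csv", index=False)
        units.to_csv(path / "units.csv", index=False)
        designs.to_csv(path / "designs.csv", index=False)
        layout_frame.to_csv(path / "layout.csv", index=False)
        if store.ledger is not None:
            store.ledger.to_frame().to_csv(path / "ledger.csv", index=False)
        (path / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True,
                                               default=str)
            for name, frame in (("cells", cells), ("units", units),
                                ("designs", designs),
                                ("layout", layout_frame)):
                grp = f.create_group(name)
                for col in frame.columns:
                    values = frame[col].to_numpy()
                    if values.dtype == object or values.dtype.kind in "US":
                        grp.create_dataset(
                            col, data=values.astype(str).tolist(),
                            dtype=h5py.string_dtype("utf-8"))
                    else:
                        grp.create_dataset(col, data=values)
                grp.attrs["columns"] = json.dumps(list(frame.columns))
            if store.ledger is not None:
                lf = store.ledger.to_frame()
                grp = f.create_group("ledger")
                for col in lf.columns:
                    values = lf[col].to_numpy()
                    if values.dtype == object:
                        grp.create_dataset(
                            col, data=values.astype(str).tolist(),
                            dtype=h5py.string_dtype("utf-8"))
                    else:
                        grp.create_dataset(col, data=values)
                grp.attrs["columns"] = json.dumps(list(lf.columns))
                grp.attrs["images_in"] = store.ledger.images_in
                grp.attrs["objects_in"] = store.ledger.objects_in
    else:
        raise ValueError(f"unknown format {format!r}")
    return {
        "path": str(path),
        "format": format,
        "n_cells": len(cells),
        "n_units": len(units),
        "n_designs": len(designs),
        "config_hash": provenance["config_hash"],
    }


def _read_group(grp) -> pd.DataFrame:
    columns = json.loads(grp.attrs["columns"])
    data = {}
    for col in columns:
        values = grp[col][()]
        if values.dtype.kind in ("O", "S"):
            values = np.array([v.decode() if isinstance(v, bytes) else v
                               for v in values])
        data[col] = values
    return pd.DataFrame(data)


def read_features(path, format: str = "csv") -> ScreenStore:
    """Load a screen and validate referential integrity."""
    path = Path(path)
    if format == "csv":
        if not (path / "cells.csv").exists():
            raise FileNotFoundError(f"no cells.csv under {path}")
        cells = pd.read_csv(path / "cells.csv")
        units = pd.read_csv(path / "units.csv")
        designs = pd.read_csv(path / "designs.csv")
        layout = layout_from_frame(pd.read_csv(path / "layout.csv"))
        prov_file = path / "provenance.json"
        provenance = json.loads(prov_file.read_text()) \
            if prov_file.exists() else {}
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            cells = _read_group(f["cells"])
            units = _read_group(f["units"])
            designs = _read_group(f["designs"])
            layout = layout_from_frame(_read_group(f["layout"]))
            provenance = json.loads(f.attrs.get("provenance", "{}"))
    else:
        raise ValueError(f"unknown format {format!r}")
    store = ScreenStore(cells=cells, units=units, designs=designs,
                        layout=layout, provenance=provenance)
    store.validate()
    return store


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "out_dir", "format",
    "synthesis", "object_filter", "count_filter", "ntoc_filter",
    "replicate_filter", "ranking", "split",
}


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration."""

    seed: int = 0
    out_dir: str = "topoqc_run"
    format: str = "csv"
    synthesis: dict = field(default_factory=dict)
    object_filter: dict = field(default_factory=lambda: {
        "diam_min": 15.0, "diam_max": 65.0})
    count_filter: dict = field(default_factory=lambda: {
        "mode": "band", "lower": 11, "upper": 64, "k": 1.5})
    ntoc_filter: dict = field(default_factory=lambda: {
        "p_low": 2.5, "p_high": 97.5})
    replicate_filter: dict = field(default_factory=lambda: {
        "features": ["nuclear_area"], "ad_band": [0.05, 1.0],
        "snr_band": [2.0, 20.0], "mode": "cells"})
    ranking: dict = field(default_factory=lambda: {
        "readout": "cell_count", "n_extreme": 90})
    split: dict = field(default_factory=lambda: {
        "test_fraction": 0.2, "val_of_test_fraction": 0.2})

    def __post_init__(self):
        of = self.object_filter
        if of["diam_min"] >= of["diam_max"]:
            raise ValueError("object_filter: diam_min must be < diam_max")
        cf = self.count_filter
        if cf.get("mode", "band") not in ("band", "iqr"):
            raise ValueError("count_filter.mode must be 'band' or 'iqr'")
        if cf.get("mode", "band") == "band" and \
                not 1 <= cf["lower"] <= cf["upper"]:
            raise ValueError(
                f"count_filter band ({cf['lower']}, {cf['upper']}) invalid: "
                "need 1 <= lower <= upper")
        nf = self.ntoc_filter
        if not 0 <= nf["p_low"] < nf["p_high"] <= 100:
            raise ValueError("ntoc_filter percentiles must satisfy "
                             "0 <= p_low < p_high <= 100")
        rf = self.replicate_filter
        if not 0 <= rf["ad_band"][0] < rf["ad_band"][1] <= 1:
            raise ValueError("replicate_filter.ad_band must be within [0, 1]")
        if not 0 <= rf["snr_band"][0] < rf["snr_band"][1]:
            raise ValueError("replicate_filter.snr_band must be increasing")
        if self.format not in ("csv", "hdf5"):
            raise ValueError("format must be 'csv' or 'hdf5'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _log_setup(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger("topoqc.pipeline")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(stage)s %(message)s")
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    return logger


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir``.

    Stage order: synthesize -> object filter -> aggregate -> count filter ->
    NtoC filter -> replicate filter -> rank & split. Every stage appends a
    ledger tier; on a stage error, partial outputs are kept next to a
    ``FAILED`` marker naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = _log_setup(out_dir)

    def log(stage, msg):
        logger.info(msg, extra={"stage": stage})

    stage = "configure"
    try:
        synth_kwargs = dict(config.synthesis)
        synth_kwargs.setdefault("seed", config.seed)
        cfg = SyntheticScreenConfig(**synth_kwargs)

        stage = "synthesize"
        screen = generate_screen(cfg)
        log(stage, f"generated {len(screen.cells)} cells in "
                   f"{len(screen.units)} units (seed={cfg.seed})")

        images_in = len(screen.units)
        objects_in = len(screen.cells)
        ledger = QCLedger(images_in=images_in, objects_in=objects_in)

        stage = "object_filter"
        obj = ObjectFilter(**config.object_filter)
        cells = obj.fit_transform(screen.cells)
        removed_objects = objects_in - len(cells)
        ledger.add_tier("object_filters", 0, removed_objects)
        log(stage, f"removed {removed_objects} objects "
                   f"(diameter band + border/wall contact)")

        stage = "aggregate"
        units = aggregate_units(cells)
        empties = images_in - len(units)
        if empties:
            ledger.add_tier("emptied_units", empties, 0)
            log(stage, f"{empties} units emptied by object filters")

        stage = "count_filter"
        cf = config.count_filter
        if cf.get("mode", "band") == "band":
            band = CountBand(cf["lower"], cf["upper"])
            units_kept, removed, tier = count_band_filter(units, band)
            ledger.add_tier(tier.name, tier.images_removed,
                            tier.objects_removed)
        else:
            iqr = IQRUnitFilter(columns=("cell_count", "mean_focus"),
                                k=cf.get("k", 1.5))
            units_kept = iqr.fit_transform(units)
            removed = iqr.removed_
            ledger.add_tier(
                f"iqr[k={cf.get('k', 1.5)}]", len(removed),
                int(removed["cell_count"].sum()))
        log(stage, f"removed {len(removed)} units / "
                   f"{int(removed['cell_count'].sum())} objects")
        removed.to_csv(out_dir / "removed_count_filter.csv", index=False)

        stage = "ntoc_filter"
        nf = config.ntoc_filter
        units_kept, removed, tier = ntoc_percentile_filter(
            units_kept, nf["p_low"], nf["p_high"])
        ledger.add_tier(tier.name, tier.images_removed, tier.objects_removed)
        log(stage, f"removed {tier.images_removed} units / "
                   f"{tier.objects_removed} objects")
        removed.to_csv(out_dir / "removed_ntoc_filter.csv", index=False)

        stage = "replicate_filter"
        rf = config.replicate_filter
        kept_keys = set(map(tuple,
                            units_kept[["chip_id", "row", "col"]].values))
        cell_key = list(map(tuple, cells[["chip_id", "row", "col"]].values))
        cells_kept = cells[[k in kept_keys for k in cell_key]]
        reports = []
        retained_designs = None
        for feat in rf["features"]:
            groups = replicate_groups_from_cells(
                cells_kept, screen.layout, feature=feat,
                mode=rf.get("mode", "cells"))
            kept, report = _dual(groups, feat, rf)
            reports.append(report)
            retained_designs = set(kept) if retained_designs is None \
                else retained_designs & set(kept)
            log(stage, f"{feat}: removed {len(report.removed_union)} designs "
                       f"(AD {len(report.removed_by_ad)}, "
                       f"SNR {len(report.removed_by_snr)})")
        removal_report(reports).to_csv(out_dir / "replicate_report.csv",
                                       index=False)

        stage = "rank_split"
        rk = config.ranking
        eligible = units_kept[
            units_kept["design_id"].isin(retained_designs)]
        readout_col = rk["readout"] if rk["readout"] in eligible.columns \
            else f"{rk['readout']}_mean"
        readouts = eligible.groupby("design_id")[readout_col].mean()
        n_extreme = min(rk["n_extreme"], len(readouts) // 2)
        labeled = rank_select(readouts,
                              RankConfig(readout=rk["readout"],
                                         n_extreme=n_extreme))
        spec = SplitSpec(seed=config.seed, **config.split)
        train, test, val = nested_split(labeled, spec)
        splits = pd.concat([
            train.assign(subset="train"),
            test.assign(subset="test"),
            val.assign(subset="validation"),
        ], ignore_index=True)
        splits.to_csv(out_dir / "splits.csv", index=False)
        log(stage, f"labeled {len(labeled)} designs; split "
                   f"{len(train)}/{len(test)}/{len(val)}")

        stage = "write"
        designs = make_design_table(screen.layout.design_ids,
                                    seed=config.seed)
        store = ScreenStore(
            cells=cells_kept, units=units_kept, designs=designs,
            layout=screen.layout, ledger=ledger,
            provenance={"seed": config.seed, "config": config.to_dict()})
        suffix = "screen.h5" if config.format == "hdf5" else "screen"
        write_features(store, out_dir / suffix, format=config.format)
        ledger.to_frame().to_csv(out_dir / "ledger.csv", index=False)
        (out_dir / "ledger.txt").write_text(ledger.to_text() + "\n")
        log("done", f"retained {ledger.images_retained} units / "
                    f"{ledger.objects_retained} objects")
    except Exception as err:
        (out_dir / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") \
            from err
    return out_dir


def _dual(groups, feature, rf):
    f = DualReplicateFilter(ad_band=tuple(rf["ad_band"]),
                            snr_band=tuple(rf["snr_band"]),
                            feature=feature).fit(groups)
    return f.retained_, f.report_
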