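"""Surface ranking, binarization, and nested stratified splitting.

Designs are ranked by a readout (e.g. mean cell count), the top and bottom N
become the positive and negative class (default N = 90 per class), and the
labeled set is split into train / test / validation by a nested stratified
scheme: 20 % held out, of which 20 % becomes validation — nominal fractions
0.80 / 0.16 / 0.04. Descriptor matrices are z-scored with statistics fitted
on the training subset only (a deliberate no-leakage choice; a global mode
fitting on the full set is available behind a flag).

The gradient-boosting stage itself is out of the core: this module exports
standardized model matrices and ships the screen's tuned LightGBM
hyperparameters as a config fixture for users who attach an external
trainer.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = [
    "RankConfig",
    "rank_select",
    "SplitSpec",
    "nested_split",
    "ModelMatrix",
    "ModelMatrixExporter",
    "export_model_matrix",
    "load_gbm_params",
]


@dataclass(frozen=True)
class RankConfig:
    """Readout and class size for top/bottom binarization."""

    readout: str = "cell_count"
    n_extreme: int = 90
    tie_rule: str = "stable_by_design_id"

    def __post_init__(self):
        if self.n_extreme < 1:
            raise ValueError("n_extreme must be >= 1")
        if self.tie_rule != "stable_by_design_id":
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


def rank_select(readouts, cfg: RankConfig | None = None) -> pd.DataFrame:
    """Label the top N designs 1 and the bottom N designs 0.

    ``readouts`` maps design_id -> readout value (dict or Series). Ties are
    broken stably by design id: among equal readouts, lexicographically
    earlier ids are taken first for the bottom class and later ids first for
    the top class, so the two classes can never overlap.
    """
    if cfg is None:
        cfg = RankConfig()
    series = pd.Series(readouts, dtype=float)
    if not np.all(np.isfinite(series.to_numpy())):
        raise ValueError("all readouts must be finite")
    n = cfg.n_extreme
    if 2 * n > len(series):
        raise ValueError(
            f"2*N = {2 * n} exceeds the {len(series)} eligible designs")
    frame = series.rename("readout").rename_axis("design_id").reset_index()
    frame["design_id"] = frame["design_id"].astype(str)
    bottom = frame.sort_values(["readout", "design_id"],
                               ascending=[True, True]).head(n)
    top = frame.sort_values(["readout", "design_id"],
                            ascending=[False, False]).head(n)
    bottom = bottom.assign(label=0)
    top = top.assign(label=1)
    out = pd.concat([top, bottom], ignore_index=True)
    return out.sort_values("design_id", kind="mergesort",
                           ignore_index=True)


@dataclass(frozen=True)
class SplitSpec:
    """Nested stratified split specification.

    ``test_fraction`` of the items is held out; ``val_of_test_fraction`` of
    that holdout becomes validation. Defaults give nominal 0.80 / 0.16 /
    0.04 train / test / validation.
    """

    test_fraction: float = 0.20
    val_of_test_fraction: float = 0.20
    stratify_on: str = "label"
    seed: int = 0

    def __post_init__(self):
        for name in ("test_fraction", "val_of_test_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def nominal_fractions(self) -> tuple:
        """Nominal (train, test, validation) fractions."""
        holdout = self.test_fraction
        val = holdout * self.val_of_test_fraction
        return (1 - holdout, holdout - val, val)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def nested_split(items: pd.DataFrame, spec: SplitSpec | None = None):
    """Split labeled designs into (train, test, validation).

    Stratified on ``spec.stratify_on``; holdout size = round-half-up of
    ``test_fraction * n``, validation = round-half-up of
    ``val_of_test_fraction * holdout``. Deterministic under ``spec.seed``.
    Subsets are disjoint, cover the input, and preserve class proportions
    within one item per subset.
    """
    if spec is None:
        spec = SplitSpec()
    labels = items[spec.stratify_on]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to stratify")
    n = len(items)
    n_holdout = _round_half_up(spec.test_fraction * n)
    n_val = _round_half_up(spec.val_of_test_fraction * n_holdout)
    n_test = n_holdout - n_val
    if n_val < len(counts) or n_test < len(counts):
        raise ValueError(
            "classes too small for every subset: per-class counts "
            f"{counts.to_dict()} with holdout {n_holdout} "
            f"(test {n_test}, validation {n_val})")
    try:
        train, holdout = train_test_split(
            items, test_size=n_holdout, stratify=labels,
            random_state=spec.seed)
        test, val = train_test_split(
            holdout, test_size=n_val, stratify=holdout[spec.stratify_on],
            random_state=spec.seed)
    except ValueError as err:
        raise ValueError(
            f"stratified split failed (per-class counts {counts.to_dict()})"
        ) from err
    return (train.reset_index(drop=True), test.reset_index(drop=True),
            val.reset_index(drop=True))


# ---------------------------------------------------------------------------
# model matrix export
# ---------------------------------------------------------------------------

@dataclass
class ModelMatrix:
    """Z-scored descriptor matrix with labels and subset assignments."""

    X: pd.DataFrame          # standardized descriptors, index = design_id
    y: pd.Series             # binary label per design
    subset: pd.Series        # 'train' | 'test' | 'validation'
    mean_: pd.Series         # standardization means (training statistics)
    scale_: pd.Series        # standardization scales
    dropped_columns: list    # zero-variance descriptors removed


class ModelMatrixExporter(BaseEstimator):
    """Standardize TDD descriptors for the classification stage.

    ``scope='train'`` (default) fits the z-scoring on the training subset
    only and applies it to all subsets; ``scope='global'`` reproduces the
    screen's standardize-before-split convention. Zero-variance descriptors
    are dropped with a record.
    """

    def __init__(self, scope: str = "train"):
        if scope not in ("train", "global"):
            raise ValueError("scope must be 'train' or 'global'")
        self.scope = scope

    def fit(self, X: pd.DataFrame, y=None):
        variances = X.var(ddof=0)
        self.dropped_columns_ = sorted(variances.index[variances == 0])
        kept = X.drop(columns=self.dropped_columns_)
        self.columns_ = list(kept.columns)
        self.scaler_ = StandardScaler().fit(kept.to_numpy())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept = X[self.columns_]
        return pd.DataFrame(self.scaler_.transform(kept.to_numpy()),
                            index=X.index, columns=self.columns_)


def export_model_matrix(labeled: pd.DataFrame, tdds: pd.DataFrame,
                        spec: SplitSpec | None = None,
                        scope: str = "train") -> ModelMatrix:
    """Join labels with descriptors, split, and z-score.

    ``labeled`` needs columns design_id and label; ``tdds`` is a design
    table (design_id + descriptor columns). Every labeled design must have a
    TDD row.
    """
    if spec is None:
        spec = SplitSpec()
    missing = set(labeled["design_id"]) - set(tdds["design_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} labeled designs lack TDD rows, e.g. "
            f"{sorted(missing)[:3]}")
    train, test, val = nested_split(labeled, spec)
    subset = pd.concat([
        pd.Series("train", index=train["design_id"]),
        pd.Series("test", index=test["design_id"]),
        pd.Series("validation", index=val["design_id"]),
    ])
    merged = labeled.merge(tdds, on="design_id").set_index("design_id")
    desc = merged.drop(columns=["label", "readout"], errors="ignore")
    exporter = ModelMatrixExporter(scope=scope)
    fit_rows = desc if scope == "global" else desc.loc[train["design_id"]]
    exporter.fit(fit_rows)
    X = exporter.transform(desc)
    return ModelMatrix(
        X=X,
        y=merged["label"],
        subset=subset.reindex(X.index),
        mean_=pd.Series(exporter.scaler_.mean_, index=exporter.columns_),
        scale_=pd.Series(exporter.scaler_.scale_, index=exporter.columns_),
        dropped_columns=exporter.dropped_columns_,
    )


def load_gbm_params() -> dict:
    """Tuned gradient-boosting hyperparameters of the screen's reference
    classifier, shipped as a config fixture for external trainers."""
    text = resources.files("topoqc").joinpath(
        "data/lightgbm_params.yaml").read_text()
    return yaml.safe_load(text)
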