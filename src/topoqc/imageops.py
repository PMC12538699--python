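"""Deterministic image-plane operations on stitched TopoChip images.

Z-projection (max or average), chip orientation via the flat-unit landmark,
bilinear tilt maps from corner focus heights, and lossless grid cropping of a
stitched chip into named TopoUnit tiles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChipLayout, format_tile_name, tile_name_for

__all__ = [
    "ProjectionSpec",
    "project_zstack",
    "TiltMap",
    "tilt_map",
    "OrientationResult",
    "orient_chip",
    "crop_units",
    "reassemble_units",
]


@dataclass(frozen=True)
class ProjectionSpec:
    """Z-projection method ('max' or 'average') and expected plane count."""

    method: str = "max"
    n_planes: int = 1

    def __post_init__(self):
        if self.method not in ("max", "average"):
            raise ValueError(f"unknown projection method {self.method!r}")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")


def project_zstack(stack, spec: ProjectionSpec) -> np.ndarray:
    """Collapse a z-stack to one plane.

    ``max`` takes the pixelwise maximum (the projection used for the nephrin
    channel, preserving the smallest high-intensity puncta); ``average``
    takes the pixelwise arithmetic mean, rounded half-up for integer dtypes.
    """
    planes = [np.asarray(p) for p in stack]
    if len(planes) != spec.n_planes:
        raise ValueError(
            f"stack has {len(planes)} planes, spec expects {spec.n_planes}")
    shape = planes[0].shape
    for i, p in enumerate(planes):
        if p.shape != shape:
            raise ValueError(
                f"plane {i} shape {p.shape} != plane 0 shape {shape}")
    stacked = np.stack(planes)
    if spec.method == "max":
        return stacked.max(axis=0)
    mean = stacked.astype(np.float64).mean(axis=0)
    dtype = planes[0].dtype
    if np.issubdtype(dtype, np.integer):
        return np.floor(mean + 0.5).astype(dtype)  # round half-up
    return mean.astype(dtype)


# ---------------------------------------------------------------------------
# tilt map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TiltMap:
    """Bilinear focal-height surface over unit centers.

    Diagnostic only: renders the chip's focal-plane tilt for autofocus setup;
    no image correction is applied.
    """

    corner_values: tuple  # (top-left, top-right, bottom-left, bottom-right)
    values: np.ndarray    # (n_rows, n_cols) interpolated heights

    def evaluate(self, row: int, col: int) -> float:
        return float(self.values[row, col])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)


def tilt_map(corner_values, n_rows: int, n_cols: int) -> TiltMap:
    """Bilinear interpolation of 4 corner heights over an n_rows x n_cols
    grid of unit centers; corner units reproduce the corner values exactly.
    """
    tl, tr, bl, br = (float(v) for v in corner_values)
    if not all(np.isfinite([tl, tr, bl, br])):
        raise ValueError("corner heights must be finite")
    fr = np.linspace(0.0, 1.0, n_rows)[:, None] if n_rows > 1 \
        else np.zeros((1, 1))
    fc = np.linspace(0.0, 1.0, n_cols)[None, :] if n_cols > 1 \
        else np.zeros((1, 1))
    top = tl + (tr - tl) * fc
    bottom = bl + (br - bl) * fc
    values = top + (bottom - top) * fr
    return TiltMap(corner_values=(tl, tr, bl, br), values=values)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

@dataclass
class OrientationResult:
    """Outcome of landmark-based orientation.

    ``rotation`` is the counterclockwise rotation (degrees, multiple of 90)
    applied to the input to bring the flat landmark to the lower-right; when
    ``ambiguous``, no rotation was applied and ``report`` explains why.
    """

    image: np.ndarray
    rotation: int
    ambiguous: bool = False
    report: str = ""
    scores: dict | None = None


def _unit_variances(image: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    h, w = image.shape
    uh, uw = h // n_rows, w // n_cols
    tiles = image[: n_rows * uh, : n_cols * uw].reshape(
        n_rows, uh, n_cols, uw).swapaxes(1, 2)
    # variance of the unit interior only: the walls between units are bright
    # in every tile and would otherwise swamp the texture signal
    tr, tc = max(1, uh // 8), max(1, uw // 8)
    interior = tiles[:, :, tr:uh - tr, tc:uw - tc]
    return interior.astype(np.float64).var(axis=(2, 3))


def lowest_variance_landmark(image: np.ndarray, layout: ChipLayout) -> float:
    """Default landmark score: median texture variance over the layout's
    flat positions (flat units lack pillars, so lower is more
    landmark-like; the median tolerates a cell sitting in one flat unit)."""
    var = _unit_variances(image, layout.n_rows, layout.n_cols)
    flats = list(layout.flat_positions)
    return float(np.median([var[r, c] for r, c in flats]))


def orient_chip(image: np.ndarray, layout: ChipLayout,
                landmark_detector=None,
                margin: float = 0.7) -> OrientationResult:
    """Rotate a stitched chip so the flat-unit landmark sits lower-right.

    Scores each rotation in {0, 90, 180, 270} with ``landmark_detector``
    (default: mean texture variance at the flat positions; lowest wins) and
    applies the unique winner. If no rotation wins by at least ``margin``
    (winner score < margin * runner-up), the result is flagged ambiguous and
    the image returned unrotated.
    """
    if landmark_detector is None:
        landmark_detector = lowest_variance_landmark
    h, w = image.shape
    if h % layout.n_rows or w % layout.n_cols:
        raise ValueError(
            f"image {image.shape} does not partition into the "
            f"{layout.n_rows}x{layout.n_cols} grid")
    rotations = (0, 90, 180, 270) if h == w else (0, 180)
    scores = {}
    for rot in rotations:
        rotated = np.rot90(image, k=rot // 90)
        scores[rot] = landmark_detector(rotated, layout)
    ordered = sorted(scores, key=scores.get)
    best, second = ordered[0], ordered[1]
    if scores[second] <= 0 or scores[best] >= margin * scores[second]:
        return OrientationResult(
            image=image, rotation=0, ambiguous=True,
            report=(
                "landmark ambiguous: rotation scores "
                + ", ".join(f"{r}deg={scores[r]:.3g}" for r in rotations)),
            scores=scores)
    return OrientationResult(image=np.rot90(image, k=best // 90),
                             rotation=best, scores=scores)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_units(image: np.ndarray, layout: ChipLayout, chip_id: str,
               channel: str, stain: str, out_dir=None):
    """Crop a stitched chip into one named tile per TopoUnit.

    The image must divide exactly into the grid; otherwise the error states
    the padding that would make it divisible (strict divisibility keeps the
    crop/reassemble round trip bit-exact). Returns ``(manifest, tiles)``:
    ``manifest`` has one row per tile (tile_name, row, col, design_id,
    checksum), ``tiles`` maps tile name to array. With ``out_dir`` set,
    tiles are also written as TIFF files under their grammar names.
    """
    h, w = image.shape
    if h % layout.n_rows or w % layout.n_cols:
        pad_r = (-h) % layout.n_rows
        pad_c = (-w) % layout.n_cols
        raise ValueError(
            f"image {image.shape} not divisible by grid "
            f"{layout.n_rows}x{layout.n_cols}; pad by ({pad_r}, {pad_c}) "
            "pixels (bottom, right) or crop to a multiple")
    uh, uw = h // layout.n_rows, w // layout.n_cols
    if out_dir is not None:
        import tifffile
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    tiles = {}
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            tn = tile_name_for(channel, chip_id, row=r + 1, col=c + 1,
                               stain=stain, n_cols=layout.n_cols)
            name = format_tile_name(tn)
            tile = image[r * uh:(r + 1) * uh, c * uw:(c + 1) * uw]
            tiles[name] = tile
            rows.append({
                "tile_name": name,
                "row": r,
                "col": c,
                "design_id": layout.design_at[(r, c)],
                "checksum": hashlib.md5(
                    np.ascontiguousarray(tile).tobytes()).hexdigest(),
            })
            if out_dir is not None:
                tifffile.imwrite(out_dir / name, tile)
    manifest = pd.DataFrame(rows)
    return manifest, tiles


def reassemble_units(tiles: dict, layout: ChipLayout) -> np.ndarray:
    """Inverse of :func:`crop_units`: stitch tiles back in grid order."""
    from .layout import parse_tile_name

    by_pos = {}
    for name, tile in tiles.items():
        tn = parse_tile_name(name)
        by_pos[(tn.row - 1, tn.col - 1)] = tile
    sample = next(iter(by_pos.values()))
    uh, uw = sample.shape
    out = np.zeros((layout.n_rows * uh, layout.n_cols * uw),
                   dtype=sample.dtype)
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            out[r * uh:(r + 1) * uh, c * uw:(c + 1) * uw] = by_pos[(r, c)]
    return out
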