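"""Reference-pattern fixtures, grid serialization, and image ingestion.

Grid file dialect: comma-separated integers (0 empty, 1 blue, 2 red), no
header, UTF-8, row-major with row index = transverse coordinate and
column index = downstream (flow) coordinate. A JSON sidecar
(``<file>.json``) round-trips the elementary-unit size and boundary mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, PatternFormatError
from .stats import ColorPattern

__all__ = [
    "ReferencePatternSpec",
    "ChannelImage",
    "generate_reference_pattern",
    "save_pattern",
    "load_pattern",
    "pattern_from_image",
    "read_channel_image",
]

_KINDS = ("random", "checkerboard", "stripes", "blocks", "voronoi")


@dataclass(frozen=True)
class ReferencePatternSpec:
    """Fixture pattern with known correlation structure.

    Kinds
    -----
    random
        Bernoulli colors at ``density`` occupancy; ξ ≤ 2.
    checkerboard
        Alternating colors by coordinate parity; anti-correlated at r=1.
    stripes
        Alternating color bands of width ``width`` along the flow axis;
        ξ tracks the stripe width.
    blocks
        width×width checkerboard of solid blocks.
    voronoi
        Each site takes the color of the nearest of ``n_seeds`` random
        founders (ties to the lowest founder index): the ideal limit in
        which every founder claims the territory around it, so ξ scales
        like L/sqrt(n_seeds).
    """

    kind: str
    L: int = 60
    width: int | None = None
    n_seeds: int | None = None
    color_ratio: float = 0.5
    density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.L < 2:
            raise InvalidParameterError("L must be >= 2")
        if self.kind in ("stripes", "blocks") and (self.width is None or self.width < 1):
            raise InvalidParameterError(f"kind {self.kind!r} requires width >= 1")
        if self.kind == "voronoi" and (self.n_seeds is None or self.n_seeds < 1):
            raise InvalidParameterError("kind 'voronoi' requires n_seeds >= 1")
        if not (0.0 <= self.color_ratio <= 1.0):
            raise InvalidParameterError("color_ratio must be in [0, 1]")
        if not (0.0 < self.density <= 1.0):
            raise InvalidParameterError("density must be in (0, 1]")


def generate_reference_pattern(spec: ReferencePatternSpec) -> ColorPattern:
    """Deterministic (given seed) fixture pattern for the analysis suite."""
    L = spec.L
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:L, 0:L]

    if spec.kind == "checkerboard":
        grid = ((xx + yy) % 2 + 1).astype(np.int8)
    elif spec.kind == "stripes":
        grid = ((xx // spec.width) % 2 + 1).astype(np.int8)
    elif spec.kind == "blocks":
        grid = ((xx // spec.width + yy // spec.width) % 2 + 1).astype(np.int8)
    elif spec.kind == "random":
        colors = np.where(rng.random((L, L)) < spec.color_ratio, 1, 2).astype(np.int8)
        if spec.density < 1.0:
            occupied = rng.random((L, L)) < spec.density
            colors[~occupied] = 0
        grid = colors
    else:  # voronoi
        flat = rng.choice(L * L, size=spec.n_seeds, replace=False)
        sy, sx = np.unravel_index(flat, (L, L))
        seed_colors = np.where(rng.random(spec.n_seeds) < spec.color_ratio, 1, 2)
        d2 = (yy[..., None] - sy) ** 2 + (xx[..., None] - sx) ** 2
        nearest = np.argmin(d2, axis=-1)  # ties -> lowest founder index
        grid = seed_colors[nearest].astype(np.int8)

    return ColorPattern(grid=grid, unit=1.0, periodic=False)


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def save_pattern(pattern: ColorPattern, path: str | Path) -> None:
    """Write a CSV integer grid plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, pattern.grid, fmt="%d", delimiter=",")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps({"unit": pattern.unit, "periodic": pattern.periodic}, indent=2)
    )


def load_pattern(path: str | Path) -> ColorPattern:
    """Load a CSV grid; save→load is the identity.

    Malformed values or ragged rows raise :class:`PatternFormatError`
    naming the offending row/column.
    """
    path = Path(path)
    rows: list[list[int]] = []
    width = None
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.split(",")
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise PatternFormatError(
                f"{path}: ragged row {i}: expected {width} columns, got {len(fields)}"
            )
        row = []
        for j, tok in enumerate(fields):
            try:
                v = int(tok.strip())
            except ValueError:
                raise PatternFormatError(
                    f"{path}: row {i}, column {j}: not an integer: {tok.strip()!r}"
                ) from None
            if v not in (0, 1, 2):
                raise PatternFormatError(
                    f"{path}: row {i}, column {j}: value {v} not in {{0, 1, 2}}"
                )
            row.append(v)
        rows.append(row)
    if not rows:
        raise PatternFormatError(f"{path}: empty pattern file")

    unit, periodic = 1.0, False
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        unit = float(meta.get("unit", 1.0))
        periodic = bool(meta.get("periodic", False))
    return ColorPattern(grid=np.asarray(rows, dtype=np.int8), unit=unit, periodic=periodic)


# ----------------------------------------------------------------------
# microscopy-image ingestion
# ----------------------------------------------------------------------
@dataclass
class ChannelImage:
    """Two co-registered fluorescence channels (blue and red strains).

    Thresholds default to Otsu's method per channel when left as None.
    The 0.065 μm default pixel size matches confocal fields of view
    imaged at 923×923 pixels per 60 μm.
    """

    blue: np.ndarray
    red: np.ndarray
    pixel_size: float = 0.065
    blue_threshold: float | None = None
    red_threshold: float | None = None

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.blue.shape != self.red.shape:
            raise InvalidParameterError(
                f"channel shapes differ: {self.blue.shape} vs {self.red.shape}"
            )
        if self.blue.ndim != 2:
            raise InvalidParameterError("channels must be 2D")


def _resolve_threshold(plane: np.ndarray, threshold: float | None) -> float:
    if threshold is not None:
        return float(threshold)
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(plane))


def pattern_from_image(img: ChannelImage) -> ColorPattern:
    """Binarize two channels into a color pattern.

    Per pixel: channels above their threshold compete; the brighter one
    assigns the color (ties go to blue). Pixels below both thresholds are
    empty. Deliberately minimal — per-channel threshold plus argmax, no
    instance segmentation.
    """
    tb = _resolve_threshold(img.blue, img.blue_threshold)
    tr = _resolve_threshold(img.red, img.red_threshold)
    blue_on = img.blue > tb
    red_on = img.red > tr
    grid = np.zeros(img.blue.shape, dtype=np.int8)
    grid[blue_on & (~red_on | (img.blue >= img.red))] = 1
    grid[red_on & (~blue_on | (img.red > img.blue))] = 2
    if not grid.any():
        raise InvalidParameterError("both channels below threshold everywhere")
    return ColorPattern(grid=grid, unit=img.pixel_size, periodic=False)


def read_channel_image(
    blue_path: str | Path,
    red_path: str | Path | None = None,
    pixel_size: float = 0.065,
    blue_threshold: float | None = None,
    red_threshold: float | None = None,
) -> ChannelImage:
    """Read two single-channel TIFFs, or one two-page TIFF (blue, red)."""
    import tifffile

    if red_path is None:
        stack = tifffile.imread(str(blue_path))
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise PatternFormatError(
                f"{blue_path}: expected a two-page TIFF, got shape {stack.shape}"
            )
        blue, red = stack[0], stack[1]
    else:
        blue = tifffile.imread(str(blue_path))
        red = tifffile.imread(str(red_path))
    return ChannelImage(
        blue=blue, red=red, pixel_size=pixel_size,
        blue_threshold=blue_threshold, red_threshold=red_threshold,
    )
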