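"""Annotation rasters and their class schemas.

An annotation raster is an integer label image in which each nonzero pixel
value encodes a histological class (cortex, medulla, capsule/edge, Hassall's
corpuscle, ...). The raster carries a physical scale ``ppm`` (pixels per
micron) linking pixel indices to continuous micron coordinates, and an
:class:`AnnotationSchema` describing which classes exist at which annotation
level (broad compartments vs fine structures).

Coordinate convention: continuous μm, origin at the image top-left corner,
y increasing downward. The center of pixel ``(i, j)`` (row, column) lies at
``((j + 0.5) / ppm, (i + 0.5) / ppm)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AnnotationSchema",
    "AnnotationRaster",
    "pixel_centers_um",
    "um_to_pixel",
    "read_raster",
    "write_raster",
]

BACKGROUND_CODE = 0


@dataclass(frozen=True)
class AnnotationSchema:
    """Class names grouped into ordered annotation levels, plus integer codes.

    Parameters
    ----------
    levels
        Ordered mapping from level name (e.g. ``"broad"``, ``"fine"``) to the
        tuple of class names annotated at that level.
    codes
        Mapping from class name to the positive integer pixel value encoding
        it. Code 0 is reserved for background and may not be assigned.
    """

    levels: dict[str, tuple[str, ...]]
    codes: dict[str, int]

    def __post_init__(self) -> None:
        for level, classes in self.levels.items():
            if len(set(classes)) != len(classes):
                raise ValueError(f"duplicate class names in level {level!r}")
            for cls in classes:
                if cls not in self.codes:
                    raise ValueError(f"class {cls!r} in level {level!r} has no code")
        if BACKGROUND_CODE in self.codes.values():
            raise ValueError("code 0 is reserved for background")
        if len(set(self.codes.values())) != len(self.codes):
            raise ValueError("class codes must be unique")

    @property
    def class_for_code(self) -> dict[int, str]:
        return {code: name for name, code in self.codes.items()}

    def classes_at(self, level: str) -> tuple[str, ...]:
        if level not in self.levels:
            raise KeyError(f"unknown annotation level {level!r}")
        return self.levels[level]

    def to_dict(self) -> dict:
        return {
            "levels": {k: list(v) for k, v in self.levels.items()},
            "codes": dict(self.codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSchema":
        return cls(
            levels={k: tuple(v) for k, v in d["levels"].items()},
            codes={k: int(v) for k, v in d["codes"].items()},
        )


@dataclass
class AnnotationRaster:
    """Integer label image with a physical scale and a class schema."""

    pixels: np.ndarray
    ppm: float
    schema: AnnotationSchema

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be an integer label array")
        if not self.ppm > 0:
            raise ValueError("ppm must be positive")
        known = set(self.schema.codes.values()) | {BACKGROUND_CODE}
        present = set(np.unique(self.pixels).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"pixel values {sorted(unknown)} missing from schema")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the raster in μm."""
        nrow, ncol = self.pixels.shape
        return ncol / self.ppm, nrow / self.ppm

    def class_mask(self, name: str) -> np.ndarray:
        return self.pixels == self.schema.codes[name]

    def tissue_mask(self) -> np.ndarray:
        return self.pixels != BACKGROUND_CODE

    def label_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Class code under each (x, y) μm position; raises if out of bounds."""
        rows, cols = um_to_pixel(x_um, y_um, self.ppm)
        nrow, ncol = self.pixels.shape
        bad = (rows < 0) | (rows >= nrow) | (cols < 0) | (cols >= ncol)
        if np.any(bad):
            raise IndexError(
                f"{int(bad.sum())} position(s) fall outside the raster bounds"
            )
        return self.pixels[rows, cols]


def pixel_centers_um(shape: tuple[int, int], ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of pixel-center coordinates (x, y) in μm."""
    nrow, ncol = shape
    x = (np.arange(ncol) + 0.5) / ppm
    y = (np.arange(nrow) + 0.5) / ppm
    return np.meshgrid(x, y)


def um_to_pixel(
    x_um: np.ndarray, y_um: np.ndarray, ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map continuous μm coordinates to (row, col) pixel indices."""
    cols = np.floor(np.asarray(x_um, dtype=float) * ppm).astype(int)
    rows = np.floor(np.asarray(y_um, dtype=float) * ppm).astype(int)
    return rows, cols


def write_raster(raster: AnnotationRaster, path: str | Path) -> None:
    """Write a label TIFF plus a JSON sidecar with scale and schema."""
    path = Path(path)
    tifffile.imwrite(path, raster.pixels.astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"ppm": raster.ppm, "schema": raster.schema.to_dict()}, indent=1)
    )


def read_raster(path: str | Path) -> AnnotationRaster:
    """Read a label TIFF written by :func:`write_raster`."""
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path)).astype(np.int64)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return AnnotationRaster(
        pixels=pixels,
        ppm=float(meta["ppm"]),
        schema=AnnotationSchema.from_dict(meta["schema"]),
    )
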