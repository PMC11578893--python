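"""Quasi-hexagonal annotation grids and per-class distance fields.

Discrete pixel annotations are moved onto a staggered point lattice before
any axis computation: points are placed at ``spacing_r`` μm intervals in x
and y, with every other row shifted by ``spacing_r / 2``, and clipped to the
tissue mask. Each grid point then carries the annotation class under its
center and, per (level, class), the mean Euclidean distance to its ``k``
nearest grid points of that class. Working on a lattice of fixed physical
pitch makes distances independent of the raster's pixel resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import AnnotationRaster, um_to_pixel

__all__ = [
    "HexGrid",
    "build_hex_grid",
    "transfer_raster_to_grid",
    "class_distance_field",
    "seed_labels_from_markers",
    "DEFAULT_SPACING_UM",
]

#: Default lattice pitch in μm.
DEFAULT_SPACING_UM = 15.0


@dataclass
class HexGrid:
    """Staggered point lattice carrying labels and distance fields.

    ``labels`` maps a level name to an object array of class names (``None``
    for background); ``distances`` maps ``(level, class)`` to a float array
    of mean-kNN distances in μm (NaN where undefined).
    """

    x: np.ndarray
    y: np.ndarray
    spacing_r: float
    origin: tuple[float, float]
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    distances: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.x.size

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-point table: x_um, y_um, label_<level>, dist_<level>_<class>."""
        cols: dict[str, np.ndarray] = {"x_um": self.x, "y_um": self.y}
        for level, lab in self.labels.items():
            cols[f"label_{level}"] = lab
        for (level, cls), d in self.distances.items():
            cols[f"dist_{level}_{cls}"] = d
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spacing_r: float = DEFAULT_SPACING_UM) -> "HexGrid":
        labels: dict[str, np.ndarray] = {}
        distances: dict[tuple[str, str], np.ndarray] = {}
        for col in df.columns:
            if col.startswith("label_"):
                lab = df[col].to_numpy(dtype=object)
                lab[pd.isna(df[col]).to_numpy()] = None
                labels[col[len("label_"):]] = lab
            elif col.startswith("dist_"):
                level, cls_name = col[len("dist_"):].split("_", 1)
                distances[(level, cls_name)] = df[col].to_numpy(dtype=float)
        x = df["x_um"].to_numpy(dtype=float)
        y = df["y_um"].to_numpy(dtype=float)
        origin = (float(x.min()), float(y.min())) if len(x) else (0.0, 0.0)
        return cls(x=x, y=y, spacing_r=spacing_r, origin=origin,
                   labels=labels, distances=distances)


def build_hex_grid(
    mask: np.ndarray,
    spacing_r: float = DEFAULT_SPACING_UM,
    ppm: float = 1.0,
    origin: tuple[float, float] | None = None,
) -> HexGrid:
    """Place a staggered lattice of points over the true pixels of a mask.

    Rows are ``spacing_r`` μm apart; within a row, points are ``spacing_r``
    apart; odd rows are offset by ``spacing_r / 2`` in x. The lattice origin
    defaults to the center of the top-left pixel. A point is kept iff its
    center falls on a true mask pixel.

    Parameters
    ----------
    mask
        Boolean 2D tissue mask (any nonzero treated as tissue).
    spacing_r
        Lattice pitch in μm (default 15).
    ppm
        Pixels per micron of the mask.
    origin
        (x, y) μm of lattice point (row 0, col 0); default top-left pixel
        center.

    Returns
    -------
    HexGrid with no labels or distance fields yet.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    if not spacing_r > 0:
        raise ValueError("spacing_r must be positive")
    if origin is None:
        origin = (0.5 / ppm, 0.5 / ppm)
    ox, oy = origin
    nrow, ncol = mask.shape
    width, height = ncol / ppm, nrow / ppm

    n_rows = int(np.floor((height - oy) / spacing_r)) + 1
    n_cols = int(np.floor((width - ox) / spacing_r)) + 1
    if n_rows <= 0 or n_cols <= 0:
        warnings.warn("mask extent smaller than one lattice step; empty grid")
        return HexGrid(np.empty(0), np.empty(0), spacing_r, origin)

    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    jj, ii = np.meshgrid(cols, rows)
    xs = ox + jj * spacing_r + (ii % 2) * (spacing_r / 2.0)
    ys = oy + ii * spacing_r
    xs, ys = xs.ravel(), ys.ravel()

    inside = (xs < width) & (ys < height) & (xs >= 0) & (ys >= 0)
    xs, ys = xs[inside], ys[inside]
    prow, pcol = um_to_pixel(xs, ys, ppm)
    on_tissue = mask[prow, pcol]
    xs, ys = xs[on_tissue], ys[on_tissue]
    if xs.size == 0:
        warnings.warn("no lattice point falls on tissue; empty grid")
    return HexGrid(x=xs, y=ys, spacing_r=spacing_r, origin=origin)


def transfer_raster_to_grid(
    raster: AnnotationRaster, grid: HexGrid, level: str
) -> HexGrid:
    """Assign each grid point the annotation class of the pixel under it.

    Codes whose class is not part of ``level`` (including background) map to
    ``None``. Idempotent: repeating the transfer rewrites identical labels.
    """
    classes = set(raster.schema.classes_at(level))
    codes = raster.label_at(grid.x, grid.y)
    code_to_class = raster.schema.class_for_code
    lab = np.array(
        [
            code_to_class.get(int(c)) if code_to_class.get(int(c)) in classes else None
            for c in codes
        ],
        dtype=object,
    )
    grid.labels[level] = lab
    return grid


def class_distance_field(
    grid: HexGrid, level: str, cls: str, k: int = 10
) -> HexGrid:
    """Mean distance from every grid point to its k nearest points of a class.

    A point carrying the class is its own nearest member (contributing 0).
    If the class has fewer than ``k`` member points in the grid, the field is
    undefined (NaN) everywhere, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if level not in grid.labels:
        raise KeyError(f"grid has no labels for level {level!r}")
    member = np.array([lab == cls for lab in grid.labels[level]], dtype=bool)
    n_members = int(member.sum())
    out = np.full(len(grid), np.nan)
    if n_members == 0:
        warnings.warn(f"class {cls!r} absent from grid level {level!r}; "
                      "distance field undefined")
    elif n_members < k:
        warnings.warn(
            f"class {cls!r} has {n_members} member(s) < k={k}; "
            "distance field undefined"
        )
    else:
        tree = cKDTree(grid.points[member])
        d, _ = tree.query(grid.points, k=k)
        if k == 1:
            out = np.asarray(d, dtype=float)
        else:
            out = d.mean(axis=1)
    grid.distances[(level, cls)] = out
    return grid


def seed_labels_from_markers(
    coords_um: np.ndarray,
    features: pd.DataFrame,
    marker_map: dict[str, str],
    shape: tuple[int, int],
    ppm: float,
    class_codes: dict[str, int],
    quantile_q: float = 0.9,
) -> np.ndarray:
    """Seed a sparse training raster from marker-high observations.

    For each class, observations whose marker expression reaches the
    per-marker ``quantile_q`` threshold (ties included) become seed pixels of
    that class. An observation passing the threshold for more than one class
    is dropped; a marker constant across observations yields no seeds.

    Parameters
    ----------
    coords_um
        (n, 2) observation positions in μm.
    features
        Observation × feature expression table containing the markers.
    marker_map
        class name → marker feature name (e.g. medulla → AIRE,
        cortex → ARPP21).
    shape, ppm
        Geometry of the raster to seed.
    class_codes
        class name → integer code for the output raster.
    quantile_q
        Quantile defining "marker-high" (default 0.9), 0 < q < 1.

    Returns
    -------
    Integer raster of ``shape`` with seed pixels coded per class, 0 elsewhere.
    """
    if not 0 < quantile_q < 1:
        raise ValueError("quantile_q must lie in (0, 1)")
    coords_um = np.asarray(coords_um, dtype=float)
    n = coords_um.shape[0]
    hits = np.zeros((n, len(marker_map)), dtype=bool)
    class_names = list(marker_map)
    for j, cls in enumerate(class_names):
        marker = marker_map[cls]
        if marker not in features.columns:
            raise KeyError(f"marker {marker!r} not in feature table")
        vals = features[marker].to_numpy(dtype=float)
        if np.all(vals == 0):
            warnings.warn(f"marker {marker!r} is all-zero; no seeds for {cls!r}")
            continue
        if vals.max() == vals.min():
            warnings.warn(
                f"marker {marker!r} is constant; all observations tie at the "
                f"threshold — no seeds for {cls!r}"
            )
            continue
        thr = np.quantile(vals, quantile_q)
        hits[:, j] = vals >= thr

    n_classes_hit = hits.sum(axis=1)
    conflicted = n_classes_hit > 1
    if conflicted.any():
        warnings.warn(
            f"{int(conflicted.sum())} observation(s) marker-high for multiple "
            "classes; dropped"
        )
    seeds = np.zeros(shape, dtype=np.int64)
    keep = (n_classes_hit == 1) & ~conflicted
    rows, cols = um_to_pixel(coords_um[:, 0], coords_um[:, 1], ppm)
    for j, cls in enumerate(class_names):
        sel = keep & hits[:, j]
        seeds[rows[sel], cols[sel]] = class_codes[cls]
    return seeds
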