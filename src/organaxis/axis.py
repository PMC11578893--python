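"""Continuous organ axes from landmark distances.

The core construction turns a pair of distance fields — distance to landmark
class A and to landmark class B — into a signed, normalized boundary metric

    H(d_A, d_B) = tanh(beta * (d_A - d_B) / C)

which is 0 exactly on the A/B boundary (d_A = d_B), negative toward A,
positive toward B, bounded in (-1, 1), and steepest at the boundary, so that
boundary-proximal displacements move the coordinate most. The normalization
length C is resolved per sample as a high percentile of |d_A - d_B|, which
makes the axis invariant to tissue size, raster scale and rotation.

A composite axis is a convex combination of several H components. The
thymic cortico-medullary axis (CMA) preset combines

    CMA = 0.2 * H(edge, cortex) + 0.8 * H(cortex, medulla)

so the coordinate runs from -1 at the capsule through 0 near the
cortico-medullary boundary to +1 in the deep medulla. The continuous axis
can be discretized into ten named anatomical levels (capsular through
medullary level 3) shared across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .grid import HexGrid
from .raster import AnnotationRaster, um_to_pixel

__all__ = [
    "AxisParams",
    "BinScheme",
    "AxisField",
    "h_metric",
    "compose_axis",
    "compute_axis_field",
    "bin_axis",
    "structure_distance",
    "map_to_observations",
    "cma_params",
    "load_preset",
    "DEFAULT_HC_CUTOFF_UM",
]

#: Default maximum distance (μm) when subsetting observations around a
#: structure such as a Hassall's corpuscle.
DEFAULT_HC_CUTOFF_UM = 350.0

#: Ten anatomical levels of the binned cortico-medullary axis, ordered from
#: the capsule inward to the deep medulla.
CMA_BIN_NAMES = (
    "capsular",
    "subcapsular",
    "cortical_1",
    "cortical_2",
    "cortical_3",
    "cortical_cmj",
    "medullary_cmj",
    "medullary_1",
    "medullary_2",
    "medullary_3",
)

# Capsular/subcapsular cutoffs sit in the negative-saturated range of the
# axis; the remaining eight bins split the rest at equal increments.
CMA_BIN_CUTOFFS = (-0.95, -0.8) + tuple(
    np.round(-0.8 + 1.8 / 8 * i, 6) for i in range(1, 8)
)


@dataclass(frozen=True)
class BinScheme:
    """Named ordered bins partitioning the axis range [-1, 1]."""

    names: tuple[str, ...]
    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.names) - 1:
            raise ValueError("need exactly len(names) - 1 interior cutoffs")
        if list(self.cutoffs) != sorted(self.cutoffs) or len(set(self.cutoffs)) != len(
            self.cutoffs
        ):
            raise ValueError("cutoffs must be strictly increasing")

    def assign(self, axis: np.ndarray) -> np.ndarray:
        """Bin index per axis value (-1 for undefined axis)."""
        axis = np.asarray(axis, dtype=float)
        idx = np.searchsorted(np.asarray(self.cutoffs), axis, side="left")
        idx = idx.astype(int)
        idx[np.isnan(axis)] = -1
        return idx

    def labels(self, axis: np.ndarray) -> np.ndarray:
        idx = self.assign(axis)
        out = np.array(
            [self.names[i] if i >= 0 else None for i in idx], dtype=object
        )
        return out


DEFAULT_CMA_BINS = BinScheme(names=CMA_BIN_NAMES, cutoffs=CMA_BIN_CUTOFFS)


@dataclass
class AxisParams:
    """Parameters of a composite organ axis.

    Attributes
    ----------
    pairs
        Ordered landmark pairs (class_A, class_B); the axis is negative
        toward class_A and positive toward class_B of each pair.
    weights
        Convex weights of the per-pair H components (must sum to 1).
    beta
        Sigmoid steepness (dimensionless), default 1.
    scale_C
        Normalization length in μm, or "auto" to resolve per sample as the
        ``auto_percentile`` percentile of |d_A - d_B|.
    k_dist
        Neighbour count of the underlying class distance fields (default 10
        for broad compartment annotations).
    level
        Annotation level carrying the landmark classes.
    bins
        BinScheme used to discretize the composite axis.
    """

    pairs: tuple[tuple[str, str], ...]
    weights: tuple[float, ...]
    beta: float = 1.0
    scale_C: float | str = "auto"
    auto_percentile: float = 95.0
    k_dist: int = 10
    level: str = "broad"
    bins: BinScheme = dc_field(default_factory=lambda: DEFAULT_CMA_BINS)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.weights):
            raise ValueError("one weight per landmark pair required")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("weights must sum to 1")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.scale_C != "auto" and not float(self.scale_C) > 0:
            raise ValueError("scale_C must be positive or 'auto'")
        if self.k_dist < 1:
            raise ValueError("k_dist must be >= 1")


def cma_params(**overrides) -> AxisParams:
    """The thymic cortico-medullary axis preset: 0.2 edge→cortex + 0.8 cortex→medulla."""
    kwargs = dict(
        pairs=(("edge", "cortex"), ("cortex", "medulla")),
        weights=(0.2, 0.8),
    )
    kwargs.update(overrides)
    return AxisParams(**kwargs)


@dataclass
class AxisField:
    """Composite axis value, per-pair H components and bin label per point."""

    axis: np.ndarray
    h_components: dict[tuple[str, str], np.ndarray]
    bin_labels: np.ndarray | None = None
    resolved_C: dict[tuple[str, str], float] = dc_field(default_factory=dict)
    grid: HexGrid | None = None


def h_metric(
    d_A: np.ndarray | float,
    d_B: np.ndarray | float,
    beta: float = 1.0,
    scale_C: float = 1.0,
) -> np.ndarray | float:
    """Signed sigmoid boundary metric tanh(beta * (d_A - d_B) / C).

    Zero iff d_A = d_B (on the boundary), antisymmetric under swapping the
    two distances, strictly increasing in d_A, bounded in (-1, 1), with
    maximal slope at the boundary. Undefined (NaN) inputs propagate.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    if not scale_C > 0:
        raise ValueError("scale_C must be positive")
    return np.tanh(beta * (np.asarray(d_A, dtype=float) - np.asarray(d_B, dtype=float)) / scale_C)


def compose_axis(
    h_values: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray | float:
    """Convex combination of per-pair H components.

    ``h_values`` has the pair dimension last; any undefined component makes
    the composite undefined.
    """
    h_values = np.asarray(h_values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if h_values.shape[-1] != weights.size:
        raise ValueError("weights must match the number of H components")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return h_values @ weights


def compute_axis_field(grid: HexGrid, params: AxisParams) -> AxisField:
    """Evaluate the composite axis on a labelled grid with distance fields.

    Requires ``grid.distances[(params.level, cls)]`` for every landmark class
    in ``params.pairs`` (computed with k = params.k_dist); raises naming the
    first missing class. With ``scale_C="auto"`` the normalization length is
    resolved per pair as the ``auto_percentile`` percentile of |d_A - d_B|
    over defined points, and recorded in ``resolved_C``.
    """
    h_comp: dict[tuple[str, str], np.ndarray] = {}
    resolved: dict[tuple[str, str], float] = {}
    for (cls_a, cls_b) in params.pairs:
        for cls in (cls_a, cls_b):
            if (params.level, cls) not in grid.distances:
                raise KeyError(
                    f"grid is missing the distance field for class {cls!r} at "
                    f"level {params.level!r}; run class_distance_field first"
                )
        d_a = grid.distances[(params.level, cls_a)]
        d_b = grid.distances[(params.level, cls_b)]
        diff = d_a - d_b
        if params.scale_C == "auto":
            defined = ~np.isnan(diff)
            if not defined.any():
                warnings.warn(
                    f"pair ({cls_a}, {cls_b}): no defined distances; H undefined"
                )
                C = 1.0
            else:
                C = float(np.percentile(np.abs(diff[defined]), params.auto_percentile))
                if C <= 0:
                    warnings.warn(
                        f"pair ({cls_a}, {cls_b}): degenerate auto scale; using 1 μm"
                    )
                    C = 1.0
        else:
            C = float(params.scale_C)
        resolved[(cls_a, cls_b)] = C
        h_comp[(cls_a, cls_b)] = h_metric(d_a, d_b, beta=params.beta, scale_C=C)

    stacked = np.stack([h_comp[p] for p in params.pairs], axis=-1)
    axis = compose_axis(stacked, np.asarray(params.weights))
    return AxisField(axis=axis, h_components=h_comp, resolved_C=resolved, grid=grid)


def bin_axis(field: AxisField, scheme: BinScheme | None = None) -> AxisField:
    """Attach ordered bin labels to every defined axis value."""
    scheme = scheme or DEFAULT_CMA_BINS
    field.bin_labels = scheme.labels(field.axis)
    return field


def structure_distance(
    coords_um: np.ndarray,
    raster: AnnotationRaster,
    cls: str,
    max_cutoff: float = DEFAULT_HC_CUTOFF_UM,
) -> pd.DataFrame:
    """Distance (μm) from each observation to the nearest pixel of a class.

    Observations whose own pixel carries the class get distance 0; others get
    the Euclidean distance to the nearest class pixel center. Observations
    farther than ``max_cutoff`` are flagged ``excluded`` (default 350 μm).
    """
    if cls not in raster.schema.codes:
        raise KeyError(f"class {cls!r} not in schema")
    mask = raster.class_mask(cls)
    if not mask.any():
        raise ValueError(f"class {cls!r} has no pixels in the raster")
    coords_um = np.asarray(coords_um, dtype=float)
    rows, cols = um_to_pixel(coords_um[:, 0], coords_um[:, 1], raster.ppm)
    nrow, ncol = raster.shape
    inside_img = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
    inside_cls = np.zeros(len(coords_um), dtype=bool)
    inside_cls[inside_img] = mask[rows[inside_img], cols[inside_img]]

    mrow, mcol = np.nonzero(mask)
    centers = np.column_stack([(mcol + 0.5) / raster.ppm, (mrow + 0.5) / raster.ppm])
    tree = cKDTree(centers)
    dist, _ = tree.query(coords_um)
    dist = np.asarray(dist, dtype=float)
    dist[inside_cls] = 0.0
    return pd.DataFrame(
        {"distance_um": dist, "excluded": dist > max_cutoff}
    )


def map_to_observations(
    field: AxisField,
    coords_um: np.ndarray,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Transfer axis values, H components and distances to observations.

    Each observation receives all values of its single nearest grid point
    (Euclidean); ties within ``tie_tol`` are broken by the lowest point index
    so the mapping is deterministic.
    """
    grid = field.grid
    if grid is None or len(grid) == 0:
        raise ValueError("axis field has no grid points to map from")
    coords_um = np.asarray(coords_um, dtype=float)
    tree = cKDTree(grid.points)
    k = min(2, len(grid))
    d, idx = tree.query(coords_um, k=k)
    if k == 1:
        nearest = np.atleast_1d(idx)
    else:
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        tied = np.isclose(d[:, 0], d[:, 1], rtol=0.0, atol=tie_tol)
        nearest = np.where(tied, np.minimum(idx[:, 0], idx[:, 1]), idx[:, 0])

    out = pd.DataFrame({"grid_index": nearest})
    out["axis"] = field.axis[nearest]
    for (cls_a, cls_b), h in field.h_components.items():
        out[f"H_{cls_a}_{cls_b}"] = h[nearest]
    if field.bin_labels is not None:
        out["axis_bin"] = field.bin_labels[nearest]
    for (level, cls), dvals in grid.distances.items():
        out[f"dist_{level}_{cls}"] = dvals[nearest]
    return out


def load_preset(path: str | Path | None = None) -> AxisParams:
    """Load an axis preset from YAML; default is the shipped CMA preset."""
    if path is None:
        ref = resources.files("organaxis").joinpath("presets/cma.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    bins_cfg = cfg.pop("bins", None)
    bins = (
        BinScheme(names=tuple(bins_cfg["names"]), cutoffs=tuple(bins_cfg["cutoffs"]))
        if bins_cfg
        else DEFAULT_CMA_BINS
    )
    pairs = tuple(tuple(p) for p in cfg.pop("pairs"))
    weights = tuple(float(w) for w in cfg.pop("weights"))
    return AxisParams(pairs=pairs, weights=weights, bins=bins, **cfg)
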