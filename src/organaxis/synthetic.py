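"""Synthetic lobule geometry and observation generators with known truth.

Every downstream component can be exercised without external data by
emulating the concentric geometry of a thymic lobule — a medulla core, a
cortex annulus and a capsule/edge ring, with optional Hassall's-corpuscle
discs inside the medulla — together with observations whose features follow
configurable functions of the true normalized radial depth (0 at the
capsule, 1 at the lobule center). A companion generator produces
reference/query pairs with Gaussian label clusters in a bridged shared
feature space for label-transfer tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import anndata as ad
from scipy.ndimage import gaussian_filter

from .raster import AnnotationRaster, AnnotationSchema
from .transfer import FeatureBridge, FeatureSet

__all__ = [
    "LobuleSpec",
    "SyntheticLobule",
    "LOBULE_SCHEMA",
    "make_lobule_raster",
    "sample_observations",
    "make_transfer_pair",
    "LINKS",
]

#: Class schema of the synthetic lobule: broad compartments plus a fine
#: level for Hassall's-corpuscle discs.
LOBULE_SCHEMA = AnnotationSchema(
    levels={"broad": ("edge", "cortex", "medulla"), "fine": ("hc",)},
    codes={"edge": 1, "cortex": 2, "medulla": 3, "hc": 4},
)


@dataclass(frozen=True)
class LobuleSpec:
    """Geometry of one synthetic lobule.

    Radii are strictly nested: medulla core < cortex annulus < edge ring
    (all in μm from the lobule center). ``hc_discs`` are (cx, cy, radius)
    in μm and must lie inside the medulla. ``jitter_sigma_px`` adds smooth
    boundary perturbations of the given pixel-scale standard deviation.
    ``ellipticity`` stretches the lobule (1 = circular) and
    ``rotation_deg`` rotates the stretched lobule about its center, so
    rotation-invariance checks are not vacuous.
    """

    r_medulla: float = 200.0
    r_cortex: float = 400.0
    r_edge: float = 440.0
    center: tuple[float, float] | None = None
    hc_discs: tuple[tuple[float, float, float], ...] = ()
    jitter_sigma_px: float = 0.0
    jitter_smooth_px: float = 8.0
    ellipticity: float = 1.0
    rotation_deg: float = 0.0
    ppm: float = 0.5
    margin_um: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_medulla < self.r_cortex < self.r_edge:
            raise ValueError("radii must be strictly nested: medulla < cortex < edge")
        if self.ppm <= 0:
            raise ValueError("ppm must be positive")
        if self.ellipticity <= 0:
            raise ValueError("ellipticity must be positive")
        stretch = max(self.ellipticity, 1.0 / self.ellipticity)
        for cx, cy, r in self.hc_discs:
            if float(self.effective_radius(cx, cy)) + r * stretch > self.r_medulla:
                raise ValueError("HC discs must lie inside the medulla core")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        stretch = max(self.ellipticity, 1.0 / self.ellipticity)
        half = self.r_edge * stretch + self.margin_um
        return (half, half)

    def shape_px(self) -> tuple[int, int]:
        stretch = max(self.ellipticity, 1.0 / self.ellipticity)
        side = 2 * (self.r_edge * stretch + self.margin_um)
        n = int(np.ceil(side * self.ppm))
        return (n, n)

    def effective_radius(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Elliptical, rotated radius of positions relative to the center."""
        cx, cy = self.resolved_center()
        theta = np.deg2rad(self.rotation_deg)
        dx, dy = np.asarray(x_um) - cx, np.asarray(y_um) - cy
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        return np.hypot(u / self.ellipticity, v * self.ellipticity)


@dataclass
class SyntheticLobule:
    """Generated rasters per level, ground-truth depth field and spec."""

    rasters: dict[str, AnnotationRaster]
    depth: np.ndarray
    spec: LobuleSpec

    @property
    def broad(self) -> AnnotationRaster:
        return self.rasters["broad"]

    @property
    def fine(self) -> AnnotationRaster:
        return self.rasters["fine"]


def make_lobule_raster(spec: LobuleSpec) -> SyntheticLobule:
    """Rasterize a concentric lobule with optional boundary jitter.

    Returns broad (edge/cortex/medulla) and fine (HC) label rasters sharing
    one schema, plus the per-pixel ground-truth normalized radial depth
    (0 at the capsule outer boundary, 1 at the lobule center). Deterministic
    for a fixed spec (the jitter field is seeded).
    """
    nrow, ncol = spec.shape_px()
    x = (np.arange(ncol) + 0.5) / spec.ppm
    y = (np.arange(nrow) + 0.5) / spec.ppm
    xx, yy = np.meshgrid(x, y)
    radius = spec.effective_radius(xx, yy)

    if spec.jitter_sigma_px > 0:
        rng = np.random.default_rng(spec.seed)
        noise = gaussian_filter(rng.standard_normal((nrow, ncol)), spec.jitter_smooth_px)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * (spec.jitter_sigma_px / spec.ppm)
        radius = radius + noise

    broad = np.zeros((nrow, ncol), dtype=np.int64)
    broad[radius <= spec.r_edge] = LOBULE_SCHEMA.codes["edge"]
    broad[radius <= spec.r_cortex] = LOBULE_SCHEMA.codes["cortex"]
    broad[radius <= spec.r_medulla] = LOBULE_SCHEMA.codes["medulla"]

    fine = np.zeros((nrow, ncol), dtype=np.int64)
    for hx, hy, hr in spec.hc_discs:
        disc = np.hypot(xx - hx, yy - hy) <= hr
        fine[disc & (broad == LOBULE_SCHEMA.codes["medulla"])] = LOBULE_SCHEMA.codes["hc"]

    depth = np.clip(1.0 - radius / spec.r_edge, 0.0, 1.0)
    rasters = {
        "broad": AnnotationRaster(pixels=broad, ppm=spec.ppm, schema=LOBULE_SCHEMA),
        "fine": AnnotationRaster(pixels=fine, ppm=spec.ppm, schema=LOBULE_SCHEMA),
    }
    return SyntheticLobule(rasters=rasters, depth=depth, spec=spec)


# Link functions mapping normalized depth (0..1) to a mean signal.
LINKS = {
    "identity": lambda d, **kw: d,
    "constant": lambda d, value=1.0, **kw: np.full_like(d, float(value)),
    "linear": lambda d, slope=1.0, intercept=0.0, **kw: slope * d + intercept,
    "sigmoid": lambda d, center=0.5, steepness=10.0, scale=1.0, **kw: scale
    / (1.0 + np.exp(-steepness * (d - center))),
}


def sample_observations(
    lobule: SyntheticLobule,
    n: int,
    features: dict[str, tuple[str, dict]] | None = None,
    noise_sigma: float = 0.1,
    mode: str = "gaussian",
    seed: int = 0,
    sample_id: str = "sample_0",
    group: str = "groupA",
) -> ad.AnnData:
    """Draw observations uniformly over the tissue with depth-linked features.

    Each feature is declared as ``name -> (link_name, params)`` with links
    from :data:`LINKS`. In ``gaussian`` mode the value is
    ``link(depth) + N(0, noise_sigma)``; in ``poisson`` mode counts are drawn
    as ``Poisson(exp(link(depth)))``. Positions (μm), the true depth, sample
    id and group label are stored in ``.obs`` / ``.obsm["spatial"]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("gaussian", "poisson"):
        raise ValueError("mode must be 'gaussian' or 'poisson'")
    features = features or {"grad": ("identity", {})}
    for name, (link, _) in features.items():
        if link not in LINKS:
            raise KeyError(f"unknown link {link!r} for feature {name!r}")

    rng = np.random.default_rng(seed)
    tissue = lobule.broad.tissue_mask()
    rows, cols = np.nonzero(tissue)
    pick = rng.integers(0, rows.size, size=n)
    ppm = lobule.spec.ppm
    x_um = (cols[pick] + rng.uniform(0, 1, n)) / ppm
    y_um = (rows[pick] + rng.uniform(0, 1, n)) / ppm
    depth = lobule.depth[rows[pick], cols[pick]]

    X = np.empty((n, len(features)))
    for j, (name, (link, params)) in enumerate(features.items()):
        mu = LINKS[link](depth, **params)
        if mode == "gaussian":
            X[:, j] = mu + rng.normal(0.0, noise_sigma, n)
        else:
            X[:, j] = rng.poisson(np.exp(mu))

    obs = pd.DataFrame(
        {
            "x_um": x_um,
            "y_um": y_um,
            "depth": depth,
            "sample": sample_id,
            "group": group,
        },
        index=[f"{sample_id}_obs{i}" for i in range(n)],
    )
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=list(features)),
    )
    adata.obsm["spatial"] = np.column_stack([x_um, y_um])
    adata.uns["generating"] = {
        "features": {k: [v[0], dict(v[1])] for k, v in features.items()},
        "noise_sigma": noise_sigma,
        "mode": mode,
        "seed": seed,
    }
    return adata


def make_transfer_pair(
    n_ref: int = 300,
    n_query: int = 300,
    n_types: int = 3,
    n_ref_features: int = 20,
    n_shared: int = 10,
    separation: float = 6.0,
    noise_sigma: float = 1.0,
    baseline: float = 5.0,
    seed: int = 0,
) -> tuple[FeatureSet, FeatureSet, pd.Series, FeatureBridge]:
    """Reference/query pair with Gaussian label clusters in a shared space.

    Cluster means are placed so that every pair of types is ``separation``
    noise-σ apart within the shared feature subspace. The reference carries
    all ``n_ref_features`` features (named ``gene_i``); the query observes
    only the ``n_shared`` shared features under protein-style names
    (``protein_i``), linked to the reference by the returned bridge. Values
    are clipped at 0 to stay count-like. Returns (reference, query,
    query truth labels, bridge).
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if n_shared > n_ref_features:
        raise ValueError("shared features cannot exceed reference features")
    if n_types > n_shared and separation > 0:
        raise ValueError("need n_shared >= n_types to separate the clusters")
    rng = np.random.default_rng(seed)

    # one-hot cluster signatures in the shared subspace: pairwise distance
    # scale * sqrt(2); scale chosen so that distance = separation * sigma
    scale = separation * noise_sigma / np.sqrt(2.0)
    means = np.zeros((n_types, n_ref_features))
    for t in range(n_types):
        means[t, t % n_shared] = scale

    ref_types = rng.integers(0, n_types, n_ref)
    query_types = rng.integers(0, n_types, n_query)
    ref_X = baseline + means[ref_types] + rng.normal(0, noise_sigma, (n_ref, n_ref_features))
    q_full = baseline + means[query_types] + rng.normal(
        0, noise_sigma, (n_query, n_ref_features)
    )
    ref_X = np.clip(ref_X, 0, None)
    q_full = np.clip(q_full, 0, None)

    gene_names = [f"gene_{i}" for i in range(n_ref_features)]
    protein_names = [f"protein_{i}" for i in range(n_shared)]
    bridge = FeatureBridge(
        tuple((protein_names[i], gene_names[i]) for i in range(n_shared))
    )
    type_names = np.array([f"type_{t}" for t in range(n_types)])

    ref = FeatureSet(
        X=pd.DataFrame(ref_X, columns=gene_names,
                       index=[f"ref{i}" for i in range(n_ref)]),
        labels=pd.Series(type_names[ref_types],
                         index=[f"ref{i}" for i in range(n_ref)], name="label"),
    )
    query = FeatureSet(
        X=pd.DataFrame(q_full[:, :n_shared], columns=protein_names,
                       index=[f"q{i}" for i in range(n_query)]),
        samples=pd.Series("query_sample", index=[f"q{i}" for i in range(n_query)],
                          name="sample"),
    )
    truth = pd.Series(type_names[query_types], index=query.X.index, name="truth")
    return ref, query, truth, bridge
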