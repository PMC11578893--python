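"""Supervised pixel classification for bootstrapping compartment annotations.

A random-forest pixel classifier predicts compartment labels (e.g. cortex vs
medulla) over a whole multi-channel image from a handful of seed pixels —
typically spots that are high in a compartment marker. Per-pixel descriptors
are the raw channel intensities plus Gaussian-smoothed copies at a few
scales, so the forest can use local context as well as raw intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian
from sklearn.ensemble import RandomForestClassifier

from .raster import AnnotationRaster, AnnotationSchema

__all__ = ["PixelClassifier", "fit_pixel_classifier", "predict_pixel_labels"]

DEFAULT_SMOOTH_SCALES = (1.0, 2.0, 4.0)


def _pixel_features(image: np.ndarray, scales: tuple[float, ...]) -> np.ndarray:
    """Stack raw + smoothed channel intensities: (n_pixels, C * (1 + len(scales)))."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    chans = [image[..., c] for c in range(image.shape[-1])]
    feats = list(chans)
    for s in scales:
        for ch in chans:
            feats.append(gaussian(ch, sigma=s, preserve_range=True))
    return np.stack([f.ravel() for f in feats], axis=1)


@dataclass
class PixelClassifier:
    model: RandomForestClassifier
    scales: tuple[float, ...]
    n_channels: int


def fit_pixel_classifier(
    image: np.ndarray,
    seeds: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SMOOTH_SCALES,
    n_estimators: int = 50,
    seed: int = 0,
) -> PixelClassifier:
    """Train a random forest on seed pixels of a multi-channel image.

    Parameters
    ----------
    image
        (H, W) or (H, W, C) intensity image.
    seeds
        (H, W) integer array; nonzero values are training class codes.
    scales
        Gaussian smoothing sigmas (px) for context descriptors.
    seed
        RNG seed for the forest; identical seeds give identical predictions.
    """
    seeds = np.asarray(seeds)
    codes = np.unique(seeds[seeds != 0])
    if codes.size < 2:
        raise ValueError("need seed pixels from at least two classes to train")
    feats = _pixel_features(image, scales)
    idx = np.flatnonzero(seeds.ravel() != 0)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(feats[idx], seeds.ravel()[idx])
    n_channels = 1 if np.asarray(image).ndim == 2 else np.asarray(image).shape[-1]
    return PixelClassifier(model=model, scales=scales, n_channels=n_channels)


def predict_pixel_labels(
    clf: PixelClassifier,
    image: np.ndarray,
    ppm: float,
    schema: AnnotationSchema,
) -> AnnotationRaster:
    """Predict a dense label raster over every pixel of an image."""
    image = np.asarray(image)
    n_channels = 1 if image.ndim == 2 else image.shape[-1]
    if n_channels != clf.n_channels:
        raise ValueError(
            f"image has {n_channels} channel(s); classifier trained on "
            f"{clf.n_channels}"
        )
    feats = _pixel_features(image, clf.scales)
    shape = image.shape[:2]
    labels = clf.model.predict(feats).reshape(shape).astype(np.int64)
    return AnnotationRaster(pixels=labels, ppm=ppm, schema=schema)
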