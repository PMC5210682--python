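"""Raster-to-edge-map preprocessing.

Histology slides arrive as RGB rasters; box counting consumes binary edge
maps.  The default pipeline is deliberately parameter-free and deterministic:
Rec. 601 luminance -> Otsu (or fixed) threshold -> morphological inner
boundary.  A gradient-based ("canny") edge mode on the grayscale image is
available through the config for users who prefer a classical detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.feature import canny
from skimage.filters import threshold_otsu

# Rec. 601 luma coefficients
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PreprocessConfig:
    """Configuration for the raster -> binary edge-map pipeline.

    Keys mirror the config-file layout: ``binarize.method``,
    ``binarize.threshold``, ``edges.mode``, ``edges.connectivity``.
    """

    binarize_method: Literal["otsu", "fixed"] = "otsu"
    binarize_threshold: float | None = None
    edges_mode: Literal["binary_boundary", "canny"] = "binary_boundary"
    edges_connectivity: Literal[4, 8] = 4
    canny_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.binarize_method == "fixed":
            if self.binarize_threshold is None:
                raise ValueError("fixed binarization requires a threshold")
            if not 0.0 <= self.binarize_threshold <= 1.0:
                raise ValueError("threshold must lie in [0, 1]")
        if self.edges_connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a raster to single-channel luminance in [0, 1].

    Accepts 2-D grayscale, (H, W, 3) RGB or (H, W, 4) RGBA arrays with
    values in [0, 255] (integer) or [0, 1] (float).  Uses Rec. 601 weights
    0.299 R + 0.587 G + 0.114 B; the alpha channel, if any, is ignored.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty input")
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D raster, got ndim={arr.ndim}")
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer) or arr.max() > 1.0:
        arr = arr / 255.0
    if arr.ndim == 2:
        gray = arr
    else:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
        if arr.shape[2] == 1:
            gray = arr[:, :, 0]
        else:
            gray = arr[:, :, :3] @ _LUMA
    return np.clip(gray, 0.0, 1.0)


def binarize(
    image: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a grayscale image to {0, 1}.

    A pixel maps to 1 iff its intensity is *strictly* above the threshold.
    With ``method="otsu"`` the threshold maximizes between-class variance of
    the intensity histogram; a constant image degenerates the histogram, in
    which case an all-zero mask is returned with a warning.
    """
    gray = np.asarray(image, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if method == "fixed":
        if threshold is None or not 0.0 <= threshold <= 1.0:
            raise ValueError("fixed method requires threshold in [0, 1]")
        t = float(threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0.0:
            warnings.warn(
                "constant image: Otsu threshold is degenerate; returning all zeros",
                stacklevel=2,
            )
            return np.zeros_like(gray, dtype=np.uint8)
        t = float(threshold_otsu(gray))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return (gray > t).astype(np.uint8)


def detect_edges(image: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Morphological inner boundary of a binary mask.

    Output pixel = 1 iff it is foreground and at least one of its
    neighbours (4- or 8-neighbourhood) is background or lies outside the
    image.  The result is always a subset of the input foreground.
    """
    mask = np.asarray(image)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("detect_edges expects a {0,1} binary image")
    mask = mask.astype(bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    if connectivity == 8:
        interior &= (
            padded[:-2, :-2] & padded[:-2, 2:] & padded[2:, :-2] & padded[2:, 2:]
        )
    elif connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    return (mask & ~interior).astype(np.uint8)


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Raster -> binary edge map: grayscale, binarize, edge detect.

    With ``edges_mode="binary_boundary"`` (default) the edge detector is the
    inner boundary of the thresholded mask.  With ``edges_mode="canny"`` a
    gradient-magnitude + hysteresis detector runs on the grayscale image
    directly and the binarization step is skipped (the detector's output is
    already binary).
    """
    config = config or PreprocessConfig()
    gray = to_grayscale(image)
    if config.edges_mode == "canny":
        return canny(gray, sigma=config.canny_sigma).astype(np.uint8)
    mask = binarize(gray, method=config.binarize_method, threshold=config.binarize_threshold)
    return detect_edges(mask, connectivity=config.edges_connectivity)


class BinaryEdgePreprocessor:
    """Sklearn-style transformer mapping rasters to binary edge maps.

    Stateless (``fit`` is a no-op) but carries the pipeline configuration so
    it can sit at the front of an ``sklearn.pipeline.Pipeline``.

    Parameters
    ----------
    binarize_method : {"otsu", "fixed"}
    binarize_threshold : float or None
        Required iff ``binarize_method="fixed"``; in [0, 1].
    edges_mode : {"binary_boundary", "canny"}
    edges_connectivity : {4, 8}
    canny_sigma : float
        Gaussian width (px) of the gradient detector, canny mode only.
    """

    def __init__(
        self,
        binarize_method: str = "otsu",
        binarize_threshold: float | None = None,
        edges_mode: str = "binary_boundary",
        edges_connectivity: int = 4,
        canny_sigma: float = 1.0,
    ):
        self.binarize_method = binarize_method
        self.binarize_threshold = binarize_threshold
        self.edges_mode = edges_mode
        self.edges_connectivity = edges_connectivity
        self.canny_sigma = canny_sigma

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            binarize_method=self.binarize_method,
            binarize_threshold=self.binarize_threshold,
            edges_mode=self.edges_mode,
            edges_connectivity=self.edges_connectivity,
            canny_sigma=self.canny_sigma,
        )

    def fit(self, X, y=None):
        self._config()  # validate parameters
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else None
        return self

    def transform(self, X):
        """Apply the pipeline to a list of rasters; returns a list of masks."""
        cfg = self._config()
        return [preprocess(img, cfg) for img in X]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "binarize_method": self.binarize_method,
            "binarize_threshold": self.binarize_threshold,
            "edges_mode": self.edges_mode,
            "edges_connectivity": self.edges_connectivity,
            "canny_sigma": self.canny_sigma,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self
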