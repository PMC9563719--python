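"""Principal-component score images of a sample's ROI cube.

The 428-band cube is treated as 10^4 pixel observations of a 428-variable
spectrum; PCA compresses it to the first three score images (PC1-PC3), which
carry the spatial texture that the co-occurrence features are computed from.
PCA is fitted per sample on that sample's own ROI pixels; cross-sample
comparability of score signs is restored by a deterministic loading-sign
convention (the largest-magnitude element of every loading is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .cube_io import Hypercube

__all__ = ["PCImageStack", "pca_score_images", "quantize"]


@dataclass
class PCImageStack:
    """Score images plus the loadings and variance shares behind them."""

    images: np.ndarray            # (n_components, rows, cols)
    loadings: np.ndarray = field(repr=False)   # (n_components, n_bands), rows orthonormal
    explained_variance_ratio: np.ndarray = field(repr=False)
    sample_id: str = ""

    @property
    def n_components(self) -> int:
        return self.images.shape[0]


def pca_score_images(roi_cube: Hypercube, n_components: int = 3, sample_id: str = "") -> PCImageStack:
    """Project every pixel's spectrum onto the cube's leading principal axes.

    Pixels are the observations, bands the variables; the pixel matrix is
    mean-centred (not scaled) and decomposed via the Gram-matrix eigensolve,
    which is exact and fast for tall-thin pixel matrices. Components are
    ordered by decreasing explained variance.
    """
    rows, cols, bands = roi_cube.data.shape
    n_pixels = rows * cols
    if n_pixels <= n_components:
        raise ValueError(f"ROI has {n_pixels} pixels; need more than {n_components}")
    X = roi_cube.data.reshape(n_pixels, bands).astype(np.float64)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate cube: zero variance across pixels")
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # sign convention: largest-|.| element of each loading vector is positive
    for k in range(n_components):
        if loadings[k, np.argmax(np.abs(loadings[k]))] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCImageStack(
        images=np.ascontiguousarray(scores.T.reshape(n_components, rows, cols)),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        sample_id=sample_id,
    )


def quantize(image: np.ndarray, levels: int = 64) -> np.ndarray:
    """Linear min-max quantization to integer gray levels {0, ..., levels-1}.

    The minimum maps to 0, the maximum to levels-1 (the top edge is folded
    down so the max is not its own level); a constant image maps to level 0.
    Invariant under positive affine transforms of the input.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    np.clip(q, 0, levels - 1, out=q)
    return q
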