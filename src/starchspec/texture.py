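"""Gray-level co-occurrence matrix (GLCM) texture features of PC score images.

For each quantized score image a symmetric, normalized GLCM is accumulated at
distance 1 in the four standard directions (0°, 45°, 90°, 135°; rows increase
downward, so 45° points up-right). Four Haralick statistics are computed per
direction and averaged over directions:

    contrast    = Σ_ij (i - j)^2 p_ij
    correlation = Σ_ij (i - μ_i)(j - μ_j) p_ij / (σ_i σ_j)   (0 if σ_i σ_j = 0)
    entropy     = -Σ_{p_ij > 0} p_ij log2 p_ij               (bits)
    uniformity  = Σ_ij p_ij^2                                 (angular second moment)

With three PC images this yields the 12-feature texture vector per sample,
named ``{feature}_PC{k}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pc_imagery import PCImageStack, quantize

__all__ = [
    "GLCM",
    "TextureTable",
    "ANGLES",
    "FEATURE_NAMES",
    "texture_feature_names",
    "glcm",
    "glcm_features",
    "texture_vector",
]

ANGLES = (0, 45, 90, 135)
FEATURE_NAMES = ("correlation", "contrast", "entropy", "uniformity")

#: pixel offsets (drow, dcol) per direction, for distance 1 and rows downward
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    """Symmetric co-occurrence probability matrix at one offset."""

    P: np.ndarray
    distance: int = 1
    angle: int = 0

    @property
    def levels(self) -> int:
        return self.P.shape[0]


def glcm(image_q: np.ndarray, levels: int | None = None, distance: int = 1, angle: int = 0) -> GLCM:
    """Co-occurrence matrix of an integer image at one direction.

    Pairs (i at x, j at x + offset) are counted in both orders (symmetric)
    and normalized to sum 1.
    """
    image_q = np.asarray(image_q)
    if not np.issubdtype(image_q.dtype, np.integer):
        raise TypeError("glcm expects an integer (quantized) image")
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if levels is None:
        levels = int(image_q.max()) + 1
    if image_q.min() < 0 or image_q.max() >= levels:
        raise ValueError("image values outside [0, levels)")

    dr, dc = (o * distance for o in _OFFSETS[angle])
    rows, cols = image_q.shape
    if rows <= abs(dr) or cols <= abs(dc):
        raise ValueError(f"image {rows}x{cols} too small for offset ({dr}, {dc})")

    src_r = slice(max(0, -dr), rows - max(0, dr))
    src_c = slice(max(0, -dc), cols - max(0, dc))
    dst_r = slice(max(0, dr), rows - max(0, -dr))
    dst_c = slice(max(0, dc), cols - max(0, -dc))
    i = image_q[src_r, src_c].ravel()
    j = image_q[dst_r, dst_c].ravel()

    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetrize: count each pair in both orders
    P = counts / counts.sum()
    return GLCM(P, distance=distance, angle=angle)


def glcm_features(G: GLCM) -> dict[str, float]:
    """The four Haralick statistics of one GLCM (see module docstring)."""
    P = G.P
    levels = P.shape[0]
    idx = np.arange(levels, dtype=np.float64)
    p_i = P.sum(axis=1)  # symmetric GLCM: marginals coincide
    mu = float(idx @ p_i)
    var = float(((idx - mu) ** 2) @ p_i)

    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float(((ii - jj) ** 2 * P).sum())
    if var <= 0:
        correlation = 0.0
    else:
        correlation = float((((ii - mu) * (jj - mu)) * P).sum() / var)
    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    uniformity = float((P ** 2).sum())
    return {
        "correlation": correlation,
        "contrast": contrast,
        "entropy": entropy,
        "uniformity": uniformity,
    }


def texture_feature_names(n_components: int = 3) -> list[str]:
    return [f"{feat}_PC{k + 1}" for k in range(n_components) for feat in FEATURE_NAMES]


def texture_vector(stack: PCImageStack, levels: int = 64, distance: int = 1) -> np.ndarray:
    """12-feature texture vector of a PC image stack.

    Each score image is min-max quantized, its GLCM computed at the four
    directions, and each feature averaged over directions; PC blocks are
    concatenated in feature order correlation, contrast, entropy, uniformity.
    """
    out = []
    for k in range(stack.n_components):
        q = quantize(stack.images[k], levels=levels)
        acc = {name: 0.0 for name in FEATURE_NAMES}
        for angle in ANGLES:
            feats = glcm_features(glcm(q, levels=levels, distance=distance, angle=angle))
            for name in FEATURE_NAMES:
                acc[name] += feats[name]
        out.extend(acc[name] / len(ANGLES) for name in FEATURE_NAMES)
    return np.array(out)


@dataclass
class TextureTable:
    """n_samples x 12 texture-feature matrix with ``{feature}_PC{k}`` names."""

    T: np.ndarray
    feature_names: list[str] = field(default_factory=texture_feature_names)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = np.atleast_2d(np.asarray(self.T, dtype=np.float64))
        if self.T.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if self.sample_ids and len(self.sample_ids) != self.T.shape[0]:
            raise ValueError("row count does not match sample ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.T, columns=self.feature_names)
        if self.sample_ids:
            df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TextureTable":
        df = pd.read_csv(path)
        ids = []
        if df.columns[0] == "sample_id":
            ids = list(df["sample_id"].astype(str))
            df = df.iloc[:, 1:]
        return cls(df.to_numpy(float), list(df.columns), ids)
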