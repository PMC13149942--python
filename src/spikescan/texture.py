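"""Texture features of the spike body region.

10 gray-level co-occurrence (GLCM) and 6 gray-level run-length (GLRM)
features over the body pixels.  Luminance is the standard-definition
luma (0.299 R + 0.587 G + 0.114 B), quantized uniformly over the
region's min-max range; pixel pairs and runs crossing a non-region
pixel are excluded/truncated rather than filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix

from .errors import ValidationError
from .phantom import LABEL_BODY

__all__ = [
    "TextureConfig",
    "GLCMFeatures",
    "GLRMFeatures",
    "GLCM_FEATURE_NAMES",
    "GLRM_FEATURE_NAMES",
    "glcm_features",
    "glrm_features",
    "quantize_region",
]

GLCM_FEATURE_NAMES = (
    "contrast", "dissimilarity", "homogeneity", "ASM", "energy",
    "correlation", "entropy", "maximum_probability",
    "cluster_shade", "cluster_prominence",
)
GLRM_FEATURE_NAMES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE")

_MIN_REGION_PX = 64


@dataclass(frozen=True)
class TextureConfig:
    gray_levels: int = 32
    glcm_distance_px: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValidationError("gray_levels must be >= 2")
        if self.glcm_distance_px < 1:
            raise ValidationError("glcm_distance_px must be >= 1")
        if not self.directions or any(
            d not in (0, 45, 90, 135) for d in self.directions
        ):
            raise ValidationError("directions must be a subset of {0,45,90,135}")


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    ASM: float
    energy: float
    correlation: float
    entropy: float
    maximum_probability: float
    cluster_shade: float
    cluster_prominence: float
    constant_region: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f"glcm_{n}": getattr(self, n) for n in GLCM_FEATURE_NAMES}


@dataclass(frozen=True)
class GLRMFeatures:
    SRE: float  # short-run emphasis
    LRE: float  # long-run emphasis
    GLN: float  # gray-level non-uniformity
    RLN: float  # run-length non-uniformity
    RP: float  # run percentage
    LGRE: float  # low gray-level run emphasis
    constant_region: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f"glrm_{n}": getattr(self, n) for n in GLRM_FEATURE_NAMES}


def _luminance(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def quantize_region(
    image: np.ndarray, region: np.ndarray, gray_levels: int
) -> tuple[np.ndarray, bool]:
    """Quantize region luminance to [0, gray_levels) over its min-max range.

    Returns (level image with non-region pixels = -1, constant_flag).
    """
    lum = _luminance(image)
    vals = lum[region]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.full(region.shape, -1, dtype=np.int64)
    if hi == lo:
        levels[region] = 0
        return levels, True
    q = np.floor((lum - lo) / (hi - lo) * gray_levels).astype(np.int64)
    levels[region] = np.clip(q[region], 0, gray_levels - 1)
    return levels, False


def _region(mask: np.ndarray) -> np.ndarray:
    region = np.asarray(mask) == LABEL_BODY
    n = int(region.sum())
    if n < _MIN_REGION_PX:
        raise ValidationError(
            f"body region has {n} px (< {_MIN_REGION_PX}); too small for texture"
        )
    return region


def glcm_features(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> GLCMFeatures:
    """Haralick-style features of the pooled, normalized co-occurrence
    matrix of the body region.

    Non-region pixels are mapped to a sentinel level and all pairs
    touching it are dropped, so only pairs fully inside the region
    contribute.  Counts are pooled over the configured directions and
    symmetrized before normalization.
    """
    cfg = cfg or TextureConfig()
    region = _region(mask)
    levels, constant = quantize_region(image, region, cfg.gray_levels)

    g = cfg.gray_levels
    lvl = np.where(levels < 0, g, levels).astype(np.uint16)
    angles = [math.radians(a) for a in cfg.directions]
    counts = graycomatrix(
        lvl,
        distances=[cfg.glcm_distance_px],
        angles=angles,
        levels=g + 1,
        symmetric=cfg.symmetric,
        normed=False,
    )
    pooled = counts[:g, :g, 0, :].sum(axis=-1).astype(float)
    total = pooled.sum()
    if total == 0:
        raise ValidationError("no valid pixel pairs inside the region")
    p = pooled / total

    i = np.arange(g, dtype=float)[:, None]
    j = np.arange(g, dtype=float)[None, :]
    diff = i - j
    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    asm = float((p**2).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(g) * pi).sum())
    mu_j = float((np.arange(g) * pj).sum())
    var_i = float(((np.arange(g) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(g) - mu_j) ** 2 * pj).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (p * (i - mu_i) * (j - mu_j)).sum() / math.sqrt(var_i * var_j)
        )
    else:
        correlation = 0.0  # constant region convention
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    shade_arg = i + j - mu_i - mu_j
    return GLCMFeatures(
        contrast=contrast,
        dissimilarity=dissimilarity,
        homogeneity=homogeneity,
        ASM=asm,
        energy=math.sqrt(asm),
        correlation=correlation,
        entropy=entropy,
        maximum_probability=float(p.max()),
        cluster_shade=float((p * shade_arg**3).sum()),
        cluster_prominence=float((p * shade_arg**4).sum()),
        constant_region=constant,
    )


def _direction_lines(a: np.ndarray, direction: int) -> list[np.ndarray]:
    """1-D views of ``a`` along a scan direction (0/45/90/135 degrees)."""
    if direction == 0:
        return [a[r, :] for r in range(a.shape[0])]
    if direction == 90:
        return [a[:, c] for c in range(a.shape[1])]
    if direction == 45:
        b = np.fliplr(a)
    else:  # 135
        b = a
    h, w = b.shape
    return [np.diagonal(b, offset=o) for o in range(-(h - 1), w)]


def _accumulate_runs(
    line_levels: np.ndarray, line_region: np.ndarray, runs: dict[tuple[int, int], int]
) -> None:
    """Run-length encode one scan line, truncating at region boundaries."""
    n = len(line_levels)
    idx = 0
    while idx < n:
        if not line_region[idx]:
            idx += 1
            continue
        level = line_levels[idx]
        length = 1
        while (
            idx + length < n
            and line_region[idx + length]
            and line_levels[idx + length] == level
        ):
            length += 1
        key = (int(level), length)
        runs[key] = runs.get(key, 0) + 1
        idx += length


def glrm_features(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> GLRMFeatures:
    """Run-length features pooled over the configured scan directions."""
    cfg = cfg or TextureConfig()
    region = _region(mask)
    levels, constant = quantize_region(image, region, cfg.gray_levels)

    runs: dict[tuple[int, int], int] = {}
    for direction in cfg.directions:
        lvl_lines = _direction_lines(levels, direction)
        reg_lines = _direction_lines(region, direction)
        for lv, rg in zip(lvl_lines, reg_lines):
            _accumulate_runs(np.asarray(lv), np.asarray(rg), runs)

    n_runs = float(sum(runs.values()))
    n_px = float(region.sum())
    sre = lre = lgre = 0.0
    by_level: dict[int, float] = {}
    by_length: dict[int, float] = {}
    for (g_lvl, length), count in runs.items():
        sre += count / length**2
        lre += count * length**2
        lgre += count / (g_lvl + 1) ** 2
        by_level[g_lvl] = by_level.get(g_lvl, 0.0) + count
        by_length[length] = by_length.get(length, 0.0) + count
    gln = sum(v**2 for v in by_level.values()) / n_runs
    rln = sum(v**2 for v in by_length.values()) / n_runs
    return GLRMFeatures(
        SRE=sre / n_runs,
        LRE=lre / n_runs,
        GLN=gln,
        RLN=rln,
        RP=n_runs / (n_px * len(cfg.directions)),
        LGRE=lgre / n_runs,
        constant_region=constant,
    )
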