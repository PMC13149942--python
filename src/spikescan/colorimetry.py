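"""Color features of the spike body and awns.

Mean color components in four spaces (RGB, CIELAB, HSV, YCrCb — 12
characteristics per region) and the three dominant colors obtained by
k-means clustering of region pixels in RGB space.  Hue is averaged
circularly; YCrCb uses the standard-definition luma coefficients
(0.299/0.587/0.114); Lab assumes sRGB primaries with a D65 white point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv, rgb2lab, rgb2ycbcr
from sklearn.cluster import KMeans

from .errors import ValidationError
from .phantom import LABEL_AWN, LABEL_BODY
from .segmentation import Calibration

__all__ = [
    "MeanColorFeatures",
    "DominantColors",
    "MEAN_COLOR_COMPONENTS",
    "mean_colors",
    "dominant_colors",
    "region_pixels",
]

REGION_LABELS = {"body": LABEL_BODY, "awn": LABEL_AWN}

MEAN_COLOR_COMPONENTS = (
    "R", "G", "B", "L", "a", "b", "H", "S", "V", "Y", "Cr", "Cb",
)


@dataclass(frozen=True)
class MeanColorFeatures:
    """Mean color components of one region, native component scales.

    RGB in [0, 255]; Lab with L in [0, 100]; H in degrees [0, 360) with
    S, V in [0, 1]; YCrCb on the digital 8-bit scale (Y in [16, 235],
    chroma centred at 128).  All-NaN for an empty region.
    """

    region: str
    mean_R: float
    mean_G: float
    mean_B: float
    mean_L: float
    mean_a: float
    mean_b: float
    mean_H: float
    mean_S: float
    mean_V: float
    mean_Y: float
    mean_Cr: float
    mean_Cb: float

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.mean_R)

    def as_dict(self) -> dict[str, float]:
        spaces = {
            "R": "RGB", "G": "RGB", "B": "RGB",
            "L": "Lab", "a": "Lab", "b": "Lab",
            "H": "HSV", "S": "HSV", "V": "HSV",
            "Y": "YCrCb", "Cr": "YCrCb", "Cb": "YCrCb",
        }
        return {
            f"{self.region}_{spaces[c]}_{c}": getattr(self, f"mean_{c}")
            for c in MEAN_COLOR_COMPONENTS
        }

    def rgb_triple(self) -> tuple[float, float, float]:
        return (self.mean_R, self.mean_G, self.mean_B)


@dataclass(frozen=True)
class DominantColors:
    """Three RGB cluster centroids ordered by descending pixel share."""

    region: str
    centroids: np.ndarray  # (3, 3) float RGB
    proportions: np.ndarray  # (3,) summing to 1
    degenerate: bool = False  # fewer distinct colors than clusters requested

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroids", np.asarray(self.centroids, float))
        object.__setattr__(self, "proportions", np.asarray(self.proportions, float))
        if self.centroids.shape != (3, 3) or self.proportions.shape != (3,):
            raise ValidationError("DominantColors holds exactly 3 entries")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i in range(3):
            for j, ch in enumerate("RGB"):
                out[f"{self.region}_dom{i + 1}_{ch}"] = float(self.centroids[i, j])
            out[f"{self.region}_dom{i + 1}_prop"] = float(self.proportions[i])
        return out


def region_pixels(
    image: np.ndarray,
    mask: np.ndarray,
    region: str,
    cal: Calibration | None = None,
) -> np.ndarray:
    """Color-corrected float RGB pixels (N, 3) of a mask region."""
    if region not in REGION_LABELS:
        raise ValidationError(f"unknown region {region!r}")
    image = np.asarray(image)
    pix = image[np.asarray(mask) == REGION_LABELS[region]].astype(float)
    if cal is not None and pix.size:
        pix = cal.apply_color(pix)
    return pix.reshape(-1, 3)


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.deg2rad(angles_deg)
    mean = math.atan2(float(np.sin(rad).mean()), float(np.cos(rad).mean()))
    return math.degrees(mean) % 360.0


def mean_colors(
    image: np.ndarray,
    mask: np.ndarray,
    region: str = "body",
    cal: Calibration | None = None,
) -> MeanColorFeatures:
    """Average color components of a region in the four color spaces.

    An empty region yields a record of NaN ("missing") values rather
    than zeros, because black is a valid color.
    """
    pix = region_pixels(image, mask, region, cal)
    if len(pix) == 0:
        return MeanColorFeatures(region, *([float("nan")] * 12))

    unit = pix[None, :, :] / 255.0  # (1, N, 3) image for skimage converters
    lab = rgb2lab(unit)[0]
    hsv = rgb2hsv(unit)[0]
    ycbcr = rgb2ycbcr(unit)[0]  # columns Y, Cb, Cr

    return MeanColorFeatures(
        region=region,
        mean_R=float(pix[:, 0].mean()),
        mean_G=float(pix[:, 1].mean()),
        mean_B=float(pix[:, 2].mean()),
        mean_L=float(lab[:, 0].mean()),
        mean_a=float(lab[:, 1].mean()),
        mean_b=float(lab[:, 2].mean()),
        mean_H=_circular_mean_deg(hsv[:, 0] * 360.0),
        mean_S=float(hsv[:, 1].mean()),
        mean_V=float(hsv[:, 2].mean()),
        mean_Y=float(ycbcr[:, 0].mean()),
        mean_Cr=float(ycbcr[:, 2].mean()),
        mean_Cb=float(ycbcr[:, 1].mean()),
    )


def dominant_colors(
    image: np.ndarray,
    mask: np.ndarray,
    region: str = "body",
    k: int = 3,
    seed: int = 0,
    cal: Calibration | None = None,
) -> DominantColors:
    """The k (= 3) dominant region colors: seeded k-means centroids in
    RGB space, ordered by descending cluster share.

    With fewer than k distinct colors the degenerate clusters are
    merged: surviving centroids are duplicated with zero proportion and
    the ``degenerate`` flag is set.
    """
    if k != 3:
        raise ValidationError("the dominant-color contract fixes k = 3")
    pix = region_pixels(image, mask, region, cal)
    if len(pix) == 0:
        raise ValidationError(f"region {region!r} is empty")

    distinct = np.unique(pix, axis=0)
    k_eff = min(k, len(distinct))
    if k_eff == 1:
        centroid = pix.mean(axis=0)
        return DominantColors(
            region=region,
            centroids=np.tile(centroid, (3, 1)),
            proportions=np.array([1.0, 0.0, 0.0]),
            degenerate=True,
        )

    km = KMeans(n_clusters=k_eff, n_init=10, tol=1e-6, random_state=seed)
    assignments = km.fit_predict(pix)
    counts = np.bincount(assignments, minlength=k_eff).astype(float)
    order = np.argsort(-counts, kind="stable")
    centroids = km.cluster_centers_[order]
    props = counts[order] / counts.sum()

    degenerate = k_eff < k
    while len(centroids) < k:
        centroids = np.vstack([centroids, centroids[-1]])
        props = np.append(props, 0.0)
    return DominantColors(
        region=region,
        centroids=centroids,
        proportions=props,
        degenerate=degenerate,
    )
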