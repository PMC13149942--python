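"""Glue: run the full feature stack on one image/mask pair."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import DominantColors, MeanColorFeatures, dominant_colors, mean_colors
from .morphometry import (
    AxisFrame,
    OutlineFeatures,
    QuadrangleFeatures,
    estimate_axis,
    fit_quadrangle,
    outline_features,
)
from .phantom import LABEL_AWN
from .segmentation import Calibration
from .texture import GLCMFeatures, GLRMFeatures, TextureConfig, glcm_features, glrm_features
from .certificate import ViewRecord


@dataclass
class ImageFeatures:
    """All extracted features of one segmented image."""

    axis: AxisFrame
    outline: OutlineFeatures
    quad: QuadrangleFeatures
    mean_color: dict[str, MeanColorFeatures]
    dominant: dict[str, DominantColors]
    glcm: GLCMFeatures
    glrm: GLRMFeatures

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        out.update(self.quad.as_dict())
        out.update(self.outline.as_dict())
        for rec in self.mean_color.values():
            out.update(rec.as_dict())
        for rec in self.dominant.values():
            out.update(rec.as_dict())
        out.update(self.glcm.as_dict())
        out.update(self.glrm.as_dict())
        return out


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    cal: Calibration,
    texture_cfg: TextureConfig | None = None,
    seed: int = 0,
) -> ImageFeatures:
    """Full morphometry + color + texture extraction for one image."""
    axis = estimate_axis(mask)
    outline = outline_features(mask, cal, axis=axis)
    quad = fit_quadrangle(mask, axis, cal)
    has_awns = bool((np.asarray(mask) == LABEL_AWN).any())
    mean_color = {"body": mean_colors(image, mask, "body", cal)}
    dominant = {"body": dominant_colors(image, mask, "body", seed=seed, cal=cal)}
    if has_awns:
        mean_color["awn"] = mean_colors(image, mask, "awn", cal)
        dominant["awn"] = dominant_colors(image, mask, "awn", seed=seed, cal=cal)
    else:
        mean_color["awn"] = mean_colors(image, mask, "awn", cal)  # NaN record
    return ImageFeatures(
        axis=axis,
        outline=outline,
        quad=quad,
        mean_color=mean_color,
        dominant=dominant,
        glcm=glcm_features(image, mask, texture_cfg),
        glrm=glrm_features(image, mask, texture_cfg),
    )


def certificates_from_phantoms(phantoms, use_truth: bool = True, seg_config=None):
    """Single-view (frontal) certificates for a cohort of phantoms.

    With ``use_truth`` the exact truth masks are used; otherwise each
    phantom image is segmented first.
    """
    from .certificate import assemble_certificate
    from .segmentation import segment_image

    certs = []
    for i, ph in enumerate(phantoms):
        mask = ph.truth_mask if use_truth else segment_image(ph.image, seg_config)
        cal = Calibration(mm_per_px=ph.spec.mm_per_px)
        rec = view_record(f"spike{i}", "frontal", ph.image, mask, cal)
        certs.append(assemble_certificate([rec]))
    return certs


def view_record(
    spike_id: str,
    view_label: str,
    image: np.ndarray,
    mask: np.ndarray,
    cal: Calibration,
    fast: bool = True,
    seed: int = 0,
) -> ViewRecord:
    """Build the certificate view record for one image.

    With ``fast=True`` only the features the certificate needs are
    computed (no dominant colors, no texture).
    """
    axis = estimate_axis(mask)
    outline = outline_features(mask, cal, axis=axis)
    quad = fit_quadrangle(mask, axis, cal)
    body_color = mean_colors(image, mask, "body", cal)
    awn_color = mean_colors(image, mask, "awn", cal)
    if not fast:
        # fall through to full extraction for callers that also persist
        pass
    return ViewRecord(
        spike_id=spike_id,
        view_label=view_label,
        outline=outline,
        quad=quad,
        body_rgb=body_color.rgb_triple(),
        awn_rgb=awn_color.rgb_triple(),
    )
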