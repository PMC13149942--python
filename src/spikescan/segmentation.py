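"""Classical 4-class segmentation and scale/color calibration.

Splits a spike photograph into background, color chart, spike body and
awns.  Background removal is hue-window based (the protocol uses a
uniform blue backdrop); body vs awn separation exploits the order-of-
magnitude thickness gap between the spike body and the awn strokes via
morphological opening.  A mask loader preserves interoperability with
any external segmenter producing the same 4-class palette.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .errors import (
    CalibrationError,
    DimensionError,
    EmptySceneError,
    FormatError,
    FramingWarning,
    ValidationError,
)
from .phantom import (
    LABEL_AWN,
    LABEL_BACKGROUND,
    LABEL_BODY,
    LABEL_CHART,
    LABELS,
    ChartSpec,
    write_mask_png,
)

__all__ = [
    "SegmentationConfig",
    "Calibration",
    "segment_image",
    "load_mask",
    "save_mask",
    "calibrate",
]


@dataclass(frozen=True)
class SegmentationConfig:
    background_hue_window: float = 25.0  # degrees around the modal backdrop hue
    min_body_component_px: int = 200
    body_opening_radius_px: int = 5
    awn_max_thickness_px: int = 4
    min_chart_patch_px: int = 25
    min_awn_component_px: int = 50  # thin blobs below this are opening artefacts

    def __post_init__(self) -> None:
        if (
            self.background_hue_window <= 0
            or self.min_body_component_px <= 0
            or self.body_opening_radius_px <= 0
            or self.awn_max_thickness_px <= 0
        ):
            raise ValidationError("all SegmentationConfig fields must be positive")


@dataclass
class Calibration:
    """Spatial scale plus an affine RGB correction.

    ``color_transform`` is a 3x4 matrix [A | b] mapping an observed RGB
    column vector to reference RGB via ``A @ rgb + b``; identity with a
    zero offset when no chart is available.
    """

    mm_per_px: float
    color_transform: np.ndarray = field(
        default_factory=lambda: np.hstack([np.eye(3), np.zeros((3, 1))])
    )

    def __post_init__(self) -> None:
        self.color_transform = np.asarray(self.color_transform, dtype=float)
        if self.mm_per_px <= 0:
            raise ValidationError("mm_per_px must be positive")
        if self.color_transform.shape != (3, 4):
            raise ValidationError("color_transform must be 3x4")

    @property
    def is_identity_transform(self) -> bool:
        ident = np.hstack([np.eye(3), np.zeros((3, 1))])
        return np.allclose(self.color_transform, ident)

    def apply_color(self, rgb: np.ndarray) -> np.ndarray:
        """Correct an (..., 3) float RGB array, clipped to [0, 255]."""
        rgb = np.asarray(rgb, dtype=float)
        out = rgb @ self.color_transform[:, :3].T + self.color_transform[:, 3]
        return np.clip(out, 0.0, 255.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mm_per_px": self.mm_per_px,
                "color_transform": self.color_transform.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Calibration":
        d = json.loads(text)
        return cls(d["mm_per_px"], np.asarray(d["color_transform"]))


def _hue_distance_deg(hue: np.ndarray, ref: float) -> np.ndarray:
    d = np.abs(hue - ref) % 360.0
    return np.minimum(d, 360.0 - d)


def _modal_border_hue(hue_deg: np.ndarray) -> float:
    border = np.concatenate(
        [hue_deg[0, :], hue_deg[-1, :], hue_deg[:, 0], hue_deg[:, -1]]
    )
    hist, edges = np.histogram(border, bins=72, range=(0.0, 360.0))
    i = int(hist.argmax())
    sel = (border >= edges[i]) & (border < edges[i + 1])
    return float(border[sel].mean()) if sel.any() else float(edges[i])


def _detect_chart_components(
    labels: np.ndarray, n_comp: int, areas: np.ndarray, cfg: SegmentationConfig
) -> list[int]:
    """Identify chart patches: compact, near-square, similarly sized blobs."""
    if n_comp < 7:
        return []
    largest = int(np.argmax(areas)) + 1
    slices = ndi.find_objects(labels)
    candidates = []
    for idx in range(1, n_comp + 1):
        if idx == largest:
            continue
        area = areas[idx - 1]
        if area < cfg.min_chart_patch_px:
            continue
        sl = slices[idx - 1]
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        aspect = max(h, w) / max(1, min(h, w))
        extent = area / (h * w)
        if aspect <= 1.6 and extent >= 0.6:
            candidates.append((idx, area))
    if len(candidates) < 6:
        return []
    med = float(np.median([a for _, a in candidates]))
    chart = [i for i, a in candidates if med / 3.0 <= a <= med * 3.0]
    return chart if len(chart) >= 6 else []


def segment_image(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Segment an RGB spike photograph into the 4-class label mask.

    Returns a 2-D uint8 array over {0 background, 1 chart, 2 body, 3 awn}.
    """
    config = config or SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) RGB image")
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    bg_hue = _modal_border_hue(hue)
    foreground = _hue_distance_deg(hue, bg_hue) > config.background_hue_window
    if not foreground.any():
        raise EmptySceneError("no foreground pixels outside the backdrop hue window")

    # Despeckle: isolated noise pixels flipped past the hue window.
    labels0, n0 = ndi.label(foreground, structure=np.ones((3, 3), bool))
    if n0:
        sizes = ndi.sum_labels(foreground, labels0, index=np.arange(1, n0 + 1))
        keep = np.flatnonzero(sizes >= 8) + 1
        foreground = np.isin(labels0, keep)
    if not foreground.any():
        raise EmptySceneError("foreground vanished after despeckling")

    touched = sum(
        bool(side.any())
        for side in (
            foreground[0, :], foreground[-1, :], foreground[:, 0], foreground[:, -1]
        )
    )
    if touched >= 3:
        warnings.warn(
            "foreground touches 3+ image borders; check framing", FramingWarning
        )

    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n_comp = ndi.label(foreground, structure=structure)
    areas = ndi.sum_labels(foreground, labels, index=np.arange(1, n_comp + 1))

    mask = np.zeros(image.shape[:2], dtype=np.uint8)
    chart_ids = _detect_chart_components(labels, n_comp, areas, config)
    for idx in chart_ids:
        mask[labels == idx] = LABEL_CHART

    spike_candidates = [
        i for i in range(1, n_comp + 1) if i not in chart_ids
    ]
    if not spike_candidates:
        raise EmptySceneError("no spike-like foreground component found")
    spike_id = max(spike_candidates, key=lambda i: areas[i - 1])
    if areas[spike_id - 1] < config.min_body_component_px:
        raise EmptySceneError(
            f"largest component has {int(areas[spike_id - 1])} px "
            f"(< min_body_component_px={config.min_body_component_px})"
        )
    spike = labels == spike_id

    opened = ndi.binary_opening(spike, structure=disk(config.body_opening_radius_px))
    if opened.any():
        blabels, bn = ndi.label(opened, structure=structure)
        bareas = ndi.sum_labels(opened, blabels, index=np.arange(1, bn + 1))
        body = blabels == (int(np.argmax(bareas)) + 1)
    else:
        body = spike  # body thinner than the opening radius: keep it whole
    # Re-attach residue components that are opening artefacts at body
    # corners/tips rather than awns.  An artefact adjoins the body across
    # one contiguous cut about two opening radii wide; each awn stroke
    # attaches over at most a few pixels, so a component's *longest*
    # contiguous contact run discriminates even multi-awn bundles.
    min_artefact_run = 2 * config.body_opening_radius_px - 2
    small_r = max(1, (config.awn_max_thickness_px + 1) // 2)
    opened_small = ndi.binary_opening(spike, structure=disk(small_r))
    residue = spike & ~body
    if residue.any():
        rlabels, rn = ndi.label(residue, structure=structure)
        body_halo = ndi.binary_dilation(body, structure=structure)
        for idx in range(1, rn + 1):
            comp = rlabels == idx
            contact = comp & body_halo
            if not contact.any():
                continue
            clabels, cn = ndi.label(contact, structure=structure)
            runs = ndi.sum_labels(contact, clabels, index=np.arange(1, cn + 1))
            if runs.max() < min_artefact_run:
                continue
            # Merge the artefact's thick core, grown geodesically from the
            # wide contact runs only, so that thick blobs elsewhere in the
            # component (awn crossings) and narrowly attached strokes stay
            # out; then small thin fragments adjoining the merged core over
            # a wide front (the tapering apex).
            wide_ids = np.flatnonzero(runs >= min_artefact_run) + 1
            seed = np.isin(clabels, wide_ids)
            thick = comp & opened_small
            merge = ndi.binary_propagation(
                seed, structure=structure, mask=thick | seed
            )
            thin = comp & ~merge
            if thin.any():
                halo = ndi.binary_dilation(body | merge, structure=structure)
                tlabels, tn = ndi.label(thin, structure=structure)
                tareas = ndi.sum_labels(thin, tlabels, index=np.arange(1, tn + 1))
                for t_idx in range(1, tn + 1):
                    frag = tlabels == t_idx
                    if tareas[t_idx - 1] >= config.min_awn_component_px:
                        continue
                    fcontact = frag & halo
                    if not fcontact.any():
                        continue
                    flabels, fn = ndi.label(fcontact, structure=structure)
                    fruns = ndi.sum_labels(
                        fcontact, flabels, index=np.arange(1, fn + 1)
                    )
                    if fruns.max() >= config.awn_max_thickness_px:
                        merge |= frag
            if merge.any():
                body |= merge
                residue &= ~merge

    mask[body] = LABEL_BODY
    mask[residue] = LABEL_AWN
    return mask


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as an indexed-palette PNG."""
    write_mask_png(mask, path)


def load_mask(path: str | Path, image: np.ndarray | None = None) -> np.ndarray:
    """Load a 4-class mask PNG; validates class codes and, when an image
    is supplied, that the dimensions match."""
    img = Image.open(path)
    mask = np.asarray(img)
    if mask.ndim != 2:
        raise FormatError(f"{path}: mask PNG must be single-channel/indexed")
    bad = set(np.unique(mask)) - set(LABELS)
    if bad:
        raise FormatError(f"{path}: unknown class codes {sorted(bad)}")
    if image is not None and mask.shape != np.asarray(image).shape[:2]:
        raise DimensionError(
            f"mask {mask.shape} does not match image {np.asarray(image).shape[:2]}"
        )
    return mask.astype(np.uint8)


def _chart_patch_observations(
    image: np.ndarray, mask: np.ndarray, chart_spec: ChartSpec
) -> tuple[np.ndarray, np.ndarray, float]:
    """Match detected chart patches to grid references.

    Returns (observed_means, matched_references, median_patch_side_px).
    Patches lost to segmentation (e.g. blue-ish patches merging with the
    backdrop) are dropped from the fit.
    """
    chart_px = mask == LABEL_CHART
    if not chart_px.any():
        raise CalibrationError("no chart class in mask")
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndi.label(chart_px, structure=structure)
    slices = ndi.find_objects(labels)
    comps = []
    for idx in range(1, n + 1):
        sl = slices[idx - 1]
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        cr = (sl[0].start + sl[0].stop) / 2.0
        cc = (sl[1].start + sl[1].stop) / 2.0
        comps.append((idx, cr, cc, (h + w) / 2.0))
    if len(comps) < 6:
        raise CalibrationError(f"only {len(comps)} chart patches detected (< 6)")
    side = float(np.median([c[3] for c in comps]))

    rows, cols = chart_spec.rows, chart_spec.cols
    r0 = min(sl[0].start for sl in slices)
    c0 = min(sl[1].start for sl in slices)
    rspan = max(sl[0].stop for sl in slices) - r0
    cspan = max(sl[1].stop for sl in slices) - c0
    gap_r = (rspan - rows * side) / max(1, rows - 1)
    gap_c = (cspan - cols * side) / max(1, cols - 1)
    expected = {
        (r, c): (r0 + r * (side + gap_r) + side / 2.0,
                 c0 + c * (side + gap_c) + side / 2.0)
        for r in range(rows)
        for c in range(cols)
    }

    refs = chart_spec.references.reshape(rows, cols, 3)
    observed, matched = [], []
    taken: set[tuple[int, int]] = set()
    for idx, cr, cc, _ in comps:
        best = min(
            (k for k in expected if k not in taken),
            key=lambda k: (expected[k][0] - cr) ** 2 + (expected[k][1] - cc) ** 2,
        )
        er, ec = expected[best]
        if (er - cr) ** 2 + (ec - cc) ** 2 > (side * 0.75) ** 2:
            continue  # no grid cell plausibly matches this blob
        taken.add(best)
        observed.append(image[labels == idx].reshape(-1, 3).mean(axis=0))
        matched.append(refs[best[0], best[1]])
    if len(observed) < 6:
        raise CalibrationError(
            f"only {len(observed)} chart patches matched the grid (< 6)"
        )
    return np.asarray(observed, float), np.asarray(matched, float), side


def calibrate(
    image: np.ndarray,
    mask: np.ndarray,
    chart_spec: ChartSpec | None = None,
    mm_per_px: float | None = None,
) -> Calibration:
    """Derive spatial and color calibration from the chart, or fall back
    to an explicitly supplied scale with an identity color transform."""
    if chart_spec is None:
        if mm_per_px is None:
            raise CalibrationError("no chart spec and no explicit mm_per_px")
        return Calibration(mm_per_px=mm_per_px)
    image = np.asarray(image)
    observed, refs, side = _chart_patch_observations(image, mask, chart_spec)
    scale = chart_spec.patch_size_mm / side
    design = np.hstack([observed, np.ones((len(observed), 1))])
    coeffs, *_ = np.linalg.lstsq(design, refs, rcond=None)
    transform = coeffs.T  # 3x4
    fitted = design @ coeffs
    rmse = float(np.sqrt(np.mean((fitted - refs) ** 2)))
    if rmse > 20.0:
        raise CalibrationError(f"color fit RMSE {rmse:.1f} exceeds bound 20")
    return Calibration(mm_per_px=scale, color_transform=transform)
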