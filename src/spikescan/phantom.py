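"""Synthetic spike-image generator with exact per-pixel ground truth.

Images emulate the single-spike acquisition protocol: a spike placed
vertically against a uniform blue backdrop, with thin awn strokes and an
optional color-reference chart in the frame.  The generator is a pure
function of (spec, seed): the same spec always yields a bit-identical
image and label mask, so every downstream stage can be tested against
known truth without real photographs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation

from .errors import SizingError, ValidationError

LABEL_BACKGROUND = 0
LABEL_CHART = 1
LABEL_BODY = 2
LABEL_AWN = 3
LABELS = (LABEL_BACKGROUND, LABEL_CHART, LABEL_BODY, LABEL_AWN)

#: Palette used when the 4-class mask is written as an indexed PNG.
MASK_PALETTE = {
    LABEL_BACKGROUND: (40, 40, 120),
    LABEL_CHART: (200, 60, 200),
    LABEL_BODY: (120, 220, 80),
    LABEL_AWN: (240, 220, 60),
}

#: sRGB reference values of the 24 patches of a classic 4x6 color
#: rendition chart, row-major.
COLORCHECKER_CLASSIC_SRGB = (
    (115, 82, 68), (194, 150, 130), (98, 122, 157), (87, 108, 67),
    (133, 128, 177), (103, 189, 170),
    (214, 126, 44), (80, 91, 166), (193, 90, 99), (94, 60, 108),
    (157, 188, 64), (224, 163, 46),
    (56, 61, 150), (70, 148, 73), (175, 54, 60), (231, 199, 31),
    (187, 86, 149), (8, 133, 161),
    (243, 243, 242), (200, 200, 200), (160, 160, 160), (122, 122, 121),
    (85, 85, 85), (52, 52, 52),
)

_MAX_CANVAS_PX = 6000


@dataclass(frozen=True)
class ChartSpec:
    """A grid of reference color patches rendered into the frame."""

    patch_grid: tuple[tuple[tuple[int, int, int], ...], ...] = ()
    patch_size_mm: float = 10.0
    position_px: tuple[int, int] | None = None  # (row, col) of top-left; auto if None
    gap_px: int | None = None  # inter-patch gap; auto (~side/5) if None

    def __post_init__(self) -> None:
        if not self.patch_grid:
            grid = tuple(
                tuple(COLORCHECKER_CLASSIC_SRGB[r * 6 + c] for c in range(6))
                for r in range(4)
            )
            object.__setattr__(self, "patch_grid", grid)
        if self.patch_size_mm <= 0:
            raise ValidationError("patch_size_mm must be positive")

    @property
    def rows(self) -> int:
        return len(self.patch_grid)

    @property
    def cols(self) -> int:
        return len(self.patch_grid[0])

    @property
    def references(self) -> np.ndarray:
        """Reference RGB triples, row-major, shape (rows*cols, 3)."""
        return np.array(
            [p for row in self.patch_grid for p in row], dtype=float
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters of one synthetic spike image."""

    body_length_mm: float = 90.0
    body_max_width_mm: float = 16.0
    width_position_rel: float = 0.4
    body_profile: str = "kite"  # "kite" | "smooth_lanceolate"
    body_rgb: tuple[int, int, int] = (172, 156, 92)
    awn_count: int = 12
    awn_length_mm: float = 25.0
    awn_width_px: int = 2
    awn_rgb: tuple[int, int, int] = (210, 190, 110)
    background_rgb: tuple[int, int, int] = (20, 40, 230)
    chart: ChartSpec | None = None
    mm_per_px: float = 0.2
    rotation_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_length_mm <= 0 or self.body_max_width_mm <= 0:
            raise ValidationError("body dimensions must be positive")
        if self.body_max_width_mm >= self.body_length_mm:
            raise ValidationError("spikes are elongated: require width < length")
        if not 0.0 < self.width_position_rel < 1.0:
            raise ValidationError("width_position_rel must lie in (0, 1)")
        if self.body_profile not in ("kite", "smooth_lanceolate"):
            raise ValidationError(f"unknown body_profile {self.body_profile!r}")
        if self.awn_count < 0:
            raise ValidationError("awn_count must be non-negative")
        if self.awn_length_mm < 0:
            raise ValidationError("awn_length_mm must be non-negative")
        if self.awn_width_px < 1:
            raise ValidationError("awn_width_px must be a positive integer")
        if self.mm_per_px <= 0:
            raise ValidationError("mm_per_px must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.chart is not None:
            bg = np.asarray(self.background_rgb)
            for patch in self.chart.references:
                if np.array_equal(patch, bg):
                    raise ValidationError(
                        "chart patch color equal to background color"
                    )

    # --- analytic ground truth -------------------------------------------

    @property
    def kite_area_mm2(self) -> float:
        """Exact body area of the kite profile: half product of diagonals."""
        return self.body_length_mm * self.body_max_width_mm / 2.0

    def width_at(self, t: float | np.ndarray) -> np.ndarray:
        """Ground-truth full body width (mm) at relative axis position t."""
        t = np.asarray(t, dtype=float)
        w, p = self.body_max_width_mm, self.width_position_rel
        if self.body_profile == "kite":
            return np.where(t <= p, w * t / p, w * (1.0 - t) / (1.0 - p))
        gamma = math.log(0.5) / math.log(p)
        return w * np.sin(np.pi * np.clip(t, 0.0, 1.0) ** gamma)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        if d.get("chart") is not None:
            c = d["chart"]
            c["patch_grid"] = tuple(
                tuple(tuple(p) for p in row) for row in c["patch_grid"]
            )
            if c.get("position_px") is not None:
                c["position_px"] = tuple(c["position_px"])
            d["chart"] = ChartSpec(**c)
        for key in ("body_rgb", "awn_rgb", "background_rgb"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Phantom:
    """A rendered synthetic spike: image, exact label mask, resolved spec."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) uint8, values in LABELS
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValidationError("image and truth_mask dimensions differ")

    @property
    def body_area_mm2(self) -> float:
        """Body area from the truth mask, in mm^2."""
        return float(
            (self.truth_mask == LABEL_BODY).sum() * self.spec.mm_per_px**2
        )

    @property
    def awn_area_mm2(self) -> float:
        return float(
            (self.truth_mask == LABEL_AWN).sum() * self.spec.mm_per_px**2
        )


def _body_polygon(spec: PhantomSpec) -> np.ndarray:
    """Body outline vertices (row, col) with the base at the origin.

    The axis runs base -> tip, tilted ``rotation_deg`` from vertical
    (image rows decrease toward the tip).
    """
    mmpp = spec.mm_per_px
    length = spec.body_length_mm / mmpp
    theta = math.radians(spec.rotation_deg)
    u = np.array([-math.cos(theta), math.sin(theta)])  # base -> tip
    n = np.array([u[1], -u[0]])  # unit normal

    if spec.body_profile == "kite":
        half = spec.body_max_width_mm / 2.0 / mmpp
        lat = spec.width_position_rel * length
        pts = [
            np.zeros(2),
            lat * u + half * n,
            length * u,
            lat * u - half * n,
        ]
        return np.array(pts)

    ts = np.linspace(0.0, 1.0, 257)
    halves = spec.width_at(ts) / 2.0 / mmpp
    right = ts[:, None] * length * u + halves[:, None] * n
    left = ts[::-1, None] * length * u - halves[::-1, None] * n
    return np.vstack([right, left])


def _awn_segments(
    spec: PhantomSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Straight awn strokes from the upper half of the body boundary."""
    mmpp = spec.mm_per_px
    length = spec.body_length_mm / mmpp
    awn_len = spec.awn_length_mm / mmpp
    theta = math.radians(spec.rotation_deg)
    u = np.array([-math.cos(theta), math.sin(theta)])
    n = np.array([u[1], -u[0]])
    segments = []
    for _ in range(spec.awn_count):
        t = rng.uniform(0.55, 0.92)
        side = 1.0 if rng.random() < 0.5 else -1.0
        half = float(spec.width_at(t)) / 2.0 / mmpp
        start = t * length * u + side * half * n
        tilt = math.radians(side * rng.uniform(25.0, 60.0))
        ca, sa = math.cos(tilt), math.sin(tilt)
        direction = np.array(
            [ca * u[0] - sa * u[1], sa * u[0] + ca * u[1]]
        )
        segments.append((start, start + awn_len * direction))
    return segments


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a spike phantom; pure function of (spec, spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    mmpp = spec.mm_per_px

    body_pts = _body_polygon(spec)
    segments = _awn_segments(spec, rng)

    pts = [body_pts]
    for a, b in segments:
        pts.append(np.vstack([a, b]))
    all_pts = np.vstack(pts)
    margin = 12 + spec.awn_width_px
    rmin = math.floor(all_pts[:, 0].min()) - margin
    rmax = math.ceil(all_pts[:, 0].max()) + margin
    cmin = math.floor(all_pts[:, 1].min()) - margin
    cmax = math.ceil(all_pts[:, 1].max()) + margin

    chart_geom = None
    chart = spec.chart
    if chart is not None:
        side = max(2, round(chart.patch_size_mm / mmpp))
        gap = chart.gap_px if chart.gap_px is not None else max(2, side // 5)
        if chart.position_px is None:
            origin = (rmin + margin, cmax + 10)
        else:
            origin = chart.position_px
        width = chart.cols * side + (chart.cols - 1) * gap
        height = chart.rows * side + (chart.rows - 1) * gap
        rmin = min(rmin, origin[0] - margin)
        cmin = min(cmin, origin[1] - margin)
        rmax = max(rmax, origin[0] + height + margin)
        cmax = max(cmax, origin[1] + width + margin)
        chart_geom = (origin, side, gap)

    h, w = rmax - rmin, cmax - cmin
    if h > _MAX_CANVAS_PX or w > _MAX_CANVAS_PX:
        raise SizingError(
            f"required canvas {h}x{w} exceeds {_MAX_CANVAS_PX} px; "
            "increase mm_per_px or shrink the spec"
        )
    offset = np.array([rmin, cmin], dtype=float)

    mask = np.zeros((h, w), dtype=np.uint8)

    shifted = body_pts - offset
    rr, cc = draw_polygon(shifted[:, 0], shifted[:, 1], shape=mask.shape)
    mask[rr, cc] = LABEL_BODY

    if segments:
        awn_canvas = np.zeros_like(mask, dtype=bool)
        for a, b in segments:
            a = a - offset
            b = b - offset
            rr, cc = draw_line(
                int(round(a[0])), int(round(a[1])),
                int(round(b[0])), int(round(b[1])),
            )
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            awn_canvas[rr[keep], cc[keep]] = True
        if spec.awn_width_px > 1:
            foot = np.ones((spec.awn_width_px, spec.awn_width_px), dtype=bool)
            awn_canvas = dilation(awn_canvas, foot)
        mask[awn_canvas & (mask == LABEL_BACKGROUND)] = LABEL_AWN

    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = np.asarray(spec.background_rgb, dtype=np.uint8)
    image[mask == LABEL_BODY] = spec.body_rgb
    image[mask == LABEL_AWN] = spec.awn_rgb

    resolved = spec
    if chart_geom is not None:
        (orow, ocol), side, gap = chart_geom
        orow, ocol = orow - rmin, ocol - cmin
        for r in range(chart.rows):
            for c in range(chart.cols):
                r0 = orow + r * (side + gap)
                c0 = ocol + c * (side + gap)
                mask[r0 : r0 + side, c0 : c0 + side] = LABEL_CHART
                image[r0 : r0 + side, c0 : c0 + side] = chart.patch_grid[r][c]
        resolved = dataclasses.replace(
            spec,
            chart=dataclasses.replace(
                chart, position_px=(int(orow), int(ocol)), gap_px=int(gap)
            ),
        )

    if spec.noise_sd > 0:
        noisy = image.astype(float) + rng.normal(0.0, spec.noise_sd, image.shape)
        image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    return Phantom(image=image, truth_mask=mask, spec=resolved)


#: Spec fields that cohort jitter may perturb, with their value kind.
_JITTERABLE: dict[str, str] = {
    "body_length_mm": "float",
    "body_max_width_mm": "float",
    "width_position_rel": "float",
    "awn_count": "int",
    "awn_length_mm": "float",
    "noise_sd": "float",
    "body_rgb": "rgb",
    "awn_rgb": "rgb",
}


def draw_cohort_specs(
    n: int,
    base_spec: PhantomSpec,
    jitter: Mapping[str, float] | None,
    seed: int,
) -> list[PhantomSpec]:
    """Draw ``n`` specs around ``base_spec`` with per-field relative sd."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    jitter = dict(jitter or {})
    for name, sd in jitter.items():
        if name not in _JITTERABLE:
            raise ValidationError(f"cannot jitter field {name!r}")
        if sd < 0:
            raise ValidationError(f"negative jitter for field {name!r}")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        changes: dict[str, object] = {}
        for name, sd in jitter.items():
            kind = _JITTERABLE[name]
            base = getattr(base_spec, name)
            if kind == "rgb":
                vals = np.asarray(base, dtype=float)
                drawn = vals * (1.0 + rng.normal(0.0, sd, size=3))
                changes[name] = tuple(
                    int(v) for v in np.clip(np.rint(drawn), 0, 255)
                )
            elif kind == "int":
                drawn = base * (1.0 + rng.normal(0.0, sd))
                changes[name] = max(0, int(round(drawn)))
            else:
                changes[name] = float(base * (1.0 + rng.normal(0.0, sd)))
        if "width_position_rel" in changes:
            changes["width_position_rel"] = float(
                np.clip(changes["width_position_rel"], 0.05, 0.95)
            )
        changes["seed"] = int(rng.integers(0, 2**31 - 1))
        specs.append(dataclasses.replace(base_spec, **changes))
    return specs


def generate_cohort(
    n: int,
    base_spec: PhantomSpec,
    jitter: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[Phantom]:
    """Render ``n`` phantoms drawn around ``base_spec``.

    The drawn per-phantom specs travel with the phantoms (``Phantom.spec``)
    as ground truth.
    """
    return [generate_phantom(s) for s in draw_cohort_specs(n, base_spec, jitter, seed)]


# --- persistence ---------------------------------------------------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a 4-class label mask as an indexed-palette PNG."""
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for code in LABELS:
        palette.extend(MASK_PALETTE[code])
    img.putpalette(palette)
    img.save(path)


def write_phantom(phantom: Phantom, out_dir: str | Path, stem: str = "phantom") -> dict[str, Path]:
    """Persist image (PNG), truth mask (indexed PNG) and spec (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "mask": out_dir / f"{stem}.mask.png",
        "spec": out_dir / f"{stem}.json",
    }
    Image.fromarray(phantom.image).save(paths["image"])
    write_mask_png(phantom.truth_mask, paths["mask"])
    paths["spec"].write_text(phantom.spec.to_json())
    return paths
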