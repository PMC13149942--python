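import numpy as np
import pytest

from spikescan import Calibration, PhantomSpec, generate_phantom
from spikescan.phantom import LABEL_BODY, ChartSpec


@pytest.fixture(scope="session")
def kite_spec():
    return PhantomSpec(
        body_length_mm=100.0,
        body_max_width_mm=20.0,
        width_position_rel=0.3,
        awn_count=0,
        noise_sd=0.0,
        mm_per_px=0.2,
        seed=1,
    )


@pytest.fixture(scope="session")
def kite_phantom(kite_spec):
    return generate_phantom(kite_spec)


@pytest.fixture(scope="session")
def awned_phantom():
    return generate_phantom(PhantomSpec(noise_sd=4.0, seed=7))


@pytest.fixture(scope="session")
def chart_phantom():
    return generate_phantom(PhantomSpec(chart=ChartSpec(), noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def cal02():
    return Calibration(mm_per_px=0.2)


@pytest.fixture()
def uniform_body_image():
    """A 40x60 all-body scene with a uniform color."""
    image = np.full((40, 60, 3), 0, dtype=np.uint8)
    image[..., 0] = 120
    image[..., 1] = 110
    image[..., 2] = 60
    mask = np.full((40, 60), LABEL_BODY, dtype=np.uint8)
    return image, mask


def paint_three_colors(phantom, colors, proportions):
    """Repaint the phantom body in planted color blocks (exact counts).

    Returns (image, exact_proportions) — the realized proportions after
    integer splitting, for oracle comparison.
    """
    image = phantom.image.copy()
    coords = np.argwhere(phantom.truth_mask == LABEL_BODY)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    n = len(coords)
    counts = [int(round(p * n)) for p in proportions[:-1]]
    counts.append(n - sum(counts))
    start = 0
    for color, count in zip(colors, counts):
        sel = coords[start : start + count]
        image[sel[:, 0], sel[:, 1]] = color
        start += count
    return image, np.array(counts, dtype=float) / n
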