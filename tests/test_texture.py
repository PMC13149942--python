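import math

import numpy as np
import pytest

from spikescan import TextureConfig, glcm_features, glrm_features
from spikescan.errors import ValidationError
from spikescan.phantom import LABEL_BODY
from spikescan.texture import GLCM_FEATURE_NAMES, GLRM_FEATURE_NAMES


def body_scene(values):
    """Wrap a 2-D uint8 luminance patch as a gray RGB image + body mask."""
    values = np.asarray(values, dtype=np.uint8)
    image = np.stack([values] * 3, axis=-1)
    mask = np.full(values.shape, LABEL_BODY, dtype=np.uint8)
    return image, mask


def checkerboard(n=16):
    return (np.indices((n, n)).sum(axis=0) % 2) * 255


# --- independent brute-force oracle --------------------------------------

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels, region, gray_levels, directions, symmetric=True):
    """Enumerate all in-region neighbor pairs and compute the features."""
    h, w = levels.shape
    counts = np.zeros((gray_levels, gray_levels), dtype=float)
    for direction in directions:
        dr, dc = _OFFSETS[direction]
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < h and 0 <= c2 < w):
                    continue
                if not (region[r, c] and region[r2, c2]):
                    continue
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    p = counts / counts.sum()
    g = gray_levels
    out = {}
    i = np.arange(g)[:, None] * np.ones((1, g))
    j = i.T
    out["contrast"] = (p * (i - j) ** 2).sum()
    out["dissimilarity"] = (p * abs(i - j)).sum()
    out["homogeneity"] = (p / (1 + (i - j) ** 2)).sum()
    out["ASM"] = (p**2).sum()
    out["energy"] = math.sqrt(out["ASM"])
    pi, pj = p.sum(1), p.sum(0)
    mi = (np.arange(g) * pi).sum()
    mj = (np.arange(g) * pj).sum()
    vi = (((np.arange(g) - mi) ** 2) * pi).sum()
    vj = (((np.arange(g) - mj) ** 2) * pj).sum()
    out["correlation"] = (
        (p * (i - mi) * (j - mj)).sum() / math.sqrt(vi * vj) if vi > 0 and vj > 0 else 0.0
    )
    nz = p[p > 0]
    out["entropy"] = float(-(nz * np.log(nz)).sum())
    out["maximum_probability"] = p.max()
    out["cluster_shade"] = (p * (i + j - mi - mj) ** 3).sum()
    out["cluster_prominence"] = (p * (i + j - mi - mj) ** 4).sum()
    return out


def brute_glrm(levels, region, directions):
    """Enumerate maximal constant-level runs line by line."""
    h, w = levels.shape
    runs = []
    for direction in directions:
        dr, dc = _OFFSETS[direction]
        dr, dc = -dr, -dc  # walk forward along the scan direction
        starts = [
            (r, c)
            for r in range(h)
            for c in range(w)
            if not (0 <= r - dr < h and 0 <= c - dc < w)
        ]
        for r0, c0 in starts:
            r, c = r0, c0
            current = None
            length = 0
            while 0 <= r < h and 0 <= c < w:
                if region[r, c]:
                    if current == levels[r, c]:
                        length += 1
                    else:
                        if length:
                            runs.append((current, length))
                        current, length = levels[r, c], 1
                else:
                    if length:
                        runs.append((current, length))
                    current, length = None, 0
                r, c = r + dr, c + dc
            if length:
                runs.append((current, length))
    n_r = len(runs)
    n_px = int(region.sum())
    out = {
        "SRE": sum(1 / l**2 for _, l in runs) / n_r,
        "LRE": sum(l**2 for _, l in runs) / n_r,
        "GLN": sum(
            v**2
            for v in np.bincount([g for g, _ in runs])
        )
        / n_r,
        "RLN": sum(v**2 for v in np.bincount([l for _, l in runs])) / n_r,
        "RP": n_r / (n_px * len(directions)),
        "LGRE": sum(1 / (g + 1) ** 2 for g, _ in runs) / n_r,
    }
    return out


class TestGLCM:
    def test_constant_region(self):
        image, mask = body_scene(np.full((16, 16), 90))
        f = glcm_features(image, mask, TextureConfig(gray_levels=8))
        assert f.contrast == 0.0
        assert f.dissimilarity == 0.0
        assert f.homogeneity == 1.0
        assert f.ASM == 1.0
        assert f.energy == 1.0
        assert f.entropy == pytest.approx(0.0, abs=1e-15)
        assert f.maximum_probability == 1.0
        assert f.correlation == 0.0  # convention
        assert f.constant_region

    def test_checkerboard_horizontal(self):
        image, mask = body_scene(checkerboard())
        cfg = TextureConfig(gray_levels=2, directions=(0,))
        f = glcm_features(image, mask, cfg)
        assert f.contrast == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.ASM == pytest.approx(0.5)
        assert f.maximum_probability == pytest.approx(0.5)

    def test_region_too_small(self):
        image, mask = body_scene(np.full((7, 9), 10))
        with pytest.raises(ValidationError):
            glcm_features(image, mask, TextureConfig())

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(40, 200, size=(20, 20))
        image1, mask = body_scene(patch)
        image2, _ = body_scene(patch + 30)
        cfg = TextureConfig(gray_levels=8)
        f1 = glcm_features(image1, mask, cfg).as_dict()
        f2 = glcm_features(image2, mask, cfg).as_dict()
        for k in f1:
            assert f2[k] == pytest.approx(f1[k], abs=1e-9)

    def test_ten_features(self):
        image, mask = body_scene(checkerboard())
        f = glcm_features(image, mask, TextureConfig(gray_levels=2))
        assert len(f.as_dict()) == 10
        assert tuple(n.removeprefix("glcm_") for n in f.as_dict()) == GLCM_FEATURE_NAMES

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_patches(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 2, size=(16, 16)) * 255
        image, mask = body_scene(patch)
        levels = (patch > 0).astype(int)
        cfg = TextureConfig(gray_levels=2)
        ours = glcm_features(image, mask, cfg).as_dict()
        oracle = brute_glcm(levels, mask == LABEL_BODY, 2, cfg.directions)
        for name, value in oracle.items():
            assert ours[f"glcm_{name}"] == pytest.approx(value, abs=1e-9), name

    def test_matches_brute_force_with_irregular_mask(self):
        rng = np.random.default_rng(7)
        patch = rng.integers(0, 2, size=(16, 16)) * 255
        image, mask = body_scene(patch)
        holes = rng.random((16, 16)) < 0.2
        mask[holes] = 0
        if (mask == LABEL_BODY).sum() < 64:  # keep the precondition satisfied
            mask[:8, :8] = LABEL_BODY
        levels = (patch > 0).astype(int)
        cfg = TextureConfig(gray_levels=2)
        ours = glcm_features(image, mask, cfg).as_dict()
        oracle = brute_glcm(levels, mask == LABEL_BODY, 2, cfg.directions)
        for name, value in oracle.items():
            assert ours[f"glcm_{name}"] == pytest.approx(value, abs=1e-9), name

    def test_probability_matrix_sums_to_one_symmetric(self):
        # indirectly: ASM of a 2-level random patch stays in (0, 1]
        rng = np.random.default_rng(11)
        image, mask = body_scene(rng.integers(0, 256, size=(20, 20)))
        f = glcm_features(image, mask, TextureConfig(gray_levels=32))
        assert 0 < f.ASM <= 1
        assert f.energy == pytest.approx(math.sqrt(f.ASM))
        assert 0 < f.maximum_probability <= 1
        assert f.entropy >= 0


class TestGLRM:
    def test_constant_region_horizontal(self):
        w, h = 16, 12
        image, mask = body_scene(np.full((h, w), 50))
        cfg = TextureConfig(gray_levels=4, directions=(0,))
        f = glrm_features(image, mask, cfg)
        assert f.LRE == pytest.approx(w**2)
        assert f.RP == pytest.approx(1 / w)
        assert f.SRE == pytest.approx(1 / w**2)

    def test_checkerboard_all_unit_runs(self):
        # Axis-aligned scans only: along either diagonal a checkerboard is
        # constant (i+j parity is preserved), so diagonal runs are long.
        image, mask = body_scene(checkerboard())
        for direction in (0, 90):
            f = glrm_features(
                image, mask, TextureConfig(gray_levels=2, directions=(direction,))
            )
            assert f.SRE == pytest.approx(1.0)
            assert f.LRE == pytest.approx(1.0)
            assert f.RP == pytest.approx(1.0)

    def test_jensen_bound_sre_lre(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            image, mask = body_scene(rng.integers(0, 256, size=(18, 18)))
            f = glrm_features(image, mask, TextureConfig(gray_levels=4))
            assert f.SRE <= 1.0 + 1e-12
            assert f.LRE >= 1.0 - 1e-12
            assert 0 < f.RP <= 1.0

    def test_six_features(self):
        image, mask = body_scene(checkerboard())
        f = glrm_features(image, mask, TextureConfig(gray_levels=2))
        assert len(f.as_dict()) == 6
        assert tuple(n.removeprefix("glrm_") for n in f.as_dict()) == GLRM_FEATURE_NAMES

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_patches(self, seed):
        rng = np.random.default_rng(seed + 100)
        patch = rng.integers(0, 2, size=(16, 16)) * 255
        image, mask = body_scene(patch)
        levels = (patch > 0).astype(int)
        cfg = TextureConfig(gray_levels=2)
        ours = glrm_features(image, mask, cfg).as_dict()
        oracle = brute_glrm(levels, mask == LABEL_BODY, cfg.directions)
        for name, value in oracle.items():
            assert ours[f"glrm_{name}"] == pytest.approx(value, abs=1e-9), name

    def test_matches_brute_force_with_irregular_mask(self):
        rng = np.random.default_rng(42)
        patch = rng.integers(0, 2, size=(16, 16)) * 255
        image, mask = body_scene(patch)
        mask[rng.random((16, 16)) < 0.25] = 0
        mask[:8, :8] = LABEL_BODY
        levels = (patch > 0).astype(int)
        cfg = TextureConfig(gray_levels=2)
        ours = glrm_features(image, mask, cfg).as_dict()
        oracle = brute_glrm(levels, mask == LABEL_BODY, cfg.directions)
        for name, value in oracle.items():
            assert ours[f"glrm_{name}"] == pytest.approx(value, abs=1e-9), name


class TestConfig:
    def test_invalid_levels(self):
        with pytest.raises(ValidationError):
            TextureConfig(gray_levels=1)

    def test_invalid_direction(self):
        with pytest.raises(ValidationError):
            TextureConfig(directions=(30,))

    def test_phantom_body_texture_runs(self, awned_phantom):
        f1 = glcm_features(awned_phantom.image, awned_phantom.truth_mask)
        f2 = glrm_features(awned_phantom.image, awned_phantom.truth_mask)
        assert not f1.constant_region
        assert f1.contrast > 0
        assert f2.SRE < 1.0
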