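"""Shared fixtures: small synthetic scenes and datasets, generated at test time."""

import numpy as np
import pandas as pd
import pytest

from plantservation import registration as reg
from plantservation import segmentation as seg
from plantservation import synthetic_field as sf


@pytest.fixture(scope="session")
def leaf_dataset():
    return sf.generate_leaf_dataset(seed=1, n_samples=150)


@pytest.fixture(scope="session")
def env300():
    return sf.generate_env_series(seed=5, n_days=300)


@pytest.fixture(scope="session")
def still_scene():
    """No-jitter, constant-brightness scene: exact geometry for truth checks."""
    cfg = sf.SceneConfig(seed=9, n_days=6, frames_per_day=1,
                         image_size=(576, 432), marble_radius=6,
                         diurnal_brightness=False, brightness_range=(1.0, 1.0))
    return sf.render_scene_series(cfg, jitter=False)


@pytest.fixture(scope="session")
def jittered_scene():
    """Jittered 10-day scene used by the registration-chain tests."""
    cfg = sf.SceneConfig(seed=3, n_days=10, frames_per_day=1,
                         image_size=(576, 432), marble_radius=6,
                         max_translation_px=5.0, max_rotation_deg=1.0)
    return sf.render_scene_series(cfg)


@pytest.fixture(scope="session")
def registered_chain(jittered_scene):
    """Marker detection → reference → homographies → warped frames → masks."""
    sc = jittered_scene
    backend = seg.ClassicalBackend()
    marker_sets = [reg.detect_markers(f.image) for f in sc.frames]
    ref = reg.reference_markers(marker_sets)
    registered, masks, homs = [], [], []
    for f, ms in zip(sc.frames, marker_sets):
        H = reg.estimate_homography(ms, ref)
        w = reg.warp_to_reference(f.image, H)
        registered.append(w)
        homs.append(H)
        masks.append(reg.tile_and_merge(w, backend.predict,
                                        downscale=1, patch_size=144))
    return {"scene": sc, "reference": ref, "homographies": homs,
            "registered": registered, "masks": masks}


def make_plant_crop(size=64, radius=14, plant_lab=(45.0, -35.0, 30.0),
                    bg="soil", seed=0):
    """A single round 'plant' on a textured background, with its truth mask."""
    from plantservation import colorimetry as col
    from skimage import draw

    rng = np.random.default_rng(seed)
    bg_lab = np.array(sf.BACKGROUND_LAB[bg])
    lab = bg_lab[None, None, :] + rng.normal(0, 1.5, (size, size, 3))
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((size / 2, size / 2), radius, shape=(size, size))
    mask[rr, cc] = True
    lab[mask] = np.array(plant_lab) + rng.normal(0, 1.5, (mask.sum(), 3))
    img = col.lab_to_srgb(lab).astype(np.uint8)
    return img, mask
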