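import numpy as np
import pytest

from mvdquant.io import EnFaceImage, ZoneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(grid, pitch=11.25, eye_id="eye"):
    return EnFaceImage(eye_id=eye_id, grid=np.asarray(grid, dtype=np.uint8),
                       pixel_pitch_um=pitch)


def ring_zones(shape, center=None, r_disc=8.0, r_beta=14.0, r_alpha=None):
    """Concentric disc / beta / (optional) alpha masks for small test grids."""
    h, w = shape
    cy, cx = center if center is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.ogrid[:h, :w]
    dist = np.hypot(yy - cy, xx - cx)
    disc = dist <= r_disc
    beta = (dist > r_disc) & (dist <= r_beta)
    if r_alpha is None:
        alpha = np.zeros(shape, dtype=bool)
    else:
        alpha = (dist > r_beta) & (dist <= r_alpha)
    return ZoneSet(disc=disc, alpha=alpha, beta=beta)


@pytest.fixture
def full_zone_image():
    """A 40x40 image whose whole grid is beta zone (no disc, no alpha)."""
    grid = np.full((40, 40), 200, dtype=np.uint8)
    zones = ZoneSet(
        disc=np.zeros((40, 40), dtype=bool),
        alpha=np.zeros((40, 40), dtype=bool),
        beta=np.ones((40, 40), dtype=bool),
    )
    return make_image(grid), zones
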