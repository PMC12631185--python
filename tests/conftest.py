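import numpy as np
import pytest

from leafstack import synthgen
from leafstack.synthgen import ClassSpec, FeatureTableSpec


@pytest.fixture
def plain_spec():
    """A lesion-free, noise-free leaf class."""
    return ClassSpec(
        name="healthy",
        base_color=(60, 160, 60),
        lesion_count_range=(0, 0),
        texture_noise_sd=0.0,
        eccentricity=0.3,
    )


@pytest.fixture
def lesioned_spec():
    return ClassSpec(
        name="spotted",
        base_color=(60, 160, 60),
        lesion_count_range=(3, 3),
        lesion_color=(140, 100, 30),
        lesion_radius_range=(5, 8),
        texture_noise_sd=0.0,
        eccentricity=0.3,
    )


@pytest.fixture
def three_specs(plain_spec, lesioned_spec):
    third = ClassSpec(
        name="mottled",
        base_color=(120, 140, 40),
        lesion_count_range=(1, 4),
        lesion_color=(90, 60, 20),
        lesion_radius_range=(4, 6),
        texture_noise_sd=4.0,
        eccentricity=0.6,
    )
    return [plain_spec, lesioned_spec, third]


@pytest.fixture
def blob_table():
    """Well-separated 3-class Gaussian blobs (n=600, d=10, separation 6)."""
    spec = FeatureTableSpec(n_per_class=200, n_classes=3, dim=10, separation=6.0, seed=42)
    X, y = synthgen.generate_feature_table(spec)
    return X, y, spec


def disk_image(radius: int, side: int | None = None, fg=200, bg=20) -> np.ndarray:
    """A bright disk on a dark background (uint8 RGB)."""
    side = side or (4 * radius)
    yy, xx = np.mgrid[:side, :side]
    c = (side - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    img = np.full((side, side, 3), bg, dtype=np.uint8)
    img[mask] = fg
    return img
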