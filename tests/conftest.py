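import numpy as np
import pytest

from lungfavc import BinaryRegion, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default study-geometry phantom: 64x64x90, 8 mm blur, no noise."""
    spec = PhantomSpec()
    grid, truth = generate_phantom(spec)
    return spec, grid, truth


@pytest.fixture(scope="session")
def sharp_phantom():
    """Default geometry without blur: measurement chain should be exact."""
    spec = PhantomSpec(blur_fwhm_mm=0.0)
    grid, truth = generate_phantom(spec)
    return spec, grid, truth


def digital_ball(radius: int, n: int | None = None, spacing: float = 1.0):
    """Digital ball mask with its centre voxel coordinate."""
    n = n if n is not None else 2 * radius + 5
    c = n // 2
    idx = np.indices((n, n, n))
    d2 = sum((idx[i] - c) ** 2 for i in range(3))
    return BinaryRegion(d2 <= radius * radius, (spacing,) * 3), c


@pytest.fixture(scope="session")
def ball20():
    return digital_ball(20)


def small_phantom_spec(seed: int = 0, scale: float = 1.0,
                       noise_sd: float = 0.0) -> PhantomSpec:
    """Reduced 40x40x48 thorax for fast multi-subject tests.

    ``scale`` multiplies the lung semi-axes, emulating inter-subject
    size variation; the airway is a straight trachea tube (no bronchi),
    which the measurement chain does not require.
    """
    from lungfavc import Cylinder, Ellipsoid

    s = float(scale)
    return PhantomSpec(
        dims=(40, 40, 48),
        right_lung=Ellipsoid((10.0, 20.0, 24.0),
                             (28.0 * s, 34.0 * s, 70.0 * s)),
        left_lung=Ellipsoid((29.0, 20.0, 24.0),
                            (26.0 * s, 32.0 * s, 65.0 * s)),
        heart_notch=Ellipsoid((23.0, 16.0, 28.0), (18.0, 18.0, 30.0)),
        body=Ellipsoid((19.5, 20.0, 24.0), (84.0, 80.0, 160.0)),
        hilum_right=(14, 20, 21),
        hilum_left=(26, 20, 21),
        trachea_seed=(19, 20, 6),
        trachea=Cylinder((19.5, 20.0, 3.0), (19.5, 20.0, 14.0), 6.0),
        bronchi=(),
        vessels_right=(Cylinder((13.0, 20.0, 18.5), (11.0, 20.0, 17.0), 4.0),),
        vessels_left=(Cylinder((26.0, 20.0, 18.5), (28.0, 20.0, 17.0), 4.0),),
        noise_sd=noise_sd,
        seed=seed,
    )
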