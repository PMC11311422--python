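import numpy as np
import pytest

import funduslight as fl


@pytest.fixture(scope="session")
def small_phantom():
    """A 160 x 220 phantom with vessels, exudates and boundary reflection.

    Foreground counts are scaled down from the full-size defaults so the
    coverage fraction stays representative (under 10%) at this size.
    """
    spec = fl.PhantomSpec(
        height=160,
        width=220,
        vessels=fl.VesselSpec(count=2),
        exudates=fl.ExudateSpec(count=4, radius=3),
        seed=7,
    )
    return fl.generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Foreground-free, noise-free 160 x 220 phantom: smooth illumination
    (gradient plus a compact boundary-reflection bump) only."""
    spec = fl.PhantomSpec(
        height=160,
        width=220,
        illumination=fl.IlluminationSpec(
            reflection=fl.ReflectionSpec(amplitude=60.0, scale=30.0)
        ),
        vessels=fl.VesselSpec(count=0),
        exudates=fl.ExudateSpec(count=0),
        noise_sigma=0.0,
        seed=7,
    )
    return fl.generate_phantom(spec)


def random_blob_mask(rng: np.random.Generator, shape=(12, 12)) -> np.ndarray:
    """A random nonempty mask with spatial structure (smoothed-noise threshold)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    mask = field > np.quantile(field, 0.55)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask
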