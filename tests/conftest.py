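import dataclasses

import numpy as np
import pytest

from archtrough import PhantomSpec, generate_phantom, run_subject


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless, confounder-free phantom with its ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """A phantom with noise, bias field and both confounders."""
    spec = PhantomSpec(
        noise_sigma=0.02,
        bias_amplitude=0.1,
        include_vertebra=True,
        include_cranium=True,
        seed=42,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_subject(clean_phantom):
    vol, truth = clean_phantom
    return run_subject(vol, truth.landmarks), truth


@pytest.fixture(scope="session")
def half_annulus():
    """Half-annulus arch mask, r in [40, 55] mm at 0.5 mm pixels."""
    from archtrough import ArchImage

    sp = 0.5
    x = np.arange(-70.0, 70.0 + 1e-9, sp)
    y = np.arange(-70.0, 70.0 + 1e-9, sp)
    X, Y = np.meshgrid(x, y, indexing="ij")
    R = np.hypot(X, Y)
    mask = (R >= 40.0) & (R <= 55.0) & (Y >= 0.0)
    ang = np.radians(20.0)
    canines = 47.5 * np.array(
        [[-np.sin(ang), np.cos(ang)], [np.sin(ang), np.cos(ang)]]
    )
    return ArchImage(mask, (sp, sp), (x[0], y[0]), reference=(0.0, 47.5), canines=canines)


@pytest.fixture(scope="session")
def rect_band():
    """Straight horizontal band of constant width 10 mm at 0.5 mm pixels."""
    from archtrough import ArchImage

    sp = 0.5
    x = np.arange(-40.0, 40.0 + 1e-9, sp)
    y = np.arange(-20.0, 20.0 + 1e-9, sp)
    X, Y = np.meshgrid(x, y, indexing="ij")
    mask = np.abs(Y) <= 5.0
    return ArchImage(
        mask, (sp, sp), (x[0], y[0]), reference=(0.0, 0.0),
        canines=np.array([[-10.0, 0.0], [10.0, 0.0]]),
    )


def scaled_spec(factor: float) -> PhantomSpec:
    """A phantom spec uniformly scaled in the axial plane."""
    s0 = PhantomSpec()
    n = int(np.ceil(300 * factor / 1.3))
    return dataclasses.replace(
        s0,
        arch_depth_mm=s0.arch_depth_mm * factor,
        arch_half_width_mm=s0.arch_half_width_mm * factor,
        junction_radius_mm=s0.junction_radius_mm * factor,
        ramus_length_mm=s0.ramus_length_mm * factor,
        canine_offset_mm=s0.canine_offset_mm * factor,
        band_width_mm=s0.band_width_mm * factor,
        shape=(n, n, 180),
        apex_y_mm=40.0,
        origin=(-(n - 1) * 0.25, -95.0, -35.0),
    )
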