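import numpy as np
import pytest

from chromodyn import ImageStack, NucleusGeometry, RenderParams


@pytest.fixture
def geometry():
    """A round-ish nucleus comfortably inside a 64x64 frame."""
    return NucleusGeometry(center=(32.0, 32.0), semi_axes=(18.0, 14.0))


@pytest.fixture
def circular_geometry():
    return NucleusGeometry(center=(32.0, 32.0), semi_axes=(20.0, 20.0))


@pytest.fixture
def clean_render():
    """Rendering with no PSF blur, no noise and no background."""
    return RenderParams(
        psf_sigma_xy=0.0, psf_sigma_z=0.0, poisson_peak=None, gaussian_sd=0.0, background=0.0
    )


@pytest.fixture
def default_render():
    return RenderParams(seed=7)


def mask_to_stack(mask: np.ndarray) -> ImageStack:
    """Wrap a 2D label mask as a single-plane stack."""
    return ImageStack(np.clip(np.asarray(mask, dtype=float), 0, None)[None])


def ci_of_mask(mask: np.ndarray) -> float:
    """CI of a noise-free mask (no background to estimate)."""
    from chromodyn import compute_ci

    return compute_ci(
        mask_to_stack(mask), background_method="fixed_offset", background_kw={"offset": 0.0}
    ).ci
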