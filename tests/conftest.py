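import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctiq.phantom import (
    InsertSpec,
    PhantomSpec,
    ReconModel,
    apply_recon_blur,
    render_phantom,
)

settings.register_profile(
    "ctiq",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ctiq")


def flat_shape(f):
    """White (flat) relative noise power spectrum."""
    return np.ones_like(np.asarray(f, dtype=float))


@pytest.fixture(scope="session")
def acrylic_disk_spec():
    """Acrylic insert (120 HU) centred on a water-equivalent disk body."""
    return PhantomSpec(
        "disk",
        (100.0, 100.0),
        0.0,
        (InsertSpec("acrylic", (0.0, 0.0), 15.0, 120.0),),
    )


@pytest.fixture(scope="session")
def sharp_disk(acrylic_disk_spec):
    """Noiseless unblurred render, pixel-centre mode, 0.5 mm grid."""
    return render_phantom(acrylic_disk_spec, (512, 512), 0.5, mode="center")


@pytest.fixture(scope="session")
def blurred_disk(sharp_disk):
    """The sharp disk blurred with a 0.5 mm Gaussian PSF."""
    model = ReconModel("gauss", 0.5, flat_shape)
    return apply_recon_blur(sharp_disk, model)
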