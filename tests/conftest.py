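import numpy as np
import pytest

from wbrt_aperture.phantom import PhantomSpec, generate_phantom, sample_spec
from wbrt_aperture.projection import BeamGeometry, project_structures, render_drr
from wbrt_aperture.segmentation import IntensityHints, segment_drr


@pytest.fixture(scope="session")
def geometry():
    """1 mm BEV sampling at gantry 270, parallel model."""
    return BeamGeometry(pixel_spacing=(1.0, 1.0))


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_volume(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def gt_structures(default_volume, geometry):
    """Approach-1 ground truth: projected masks of the default phantom."""
    return project_structures(default_volume, geometry)


@pytest.fixture(scope="session")
def default_drr(default_volume, geometry):
    return render_drr(
        default_volume.ct, default_volume.spacing, default_volume.origin, geometry
    )


@pytest.fixture(scope="session")
def segmented_structures(default_spec, default_drr):
    """Approach-2 structures on the default noise-free phantom."""
    return segment_drr(default_drr, IntensityHints.from_spec(default_spec))


@pytest.fixture(scope="session")
def random_specs():
    """20 randomized, noise-free phantom specs: the anatomical variability the
    aperture rules must tolerate."""
    rng = np.random.default_rng(20240901)
    return [sample_spec(rng) for _ in range(20)]


@pytest.fixture(scope="session")
def random_volumes(random_specs):
    return [generate_phantom(s) for s in random_specs]
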