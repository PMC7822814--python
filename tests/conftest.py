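import numpy as np
import pytest

from fluorox.image_io import GridSpec
from fluorox.synthetic import PhantomConfig

# Reduced anatomical matrix (same field of view, coarser pixels) keeps the
# interpolation/smoothing stages cheap in plumbing tests; the fluorine grid
# stays at acquisition size so ROI rasterization is realistic.
SMALL_ANAT = GridSpec(shape=(98, 128, 10), spacing=(39.2 / 98, 51.2 / 128, 2.4))


@pytest.fixture(scope="session")
def study_trs():
    return np.array([318.0, 719.0, 1398.0, 5000.0])


@pytest.fixture(scope="session")
def small_config():
    """A small but complete two-genotype study for pipeline plumbing."""
    return PhantomConfig(
        n_mothers=(2, 2), n_placentas=(4, 4), seed=7, anat_grid=SMALL_ANAT
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    from fluorox.synthetic import generate_study

    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_records():
    """Record-level simulation of the full study design (no imaging chain)."""
    from fluorox.synthetic import simulate_records

    return simulate_records(PhantomConfig(), seed=11)
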