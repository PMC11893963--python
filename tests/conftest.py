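import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

from lsfquant import NoiseModel, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def clean_study():
    """Noiseless, blur-free, motion-free default phantom (seed 1)."""
    spec = PhantomSpec(seed=1, noise=NoiseModel.NONE, psf_fwhm_mm=0.0)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def default_study():
    """Default acquisition conditions (12 mm PSF, Poisson noise, seed 1)."""
    return build_phantom(PhantomSpec(seed=1))
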