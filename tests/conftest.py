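import numpy as np
import pytest

from dcepk.phantom import PhantomSpec, build_phantom, render_dce
from dcepk.physics import TimeGrid, population_aif


@pytest.fixture(scope="session")
def grid60():
    return TimeGrid.uniform()


@pytest.fixture(scope="session")
def parker_aif(grid60):
    return population_aif(grid60)


@pytest.fixture(scope="session")
def noiseless_phantom(grid60, parker_aif):
    """A 32x32 single-slice phantom rendered without noise."""
    spec = PhantomSpec(noise_sd=0.0, seed=3)
    gt, masks, class_map = build_phantom(spec)
    dce = render_dce(gt, masks, parker_aif, noise_sd=0.0, seed=0)
    return {"gt": gt, "masks": masks, "class_map": class_map, "dce": dce}


@pytest.fixture(scope="session")
def noisy_phantom(grid60, parker_aif):
    """The same phantom at the default noise level."""
    spec = PhantomSpec(seed=3)
    gt, masks, class_map = build_phantom(spec)
    dce = render_dce(gt, masks, parker_aif, noise_sd=spec.noise_sd, seed=11)
    return {"gt": gt, "masks": masks, "class_map": class_map, "dce": dce}
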