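import numpy as np
import pytest

from pointtex.simulate import MarkerField, PSFModel, default_class_params, render_image, sample_field


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def triangle_field():
    """3-4-5 right triangle with hand-computable distance sets."""
    return MarkerField(np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]]), "t", (100, 100))


@pytest.fixture
def c1_image(rng):
    """One rendered C1 image at the reference PSF width (k = 1.3)."""
    fld = sample_field(default_class_params("C1"), rng)
    return render_image(fld, PSFModel(0.8), crop=216)
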