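import numpy as np
import pytest

from pdacwsi import synthetic
from pdacwsi.heatmap import ProbabilityHeatmap


@pytest.fixture(scope="session")
def small_slide():
    """A 1024x512 cancerous pseudo-slide with one tumor region."""
    return synthetic.generate_slide(1024, 512, 1, seed=7, min_size=256,
                                    region_radius_frac=(0.4, 0.5))


@pytest.fixture(scope="session")
def normal_slide():
    return synthetic.generate_slide(1024, 512, 0, seed=8, min_size=256)


def make_heatmap(p_tumor, slide_id="hm", patch_size=256, background=None):
    """Build a ProbabilityHeatmap from a 2-D array of tumor probabilities."""
    p_tumor = np.asarray(p_tumor, dtype=float)
    grid = np.stack([1.0 - p_tumor, p_tumor], axis=-1)
    return ProbabilityHeatmap(slide_id=slide_id, grid=grid,
                              patch_size=patch_size, stride=patch_size,
                              background=background)
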