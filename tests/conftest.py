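import numpy as np
import pytest
from shapely.geometry import box

from sriaquant import SectionImage, SectionSimConfig, generate_section_pair
from sriaquant.quantify import RegionAnnotation

# Test-scale sections: 512 px at 4 µm/px gives the same ~4.2 mm² field of
# view as the 2048 px / 1 µm default at a fraction of the cost.
SMALL = dict(width_px=512, height_px=512, microns_per_pixel=4.0)


@pytest.fixture(scope="session")
def section_pair_small():
    """One simulated frozen/paraffin pair with ground truth, reused widely."""
    cfg = SectionSimConfig(
        **SMALL, true_fraction_pct=30.0, frozen_delta_pct=7.8, seed=42
    )
    frozen, paraffin, truth_f, truth_p = generate_section_pair(cfg)
    return cfg, frozen, paraffin, truth_f, truth_p


def make_flat_section(shape=(100, 100), mpp=10.0, cortex=None, exclusions=(),
                      kind="paraffin", biopsy_id="toy"):
    """A dummy SectionImage whose pixels are irrelevant (channel supplied by
    the test); only geometry and calibration matter."""
    h, w = shape
    if cortex is None:
        cortex = box(-0.5, -0.5, w - 0.5, h - 0.5)
    anns = [RegionAnnotation("cortex", cortex)]
    anns += [RegionAnnotation(role, geom) for role, geom in exclusions]
    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    return SectionImage(pixels, mpp, kind, anns, biopsy_id)
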