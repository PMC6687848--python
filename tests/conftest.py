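import numpy as np
import pytest

from tendonkit.image import PolygonROI
from tendonkit import synthetic as syn

# Cohort-scale reference values used as generator ground truth throughout:
# maximum tendon force 4399 N, stiffness 1338 N/mm, rest length 52.9 mm,
# moment arm 54.1 mm, proximal/distal CSA 118/119 mm^2, strain at 80 % 6.6 %.
TFMAX_N = 4399.0
STIFFNESS = 1338.0
REST_LENGTH = 52.9
MOMENT_ARM = 54.1
CSA_PROX = 118.0
CSA_DIST = 119.0
CSA_FULL = 118.5
STRAIN80 = 6.6


@pytest.fixture(scope="session")
def toe_exponent():
    return syn.toe_exponent_for_strain80(TFMAX_N, STIFFNESS, REST_LENGTH, STRAIN80)


@pytest.fixture(scope="session")
def clean_ramp_set(toe_exponent):
    """Noise-free ramp session whose ground truth matches the reference scalars."""
    return syn.gen_ramp_trials(syn.RampSpec(toe_exponent=toe_exponent, noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def band_image():
    """Noise-free aligned-band image: 0.5 mm spacing, 0.05 mm pixels."""
    return syn.gen_speckle_image(syn.SpeckleSpec(
        image_size_px=(96, 160), pixel_size_mm=(0.05, 0.05),
        band_spacing_mm=0.5, disorganization=0.0, speckle_contrast=0.0, seed=1))


@pytest.fixture(scope="session")
def full_roi():
    return PolygonROI.rectangle(-0.5, -0.5, 95.5, 159.5)
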