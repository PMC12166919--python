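"""Shared fixtures: small/fast synthetic study configurations.

The ``small_cfg`` geometry (6 cm field on a 15 x 90 mm strip) keeps unit
tests fast; study-scale tests use the default configuration (15 cm field,
25.4 x 203.2 mm strips, 127 dpi).
"""

import numpy as np
import pytest

from wedgecal import GroundTruthConfig
from wedgecal.wedge import FieldGeometry


@pytest.fixture
def small_cfg():
    return GroundTruthConfig(
        seed=99,
        geometry=FieldGeometry(field_size_cm=6.0, ssd_cm=100.0, depth_cm=5.0,
                               wedge_angle_deg=60.0),
        strip_width_mm=15.0,
        strip_length_mm=90.0,
        penumbra_mm=4.0,
    )


@pytest.fixture
def small_noiseless_cfg(small_cfg):
    from dataclasses import replace

    return replace(small_cfg, pixel_noise_rel=0.0, film_nonuniformity_rel=0.0,
                   n_repeat_scans=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
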