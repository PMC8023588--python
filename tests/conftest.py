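"""Shared fixtures: small, fast phantom configurations.

All fixtures generate data programmatically; nothing is read from disk. The
"small" geometry (96 A-lines x 80 radial pixels, 64-pixel crop) keeps network
training in unit tests to seconds while preserving every structural feature
of the full-size phantom (eccentric lumen, guidewire shadow, speckle,
drifting lesion).
"""

from __future__ import annotations

import numpy as np
import pytest

from octselect.phantom import LesionParams, PhantomConfig, generate_voi
from octselect.preprocess import PreprocessConfig, preprocess_voi
from octselect.select import SamplerConfig


SMALL_KW = dict(
    n_alines=96, n_radial=80,
    lumen_radius_mean=10.0, lumen_amplitude=3.0,
    guidewire_width=6,
    tissue_attenuation_px=30.0,
)
SMALL_LESION = LesionParams(arc_center_deg=120.0, arc_extent_deg=120.0,
                            depth_px=5.0, thickness_px=25.0,
                            depth_mod_px=2.0, center_drift_deg_per_frame=1.5)


def small_config(**overrides) -> PhantomConfig:
    kw = dict(SMALL_KW, lesion=SMALL_LESION, n_frames=12, seed=0)
    kw.update(overrides)
    return PhantomConfig(**kw)


def small_preprocess() -> PreprocessConfig:
    return PreprocessConfig(crop_depth=64)


def small_sampler(**overrides) -> SamplerConfig:
    kw = dict(ae_epochs=10, ae_batch=8, ae_widths=(4, 8, 12), ae_bottleneck=12,
              ae_dec_widths=(8, 4), seed=0)
    kw.update(overrides)
    return SamplerConfig(**kw)


@pytest.fixture(scope="session")
def small_voi():
    """A 12-frame calcification VOI at small geometry."""
    return generate_voi(small_config())


@pytest.fixture(scope="session")
def small_frames(small_voi):
    """Preprocessed (aligned, cropped, smoothed) frames of ``small_voi``."""
    return preprocess_voi(small_voi, small_preprocess())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
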