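"""Shared fixtures: scaled transducer profiles and cached simulations.

Simulations use reduced image sizes (fewer scan lines, shallower frames)
so the suite stays fast; bands, pitches and sampling rates are the full
presets' values, which is what the estimators are sensitive to.
"""

import numpy as np
import pytest

import refqus as rq
from refqus.pipeline import PipelineConfig, ReferenceBank


@pytest.fixture(scope="session")
def st_small():
    return rq.ST.scaled(n_lines=128, n_samples=1400)


@pytest.fixture(scope="session")
def cl_small():
    return rq.CL15.scaled(n_lines=58, n_samples=1060)


@pytest.fixture(scope="session")
def phantom_medium():
    return rq.reference_phantom_medium()


@pytest.fixture(scope="session")
def st_bank(st_small):
    """Reference phantom bank for the scaled cart-based profile."""
    return ReferenceBank.simulate(st_small, n_frames=6, seed=424242)


@pytest.fixture(scope="session")
def phantom_frames_st(st_small, phantom_medium):
    frames, spec = rq.simulate_reference_phantom(
        st_small, phantom_medium, n_frames=4, seed=31337
    )
    return frames, spec


@pytest.fixture(scope="session")
def selfnorm_config(phantom_medium):
    """Pipeline config for sample ≡ phantom runs: the intervening medium is
    the phantom itself, so its slope is the tissue slope."""
    return PipelineConfig(alpha_tissue=phantom_medium.attenuation_db_mhz_cm)


@pytest.fixture(scope="session")
def roi_rect():
    """Rectangular ROI from 8 to 20 mm depth, 1.5–13.5 mm laterally."""
    return rq.ROIPolygon([(1.5, 8.0), (13.5, 8.0), (13.5, 20.0), (1.5, 20.0)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
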