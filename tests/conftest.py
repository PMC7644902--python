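import numpy as np
import pytest

import rsdelta as rd


@pytest.fixture(scope="session")
def inverse_setup():
    """Shared desk-scale source geometry: space, lead field, inverse."""
    space = rd.build_source_space(grid_mm=10.0)
    lf = rd.compute_lead_field(space)
    inv = rd.eloreta_inverse(lf, alpha=1e-2)
    return space, lf, inv


@pytest.fixture(scope="session")
def background_recording():
    """Two minutes of clean synthetic resting-state EEG."""
    return rd.synthesize_background(128.0, 120.0, iaf=9.5, seed=42)


def subject_regional(rec, inv, space, span_s=60.0):
    """Temporal-delta log10 regional activity of one recording."""
    eps = rd.segment_epochs(rec, span_s=span_s)
    psd = rd.welch_psd(rec, eps)
    lm = rd.estimate_landmarks(psd)
    scheme = rd.define_bands(lm.tf, lm.iaf)
    sub = rd.map_subject(psd, inv, space, scheme)
    return sub
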