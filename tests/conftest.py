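from dataclasses import replace

import numpy as np
import pytest

from fibrilmpl.band_sampler import extract_profile, extract_profiles
from fibrilmpl.mpl_calc import calibrate, measure_fibril
from fibrilmpl.selections import SelectionLine
from fibrilmpl.synth import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default three-bar phantom with zero noise: (Image, SelectionSet)."""
    spec = replace(PhantomSpec(), noise_sd=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_phantom):
    img, sels = noiseless_phantom
    return calibrate(extract_profiles(img, sels.standards))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def measure_label(img, sels, cal, label, gap=2.0):
    """Run the measurement pipeline for one fibril selection label."""
    (sel,) = [s for s in sels.fibrils if s.label == label]
    return measure_fibril(extract_profile(img, sel, gap=gap), cal)


def standard_as_fibril(img, cal, width=30.0, center_x=100.0, y0=5.0, y1=506.0):
    """Measure the standard bar as if it were a fibril (calibration identity)."""
    sel = SelectionLine("fibril", "STD_as_fibril", center_x, y0, center_x, y1, width)
    return measure_fibril(extract_profile(img, sel), cal)
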