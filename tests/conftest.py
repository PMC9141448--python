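import numpy as np
import pytest

from thtbind.binding import BindingMode, BindingPoint
from thtbind.simulate import GeneratorTruth, solve_equilibrium
from thtbind.spectra import Spectrum


@pytest.fixture
def one_mode_truth():
    return GeneratorTruth(seed=7)


@pytest.fixture
def two_mode_truth():
    return GeneratorTruth.two_mode(seed=7)


@pytest.fixture
def flat_spectrum():
    wl = np.arange(300.0, 701.0)
    return Spectrum(wl, np.full(wl.size, 0.05), "absorption")


def exact_binding_points(truth, n_points=None):
    """Noiseless titration points from the equilibrium solver."""
    c0s = truth.C0_series_M if n_points is None else truth.C0_series_M[:n_points]
    pts = []
    for c0 in c0s:
        cf, cb = solve_equilibrium(c0, truth.Cp_M, truth.modes)
        pts.append(BindingPoint(Cf=cf, Cb=cb, C0=c0, Cp=truth.Cp_M))
    return pts


@pytest.fixture
def exact_one_mode_points(one_mode_truth):
    return exact_binding_points(one_mode_truth)
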