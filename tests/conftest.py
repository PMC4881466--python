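import numpy as np
import pytest

from hemekin.bands import load_band_library
from hemekin.spectra import default_grid


@pytest.fixture(scope="session")
def lib():
    """Packaged reference-band library (shared, read-only)."""
    return load_band_library()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def deoxy_nitrosyl_refs(lib):
    """The AHb1 H69L deoxy/ferric/nitrosyl reference triple."""
    return {
        "deoxy": lib.reference("AHb1_H69L_deoxy"),
        "ferric": lib.reference("AHb1_H69L_ferric"),
        "nitrosyl": lib.reference("AHb1_H69L_nitrosyl"),
    }


def simplex_grid_deconvolve(spectrum, refs, c_max=1.5, steps=76):
    """Brute-force oracle for two-reference NNLS: exhaustive search of the
    nonnegative coefficient grid minimising the residual 2-norm."""
    cs = np.linspace(0.0, c_max, steps)
    a = np.column_stack([r.absorbance for r in refs])
    best, best_c = np.inf, None
    for c1 in cs:
        for c2 in cs:
            r = spectrum.absorbance - a @ np.array([c1, c2])
            norm = float(np.sqrt(np.sum(r * r)))
            if norm < best:
                best, best_c = norm, (c1, c2)
    return np.array(best_c), best
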