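import numpy as np
import pytest

from coilmap import CrickParams, generate_crick_bundle


@pytest.fixture(scope="session")
def canonical_params():
    """Canonical left-handed parallel dimer, KfrA-like domain length."""
    return CrickParams(n_residues=251)


@pytest.fixture(scope="session")
def canonical_bundle(canonical_params):
    return generate_crick_bundle(canonical_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_canonical_params(rng, n_residues=120):
    """A random draw of canonical (left-handed, undistorted) parameters.

    The Crick phase is drawn away from heptad bin edges (5° margin): a
    canonical register whose phases sit exactly on a bin boundary is
    intrinsically ambiguous under any finite-precision measurement.
    """
    bin_w = 360.0 / 7.0
    phase = rng.integers(0, 7) * bin_w + bin_w / 2 + rng.uniform(-bin_w / 2 + 5,
                                                                 bin_w / 2 - 5)
    return CrickParams(
        n_residues=n_residues,
        superhelix_radius=float(rng.uniform(4.4, 5.6)),
        superhelix_freq=float(rng.uniform(-4.8, -2.2)),
        crick_phase=float(phase),
    )
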