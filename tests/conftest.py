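"""Shared fixtures: small grids and a reduced-scale comparison phantom.

The reduced scale (48 in-plane voxels at 6.5 mm, 24 angles) keeps full
pipeline runs to seconds while preserving every physical ingredient;
quantitative acceptance checks use the 64-voxel, 4.8-mm, 60-angle scale.
"""

import numpy as np
import pytest

from qspect.intercomparison import make_comparison_phantom, site_protocols
from qspect.phantom import ShellSourceSpec, empty_grid


@pytest.fixture(scope="session")
def small_bundle():
    return make_comparison_phantom("H1", spacing=6.5, n_xy=48, n_z=32)


@pytest.fixture(scope="session")
def small_protocols():
    return site_protocols(n_projections=24)


@pytest.fixture(scope="session")
def shell_spec():
    return ShellSourceSpec(26.1, 80.8)


@pytest.fixture()
def grid32():
    return empty_grid(32, 32, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
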