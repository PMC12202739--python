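"""Shared small-scale fixtures.

Everything is generated programmatically; sizes are kept small (16-64
grids, short sequences, coarse dictionaries) so the full suite stays
fast while still exercising every code path at realistic structure.
"""

import numpy as np
import pytest

from qrfthermo import (
    DictionaryGrid,
    SequenceParams,
    build_dictionary,
    make_disc_phantom,
    make_spiral_trajectory,
)
from qrfthermo.dictionary import default_frequency_grid
from qrfthermo.nufft import NufftPlan


@pytest.fixture(scope="session")
def params_short() -> SequenceParams:
    """Short default-style sequence (440 TRs: one discard + one window of
    220 at the standard TR/flip/curvature)."""
    return SequenceParams(n_tr=440)


@pytest.fixture(scope="session")
def small_grid(params_short) -> DictionaryGrid:
    """Coarse single-linewidth frequency grid for matching tests."""
    return DictionaryGrid(
        freqs_hz=default_frequency_grid(512, params_short.tr_s),
        linewidths_hz=np.array([1.0]),
        t1t2_pairs_s=((0.825, 0.070),),
    )


@pytest.fixture(scope="session")
def small_dictionary(small_grid, params_short):
    return build_dictionary(small_grid, params_short)


@pytest.fixture(scope="session")
def phantom32():
    """32-voxel-diameter disc on a 64 grid (quarter-scale phantom)."""
    return make_disc_phantom(grid=64, diameter_vox=32)


@pytest.fixture(scope="session")
def plan64(params_short):
    traj = make_spiral_trajectory(params_short, matrix=64)
    return NufftPlan(traj)


@pytest.fixture(scope="session")
def fully_sampled_params() -> SequenceParams:
    """Single-interleaf spiral that covers k-space every TR (used to test
    noiseless recovery without undersampling aliasing)."""
    return SequenceParams(n_tr=440, n_interleaves=1, readout_s=0.008, dwell_s=0.8e-6)
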