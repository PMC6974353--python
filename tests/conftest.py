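"""Shared fixtures: the desk-scale paired-architecture experiment is expensive
(plane-wave propagation through a 256x256x128 volume per model), so it is
computed once per session and shared between the scattering tests and the
acceptance suite."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from onloptics.bpm import compare_models
from onloptics.phantom import ChromatinParams, generate_packed_nuclei

#: Desk-scale study conditions: ~40 nuclei in a 42.5 x 42.5 x 21 um slab at
#: 0.166 um voxels, chromatin indices n1=1.357 / n2=1.382 in n0=1.33.
DESK_SCALE = dict(
    n_nuclei=40,
    domain_shape=(128, 256, 256),
    voxel_size_um=0.166,
    radius_um=(2.8, 0.3),
)
GEOMETRY_SEED = 11
MODEL_SEED = 42


@pytest.fixture(scope="session")
def desk_labels():
    return generate_packed_nuclei(seed=GEOMETRY_SEED, **DESK_SCALE)


@pytest.fixture(scope="session")
def chromatin_params():
    return ChromatinParams()


@pytest.fixture(scope="session")
def paired_report(desk_labels, chromatin_params):
    """Paired inverted vs chromocenter scattering run on identical geometry."""
    return compare_models(desk_labels, chromatin_params, seed=MODEL_SEED)
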