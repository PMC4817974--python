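"""Shared fixtures: all inputs are generated programmatically at test time.

Session scope is used for the expensive synthetic trajectories and tubes
so the whole suite builds each of them once; tests that mutate geometry
must copy first (PrimordiumFrame.copy / mirror_frame / perturb_frame all
return new objects).
"""

import numpy as np
import pytest
import trimesh

from gutmorph import (
    MorphogenesisSchedule,
    PackingSpec,
    generate_trajectory,
    generate_tube,
    hatching_configs,
    sample_diagonal_configs,
    wt_reference_trajectory,
)


@pytest.fixture(scope="session")
def ral_spec():
    return PackingSpec(p_RaL=1.0, p_LaR=0.0, p_Cross=0.0)


@pytest.fixture(scope="session")
def ral_tube(ral_spec):
    """Ideal hexagonal (all-RaL) 9-ring tube."""
    return generate_tube(ral_spec)


@pytest.fixture(scope="session")
def cross_spec():
    return PackingSpec(p_RaL=0.0, p_LaR=0.0, p_Cross=1.0)


@pytest.fixture(scope="session")
def cross_tube(cross_spec):
    """Symmetric tube: every interface is a four-cell Cross vertex."""
    return generate_tube(cross_spec)


@pytest.fixture(scope="session")
def larval_tube():
    """Post-hatching fixture: 4-cell int1, RaL+RaL posterior packing and
    the invariant RaL+LaR int2-int1 pair."""
    spec = PackingSpec(cells_per_ring={1: 4})
    return generate_tube(spec, configs=hatching_configs(spec))


@pytest.fixture(scope="session")
def mixed_tube():
    """Tube with a seeded mix of RaL/LaR/Cross junctions plus its ground
    truth, for classifier-recovery and mirror tests."""
    spec = PackingSpec(seed=7, p_RaL=0.5, p_LaR=0.3, p_Cross=0.2)
    configs = sample_diagonal_configs(spec)
    return spec, configs, generate_tube(spec, configs)


@pytest.fixture(scope="session")
def wt_frames_mode1():
    """Canonical wild-type trajectory, int2 closing in mode 1."""
    return wt_reference_trajectory(int2_mode=1)


@pytest.fixture(scope="session")
def wt_frames_mode2():
    return wt_reference_trajectory(int2_mode=2)


@pytest.fixture(scope="session")
def static_frames():
    """Short trajectory with no scheduled events (frames identical)."""
    spec = PackingSpec(n_rings=5)
    configs = sample_diagonal_configs(spec)
    return generate_trajectory(
        spec, MorphogenesisSchedule(()), 0.0, 24.0, 8.0, configs=configs
    )


def make_cubes(size=2.0, gap=1e-9):
    """Two axis-aligned cubes separated by ``gap`` along x."""
    a = trimesh.creation.box(extents=(size,) * 3)
    b = trimesh.creation.box(extents=(size,) * 3)
    b.apply_translation((size + gap, 0.0, 0.0))
    return a, b


@pytest.fixture
def cube_pair():
    return make_cubes()
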