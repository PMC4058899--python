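import numpy as np
import pytest

from connclass.atlas import NetworkAtlas, Node, load_atlas
from connclass.pipeline import compute_feature_tables
from connclass.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def atlas56():
    return load_atlas()


def make_atlas(sizes: dict[str, int]) -> NetworkAtlas:
    """Synthetic atlas with the given network -> node-count layout."""
    nodes, nid = [], 1
    for net, size in sizes.items():
        for _ in range(size):
            nodes.append(Node(id=nid, name=f"node{nid}", network=net,
                              centroid=(0.0, 0.0, 0.0), volume=10))
            nid += 1
    return NetworkAtlas(networks=list(sizes), nodes=nodes)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort used by unit tests: quick but structurally complete."""
    return SimulationConfig(
        n_per_group=4, n_volumes=80, voxels_per_node=2,
        n_wm_voxels=10, n_csf_voxels=10, motion_spike_rate=0.03, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_tables(tiny_cohort):
    recordings, maps, atlas = tiny_cohort
    return compute_feature_tables(recordings, maps, atlas)
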