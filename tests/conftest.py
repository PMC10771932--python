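import numpy as np
import pytest

from pulmoflow import (
    BreathConfig,
    CohortParams,
    DaverTable,
    Demographics,
    RunConfig,
)
from pulmoflow.pipeline import run_pipeline
from pulmoflow.tree import AirwayTree, Branch


@pytest.fixture(scope="session")
def daver_table() -> DaverTable:
    return DaverTable.default()


@pytest.fixture
def male_60y() -> Demographics:
    return Demographics(sex=0, height=1.70, age=60)


def build_symmetric_tree(levels: int = 3, diameter: float = 4.0,
                         length: float = 20.0, lobe: str = "LUL") -> AirwayTree:
    """Perfect binary tree with `levels` generations, halving diameter by 1.3x."""
    tree = AirwayTree(volume_state="TLC")
    tree.add_node(0, (0, 0, 0))
    tree.add_node(1, (0, 0, -length))
    tree.add_branch(Branch(id=0, parent=None, prox_node=0, dist_node=1,
                           lobe=lobe, generation=1, order=None,
                           diameter_mm=diameter, length_mm=length, resolved=True))
    frontier = [0]
    for lv in range(1, levels):
        nxt = []
        for pid in frontier:
            parent = tree.branches[pid]
            for k in range(2):
                nid = tree.next_node_id()
                off = (2 * k - 1) * length / (lv + 1)
                tree.add_node(nid, tree.nodes[parent.dist_node] + np.array(
                    [off, 0.0, -length / (lv + 1)]))
                nxt.append(tree.add_branch(Branch(
                    id=tree.next_branch_id(), parent=pid,
                    prox_node=parent.dist_node, dist_node=nid, lobe=lobe,
                    generation=parent.generation + 1, order=None,
                    diameter_mm=diameter / (1.3 ** lv),
                    length_mm=length / (lv + 1), resolved=True)).id)
        frontier = nxt
    return tree


@pytest.fixture
def symmetric_tree() -> AirwayTree:
    return build_symmetric_tree()


@pytest.fixture(scope="session")
def small_cohort_params() -> CohortParams:
    """Reduced problem sizes for unit-level end-to-end checks."""
    return CohortParams(n_a=5, n_b=4, points_per_lobe=64, voxels_per_lobe=500,
                        master_seed=11)


@pytest.fixture(scope="session")
def default_pipeline_run(tmp_path_factory):
    """One full default-scale pipeline run (36 subjects), shared by tests."""
    out = tmp_path_factory.mktemp("run_default")
    config = RunConfig(seed=1, out_dir=str(out))
    config.breath.steps_per_cycle = 40
    results, report, out_dir = run_pipeline(config)
    return results, report, out_dir
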