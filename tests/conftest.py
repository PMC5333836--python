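import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import vasctree as vt


@pytest.fixture(scope="session")
def default_tree():
    """Default synthetic tree and its ground truth (31 segments, 5 levels)."""
    return vt.generate_tree(vt.TreeSpec())


@pytest.fixture(scope="session")
def default_centerline(default_tree):
    tree, _ = default_tree
    return vt.tree_to_centerline(tree)


@pytest.fixture(scope="session")
def voxel_pipeline_result(default_tree):
    """Full voxel pipeline on the default tree, shared across tests.

    Voxelizes at 16 um, segments, reconstructs, orders and computes the
    directed graph; expensive, so computed once per session.
    """
    tree, gt = default_tree
    vol = vt.voxelize_tree(tree, spacing=16.0)
    cs = vt.segment_volume(vol, vt.SegmentationParams(hu_low=1000, hu_high=4000))
    g = vt.reconstruct(cs)
    segments = vt.extract_segments(g)
    root = vt.select_root(g)
    vt.assign_strahler(segments, g, root)
    segments, ddso_info = vt.assign_ddso(segments)
    dg = vt.orient_from_root(g, root)
    return {
        "tree": tree, "gt": gt, "volume": vol, "centerline": cs, "graph": g,
        "segments": segments, "root": root, "ddso_info": ddso_info, "digraph": dg,
    }


def make_chain_graph(points, diameters=None):
    """Edge-less graph from explicit coordinates (testing helper)."""
    points = np.asarray(points, dtype=float)
    if diameters is None:
        diameters = np.full(len(points), 10.0)
    cs = vt.CenterlineSet(points, diameters)
    from vasctree.graph import build_node_graph

    return cs, build_node_graph(cs)
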