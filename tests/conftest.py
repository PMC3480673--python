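"""Shared fixtures: coarse heart models and cached simulation products.

The pattern-level tests run the full electromechanical pipeline on a reduced
resolution heart (16 circumferential x 14 layers x 2 transmural, dt 0.1 ms);
session scoping means each activation map and mechanics run is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiosync import synthetic_heart as sh
from cardiosync.pipeline import HeartModel

COARSE_CFG = {
    "mesh": {"n_circumferential": 16, "n_transmural": 2},
    "electrics": {"dt_ms": 0.1},
}


@pytest.fixture(scope="session")
def coarse_model() -> HeartModel:
    return HeartModel(COARSE_CFG)


@pytest.fixture(scope="session")
def sinus_map(coarse_model):
    return coarse_model.sinus_map()


@pytest.fixture(scope="session")
def lbbb_map(coarse_model):
    return coarse_model.lbbb_map()


@pytest.fixture(scope="session")
def baseline_records(coarse_model, sinus_map, lbbb_map):
    return {
        "sinus": coarse_model.evaluate(sinus_map, label="sinus"),
        "lbbb": coarse_model.evaluate(lbbb_map, label="lbbb"),
    }


@pytest.fixture(scope="session")
def paced_records(coarse_model):
    """LAT-E paced records over a reduced VVD set (0, 24, 60, 72 ms)."""
    out = {}
    for vvd in (0.0, 24.0, 60.0, 72.0):
        amap = coarse_model.paced_map(coarse_model.make_protocol("LAT-E", vvd))
        out[vvd] = coarse_model.evaluate(amap, lv_site="LAT-E", vvd=vvd)
    return out


@pytest.fixture(scope="session")
def coarse_mesh(coarse_model):
    return coarse_model.mesh


@pytest.fixture(scope="session")
def axisymmetric_mesh():
    """Pure-LV ellipsoid: equal wall thickness, vanishing RV bulge.

    The zero-size RV elements all collapse and are dropped, leaving an
    axisymmetric thick-walled truncated ellipsoid for symmetry tests.
    """
    spec = sh.MeshSpec(n_circumferential=30, n_transmural=2,
                       wall_thickness_septum=10.0, rv_bulge_mm=1e-9,
                       wall_thickness_rv=1e-6)
    mesh = sh.build_biventricular_mesh(spec)
    sh.label_segments(mesh)
    sh.assign_fiber_orientations(mesh)
    return mesh


def segment_node_mask(mesh, name: str) -> np.ndarray:
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    sel = (mesh.segment == name) & (mesh.part == "lv")
    mask[mesh.elements[sel].ravel()] = True
    return mask
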