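"""Shared fixtures: coarse meshes and session-scoped simulation runs.

The expensive bidomain runs (embedded three-stimulus protocol, SAN-driven
whole heart) are computed once per session and reused across the solver,
ECG, experiment and acceptance tests.
"""

import numpy as np
import pytest

import cardiofield as cf
from cardiofield import geometry as G
from cardiofield import ionic, solver


@pytest.fixture(scope="session")
def model3():
    return ionic.get_model(3)


@pytest.fixture(scope="session")
def heart_mesh():
    """Default simplified whole heart (all 7 subdomains)."""
    return cf.build_simplified_heart()


@pytest.fixture(scope="session")
def coarse_config():
    """Coarser-than-default geometry for cheap experiment-level tests."""
    return G.GeometryConfig(h_heart=6.5e-3, h_torso=60e-3, h_conduction=2e-3)


@pytest.fixture(scope="session")
def coarse_disconnected_config():
    return G.disconnected_chambers_config(h_heart=6.5e-3, h_torso=60e-3,
                                          h_conduction=2e-3)


@pytest.fixture(scope="session")
def bar_mesh():
    return cf.build_bar_mesh(20e-3, 3e-3, 1.5e-3)


@pytest.fixture(scope="session")
def protocol_run(model3):
    """Embedded disconnected-chambers run with the three-stimulus protocol.

    This is the package's reproduction of the stimulus-bridged whole-cycle
    study: 600 ms at dt = 1 ms on the default mesh.
    """
    mesh = cf.embed_in_torso(G.disconnected_chambers_config())
    layout = cf.place_electrodes(mesh)
    protocol = solver.standard_protocol(mesh)
    cfg = solver.SolverConfig(t_end=0.6)
    res = solver.run(mesh, model3, protocol, cfg, ground_node=layout.ground_node)
    return {"mesh": mesh, "layout": layout, "protocol": protocol,
            "cfg": cfg, "result": res}


@pytest.fixture(scope="session")
def san_run(heart_mesh, model3):
    """SAN-driven whole-heart run (no external stimuli), heart-only mesh.

    Long enough for the first spontaneous pacemaker cycle to activate the
    ventricles (the Model 3 SAN fires around 0.9 s from the published
    initial conditions).
    """
    cfg = solver.SolverConfig(t_end=1.3)
    res = solver.run(heart_mesh, model3, [], cfg)
    return {"mesh": heart_mesh, "cfg": cfg, "result": res}


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
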