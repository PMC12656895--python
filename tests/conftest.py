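import numpy as np
import pytest

import vpglu as vg
from vpglu import REFERENCE_THETA_DB, REFERENCE_THETA_NDB
from vpglu.cable import NodeHH, PassiveProperties
from vpglu.channels import ConductanceVector


@pytest.fixture(scope="session")
def settings():
    return vg.SimulationSettings()


@pytest.fixture(scope="session")
def desk_cfg():
    """Reduced-axon configuration used throughout the calibration-scale tests."""
    return vg.desk_config()


@pytest.fixture(scope="session")
def full_morphology():
    return vg.build_morphology()


@pytest.fixture(scope="session")
def short_morphology():
    return vg.build_morphology({"axon_node_count": 10, "dendrite": {"nseg": 21}})


ZERO_THETA = ConductanceVector(0, 0, 0, 0, 0, 0, 0, 0, 0)


def passive_leak_properties(g_leak: float = 1e-4, e_leak: float = -60.0) -> PassiveProperties:
    """Uniform explicit leak on every section kind (theta-independent)."""
    kinds = ("soma", "hillock", "dendrite", "node", "internode")
    return PassiveProperties(
        membrane_capacitance={k: 1.0 for k in kinds},
        axial_resistivity=150.0,
        leak_conductance={k: g_leak for k in kinds},
        leak_reversal={k: e_leak for k in kinds},
    )


def passive_cell(morphology, g_leak: float = 1e-4) -> vg.DiscretizedCell:
    """All-passive cell: zero active conductances, nodal HH silenced."""
    return vg.discretize(
        morphology,
        passive_leak_properties(g_leak),
        ZERO_THETA,
        node_hh=NodeHH(g_na=0.0, g_k=0.0, g_leak=g_leak, e_leak=-60.0),
    )


@pytest.fixture(scope="session")
def reference_metrics_ndb(desk_cfg):
    cell = desk_cfg.build(REFERENCE_THETA_NDB)
    return vg.measure_metrics(cell, desk_cfg.settings)


@pytest.fixture(scope="session")
def reference_metrics_db(desk_cfg):
    cell = desk_cfg.build(REFERENCE_THETA_DB)
    return vg.measure_metrics(cell, desk_cfg.settings)
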