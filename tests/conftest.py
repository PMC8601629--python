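"""Shared fixtures: canonical shapes, meshes, and one reusable rod run."""

from __future__ import annotations

import numpy as np
import pytest

import morphogrow as mg
from morphogrow.geometry import BoundaryCurve, mesh_interior


@pytest.fixture(scope="session")
def unit_disk() -> BoundaryCurve:
    """Unit-radius disk boundary centered at the origin, spacing 0.05."""
    c = mg.make_elliptical_cluster(2.0, 2.0, 0.05)
    return BoundaryCurve(c.points - np.array([1.0, 0.0]))


@pytest.fixture(scope="session")
def unit_disk_mesh(unit_disk):
    return mesh_interior(unit_disk, 0.05)


@pytest.fixture(scope="session")
def parabola() -> BoundaryCurve:
    """The standard initial cluster: length 1.5, width 1."""
    return mg.make_parabolic_cluster(1.5, 1.0, 0.05)


@pytest.fixture(scope="session")
def parabola_mesh(parabola):
    return mesh_interior(parabola, 0.06)


@pytest.fixture(scope="session")
def rod_trajectory():
    """A grown single-inhibitor rod (reused by several long-run tests)."""
    cfg = mg.scenario_config("fig3_muX8", snapshot_every=5)
    return mg.run(cfg)
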