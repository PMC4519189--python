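"""Shared fixtures: small compositions and hand-constructed trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from memdomain.model_io import CompositionSpec, Topology, Trajectory, table1_composition


@pytest.fixture(scope="session")
def table1() -> CompositionSpec:
    return table1_composition()


@pytest.fixture(scope="session")
def small_spec(table1) -> CompositionSpec:
    """Table-1 composition scaled to ~100 lipids per leaflet, a little water."""
    spec = table1.scaled(0.2)
    spec.water_count = 50
    return spec


def build_topology(entries, n_res=24) -> Topology:
    return Topology.from_molecules(entries, n_res_protein=n_res)


def build_traj(top: Topology, coords: np.ndarray, stride: float = 50.0,
               box=(10.0, 10.0, 10.0)) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    F = coords.shape[0]
    times = np.arange(F, dtype=float) * stride
    boxes = np.tile(np.asarray(box, dtype=float), (F, 1))
    return Trajectory(top, times, boxes, coords)


@pytest.fixture
def make_topology():
    return build_topology


@pytest.fixture
def make_traj():
    return build_traj
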