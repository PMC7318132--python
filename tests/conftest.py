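"""Shared fixtures: tiny hand-built active-site trajectories.

All fixtures are generated programmatically; the canonical toy geometry
places the iron at the origin and the oxo atom at (0, 0, 1.62) Å, so a
hydrogen on the +z axis above the oxo is collinear (H–oxo–Fe = 180°).
"""

from __future__ import annotations

import numpy as np
import pytest

from p450nac.nac_profiler import CatalyticCenter, SiteDefinition, SiteMap
from p450nac.structure_io import AtomRecord, Trajectory

FE_POS = (0.0, 0.0, 0.0)
OXO_POS = (0.0, 0.0, 1.62)


def make_trajectory(hydrogen_frames, hydrogen_names=None):
    """Trajectory with Fe, oxo and one H atom per entry of each frame dict.

    ``hydrogen_frames`` is a list of dicts mapping hydrogen name -> xyz; all
    frames must use the same names (the topology).
    """
    names = hydrogen_names or sorted(hydrogen_frames[0])
    topology = [
        AtomRecord(1, "FE", "HEM", 1, "A", "FE", FE_POS),
        AtomRecord(2, "OXO", "HEM", 1, "A", "O", OXO_POS),
    ]
    for i, name in enumerate(names):
        topology.append(
            AtomRecord(3 + i, name, "LIG", 2, "A", "H", tuple(hydrogen_frames[0][name]))
        )
    frames = np.array(
        [
            [FE_POS, OXO_POS] + [frame[name] for name in names]
            for frame in hydrogen_frames
        ],
        dtype=float,
    )
    return Trajectory(topology=topology, frames=frames)


def hydrogen_index(trajectory, name):
    return next(i for i, a in enumerate(trajectory.topology) if a.name == name)


@pytest.fixture
def center():
    return CatalyticCenter(fe_index=0, oxo_index=1)


@pytest.fixture
def two_site_fixture(center):
    """4-frame trajectory: site A accessed in frames 0-2, B in frame 2 only,
    nothing in frame 3 — the hand-enumerated 75/25 profile case."""
    on = (0.0, 0.0, 1.62 + 2.5)       # collinear above the oxo: accessible
    on_b = (0.0, 0.5, 1.62 + 2.8)     # slightly off axis, still accessible
    off = (0.0, 0.0, 1.62 + 6.0)      # beyond the distance window
    frames = [
        {"HA": on, "HB": off},
        {"HA": on, "HB": off},
        {"HA": on, "HB": on_b},
        {"HA": off, "HB": off},
    ]
    trajectory = make_trajectory(frames)
    site_map = SiteMap(
        {
            "A": SiteDefinition((hydrogen_index(trajectory, "HA"),), "beta"),
            "B": SiteDefinition((hydrogen_index(trajectory, "HB"),), "methyl"),
        }
    )
    return trajectory, site_map, center
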