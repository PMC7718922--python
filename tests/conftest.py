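"""Shared fixtures: hand-written caDNAno documents and cached models."""

from __future__ import annotations

import json

import numpy as np
import pytest

from origamifit.design import parse_cadnano
from origamifit.model import build_ideal_model
from origamifit.restraints import build_elastic_network
from origamifit.synthetic import FixtureSpec, make_dataset, make_design


def straight_lane(helix: int, lo: int, hi: int, n: int, direction: int):
    """Pointer quadruples for one continuous strand on [lo, hi)."""
    arr = [[-1, -1, -1, -1] for _ in range(n)]
    for s in range(lo, hi):
        prev, nxt = s - direction, s + direction
        if lo <= prev < hi:
            arr[s][0], arr[s][1] = helix, prev
        if lo <= nxt < hi:
            arr[s][2], arr[s][3] = helix, nxt
    return arr


def vstrand(num, row, col, scaf, stap, n):
    return {
        "num": num,
        "row": row,
        "col": col,
        "scaf": scaf,
        "stap": stap,
        "loop": [0] * n,
        "skip": [0] * n,
        "stap_colors": [],
    }


def cadnano_doc(vstrands, name="fixture"):
    return json.dumps({"name": name, "vstrands": vstrands})


@pytest.fixture(scope="session")
def two_helix_json():
    """Minimal 2-helix, 32-slot document: one circular scaffold loop and
    two whole-lane staples (no staple crossovers)."""
    n = 32
    scaf0 = straight_lane(0, 0, n, n, +1)
    scaf1 = straight_lane(1, 0, n, n, -1)
    # close the scaffold into one loop: 0 and 1 joined at both ends
    scaf0[n - 1][2], scaf0[n - 1][3] = 1, n - 1
    scaf1[n - 1][0], scaf1[n - 1][1] = 0, n - 1
    scaf1[0][2], scaf1[0][3] = 0, 0
    scaf0[0][0], scaf0[0][1] = 1, 0
    stap0 = straight_lane(0, 0, n, n, -1)
    stap1 = straight_lane(1, 0, n, n, +1)
    return cadnano_doc(
        [vstrand(0, 0, 0, scaf0, stap0, n), vstrand(1, 0, 1, scaf1, stap1, n)]
    )


@pytest.fixture(scope="session")
def two_helix_design(two_helix_json):
    return parse_cadnano(two_helix_json, lattice="honeycomb")


@pytest.fixture(scope="session")
def duplex_design():
    _, design = make_design(
        FixtureSpec(kind="duplex", length=21, nick_every=0)
    )
    return design


@pytest.fixture(scope="session")
def duplex_model(duplex_design):
    return build_ideal_model(duplex_design)


@pytest.fixture(scope="session")
def tube_design():
    _, design = make_design(FixtureSpec(kind="six_helix_tube", length=64))
    return design


@pytest.fixture(scope="session")
def tube_model(tube_design):
    return build_ideal_model(tube_design)


@pytest.fixture(scope="session")
def tube_network(tube_model, tube_design):
    return build_elastic_network(tube_model, tube_design)


@pytest.fixture(scope="session")
def tube_dataset():
    """Noise-free twisted six-helix tube with its 10 Å map."""
    return make_dataset(
        FixtureSpec(kind="six_helix_tube", length=64, twist=0.9,
                    resolution=10.0, voxel_size=2.0)
    )


@pytest.fixture()
def rng():
    # function-scoped so draws do not depend on test execution order
    return np.random.default_rng(20260919)
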