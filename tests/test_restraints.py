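"""Elastic-network construction, analytic forces, excluded volume."""

import numpy as np
import pytest

from origamifit.design import parse_cadnano
from origamifit.model import build_ideal_model
from origamifit.restraints import (
    BASEPAIR,
    INTERHELICAL,
    INTRAHELICAL,
    NetworkParams,
    RestraintSet,
    build_elastic_network,
    energy_and_forces,
    excluded_volume_forces,
)
from origamifit.synthetic import FixtureSpec, make_design

from conftest import cadnano_doc, straight_lane, vstrand

ALL = frozenset({"interhelical", "intrahelical", "basepair"})


def _single_bond(r0=10.0, k=1.0):
    return RestraintSet(
        i=np.array([0]), j=np.array([1]), r0=np.array([r0]),
        k=np.array([k]), cls=np.array([INTRAHELICAL], dtype=np.int8),
        exclusions=np.array([[0, 1]], dtype=np.int32),
    )


class TestBuildNetwork:
    def test_single_duplex_has_no_interhelical_bonds(self, duplex_model,
                                                     duplex_design):
        rs = build_elastic_network(duplex_model, duplex_design)
        assert np.sum(rs.cls == BASEPAIR) == 21
        assert np.sum(rs.cls == INTERHELICAL) == 0
        assert np.sum(rs.cls == INTRAHELICAL) > 0

    def test_double_crossover_adds_two_covalent_bonds(self):
        n = 32
        scaf0 = straight_lane(0, 0, n, n, +1)
        scaf1 = straight_lane(1, 0, n, n, -1)
        stap0 = straight_lane(0, 0, n, n, -1)
        stap1 = straight_lane(1, 0, n, n, +1)
        stap0[16][2], stap0[16][3] = 1, 16
        stap1[16][0], stap1[16][1] = 0, 16
        stap1[15][2], stap1[15][3] = 0, 15
        stap0[15][0], stap0[15][1] = 1, 15
        d = parse_cadnano(
            cadnano_doc([vstrand(0, 0, 0, scaf0, stap0, n),
                         vstrand(1, 0, 1, scaf1, stap1, n)]),
            lattice="honeycomb",
        )
        model = build_ideal_model(d)
        rs = build_elastic_network(model, d)
        inter = np.nonzero(rs.cls == INTERHELICAL)[0]
        assert inter.size > 0
        # covalent crossover bonds: consecutive-in-strand P beads that
        # sit on different helices
        helix_of_bead = model.nuc_helix[model.bead_nuc]
        covalent = 0
        for sid in np.unique(model.nuc_strand):
            nucs = np.nonzero(model.nuc_strand == sid)[0]
            for a, b in zip(nucs[:-1], nucs[1:]):
                i, j = int(model.nuc_p[a]), int(model.nuc_p[b])
                if helix_of_bead[i] != helix_of_bead[j]:
                    covalent += 1
                    key = (min(i, j), max(i, j))
                    pairs = set(
                        zip(np.minimum(rs.i, rs.j)[inter],
                            np.maximum(rs.i, rs.j)[inter])
                    )
                    assert key in pairs
        assert covalent == 2

    def test_no_backbone_bond_across_a_nick(self):
        # duplex with one staple nick at the 16/17 boundary
        n = 32
        scaf = straight_lane(0, 0, n, n, +1)
        stap = straight_lane(0, 0, n, n, -1)
        stap[17][2] = stap[17][3] = -1
        stap[16][0] = stap[16][1] = -1
        d = parse_cadnano(cadnano_doc([vstrand(0, 0, 0, scaf, stap, n)]),
                          lattice="honeycomb")
        from origamifit.design import find_nicks

        assert len(find_nicks(d)) == 1
        model = build_ideal_model(d)
        rs = build_elastic_network(model, d)
        staple_nucs = {
            s: n_
            for n_ in range(model.n_nucleotides)
            for s in [model.nuc_slot[n_]]
            if model.strand_kind[model.nuc_strand[n_]] == "staple"
        }
        pa = int(model.nuc_p[staple_nucs[16]])
        pb = int(model.nuc_p[staple_nucs[17]])
        pairs = set(zip(np.minimum(rs.i, rs.j), np.maximum(rs.i, rs.j)))
        assert (min(pa, pb), max(pa, pb)) not in pairs

    def test_rest_state_has_zero_energy_and_forces(self, tube_model,
                                                   tube_network):
        e, f, _ = energy_and_forces(tube_model, tube_network)
        assert e == pytest.approx(0.0, abs=1e-18)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    def test_tsv_round_trip(self, tube_network, tmp_path):
        path = tmp_path / "net.tsv"
        tube_network.to_tsv(path)
        back = RestraintSet.from_tsv(path)
        assert back.n_bonds == tube_network.n_bonds
        assert np.allclose(back.r0, tube_network.r0)
        assert np.array_equal(back.cls, tube_network.cls)


class TestEnergyAndForces:
    def test_single_stretched_bond_closed_form(self):
        rs = _single_bond(r0=10.0, k=1.0)
        coords = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        e, f, _ = energy_and_forces(coords, rs)
        assert e == pytest.approx(0.5 * 1.0 * 2.0 ** 2)
        assert np.linalg.norm(f[0]) == pytest.approx(2.0)
        assert np.allclose(f[0], -f[1])
        assert f[0][0] > 0  # pulls the beads together

    def test_forces_match_finite_differences(self, tube_model, tube_network,
                                             rng):
        x = tube_model.coords + 0.4 * rng.standard_normal(
            tube_model.coords.shape
        )
        _, f, _ = energy_and_forces(x, tube_network)
        h = 1e-6
        for _ in range(8):
            i = int(rng.integers(len(x)))
            a = int(rng.integers(3))
            xp, xm = x.copy(), x.copy()
            xp[i, a] += h
            xm[i, a] -= h
            ep, _, _ = energy_and_forces(xp, tube_network)
            em, _, _ = energy_and_forces(xm, tube_network)
            fd = -(ep - em) / (2 * h)
            assert fd == pytest.approx(f[i, a], rel=1e-6, abs=1e-8)

    def test_newtons_third_law(self, tube_model, tube_network, rng):
        x = tube_model.coords + 0.5 * rng.standard_normal(
            tube_model.coords.shape
        )
        _, f, _ = energy_and_forces(x, tube_network)
        scale = np.abs(f).max()
        assert np.linalg.norm(f.sum(axis=0)) <= 1e-9 * scale * len(x)
        torque = np.cross(x - x.mean(axis=0), f).sum(axis=0)
        assert np.linalg.norm(torque) <= 1e-9 * scale * len(x) * 100

    def test_energy_invariant_under_rigid_motion(self, tube_model,
                                                 tube_network, rng):
        x = tube_model.coords + 0.3 * rng.standard_normal(
            tube_model.coords.shape
        )
        e0, _, _ = energy_and_forces(x, tube_network)
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        e1, _, _ = energy_and_forces(x @ R.T + np.array([5.0, -3.0, 11.0]),
                                     tube_network)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_class_gating_is_additive(self, tube_model, tube_network, rng):
        x = tube_model.coords + 0.3 * rng.standard_normal(
            tube_model.coords.shape
        )
        total, _, br = energy_and_forces(x, tube_network,
                                         breakdown_terms=True)
        parts = sum(
            energy_and_forces(x, tube_network, frozenset({c}),
                              include_excluded_volume=False)[0]
            for c in ALL
        )
        assert total == pytest.approx(parts + br["excluded_volume"],
                                      rel=1e-12)
        # deactivating a class never increases the remaining terms
        e_no_inter, _, _ = energy_and_forces(
            x, tube_network, frozenset({"intrahelical", "basepair"})
        )
        assert e_no_inter <= total + 1e-12

    def test_coincident_beads_give_finite_zero_force(self):
        rs = _single_bond()
        coords = np.zeros((2, 3))
        e, f, _ = energy_and_forces(coords, rs)
        assert np.isfinite(e)
        assert np.all(f == 0.0)


class TestExcludedVolume:
    def test_beyond_cutoff_is_zero(self):
        coords = np.array([[0.0, 0.0, 0.0], [15.0, 0.0, 0.0]])
        e, f = excluded_volume_forces(coords)
        assert e == 0.0 and np.all(f == 0.0)

    def test_continuous_at_sigma(self):
        params = NetworkParams()
        coords = np.array([[0.0, 0.0, 0.0],
                           [params.sigma_ev, 0.0, 0.0]])
        e, f = excluded_volume_forces(coords, params)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_neighbor_search_equals_brute_force(self, rng):
        coords = 20.0 * rng.random((50, 3))
        e1, f1 = excluded_volume_forces(coords)
        e2, f2 = excluded_volume_forces(coords, brute_force=True)
        assert e1 == pytest.approx(e2, abs=1e-12)
        assert np.allclose(f1, f2, atol=1e-12)

    def test_switch_region_forces_match_finite_differences(self, rng):
        # sigma beyond the switch-on distance exercises the smooth taper
        params = NetworkParams(sigma_ev=9.5, k_ev=2.0)
        coords = 12.0 * rng.random((20, 3))
        _, f = excluded_volume_forces(coords, params)
        h = 1e-6
        for _ in range(6):
            i = int(rng.integers(len(coords)))
            a = int(rng.integers(3))
            xp, xm = coords.copy(), coords.copy()
            xp[i, a] += h
            xm[i, a] -= h
            ep, _ = excluded_volume_forces(xp, params)
            em, _ = excluded_volume_forces(xm, params)
            assert -(ep - em) / (2 * h) == pytest.approx(
                f[i, a], rel=1e-5, abs=1e-8
            )

    def test_bonded_exclusions_silence_rest_contacts(self, tube_model,
                                                     tube_network):
        e, _ = excluded_volume_forces(
            tube_model.coords, tube_network.params,
            exclusions=tube_network.exclusions,
        )
        assert e == pytest.approx(0.0, abs=1e-12)
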