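"""Map I/O, simulation, blurring, metrics, masks and compositing."""

import numpy as np
import pytest

from origamifit.density import (
    DensityMap,
    blur_cascade,
    blur_map,
    composite_frankenstein,
    density_and_gradient,
    focal_scan_bodies,
    fsc,
    make_body_mask,
    masked_ccc,
    parse_selection,
    read_map,
    segment_layers,
    simulate_map,
    transfer_function,
    trilinear,
    write_map,
    zone_map,
    _soft_edge,
)
from origamifit.model import build_ideal_model
from origamifit.synthetic import FixtureSpec, make_dataset, make_design


def _cubify(dmap, n=None):
    n = n or min(dmap.shape)
    return DensityMap(dmap.values[:n, :n, :n], dmap.voxel_size,
                      dmap.origin, resolution=dmap.resolution)


@pytest.fixture(scope="module")
def tube_map(tube_dataset):
    return tube_dataset.dmap


@pytest.fixture(scope="module")
def cube_map(tube_map):
    return _cubify(tube_map)


class TestMapIO:
    def test_round_trip_bitwise(self, tmp_path, rng):
        vals = rng.random((9, 11, 13)).astype(np.float32).astype(np.float64)
        dmap = DensityMap(vals, 1.5, np.array([3.0, -2.0, 7.5]))
        path = tmp_path / "map.mrc"
        write_map(dmap, path)
        back = read_map(path)
        assert np.array_equal(back.values, dmap.values)
        assert back.voxel_size == pytest.approx(1.5, rel=1e-6)
        assert np.allclose(back.origin, dmap.origin)

    def test_one_voxel_map(self, tmp_path):
        dmap = DensityMap(np.ones((1, 1, 1)), 2.0)
        path = tmp_path / "one.mrc"
        write_map(dmap, path)
        assert read_map(path).values.shape == (1, 1, 1)

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.mrc"
        path.write_bytes(b"this is not a density map at all" * 10)
        with pytest.raises(ValueError):
            read_map(path)

    def test_anisotropic_voxels_rejected(self, tmp_path):
        import gemmi

        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.zeros((4, 4, 4), dtype=np.float32))
        m.grid.set_unit_cell(gemmi.UnitCell(4, 8, 4, 90, 90, 90))
        m.grid.spacegroup = gemmi.SpaceGroup("P1")
        m.update_ccp4_header()
        path = tmp_path / "aniso.mrc"
        m.write_ccp4_map(str(path))
        with pytest.raises(ValueError, match="anisotropic"):
            read_map(path)


class TestSimulateMap:
    def test_single_bead_peaks_at_bead_voxel(self):
        dmap = simulate_map(np.array([[1.0, 2.0, 3.0]]), 10.0, 2.0)
        peak = np.unravel_index(np.argmax(dmap.values), dmap.shape)
        pos = dmap.origin + np.array(peak) * dmap.voxel_size
        assert np.all(np.abs(pos - [1, 2, 3]) <= dmap.voxel_size)

    def test_two_distant_beads_give_two_equal_maxima(self):
        # both beads on grid nodes so the sampled peaks match exactly
        pts = np.array([[0.0, 0.0, 0.0], [14.0, 0.0, 0.0]])  # > 6 sigma
        dmap = simulate_map(pts, 10.0, 2.0,
                            origin=np.array([-14.0, -14.0, -14.0]),
                            shape=(22, 15, 15))
        v = dmap.values
        interior = (
            (v >= np.roll(v, 1, 0)) & (v >= np.roll(v, -1, 0))
            & (v >= np.roll(v, 1, 1)) & (v >= np.roll(v, -1, 1))
            & (v >= np.roll(v, 1, 2)) & (v >= np.roll(v, -1, 2))
            & (v > 0.5 * v.max())
        )
        peaks = v[interior]
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(peaks[1], rel=1e-9)

    def test_mass_equals_total_weight(self, rng):
        pts = 30.0 * rng.random((25, 3))
        weights = 1.0 + rng.random(25)
        dmap = simulate_map(pts, 12.0, 2.0, weights=weights)
        assert dmap.total_mass() == pytest.approx(weights.sum(), rel=1e-6)

    def test_resolution_below_sampling_rejected(self):
        with pytest.raises(ValueError, match="twice the voxel"):
            simulate_map(np.zeros((1, 3)), 3.0, 2.0)


class TestBlur:
    def test_blur_to_own_resolution_is_identity(self, tube_map):
        out = blur_map(tube_map, tube_map.resolution)
        assert np.array_equal(out.values, tube_map.values)

    def test_cascade_preserves_mass(self, tube_map):
        maps = blur_cascade(tube_map, [22.0, 18.0, 14.0, 10.0])
        m0 = tube_map.total_mass()
        for m in maps:
            assert m.total_mass() == pytest.approx(m0, rel=1e-9)

    def test_cascade_requires_sorted_resolutions(self, tube_map):
        with pytest.raises(ValueError, match="sorted"):
            blur_cascade(tube_map, [10.0, 22.0])
        with pytest.raises(ValueError, match="better than"):
            blur_map(tube_map, 5.0)

    def test_point_source_blurs_to_closed_form_sigma(self):
        dmap = simulate_map(np.zeros((1, 3)), 6.0, 1.0, pad_sigmas=20.0)
        out = blur_map(dmap, 20.0)
        # recovered variance of the Gaussian = (0.225 R)^2
        pts = out.grid_points()
        w = out.values.ravel() / out.values.sum()
        var = float(w @ np.sum(pts ** 2, axis=1)) / 3.0
        assert np.sqrt(var) == pytest.approx(0.225 * 20.0, rel=1e-3)

    def test_transfer_resolution_decreases_along_cascade(self, cube_map):
        maps = blur_cascade(cube_map, [22.0, 16.0, 12.0])
        res = [transfer_function(cube_map, m).resolution_at(0.5)
               for m in maps]
        assert res[0] > res[1] > res[2]


class TestInterpolation:
    def test_node_values_exact(self, tube_map, rng):
        idx = np.stack([rng.integers(0, s, 10) for s in tube_map.shape],
                       axis=1)
        pts = tube_map.origin + idx * tube_map.voxel_size
        vals, _ = density_and_gradient(tube_map, pts, normalized=False)
        assert np.allclose(vals, tube_map.values[tuple(idx.T)], atol=1e-12)

    def test_uniform_map_has_zero_gradient(self):
        dmap = DensityMap(np.full((6, 6, 6), 3.3), 2.0)
        pts = np.array([[4.1, 5.7, 3.3], [0.0, 0.0, 0.0]])
        _, grad = density_and_gradient(dmap, pts, normalized=False)
        assert np.allclose(grad, 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        values = rng.random((8, 9, 10))
        g = rng.random((30, 3)) * [5, 6, 7] + 1.0
        _, grad = trilinear(values, g)
        h = 1e-7
        for a in range(3):
            gp, gm = g.copy(), g.copy()
            gp[:, a] += h
            gm[:, a] -= h
            vp, _ = trilinear(values, gp)
            vm, _ = trilinear(values, gm)
            assert np.allclose((vp - vm) / (2 * h), grad[:, a], atol=1e-6)

    def test_empty_point_list_rejected(self, tube_map):
        with pytest.raises(ValueError):
            density_and_gradient(tube_map, np.empty((0, 3)))


class TestMetrics:
    def test_ccc_identities(self, tube_map):
        assert masked_ccc(tube_map, tube_map) == pytest.approx(1.0)
        neg = tube_map.copy()
        neg.values = -neg.values
        assert masked_ccc(tube_map, neg) == pytest.approx(-1.0)
        shifted = tube_map.copy()
        shifted.values = shifted.values + 7.7
        assert masked_ccc(tube_map, shifted) == pytest.approx(1.0)

    def test_fsc_self_is_one(self, cube_map):
        curve = fsc(cube_map, cube_map)
        power = np.abs(np.fft.fftn(cube_map.values)) ** 2
        assert curve.values[0] == pytest.approx(1.0)
        assert np.all(curve.values[curve.values != 0] > 0.999999)

    def test_fsc_against_white_noise_is_small(self):
        # frozen Monte-Carlo instance on a 64^3 grid: a smooth structured
        # map against independent white noise decorrelates in every
        # shell beyond the first
        import scipy.ndimage as ndi

        rng = np.random.default_rng(0)
        struct = DensityMap(
            ndi.gaussian_filter(rng.standard_normal((64, 64, 64)), 3.0), 2.0
        )
        noise = DensityMap(
            np.random.default_rng(100).standard_normal((64, 64, 64)), 2.0
        )
        curve = fsc(struct, noise)
        assert np.all(np.abs(curve.values[2:]) < 0.2)

    def test_transfer_crossing_matches_blur_resolution(self, cube_map):
        blurred = blur_map(cube_map, 20.0)
        curve = transfer_function(cube_map, blurred)
        crossing = curve.resolution_at(0.5)
        # closed form: exp(-2 pi^2 sigma^2 f^2) = 0.5 with
        # sigma = 0.225 sqrt(20^2 - 10^2)
        sigma = 0.225 * np.sqrt(20.0 ** 2 - cube_map.resolution ** 2)
        expected = 1.0 / (np.sqrt(np.log(2.0) / 2.0) / (np.pi * sigma))
        shell = 1.0 / (cube_map.shape[0] * cube_map.voxel_size)
        assert abs(1.0 / crossing - 1.0 / expected) <= shell

    def test_fsc_requires_matching_cubic_grids(self, tube_map, cube_map):
        with pytest.raises(ValueError):
            fsc(tube_map, cube_map)
        zero = DensityMap(np.zeros(cube_map.shape), cube_map.voxel_size,
                          cube_map.origin)
        with pytest.raises(ValueError, match="all-zero"):
            fsc(cube_map, zero)


class TestBodyMasks:
    def test_soft_edge_profile(self):
        binary = np.zeros((11, 11, 11), dtype=bool)
        binary[5, 5, 5] = True
        out = _soft_edge(binary, 3)
        assert out[5, 5, 5] == 1.0
        assert out[5, 5, 6] == pytest.approx(0.75)  # (1+cos(pi/3))/2
        assert out[5, 5, 7] == pytest.approx(0.25)  # (1+cos(2pi/3))/2
        assert out[5, 5, 8] == pytest.approx(0.0)

    def test_zero_soft_layers_is_binary(self, tube_map):
        mask = make_body_mask(tube_map, lp_resolution=20.0, threshold=0.2,
                              soft_layers=0)
        assert set(np.unique(mask.values)) <= {0.0, 1.0}

    def test_values_bounded_and_interior_one(self, tube_map):
        mask = make_body_mask(tube_map, lp_resolution=20.0, threshold=0.2,
                              soft_layers=3)
        assert mask.values.min() >= 0.0 and mask.values.max() <= 1.0
        import scipy.ndimage as ndi

        interior = ndi.binary_erosion(mask.values >= 1.0)
        assert np.all(mask.values[interior] == 1.0)

    def test_threshold_excluding_everything_rejected(self, tube_map):
        with pytest.raises(ValueError):
            make_body_mask(tube_map, lp_resolution=20.0, threshold=2.0)


class TestZoning:
    def test_full_selection_covers_all_beads(self, tube_dataset):
        model = tube_dataset.truth
        sel = {h.num: None for h in tube_dataset.design.helices}
        mask, cropped, nucs = zone_map(tube_dataset.dmap, model, sel)
        vals, _ = density_and_gradient(mask, model.coords, normalized=False)
        assert np.all(vals >= 0.99)
        assert len(nucs) == model.n_nucleotides

    def test_selection_grammar(self):
        sel = parse_selection("h3:10-42,h5:*")
        assert sel == {3: (10, 42), 5: None}
        with pytest.raises(ValueError):
            parse_selection("helix3")

    def test_disjoint_selections_give_disjoint_cores(self, tube_dataset):
        model = tube_dataset.truth
        m1, _, _ = zone_map(tube_dataset.dmap, model, {0: (0, 20)},
                            soft_layers=0)
        m2, _, _ = zone_map(tube_dataset.dmap, model, {3: (40, 63)},
                            soft_layers=0)
        assert np.all(m1.values * m2.values == 0.0)

    def test_cropped_map_identifies_its_own_helix(self):
        ds = make_dataset(FixtureSpec(kind="two_helix", length=64,
                                      resolution=10.0))
        model = ds.truth
        mask, cropped, _ = zone_map(ds.dmap, model, {0: None})
        sim0 = simulate_map(
            model.coords[model.beads_for_nucleotides(
                model.nucleotides_for({0: None}))],
            10.0, 2.0, origin=cropped.origin, shape=cropped.shape,
        )
        sim1 = simulate_map(
            model.coords[model.beads_for_nucleotides(
                model.nucleotides_for({1: None}))],
            10.0, 2.0, origin=cropped.origin, shape=cropped.shape,
        )
        assert masked_ccc(cropped, sim0) > masked_ccc(cropped, sim1)

    def test_empty_selection_rejected(self, tube_dataset):
        with pytest.raises(ValueError):
            zone_map(tube_dataset.dmap, tube_dataset.truth, {99: None})


class TestLayersAndFocalScan:
    def test_one_mask_per_lattice_row(self, tube_dataset):
        masks = segment_layers(tube_dataset.design, tube_dataset.truth,
                               tube_dataset.dmap)
        rows = {h.row for h in tube_dataset.design.helices}
        assert len(masks) == len(rows)
        union = np.maximum.reduce([m.values for m in masks])
        vals, _ = density_and_gradient(
            DensityMap(union, tube_dataset.dmap.voxel_size,
                       tube_dataset.dmap.origin),
            tube_dataset.truth.coords, normalized=False,
        )
        assert np.all(vals >= 0.99)

    def test_2x2_block_full_length_gives_one_pair(self):
        ds = make_dataset(FixtureSpec(kind="block_2x2", length=32,
                                      resolution=12.0))
        pairs = focal_scan_bodies(ds.design, ds.truth, ds.dmap,
                                  focal_shape=(2, 2))
        assert len(pairs) == 1
        focal, remainder = pairs[0]
        assert remainder.values.max() == 0.0  # nothing outside the block

    def test_4x4_focal_2x2_stride_2_has_four_positions(self):
        ds = make_dataset(FixtureSpec(kind="block_4x4", length=32,
                                      resolution=12.0))
        pairs = focal_scan_bodies(
            ds.design, ds.truth, ds.dmap, focal_shape=(2, 2),
            focal_length=32, stride=2,
        )
        assert len(pairs) == 4  # 2x2 lattice positions, one slot window

    def test_focal_scan_covers_every_nucleotide(self):
        ds = make_dataset(FixtureSpec(kind="block_4x4", length=32,
                                      resolution=12.0))
        pairs = focal_scan_bodies(
            ds.design, ds.truth, ds.dmap, focal_shape=(2, 2),
            focal_length=16, stride=2,
        )
        covered = np.zeros(ds.truth.n_nucleotides, dtype=bool)
        for focal, _ in pairs:
            vals, _ = density_and_gradient(
                focal, ds.truth.coords[ds.truth.nuc_b], normalized=False
            )
            covered |= vals >= 0.99
        assert covered.all()

    def test_block_too_large_rejected(self, tube_dataset):
        with pytest.raises(ValueError, match="larger"):
            focal_scan_bodies(tube_dataset.design, tube_dataset.truth,
                              tube_dataset.dmap, focal_shape=(5, 5))


class TestCompositing:
    def test_identity_with_unit_mask(self, tube_map):
        from origamifit.density import BodyMask

        ones = BodyMask(np.ones(tube_map.shape), tube_map.voxel_size,
                        tube_map.origin)
        out = composite_frankenstein([tube_map], [ones])
        assert np.array_equal(out.values, tube_map.values)

    def test_partition_of_unity_recovers_original(self, tube_map):
        from origamifit.density import BodyMask

        half = np.zeros(tube_map.shape)
        half[: tube_map.shape[0] // 2] = 1.0
        m1 = BodyMask(half, tube_map.voxel_size, tube_map.origin)
        m2 = BodyMask(1.0 - half, tube_map.voxel_size, tube_map.origin)
        out = composite_frankenstein([tube_map, tube_map.copy()], [m1, m2])
        assert np.max(np.abs(out.values - tube_map.values)) <= 1e-12

    def test_overlap_takes_weighted_mean(self):
        from origamifit.density import BodyMask

        shape = (4, 4, 4)
        a = DensityMap(np.full(shape, 1.0), 2.0)
        b = DensityMap(np.full(shape, 3.0), 2.0)
        w = BodyMask(np.full(shape, 0.5), 2.0, np.zeros(3))
        out = composite_frankenstein([a, b], [w, w.copy()])
        assert np.allclose(out.values, 2.0)

    def test_mismatched_lists_rejected(self, tube_map):
        with pytest.raises(ValueError):
            composite_frankenstein([tube_map], [])
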