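"""Lattice estimation, hole detection, selection, grouping, export."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from icemap import (
    Hole,
    HoleLattice,
    IcemapError,
    ImagePlane,
    LatticeError,
    SelectionPolicy,
    StageTransform,
    align_pair,
    correlate_quality,
    dataframe_to_holes,
    detect_holes,
    estimate_lattice,
    export_navigator,
    group_holes,
    holes_to_dataframe,
    measure_holes,
    parse_navigator,
    reselect_holes,
    select_holes,
)
from icemap.targeting import items_to_holes
from icemap.synthetic import (
    SyntheticScene,
    make_lattice,
    make_thickness_field,
    simulate_pair,
)


def _unit_lattice(spacing=20.0, radius=5.0):
    return HoleLattice(
        origin_px=(0.0, 0.0),
        v1_px=(spacing, 0.0),
        v2_px=(0.0, spacing),
        hole_radius_px=radius,
        spacing_um=spacing * 144.6e-4,
    )


def _grid_holes(n_side=6, spacing=20.0, thicknesses=None, selected=None):
    holes = []
    hid = 0
    for i in range(n_side):
        for j in range(n_side):
            t = None if thicknesses is None else thicknesses[hid]
            holes.append(
                Hole(
                    id=hid,
                    center_px=(i * spacing, j * spacing),
                    mean_unfiltered=10.0,
                    mean_filtered=9.0,
                    thickness_nm=t,
                    selected=False if selected is None else selected[hid],
                )
            )
            hid += 1
    return holes


class TestEstimateLattice:
    def test_spacing_and_radius_on_truth(self, uniform_scene):
        scene, pair, _ = uniform_scene
        lat = estimate_lattice(pair.unfiltered)
        true_len = math.hypot(*scene.lattice.v1_px)
        assert math.hypot(*lat.v1_px) == pytest.approx(true_len, abs=0.5)
        assert lat.hole_radius_px == pytest.approx(
            scene.lattice.hole_radius_px, abs=1.0
        )
        assert lat.spacing_um == pytest.approx(2.5, abs=0.01)

    def test_rotated_lattice_recovered(self):
        shape = (1024, 1024)
        true = make_lattice(shape, rotation_deg=15.0)
        scene = SyntheticScene(
            lattice=true,
            image_shape=shape,
            thickness_field=make_thickness_field("uniform", {"value": 30.0}, shape),
            poisson_noise=True,
            seed=21,
        )
        pair, _ = simulate_pair(scene)
        lat = estimate_lattice(pair.unfiltered)
        # recovered basis vectors match some true lattice vector to 0.5 px / 1 deg
        true_vs = [np.array(true.v1_px), np.array(true.v2_px)]
        for v in (np.array(lat.v1_px), np.array(lat.v2_px)):
            dists = [
                min(np.linalg.norm(v - t), np.linalg.norm(v + t)) for t in true_vs
            ]
            assert min(dists) < 0.5
        for v, t in [(lat.v1_px, true_vs[0]), (lat.v2_px, true_vs[1])]:
            angle_v = math.degrees(math.atan2(v[1], v[0])) % 90
            angle_t = math.degrees(math.atan2(t[1], t[0])) % 90
            assert abs(angle_v - angle_t) < 1.0 or abs(angle_v - angle_t) > 89.0

    def test_blank_image_errors(self):
        rng = np.random.default_rng(0)
        plane = ImagePlane(
            rng.poisson(10.7, (512, 512)).astype(float), pixel_size_a=144.6
        )
        with pytest.raises(LatticeError):
            estimate_lattice(plane)


class TestDetectHoles:
    def test_full_recovery_on_clean_scene(self, uniform_scene):
        scene, pair, truth = uniform_scene
        lat = estimate_lattice(pair.unfiltered)
        holes = detect_holes(pair.unfiltered, lat)
        interior = truth[~truth.is_edge]
        assert len(holes) == len(interior)
        tree = cKDTree(interior[["row_px", "col_px"]].to_numpy())
        dist, _ = tree.query(np.array([h.center_px for h in holes]))
        assert dist.max() <= 1.0

    def test_constant_image_yields_nothing(self):
        plane = ImagePlane(np.full((512, 512), 7.0), pixel_size_a=144.6)
        holes = detect_holes(plane, _unit_lattice(spacing=170, radius=40))
        assert holes == []

    def test_border_holes_flagged_edge(self):
        shape = (1024, 1024)
        # origin placed so one column of holes overlaps the image border
        lat = make_lattice(shape, origin_px=(512.0, 30.0))
        scene = SyntheticScene(
            lattice=lat,
            image_shape=shape,
            thickness_field=make_thickness_field("uniform", {"value": 30.0}, shape),
            poisson_noise=False,
        )
        pair, truth = simulate_pair(scene)
        est = estimate_lattice(pair.unfiltered)
        with_edge = detect_holes(pair.unfiltered, est, include_edge=True)
        default = detect_holes(pair.unfiltered, est)
        edge = [h for h in with_edge if h.has_flag("edge")]
        assert truth.is_edge.any()
        assert len(edge) > 0
        assert len(default) == len(with_edge) - len(edge)
        assert all(not h.has_flag("edge") for h in default)


class TestMeasureHoles:
    def test_uniform_noiseless_thickness(self, uniform_scene, uniform_aligned, profile_200_msa):
        scene, pair, truth = uniform_scene
        lat = estimate_lattice(pair.unfiltered)
        holes = detect_holes(pair.unfiltered, lat)
        measured = measure_holes(holes, uniform_aligned, profile_200_msa, lat.hole_radius_px, 0.5)
        for h in measured:
            assert h.thickness_nm == pytest.approx(30.0, abs=1e-6)

    def test_matches_pixel_loop_oracle(self, noisy_scene, profile_200_msa):
        scene, pair, _ = noisy_scene
        aligned = align_pair(pair, (0.0, 0.0))
        lat = estimate_lattice(pair.unfiltered)
        holes = detect_holes(pair.unfiltered, lat)[:5]
        frac = 0.5
        measured = measure_holes(holes, aligned, profile_200_msa, lat.hole_radius_px, frac)
        radius = frac * lat.hole_radius_px
        for h in measured:
            cy, cx = h.center_px
            su = sf = n = 0.0
            for r in range(int(cy - radius) - 1, int(cy + radius) + 2):
                for c in range(int(cx - radius) - 1, int(cx + radius) + 2):
                    if (r - cy) ** 2 + (c - cx) ** 2 <= radius**2:
                        su += aligned.unfiltered.data[r, c]
                        sf += aligned.filtered.data[r, c]
                        n += 1
            expected = profile_200_msa.scale_nm * math.log(su / sf) - 4.0
            assert h.mean_unfiltered == pytest.approx(su / n, rel=1e-12)
            assert h.thickness_nm == pytest.approx(expected, abs=1e-9)

    def test_dead_region_flags_invalid(self, uniform_scene, profile_200_msa):
        scene, pair, _ = uniform_scene
        aligned = align_pair(pair, (0.0, 0.0))
        lat = estimate_lattice(pair.unfiltered)
        holes = detect_holes(pair.unfiltered, lat)
        # kill the counts around the first hole
        cy, cx = holes[0].center_px
        aligned.filtered.data[
            int(cy) - 45 : int(cy) + 45, int(cx) - 45 : int(cx) + 45
        ] = 0.0
        measured = measure_holes(holes, aligned, profile_200_msa, lat.hole_radius_px)
        assert measured[0].has_flag("invalid")
        assert not np.isfinite(measured[0].thickness_nm)
        assert not measured[1].has_flag("invalid")

    def test_unaligned_pair_rejected(self, uniform_scene, profile_200_msa):
        scene, pair, _ = uniform_scene
        with pytest.raises(IcemapError):
            measure_holes([], pair, profile_200_msa, 40.0)


class TestSelection:
    def test_window_selection_and_summary(self):
        holes = _grid_holes(2, thicknesses=[10.0, 25.0, 35.0, 50.0])
        out, summary = select_holes(holes, SelectionPolicy(20, 40))
        assert [h.selected for h in out] == [False, True, True, False]
        assert (summary.n_below, summary.n_within, summary.n_above,
                summary.n_flagged) == (1, 2, 1, 0)

    def test_default_policy_bounds(self):
        policy = SelectionPolicy()
        assert (policy.t_min_nm, policy.t_max_nm) == (20.0, 40.0)

    @pytest.mark.parametrize("boundary", [20.0, 40.0])
    def test_boundaries_inclusive(self, boundary):
        holes = _grid_holes(2, thicknesses=[boundary] * 4)
        out, summary = select_holes(holes, SelectionPolicy(20, 40))
        assert all(h.selected for h in out)
        assert summary.n_within == 4

    def test_flagged_holes_never_selected(self):
        holes = _grid_holes(2, thicknesses=[30.0] * 4)
        from dataclasses import replace

        holes[0] = replace(holes[0], flags=frozenset({"edge"}))
        holes[1] = replace(holes[1], flags=frozenset({"invalid"}))
        out, summary = select_holes(holes, SelectionPolicy(20, 40))
        assert [h.selected for h in out] == [False, False, True, True]
        assert summary.n_flagged == 2

    def test_partition_counts_sum(self):
        rng = np.random.default_rng(0)
        holes = _grid_holes(6, thicknesses=list(rng.uniform(-5, 80, 36)))
        _, summary = select_holes(holes, SelectionPolicy(20, 40))
        assert summary.n_total == 36

    def test_reselect_idempotent(self):
        holes = _grid_holes(4, thicknesses=list(np.linspace(5, 60, 16)))
        policy = SelectionPolicy(20, 40)
        once, s1 = select_holes(holes, policy)
        twice, s2 = reselect_holes(once, policy)
        assert [h.selected for h in once] == [h.selected for h in twice]
        assert s1 == s2

    def test_reselect_many_points_matches_select(self):
        rng = np.random.default_rng(1)
        n = 5000
        holes = [
            Hole(id=i, center_px=(float(i), 0.0), thickness_nm=float(t))
            for i, t in enumerate(rng.uniform(0, 100, n))
        ]
        policy = SelectionPolicy(20, 40)
        a, _ = select_holes(holes, policy)
        b, _ = reselect_holes(holes, policy)
        assert [h.selected for h in a] == [h.selected for h in b]

    def test_reselect_widened_selects_all(self):
        holes = _grid_holes(3, thicknesses=list(np.linspace(1, 200, 9)))
        out, summary = reselect_holes(holes, SelectionPolicy(0, 1000))
        assert all(h.selected for h in out)
        assert summary.n_within == 9

    def test_reselect_missing_thickness_lists_ids(self):
        holes = _grid_holes(2, thicknesses=[30.0, None, 25.0, None])
        with pytest.raises(IcemapError, match=r"\[1, 3\]"):
            reselect_holes(holes, SelectionPolicy(20, 40))


class TestGrouping:
    def test_full_block_one_group(self):
        holes = _grid_holes(3, thicknesses=[30.0] * 9)
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, groups = group_holes(holes, _unit_lattice(), (3, 3))
        assert len(groups) == 1
        assert sorted(groups[0].member_ids) == list(range(9))

    def test_unselected_members_skipped(self):
        t = [30.0] * 9
        t[4] = 50.0
        t[7] = 10.0
        holes = _grid_holes(3, thicknesses=t)
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, groups = group_holes(holes, _unit_lattice(), (3, 3))
        assert len(groups) == 1
        assert len(groups[0].member_ids) == 7
        assert 4 not in groups[0].member_ids and 7 not in groups[0].member_ids

    def test_nothing_selected(self):
        holes = _grid_holes(3, thicknesses=[50.0] * 9)
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, groups = group_holes(holes, _unit_lattice(), (3, 3))
        assert groups == []
        assert all(h.group_id is None for h in holes)

    def test_anchor_is_member_nearest_centroid(self):
        holes = _grid_holes(3, thicknesses=[30.0] * 9)
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, groups = group_holes(holes, _unit_lattice(), (3, 3))
        assert groups[0].anchor_id == 4  # center of the 3x3 block

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        rows=st.integers(1, 4),
        cols=st.integers(1, 4),
    )
    def test_groups_partition_selected_set(self, seed, rows, cols):
        rng = np.random.default_rng(seed)
        n_side = 6
        thicknesses = list(rng.uniform(0, 80, n_side * n_side))
        holes = _grid_holes(n_side, thicknesses=thicknesses)
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, groups = group_holes(holes, _unit_lattice(), (rows, cols))
        member_ids = [i for g in groups for i in g.member_ids]
        selected_ids = [h.id for h in holes if h.selected]
        assert sorted(member_ids) == sorted(selected_ids)  # union + disjoint
        assert len(member_ids) == len(set(member_ids))
        assert all(len(g.member_ids) <= rows * cols for g in groups)
        by_id = {h.id: h for h in holes}
        for g in groups:
            assert all(by_id[i].selected for i in g.member_ids)
            assert all(by_id[i].group_id == g.id for i in g.member_ids)


class TestNavigator:
    def _measured_holes(self):
        rng = np.random.default_rng(4)
        thicknesses = rng.uniform(5, 60, 25)
        # keep clear of the 0.05 rounding boundary at the policy edges
        thicknesses = np.where(np.abs(thicknesses - 20) < 0.1, 21.0, thicknesses)
        thicknesses = np.where(np.abs(thicknesses - 40) < 0.1, 39.0, thicknesses)
        holes = _grid_holes(5, thicknesses=list(thicknesses))
        holes, _ = select_holes(holes, SelectionPolicy(20, 40))
        holes, _ = group_holes(holes, _unit_lattice(), (3, 3))
        return holes

    def test_roundtrip_lossless(self):
        holes = self._measured_holes()
        text = export_navigator(holes, pixel_size_a=144.6)
        items = parse_navigator(text)
        assert len(items) == len(holes)
        for h, it in zip(sorted(holes, key=lambda h: h.id), items):
            assert it.id == h.id
            assert it.thickness_nm == pytest.approx(round(h.thickness_nm, 1))
            assert it.acquire == h.selected
            assert it.group_id == h.group_id
            s = 144.6e-4
            assert it.stage_xy_um[0] == pytest.approx(h.center_px[1] * s, abs=1e-4)
            assert it.stage_xy_um[1] == pytest.approx(h.center_px[0] * s, abs=1e-4)

    def test_crlf_accepted(self):
        holes = self._measured_holes()
        text = export_navigator(holes, pixel_size_a=144.6)
        assert parse_navigator(text.replace("\n", "\r\n")) == parse_navigator(text)

    def test_note_format(self):
        holes = [
            Hole(id=0, center_px=(100.0, 200.0), thickness_nm=30.04, selected=True)
        ]
        text = export_navigator(
            holes, stage_transform=StageTransform(((0, 1), (1, 0)))
        )
        assert "Note = 30.0 nm" in text
        assert "Acquire = 1" in text
        assert "StageXYZ = 200.0000 100.0000 0" in text

    def test_empty_list_header_only(self):
        text = export_navigator([], pixel_size_a=144.6)
        assert text.startswith("AdocVersion")
        assert "[Item" not in text

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            StageTransform(((1.0, 2.0), (2.0, 4.0)))

    def test_reselect_from_parsed_items(self):
        holes = self._measured_holes()
        text = export_navigator(holes, pixel_size_a=144.6)
        rebuilt = items_to_holes(parse_navigator(text))
        out, _ = reselect_holes(rebuilt, SelectionPolicy(20, 40))
        expected = [h.selected for h in sorted(holes, key=lambda h: h.id)]
        assert [h.selected for h in out] == expected


class TestQualityCorrelation:
    def _holes(self, thicknesses):
        return _grid_holes(
            int(math.isqrt(len(thicknesses))), thicknesses=list(thicknesses)
        )

    def test_monotone_relation_positive_rho(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(10, 80, 36)
        holes = self._holes(t)
        # CTF resolution worsens (grows) with thickness
        table = pd.DataFrame(
            {"id": range(36), "ctf_resolution_a": 2.5 + 0.05 * t}
        )
        result = correlate_quality(holes, table)
        assert result.spearman_rho > 0.99
        assert len(result.table) == 36

    def test_permuted_quality_near_zero(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(10, 80, 36)
        holes = self._holes(t)
        res = 2.5 + 0.05 * t
        table = pd.DataFrame(
            {"id": range(36), "ctf_resolution_a": rng.permutation(res)}
        )
        result = correlate_quality(holes, table)
        assert abs(result.spearman_rho) < 0.35

    def test_binned_summary(self):
        t = [5.0, 8.0, 15.0, 25.0]
        holes = self._holes(t)
        table = pd.DataFrame({"id": range(4), "ctf_resolution_a": [3, 5, 4, 6]})
        result = correlate_quality(holes, table, bin_width_nm=10.0)
        bins = dict(zip(result.binned["bin_nm"], result.binned["mean"]))
        assert bins[0.0] == pytest.approx(4.0)
        assert bins[10.0] == pytest.approx(4.0)
        assert bins[20.0] == pytest.approx(6.0)

    def test_no_matching_ids_errors(self):
        holes = self._holes([30.0] * 4)
        table = pd.DataFrame({"id": [100, 101], "ctf_resolution_a": [3.0, 4.0]})
        with pytest.raises(IcemapError):
            correlate_quality(holes, table)

    def test_missing_column_errors(self):
        holes = self._holes([30.0] * 4)
        with pytest.raises(IcemapError, match="ctf_resolution_a"):
            correlate_quality(holes, pd.DataFrame({"id": [0]}))


def test_holes_csv_roundtrip(tmp_path):
    holes = _grid_holes(3, thicknesses=[30.0] * 9)
    holes, _ = select_holes(holes, SelectionPolicy(20, 40))
    holes, _ = group_holes(holes, _unit_lattice(), (3, 3))
    from dataclasses import replace

    holes[2] = replace(holes[2], flags=frozenset({"edge", "low_confidence"}))
    path = tmp_path / "holes.csv"
    holes_to_dataframe(holes).to_csv(path, index=False)
    back = dataframe_to_holes(pd.read_csv(path))
    for a, b in zip(holes, back):
        assert (a.id, a.center_px, a.selected, a.group_id, a.flags) == (
            b.id,
            b.center_px,
            b.selected,
            b.group_id,
            b.flags,
        )
        assert b.thickness_nm == pytest.approx(a.thickness_nm)
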