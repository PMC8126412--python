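"""The three measurements and their invariances."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribcage import (
    AnalysisConfig,
    BoundingCuboid,
    collectivity_index,
    compute_metrics,
    define_midline,
    generate_embryo,
    migration_path_length,
    nearest_posterior_pairs,
    normalized_midline_distance,
)
from _oracles import (
    brute_force_collectivity_pct,
    brute_force_nearest_posterior_pairs,
    brute_force_path_length,
)

WIDTH50 = BoundingCuboid(0, 50, 0, 100, 0, 30)
MID = define_midline((25.0, 0.0, 15.0))


def track_df(positions, interval=5.0):
    rows = [("e", "n1", i * interval, *p) for i, p in enumerate(positions)]
    return pd.DataFrame(rows, columns=["embryo_id", "nucleus_id", "t_minutes", "x_um", "y_um", "z_um"])


class TestNormalizedMidlineDistance:
    def test_single_nucleus_arithmetic(self):
        # 15 µm from the midline, width 50 µm -> 30%
        assert normalized_midline_distance([(40.0, 50.0, 15.0)], MID, WIDTH50) == pytest.approx(30.0)

    def test_all_on_midline_is_zero(self):
        pts = [(25.0, y, 15.0) for y in (10.0, 20.0, 30.0)]
        assert normalized_midline_distance(pts, MID, WIDTH50) == 0.0

    def test_empty_side_is_missing_not_zero(self):
        assert math.isnan(normalized_midline_distance(np.empty((0, 3)), MID, WIDTH50))

    def test_matches_brute_force_mean_of_percentages(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 50, size=(40, 3))
        want = np.mean(
            [100.0 * math.hypot(x - 25.0, z - 15.0) / 50.0 for x, _, z in pts]
        )
        assert normalized_midline_distance(pts, MID, WIDTH50) == pytest.approx(want, abs=1e-9)

    def test_adding_midline_nucleus_cannot_raise_mean(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, size=(10, 3)).tolist()
        before = normalized_midline_distance(pts, MID, WIDTH50)
        after = normalized_midline_distance(pts + [[25.0, 50.0, 15.0]], MID, WIDTH50)
        assert after <= before


class TestCollectivityIndex:
    def test_single_pair(self):
        pts = [(10.0, 0.0, 0.0), (10.0, 10.0, 0.0)]
        assert collectivity_index(pts, WIDTH50) == pytest.approx(20.0)

    def test_collinear_chain(self):
        cuboid = BoundingCuboid(0, 100, 0, 100, 0, 30)
        pts = [(50.0, 0.0, 0.0), (50.0, 10.0, 0.0), (50.0, 20.0, 0.0)]
        # pairs {1,2} and {2,3}, both 10 µm, width 100 -> 10%
        assert collectivity_index(pts, cuboid) == pytest.approx(10.0)

    def test_fewer_than_two_nuclei_missing(self):
        assert math.isnan(collectivity_index([(1.0, 2.0, 3.0)], WIDTH50))

    def test_all_same_y_missing_with_no_posterior_relations(self):
        pts = [(10.0, 5.0, 0.0), (20.0, 5.0, 0.0), (30.0, 5.0, 0.0)]
        assert math.isnan(collectivity_index(pts, WIDTH50))

    def test_pair_deduplication_counts_shared_links_once(self):
        # two anterior nuclei share the same nearest posterior neighbor:
        # 3 nuclei, 2 distinct pairs
        pts = [(10.0, 0.0, 0.0), (40.0, 0.5, 0.0), (25.0, 10.0, 0.0)]
        pairs = nearest_posterior_pairs(pts)
        assert {tuple(sorted(p[:2])) for p in pairs} == {(0, 2), (1, 2)}

    def test_distance_tie_breaks_to_smallest_id(self):
        # two posterior candidates equidistant from nucleus a
        pts = [(25.0, 0.0, 0.0), (20.0, 10.0, 0.0), (30.0, 10.0, 0.0)]
        pairs = nearest_posterior_pairs(pts, ids=["a", "b", "c"])
        linked = {frozenset(p[:2]) for p in pairs}
        assert frozenset({"a", "b"}) in linked

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 41)
        pts = rng.uniform(0, 100, size=(n, 3))
        got = collectivity_index(pts, BoundingCuboid(0, 100, 0, 100, 0, 100))
        want = brute_force_collectivity_pct(pts.tolist(), 100.0)
        assert got == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=15,
        )
    )
    def test_property_same_pairs_as_brute_force(self, pts):
        got = nearest_posterior_pairs([list(p) for p in pts])
        want = brute_force_nearest_posterior_pairs([list(p) for p in pts])
        assert {frozenset(p[:2]) for p in got} == {frozenset(k) for k in want}

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 50, size=(12, 3))
        base = collectivity_index(pts, WIDTH50)
        scaled = collectivity_index(pts * 3.0, BoundingCuboid(0, 150, 0, 300, 0, 90))
        assert scaled == pytest.approx(base, rel=1e-12)


class TestMigrationPathLength:
    def test_stationary_is_zero(self):
        t = track_df([(5.0, 5.0, 5.0)] * 7)
        assert migration_path_length(t) == 0.0

    def test_straight_line_six_steps(self):
        t = track_df([(2.0 * i, 0.0, 0.0) for i in range(7)])
        assert migration_path_length(t, projection="xy") == pytest.approx(12.0)

    def test_single_point_missing(self):
        assert math.isnan(migration_path_length(track_df([(0.0, 0.0, 0.0)])))

    def test_xy_never_exceeds_xyz_and_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(0, 1, size=(8, 3)), axis=0)
        t = track_df(pos.tolist())
        xy = migration_path_length(t, projection="xy")
        xyz = migration_path_length(t, projection="xyz")
        assert xy <= xyz + 1e-12
        assert xyz == pytest.approx(brute_force_path_length(pos.tolist()), abs=1e-9)
        want_xy = brute_force_path_length([(x, y, 0.0) for x, y, _ in pos.tolist()])
        assert xy == pytest.approx(want_xy, abs=1e-9)


class TestComputeMetrics:
    def test_zero_noise_symmetric_embryo_has_equal_sides(self, wt_zero_noise_spec):
        table = compute_metrics(generate_embryo(wt_zero_noise_spec, "e"))
        dist = table[table["metric"] == "midline_distance_pct"]
        for tp, grp in dist.groupby("timepoint"):
            by_side = grp.set_index("side")["value"]
            assert by_side["left"] == pytest.approx(by_side["right"], abs=1e-12)

    def test_dlp_like_closer_to_midline_than_wildtype(self, wt_zero_noise_spec, dlp_zero_noise_spec):
        wt = compute_metrics(generate_embryo(wt_zero_noise_spec, "wt"))
        dlp = compute_metrics(generate_embryo(dlp_zero_noise_spec, "dlp"))
        for side in ("left", "right"):
            for tp in ("T1", "T2", "T3", "T4"):
                w = wt[(wt["side"] == side) & (wt["timepoint"] == tp)
                       & (wt["metric"] == "midline_distance_pct")]["value"].iloc[0]
                d = dlp[(dlp["side"] == side) & (dlp["timepoint"] == tp)
                        & (dlp["metric"] == "midline_distance_pct")]["value"].iloc[0]
                assert d < w

    def test_row_schema(self, wt_spec):
        table = compute_metrics(generate_embryo(wt_spec, "e"))
        assert list(table.columns) == ["embryo_id", "side", "timepoint", "metric", "value", "n_nuclei"]
        # 2 sides x 4 timepoints for distance and collectivity, 2 sides for paths
        dist = table[table["metric"] == "midline_distance_pct"]
        assert len(dist) == 8
        assert (table["n_nuclei"] >= 1).all()
        pct = table[table["metric"].isin(["midline_distance_pct", "collectivity_pct"])]["value"]
        assert ((pct >= 0) & (pct <= 100)).all()
        assert (table[table["metric"] == "path_length_um"]["value"] >= 0).all()

    def test_reflection_about_midline_swaps_side_values(self, wt_spec):
        s = generate_embryo(wt_spec, "e")
        mirrored = dataclasses.replace(
            s,
            nuclei=s.nuclei.assign(x_um=50.0 - s.nuclei["x_um"]),
            tracks=s.tracks.assign(x_um=50.0 - s.tracks["x_um"]),
        )
        a = compute_metrics(s).set_index(["side", "timepoint", "metric"])["value"]
        b = compute_metrics(mirrored).set_index(["side", "timepoint", "metric"])["value"]
        swap = {"left": "right", "right": "left"}
        for (side, tp, metric), val in a.items():
            assert b[(swap[side], tp, metric)] == pytest.approx(val, abs=1e-9)

    def test_pipeline_invariant_to_y_translation(self, wt_spec):
        s = generate_embryo(wt_spec, "e")
        dy = 37.5
        shifted = dataclasses.replace(
            s,
            nuclei=s.nuclei.assign(y_um=s.nuclei["y_um"] + dy),
            tracks=s.tracks.assign(y_um=s.tracks["y_um"] + dy),
            mesh_vertices=s.mesh_vertices + np.array([0.0, dy, 0.0]),
            merge_point=(s.merge_point[0], s.merge_point[1] + dy, s.merge_point[2]),
        )
        a = compute_metrics(s).set_index(["side", "timepoint", "metric"])["value"]
        b = compute_metrics(shifted).set_index(["side", "timepoint", "metric"])["value"]
        assert sorted(a.index) == sorted(b.index)
        for key, val in a.items():
            assert b[key] == pytest.approx(val, abs=1e-9)

    def test_uniform_scaling_preserves_percentages_and_scales_paths(self, wt_spec):
        c = 2.0
        s = generate_embryo(wt_spec, "e")
        scaled = dataclasses.replace(
            s,
            nuclei=s.nuclei.assign(
                x_um=c * s.nuclei["x_um"], y_um=c * s.nuclei["y_um"], z_um=c * s.nuclei["z_um"]
            ),
            tracks=s.tracks.assign(
                x_um=c * s.tracks["x_um"], y_um=c * s.tracks["y_um"], z_um=c * s.tracks["z_um"]
            ),
            mesh_vertices=c * s.mesh_vertices,
            merge_point=tuple(c * v for v in s.merge_point),
        )
        cfg = AnalysisConfig()
        cfg_scaled = dataclasses.replace(cfg, region_near_um=c * 40.0, region_far_um=c * 80.0)
        a = compute_metrics(s, cfg).set_index(["side", "timepoint", "metric"])["value"]
        b = compute_metrics(scaled, cfg_scaled).set_index(["side", "timepoint", "metric"])["value"]
        for (side, tp, metric), val in a.items():
            expected = c * val if metric == "path_length_um" else val
            assert b[(side, tp, metric)] == pytest.approx(expected, rel=1e-9)

    def test_path_window_config(self, wt_spec):
        s = generate_embryo(wt_spec, "e")
        short = compute_metrics(s, AnalysisConfig(path_window_minutes=10.0))
        full = compute_metrics(s, AnalysisConfig(path_window_minutes=30.0))
        p_short = short[short["metric"] == "path_length_um"]["value"].mean()
        p_full = full[full["metric"] == "path_length_um"]["value"].mean()
        assert p_short < p_full
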