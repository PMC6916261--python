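import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from papyrusnet import (
    OccupancyTable,
    build_turnover_datasets,
    compute_circularity,
    covariate_frame,
    load_occupancy_table,
    load_patch_table,
    pairwise_edge_distances,
)
from papyrusnet.patch_io import (
    Patch,
    PatchNetwork,
    PatchValidationError,
    write_occupancy_table,
    write_patch_table,
)
from tests.conftest import make_patch


class TestCircularity:
    @pytest.mark.parametrize(
        "area, perimeter, expected",
        [
            (math.pi, 2 * math.pi, 1.0),  # unit circle: isoperimetric identity
            (1.0, 4.0, math.pi / 4),  # unit square
            (2.0, 6.0, 8 * math.pi / 36),  # 1x2 rectangle
        ],
    )
    def test_known_shapes(self, area, perimeter, expected):
        assert compute_circularity(area, perimeter) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("area, perimeter", [(0, 1), (1, 0), (-1, 4), (1, -4)])
    def test_nonpositive_inputs_rejected(self, area, perimeter):
        with pytest.raises(ValueError):
            compute_circularity(area, perimeter)

    @given(
        area=st.floats(0.01, 1e6),
        perimeter=st.floats(0.1, 1e5),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, area, perimeter, scale):
        # scaling a polygon by s multiplies area by s^2 and perimeter by s
        c1 = compute_circularity(area, perimeter)
        c2 = compute_circularity(area * scale**2, perimeter * scale)
        assert c2 == pytest.approx(c1, rel=1e-9)


class TestEdgeDistances:
    def test_point_euclidean(self):
        dm = pairwise_edge_distances(np.array([[0.0, 0.0], [3.0, 4.0]]), ids=["a", "b"])
        assert dm.d[0, 1] == pytest.approx(5.0)
        assert dm.d[0, 0] == 0.0 and dm.d[1, 1] == 0.0

    def test_polygon_gap(self):
        # two unit squares with a 10 m gap between nearest edges
        sq1 = box(0, 0, 1, 1)
        sq2 = box(11, 0, 12, 1)
        dm = pairwise_edge_distances([sq1, sq2], ids=["a", "b"])
        assert dm.d[0, 1] == pytest.approx(10.0)

    def test_touching_polygons_zero(self):
        dm = pairwise_edge_distances([box(0, 0, 1, 1), box(1, 0, 2, 1)])
        assert dm.d[0, 1] == 0.0

    def test_fewer_than_two_features_rejected(self):
        with pytest.raises(ValueError):
            pairwise_edge_distances(np.array([[0.0, 0.0]]))


class TestPatchValidation:
    def test_vegetation_sum_violation_names_patch(self):
        with pytest.raises(PatchValidationError, match="px"):
            make_patch("px", veg_disturbed=0.1, veg_moderate=0.5, veg_undisturbed=0.2,
                       veg_mixed=0.1)  # sums to 0.9

    def test_small_rounding_slack_renormalized(self):
        p = make_patch("p", veg_disturbed=0.1001, veg_moderate=0.5, veg_undisturbed=0.3,
                       veg_mixed=0.1)
        total = p.veg_disturbed + p.veg_moderate + p.veg_undisturbed + p.veg_mixed
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_parent_must_be_broad_wetland(self):
        patches = [make_patch("a"), make_patch("b", parent_wetland_id="a")]
        with pytest.raises(PatchValidationError, match="broad_wetland"):
            PatchNetwork(patches)

    def test_orphan_parent_rejected(self):
        patches = [make_patch("a"), make_patch("b", parent_wetland_id="zzz")]
        with pytest.raises(PatchValidationError, match="zzz"):
            PatchNetwork(patches)

    def test_duplicate_patch_id_rejected(self):
        with pytest.raises(PatchValidationError, match="duplicate"):
            PatchNetwork([make_patch("a"), make_patch("a")])


class TestRoundTrip:
    def test_patch_and_occupancy_round_trip(self, toy_network, toy_occupancy, tmp_path):
        ppath = tmp_path / "patches.csv"
        opath = tmp_path / "occupancy.csv"
        write_patch_table(toy_network, ppath)
        write_occupancy_table(toy_occupancy, opath)
        network, occupancy = load_patch_table(ppath, opath)
        assert network.patch_ids == toy_network.patch_ids
        for pid in network.patch_ids:
            a, b = network[pid], toy_network[pid]
            assert a.area == b.area and a.perimeter == b.perimeter
            assert a.veg_mixed == pytest.approx(b.veg_mixed)
        assert occupancy.entries == toy_occupancy.entries
        # data columns round-trip byte-identically
        df1 = pd.read_csv(ppath)
        write_patch_table(network, tmp_path / "again.csv")
        df2 = pd.read_csv(tmp_path / "again.csv")
        pd.testing.assert_frame_equal(df1, df2)

    def test_latlong_refused(self, tmp_path):
        df = pd.DataFrame(
            {
                "patch_id": ["a", "b"],
                "patch_type": ["papyrus", "papyrus"],
                "x": [29.9, 29.8],
                "y": [-1.28, -1.29],
                "area": [1.0, 1.0],
                "perimeter": [400.0, 400.0],
                "veg_disturbed": [0.25, 0.25],
                "veg_moderate": [0.25, 0.25],
                "veg_undisturbed": [0.25, 0.25],
                "veg_mixed": [0.25, 0.25],
            }
        )
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PatchValidationError, match="lat/long"):
            load_patch_table(path)

    def test_occupancy_value_outside_binary_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"patch_id": ["a", "a"], "species": ["s", "s"], "year": [2014, 2015],
             "present": [0, 2]}
        )
        path = tmp_path / "o.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PatchValidationError):
            load_occupancy_table(path)

    def test_geojson_polygons(self, tmp_path):
        import json

        feats = []
        for pid, x0 in (("a", 0.0), ("b", 2000.0)):
            poly = box(500_000 + x0, 9_800_000, 500_100 + x0, 9_800_100)
            feats.append(
                {
                    "type": "Feature",
                    "geometry": poly.__geo_interface__,
                    "properties": {
                        "patch_id": pid,
                        "patch_type": "papyrus",
                        "veg_disturbed": 0.25,
                        "veg_moderate": 0.25,
                        "veg_undisturbed": 0.25,
                        "veg_mixed": 0.25,
                    },
                }
            )
        path = tmp_path / "p.geojson"
        path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        network, _ = load_patch_table(path, format="geojson")
        assert network["a"].area == pytest.approx(1.0)  # 100 m x 100 m = 1 ha
        assert network["a"].perimeter == pytest.approx(400.0)


class TestTurnoverDatasets:
    def test_toy_partition_counts(self, toy_network, toy_occupancy):
        cov = covariate_frame(toy_network, toy_network.patch_ids,
                              connectivity={p: 0.0 for p in toy_network.patch_ids})
        col, surv, counts = build_turnover_datasets(toy_occupancy, "sp", cov)
        assert (counts.colonized, counts.survived, counts.extinct, counts.vacant) == (
            1, 1, 1, 1,
        )
        assert counts.surveyed == 4
        # partition: colonization set = absent year 1, survival = present year 1
        assert sorted(col.data.index) == ["a", "d"]
        assert sorted(surv.data.index) == ["b", "c"]
        assert set(col.data.index).isdisjoint(surv.data.index)
        assert counts.colonized + counts.vacant == col.n
        assert counts.survived + counts.extinct == surv.n

    def test_unknown_species_rejected(self, toy_network, toy_occupancy):
        cov = covariate_frame(toy_network, toy_network.patch_ids)
        with pytest.raises(KeyError):
            build_turnover_datasets(toy_occupancy, "nope", cov)

    def test_species_absent_everywhere(self, toy_network):
        entries = {}
        for pid in toy_network.patch_ids:
            entries[(pid, "sp", 2014)] = 0
            entries[(pid, "sp", 2015)] = 0
        occ = OccupancyTable(entries=entries, years=(2014, 2015))
        cov = covariate_frame(toy_network, toy_network.patch_ids)
        col, surv, counts = build_turnover_datasets(occ, "sp", cov)
        assert surv.n == 0
        assert col.n == 4 and col.n_events == 0

    def test_unsurveyed_patches_excluded(self, toy_network, toy_occupancy):
        entries = dict(toy_occupancy.entries)
        del entries[("d", "sp", 2015)]  # d unsurveyed in year 2
        occ = OccupancyTable(entries=entries, years=(2014, 2015))
        cov = covariate_frame(toy_network, toy_network.patch_ids)
        col, surv, counts = build_turnover_datasets(occ, "sp", cov)
        assert counts.surveyed == 3
        assert "d" not in col.data.index and "d" not in surv.data.index

    def test_missing_perimeter_drops_patch(self, toy_occupancy):
        patches = [make_patch(pid) for pid in "abc"] + [make_patch("d", perimeter=None)]
        network = PatchNetwork(patches)
        cov = covariate_frame(network, network.patch_ids)
        assert "d" not in cov.index
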