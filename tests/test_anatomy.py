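"""Landmark schema, region partition and the 30-variable record."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from airwaymorph import anatomy
from airwaymorph.anatomy import (
    LANDMARK_NAMES,
    VARIABLES,
    MeasurementRecord,
    RegionPartition,
    average_relative_error,
    measure_partition,
    partition_regions,
    piriform_lengths,
    resolve_landmarks,
    velum_length,
    vtl_incisor,
)
from airwaymorph.centerline import Centerline, slice_orthogonal
from airwaymorph.meshing import AirwayMesh


def full_landmark_set(**overrides):
    """A plausible raw 26-landmark mapping on a vertical tube at the origin."""
    raw = {
        "ga": (0.0, 2.0, -30.0), "gp": (0.0, -2.0, -30.0),
        "epS": (0.0, 1.0, -25.0), "epBse": (0.0, 2.0, -26.0), "epBsePo": (0.0, -2.0, -26.0),
        "PSInL": (-4.0, 0.0, -28.0), "PSInR": (4.0, 0.0, -28.0),
        "PSSuL": (-4.0, 0.0, -20.0), "PSSuR": (4.0, 0.0, -20.0),
        "VaInL": (-2.0, 1.0, -17.0), "VaInR": (2.0, 1.0, -17.0),
        "VeAn": (0.0, 3.0, -15.0), "VePo": (0.0, -3.0, -15.0),
        "VeBa": (0.0, 5.0, -8.0), "VeEnd": (0.0, 0.0, -15.0),
        "NpxAn": (0.0, 3.0, -3.0), "NpxPo": (0.0, -3.0, -3.0),
        "NasalS": (0.0, 4.0, -1.0),
        "ANS": (0.0, 40.0, -5.0), "PNS": (0.0, 10.0, -5.0),
        "ABI": (0.0, 45.0, -8.0), "PIC": (0.0, 38.0, -7.0), "PALS": (0.0, 30.0, -7.0),
    }
    raw.update(overrides)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items() if v is not None}


def straight_centerline(length=40.0, step=1.0):
    n = int(length / step) + 1
    pts = np.column_stack([np.zeros(n), np.zeros(n), -np.arange(n) * step])
    return Centerline.from_points(pts)


def tube_mesh(radius=5.0, length=40.0):
    tm = trimesh.creation.cylinder(radius=radius, height=length, sections=96)
    tm = tm.subdivide_to_size(1.0)
    tm.apply_translation([0.0, 0.0, -length / 2.0])
    return AirwayMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


class TestResolveLandmarks:
    def test_derived_midpoints(self):
        lms = resolve_landmarks(full_landmark_set())
        np.testing.assert_allclose(lms["MidVe"], [0.0, 0.0, -15.0])
        np.testing.assert_allclose(lms["NpxMid"], [0.0, 0.0, -3.0])
        np.testing.assert_allclose(lms["MMax"], [0.0, 34.0, -7.0])

    def test_registry_has_26_names(self):
        lms = resolve_landmarks(full_landmark_set())
        assert len(LANDMARK_NAMES) == 26
        assert sum(1 for n in LANDMARK_NAMES if n in lms) == 26

    def test_missing_required_is_named(self):
        raw = full_landmark_set()
        del raw["PNS"]
        with pytest.raises(ValueError, match="missing required landmark: PNS"):
            resolve_landmarks(raw)

    def test_unilateral_piriform_allowed(self):
        raw = full_landmark_set(PSInR=None)
        lms = resolve_landmarks(raw)
        assert "PSInR" not in lms

    def test_unknown_name_rejected(self):
        raw = full_landmark_set()
        raw["Sella"] = np.zeros(3)
        with pytest.raises(ValueError, match="unknown landmark"):
            resolve_landmarks(raw)

    def test_ans_must_be_anterior_to_pns(self):
        raw = full_landmark_set(ANS=(0.0, 5.0, -5.0))
        with pytest.raises(ValueError, match="anterior"):
            resolve_landmarks(raw)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        raw = full_landmark_set()
        rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in raw.items()]
        path = tmp_path / "lms.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        lms = resolve_landmarks(path)
        np.testing.assert_allclose(lms["PNS"], raw["PNS"])


class TestPartition:
    def test_planted_boundaries_on_straight_tube(self):
        # palatal plane crosses at z=-5 (s=5); anchors at s=15, 20, 30
        line = straight_centerline()
        lms = resolve_landmarks(full_landmark_set())
        part = partition_regions(line, lms)
        assert part.s_a == pytest.approx(5.0, abs=1e-9)
        assert part.s_b == pytest.approx(15.0, abs=1e-9)
        assert part.s_c == pytest.approx(20.0, abs=1e-9)
        assert part.s_d == pytest.approx(30.0, abs=1e-9)
        assert part.s_e == pytest.approx(40.0, abs=1e-9)

    def test_anchor_on_centerline_point_is_exact(self):
        line = straight_centerline()
        lms = resolve_landmarks(full_landmark_set(VeEnd=(0.0, 0.0, -17.0)))
        assert partition_regions(line, lms).s_b == pytest.approx(17.0, abs=1e-12)

    def test_out_of_order_boundaries_rejected(self):
        line = straight_centerline()
        lms = resolve_landmarks(
            full_landmark_set(PSSuL=(-4.0, 0.0, -35.0), PSSuR=(4.0, 0.0, -35.0))
        )
        with pytest.raises(ValueError, match="out of order"):
            partition_regions(line, lms)

    def test_no_palatal_crossing_rejected(self):
        line = straight_centerline()
        lms = resolve_landmarks(
            full_landmark_set(ANS=(0.0, 40.0, 10.0), PNS=(0.0, 10.0, 10.0),
                              VeBa=(0.0, 5.0, 5.0))
        )
        with pytest.raises(ValueError, match="palatal"):
            partition_regions(line, lms)

    def test_pipeline_partition_matches_planted_arcs(self, cylinder_run):
        found = np.asarray(cylinder_run["result"].partition.bounds)
        planted = np.asarray(cylinder_run["truth"].boundaries)
        np.testing.assert_allclose(found, planted, atol=1.0)


class TestMeasurePartition:
    @pytest.fixture(scope="class")
    @staticmethod
    def tube_setup():
        mesh = tube_mesh()
        line = straight_centerline()
        sections = slice_orthogonal(mesh, line)
        return mesh, line, sections

    def test_cylinder_region_volumes_and_lengths(self, tube_setup):
        mesh, line, sections = tube_setup
        part = RegionPartition(s_a=0.0, s_b=15.0, s_c=30.0, s_d=35.0, s_e=40.0)
        vals = measure_partition(mesh, line, sections, part)
        for name, expect in [("Nasopharynx", 15.0), ("Oropharynx", 15.0),
                             ("Laryngopharynx", 5.0), ("Subglottal", 5.0)]:
            assert vals[name] == pytest.approx(np.pi * 25.0 * expect, rel=0.03)
        assert vals["NasopharynxL"] == 15.0
        assert vals["OropharynxL"] == 15.0
        assert vals["LaryngopharynxL"] == 5.0
        assert vals["SubglottalL"] == 5.0

    def test_additivity_exact(self, tube_setup):
        mesh, line, sections = tube_setup
        part = RegionPartition(s_a=2.0, s_b=13.0, s_c=27.0, s_d=33.0, s_e=40.0)
        vals = measure_partition(mesh, line, sections, part)
        assert vals["PharynxVolume"] == vals["Nasopharynx"] + vals["Oropharynx"] + vals["Laryngopharynx"]
        assert vals["PharynxLength"] == vals["NasopharynxL"] + vals["OropharynxL"] + vals["LaryngopharynxL"]

    def test_zero_length_region_has_zero_volume(self, tube_setup):
        mesh, line, sections = tube_setup
        part = RegionPartition(s_a=2.0, s_b=20.0, s_c=20.0, s_d=33.0, s_e=40.0)
        vals = measure_partition(mesh, line, sections, part)
        assert vals["Oropharynx"] == 0.0
        assert vals["OropharynxL"] == 0.0

    def test_volume_against_divergence_theorem(self, cylinder_run):
        """Trapezoidal CSA integral agrees with the mesh enclosed volume."""
        from airwaymorph.meshing import enclosed_volume

        rec = cylinder_run["result"].record
        total = rec["PharynxVolume"] + rec["Subglottal"]
        part = cylinder_run["result"].partition
        mesh_vol = enclosed_volume(cylinder_run["result"].faired)
        # the mesh also includes the tube above the palatal plane (s < s_a)
        extra = part.s_a * np.pi * 25.0
        assert total + extra == pytest.approx(mesh_vol, rel=0.02)


class TestVocalTractAndVelum:
    def test_vtl_collinear_oral_path(self):
        line = straight_centerline()
        lms = resolve_landmarks(full_landmark_set(
            ABI=(0.0, 30.0, -5.0), PIC=(0.0, 24.0, -5.0), PALS=(0.0, 16.0, -5.0),
            ANS=(0.0, 40.0, -5.0), PNS=(0.0, 10.0, -5.0),
        ))
        part = partition_regions(line, lms)
        # collinear ABI -> MMax -> PNS -> axis point at s_a, then down to s_d
        expect = 30.0 + (part.s_d - part.s_a)
        assert vtl_incisor(line, part, lms) == pytest.approx(expect, abs=1e-9)

    def test_vtl_planted_segments(self, cylinder_run):
        rec = cylinder_run["result"].record
        truth = cylinder_run["truth"].record["VTLength_i"]
        assert rec["VTLength_i"] == pytest.approx(truth, abs=1.0)

    def test_vtl_degenerate_pharynx(self):
        line = straight_centerline()
        lms = resolve_landmarks(full_landmark_set())
        part = RegionPartition(s_a=5.0, s_b=5.0, s_c=5.0, s_d=5.0, s_e=40.0)
        oral = vtl_incisor(line, part, lms)
        p_a = np.array([0.0, 0.0, -5.0])
        path = [lms["ABI"], lms["MMax"], lms["PNS"], p_a]
        expect = sum(np.linalg.norm(b - a) for a, b in zip(path[:-1], path[1:]))
        assert oral == pytest.approx(expect, abs=1e-9)

    def test_velum_collinear_points(self):
        lms = resolve_landmarks(full_landmark_set(
            PNS=(0.0, 10.0, -5.0), VeBa=(0.0, 10.0, -15.0), VeEnd=(0.0, 10.0, -25.0)
        ))
        assert velum_length(lms) == pytest.approx(20.0, abs=1e-6)

    def test_velum_right_angle_between_chord_and_polyline(self):
        lms = resolve_landmarks(full_landmark_set(
            PNS=(0.0, 10.0, 0.0), VeBa=(0.0, 20.0, 0.0), VeEnd=(10.0, 20.0, 0.0),
            ANS=(0.0, 40.0, 0.0),
        ))
        length = velum_length(lms)
        chord = np.sqrt(200.0)
        assert chord < length < 20.0
        # quadrature oracle: quadratic Bezier arc controlled by VeBa
        p0, p1, p2 = lms["PNS"], lms["VeBa"], lms["VeEnd"]
        ref, _ = quad(
            lambda t: np.linalg.norm(2 * ((1 - t) * (p1 - p0) + t * (p2 - p1))), 0, 1, limit=200
        )
        assert length == pytest.approx(ref, rel=1e-6)

    def test_velum_midpoint_degenerates_to_chord(self):
        lms = resolve_landmarks(full_landmark_set(
            PNS=(0.0, 10.0, -5.0), VeBa=(0.0, 7.5, -10.0), VeEnd=(0.0, 5.0, -15.0)
        ))
        assert velum_length(lms) == pytest.approx(np.sqrt(25.0 + 100.0), abs=1e-6)


class TestPiriform:
    def test_symmetric_pairs(self):
        lms = resolve_landmarks(full_landmark_set(
            PSSuL=(0.0, 0.0, 10.0), PSInL=(0.0, 0.0, 0.0),
            PSSuR=(0.0, 0.0, 10.0), PSInR=(0.0, 0.0, 0.0),
        ))
        left, right, avg = piriform_lengths(lms)
        assert left == right == avg == pytest.approx(10.0)

    def test_single_side_fallback(self):
        lms = resolve_landmarks(full_landmark_set(
            PSSuL=(0.0, 0.0, 8.0), PSInL=(0.0, 0.0, 0.0), PSInR=None,
        ))
        left, right, avg = piriform_lengths(lms)
        assert right is None
        assert left == avg == pytest.approx(8.0)

    def test_mean_of_both_sides(self):
        lms = resolve_landmarks(full_landmark_set(
            PSSuL=(0.0, 0.0, 6.0), PSInL=(0.0, 0.0, 0.0),
            PSSuR=(0.0, 0.0, 10.0), PSInR=(0.0, 0.0, 0.0),
        ))
        assert piriform_lengths(lms)[2] == pytest.approx(8.0)


class TestARE:
    def test_identity_is_zero(self, arc_run):
        rec = arc_run["result"].record
        assert average_relative_error(rec, rec) == 0.0

    def test_hand_computed_value(self):
        assert average_relative_error({"v": 100.0}, {"v": 110.0}) == pytest.approx(10.0 / 105.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=1e4),
        b=st.floats(min_value=0.1, max_value=1e4),
        c=st.floats(min_value=0.1, max_value=1e4),
        d=st.floats(min_value=0.1, max_value=1e4),
    )
    def test_symmetry(self, a, b, c, d):
        x, y = {"u": a, "v": c}, {"u": b, "v": d}
        assert average_relative_error(x, y) == pytest.approx(average_relative_error(y, x))

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError, match="share"):
            average_relative_error({"u": 1.0}, {"v": 1.0})


class TestMeasurementRecord:
    def test_full_pipeline_record_has_30_variables(self, arc_run):
        rec = arc_run["result"].record
        assert len(rec) == 30
        assert set(rec.values) == set(VARIABLES)

    def test_missing_piriform_side_handling(self, cylinder_spec):
        import dataclasses

        from airwaymorph import phantom, pipeline

        vol, lms, truth = phantom.generate_phantom(dataclasses.replace(cylinder_spec, seed=6))
        for name in ("PSInR",):
            lms.coordinates[name] = None
        res = pipeline.run_pipeline(vol, lms, roi_superior=truth.roi_superior_z,
                                    roi_inferior=truth.roi_inferior_z)
        rec = res.record
        assert rec["PSLengthRight"] is None
        assert rec["PSLengthLeft"] is not None
        assert rec["AveragePSLength"] == rec["PSLengthLeft"]
        numeric = [v for v in rec.values.values() if v is not None]
        assert len(numeric) == 29

    def test_inconsistent_provenance_rejected(self, cylinder_run, arc_run):
        with pytest.raises(ValueError, match="provenance"):
            anatomy.measure_all(
                cylinder_run["volume"],
                cylinder_run["result"].mask,
                arc_run["result"].faired,
                arc_run["result"].centerline,
                arc_run["result"].sections,
                arc_run["landmarks"],
            )

    def test_wrong_variable_count_rejected(self):
        vals = {k: 1.0 for k in VARIABLES[:-1]}
        with pytest.raises(ValueError, match="30 variables"):
            MeasurementRecord(values=vals)

    def test_missing_only_allowed_for_piriform(self):
        vals = {k: 1.0 for k in VARIABLES}
        vals["PharynxVolume"] = 3.0
        vals["PharynxLength"] = 3.0
        vals["GlottisArea"] = None
        with pytest.raises(ValueError, match="GlottisArea"):
            MeasurementRecord(values=vals)

    def test_tidy_and_wide_csv(self, tmp_path, arc_run):
        import pandas as pd

        rec = arc_run["result"].record
        anatomy.write_tidy_csv([rec], tmp_path / "tidy.csv")
        anatomy.write_wide_csv([rec], tmp_path / "wide.csv")
        tidy = pd.read_csv(tmp_path / "tidy.csv")
        wide = pd.read_csv(tmp_path / "wide.csv", index_col=0)
        assert len(tidy) == 30
        assert wide.shape == (1, 30)
        assert tidy[tidy.variable == "PharynxVolume"].value.iloc[0] == pytest.approx(
            rec["PharynxVolume"]
        )
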