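"""Data model, mesh I/O, snapping, side canonicalization and mark I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taphos3d import (
    AnatomicalFrame,
    BoneTemplate,
    Mark,
    MarkDatabase,
    SpecimenRecord,
    canonicalize_side,
    load_mesh,
    mark_reference_point,
    read_marks,
    save_mesh,
    segment_region,
    snap_to_surface,
    write_marks,
)
from taphos3d.bone_model import CANONICAL_LENGTH_MM
from taphos3d.synthetic import sample_surface_uniform


class TestMeshIO:
    def test_unit_cube_identity_read(self, unit_cube_path):
        mesh = load_mesh(unit_cube_path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12

    @pytest.mark.parametrize("suffix", ["obj", "ply"])
    def test_round_trip_phantom(self, phantom, tmp_path, suffix):
        path = tmp_path / f"phantom.{suffix}"
        save_mesh(phantom, path)
        back = load_mesh(path)
        assert back.n_faces == phantom.n_faces
        assert np.allclose(back.vertices, phantom.vertices, atol=1e-4)

    def test_quad_face_rejected_with_face_index(self, tmp_path):
        path = tmp_path / "quad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        with pytest.raises(ValueError, match="face 0"):
            load_mesh(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_mesh(tmp_path / "nope.obj")

    def test_canonical_length_validation(self, phantom):
        phantom.validate_length()  # within 10% of 250 mm
        squashed = BoneTemplate(AnatomicalFrame("tibia"), "right",
                                phantom.vertices, phantom.faces)
        with pytest.raises(ValueError, match="canonical"):
            squashed.validate_length()


class TestSnapToSurface:
    def test_vertex_is_fixed_point(self, unit_cube_path):
        mesh = load_mesh(unit_cube_path)
        pt, face_id, d = snap_to_surface([0, 0, 0], mesh)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(pt, [0, 0, 0])

    def test_point_above_triangle_centroid(self):
        # closed-form projection cross-checked by a barycentric grid search
        tri = BoneTemplate(
            AnatomicalFrame("humerus"), "right",
            np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0]]),
            np.array([[0, 1, 2]]))
        query = np.array([1.0, 1.0, 1.0])
        pt, face_id, d = snap_to_surface(query, tri)
        assert np.allclose(pt, [1, 1, 0], atol=1e-12)
        assert d == pytest.approx(1.0, abs=1e-12)
        # brute-force minimisation over a barycentric grid
        best = np.inf
        a, b, c = tri.vertices
        for u in np.linspace(0, 1, 201):
            for v in np.linspace(0, 1 - u, max(int(201 * (1 - u)), 1)):
                p = a + u * (b - a) + v * (c - a)
                best = min(best, np.linalg.norm(p - query))
        assert d <= best + 1e-9

    def test_tie_broken_by_lowest_face_index(self):
        # two parallel triangles, query equidistant between them
        mesh = BoneTemplate(
            AnatomicalFrame("humerus"), "right",
            np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0],
                      [0, 0, 2], [4, 0, 2], [0, 4, 2]]),
            np.array([[0, 1, 2], [3, 4, 5]]))
        _, face_id, d = snap_to_surface([1, 1, 1], mesh)
        assert d == pytest.approx(1.0)
        assert face_id == 0

    def test_distance_bounded_by_dense_surface_sampling(self, phantom, rng):
        samples = sample_surface_uniform(phantom, 10000, seed=7)
        for query in rng.uniform([-20, -40, -40], [270, 40, 40], size=(5, 3)):
            _, _, d = snap_to_surface(query, phantom)
            d_sampled = np.linalg.norm(samples - query, axis=1).min()
            assert d <= d_sampled + 1e-9

    def test_empty_mesh_rejected(self):
        empty = BoneTemplate(AnatomicalFrame("humerus"), "right",
                             np.empty((0, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            snap_to_surface([0, 0, 0], empty)


class TestMarkModel:
    def test_reference_point_circular(self):
        m = Mark("m1", "circular", "tooth_pit", [10.0, 0.0, 5.0])
        assert np.allclose(mark_reference_point(m), [10, 0, 5])

    def test_reference_point_linear_is_middle(self):
        m = Mark("m2", "linear", "tooth_score",
                 [[0, 0, 0], [5, 1, 0], [10, 2, 0]])
        assert np.allclose(mark_reference_point(m), [5, 1, 0])

    def test_linear_mark_needs_three_points(self):
        with pytest.raises(ValueError, match="3 point"):
            Mark("m3", "linear", "tooth_score", [[0, 0, 0], [1, 1, 1]])

    def test_label_kind_consistency(self):
        with pytest.raises(ValueError, match="requires kind"):
            Mark("m4", "linear", "tooth_pit",
                 [[0, 0, 0], [1, 1, 1], [2, 2, 2]])


class TestCanonicalizeSide:
    def test_right_identity_left_reflection(self):
        m = Mark("m1", "circular", "tooth_pit", [100.0, 4.0, -3.0])
        (right,) = canonicalize_side([m], "right")
        assert np.allclose(right.points, [[100, 4, -3]])
        (left,) = canonicalize_side([m], "left")
        assert np.allclose(left.points, [[100, -4, -3]])

    def test_unknown_side(self):
        with pytest.raises(ValueError, match="unknown side"):
            canonicalize_side([], "dorsal")

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(-300, 300, allow_nan=False),
        st.floats(-50, 50, allow_nan=False),
        st.floats(-50, 50, allow_nan=False)), min_size=1, max_size=5))
    def test_involution_preserves_x_and_z(self, coords):
        marks = [Mark(f"m{i}", "circular", "tooth_pit", list(c))
                 for i, c in enumerate(coords)]
        once = canonicalize_side(marks, "left")
        twice = canonicalize_side(once, "left")
        for orig, mirrored, restored in zip(marks, once, twice):
            assert np.array_equal(orig.points, restored.points)
            assert np.array_equal(orig.points[:, [0, 2]],
                                  mirrored.points[:, [0, 2]])


class TestSegmentRegion:
    def test_full_range_keeps_all_faces(self, phantom):
        sub = segment_region(phantom, (0.0, 251.0))
        assert sub.n_faces == phantom.n_faces

    def test_out_of_range_is_empty_with_warning(self, phantom):
        with pytest.warns(UserWarning, match="no faces"):
            sub = segment_region(phantom, (400.0, 500.0))
        assert sub.n_faces == 0

    def test_midpoint_split_partitions_faces(self, phantom):
        lo = segment_region(phantom, (0.0, 125.0))
        hi = segment_region(phantom, (125.0, 250.0))
        assert lo.n_faces + hi.n_faces == phantom.n_faces


def _example_database():
    rec1 = SpecimenRecord(item_id="C2-hum-L", site="Tarangire", taxon="zebra",
                          element="humerus", side="left", age="adult",
                          animal_size="3")
    rec1.marks = [
        Mark("p1", "circular", "tooth_pit", [210.0, 12.5, -3.0]),
        Mark("s1", "linear", "tooth_score",
             [[100.0, 1.0, 2.0], [105.0, 2.0, 2.5], [111.0, 2.5, 3.0]]),
    ]
    rec2 = SpecimenRecord(item_id="C2-hum-R", site="Tarangire", taxon="zebra",
                          element="humerus", side="right")
    rec2.marks = [Mark("p1", "circular", "percussion_mark", [50.0, -8.0, 1.0])]
    return MarkDatabase([rec1, rec2])


class TestMarkDatabaseIO:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        db = _example_database()
        path = tmp_path / f"marks.{fmt}"
        write_marks(db, path)
        assert read_marks(path) == db

    def test_linear_mark_missing_end_row(self, tmp_path):
        db = _example_database()
        path = tmp_path / "marks.csv"
        write_marks(db, path)
        lines = path.read_text().splitlines()
        lines = [ln for ln in lines if ",end," not in ln]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="s1"):
            read_marks(path)

    def test_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        from taphos3d.bone_model import MARKS_CSV_COLUMNS
        path.write_text(",".join(MARKS_CSV_COLUMNS) + "\n")
        assert len(read_marks(path)) == 0

    def test_duplicate_point_role_rejected(self, tmp_path):
        db = _example_database()
        path = tmp_path / "marks.csv"
        write_marks(db, path)
        lines = path.read_text().splitlines()
        dup = next(ln for ln in lines if ",middle," in ln)
        path.write_text("\n".join(lines + [dup]) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_marks(path)

    def test_duplicate_item_id_rejected(self):
        db = MarkDatabase([SpecimenRecord(item_id="A")])
        with pytest.raises(ValueError, match="duplicate item_id"):
            db.add(SpecimenRecord(item_id="A"))

    def test_empty_item_id_rejected(self):
        with pytest.raises(ValueError, match="item_id"):
            SpecimenRecord(item_id="")


def test_canonical_lengths():
    assert [CANONICAL_LENGTH_MM[e] for e in
            ("humerus", "femur", "radius-ulna", "tibia")] == \
        [250.0, 280.0, 300.0, 350.0]
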