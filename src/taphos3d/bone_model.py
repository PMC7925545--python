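"""Data model and I/O for bone meshes, surface marks and specimen records.

Coordinates live in a canonical anatomical frame, in millimetres:

* ``x`` — longitudinal axis, 0 at the distal end, increasing proximally;
* ``y`` — lateral (negative) to medial (positive);
* ``z`` — caudal (negative) to cranial (positive).

Left-side material is mirrored across the sagittal plane (``y -> -y``) by
:func:`canonicalize_side` so that lateral/medial semantics coincide for both
sides of an element, which is what every bilateral comparison downstream
assumes.

Marks are recorded as landmarks on the mesh surface: circular marks (tooth
pits, percussion marks) are a single point; linear marks (tooth scores, cut
marks) are three ordered points — beginning, middle, end.  Only the central
point of a mark is used as its reference location in the spatial statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ELEMENTS",
    "CANONICAL_LENGTH_MM",
    "SNAP_TOLERANCE_MM",
    "AnatomicalFrame",
    "BoneTemplate",
    "Mark",
    "SpecimenRecord",
    "MarkDatabase",
    "load_mesh",
    "save_mesh",
    "snap_to_surface",
    "mark_reference_point",
    "canonicalize_side",
    "segment_region",
    "read_marks",
    "write_marks",
]

#: Long-bone elements covered by the recording schema.
ELEMENTS = ("humerus", "femur", "radius-ulna", "tibia")

#: Canonical longitudinal extent of each element's frame, mm.
CANONICAL_LENGTH_MM = {
    "humerus": 250.0,
    "femur": 280.0,
    "radius-ulna": 300.0,
    "tibia": 350.0,
}

#: Maximum distance (mm) a recorded mark point may sit off the mesh surface.
SNAP_TOLERANCE_MM = 2.0

SIDES = ("left", "right")
MARK_KINDS = ("circular", "linear")
MARK_LABELS = ("tooth_pit", "tooth_score", "cut_mark", "percussion_mark")
#: Which recording kind each mark label requires.
LABEL_KIND = {
    "tooth_pit": "circular",
    "percussion_mark": "circular",
    "tooth_score": "linear",
    "cut_mark": "linear",
}
POINT_ROLES_LINEAR = ("begin", "middle", "end")

MARKS_CSV_COLUMNS = [
    "item_id", "site", "taxon", "element", "side", "age", "animal_size",
    "mark_id", "label", "kind", "point_role", "x_mm", "y_mm", "z_mm",
]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Canonical coordinate frame of a long-bone element."""

    element: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(
                f"unknown element {self.element!r}; expected one of {ELEMENTS}"
            )

    @property
    def canonical_length(self) -> float:
        """Longitudinal extent of the frame in mm (distal end at x = 0)."""
        return CANONICAL_LENGTH_MM[self.element]


@dataclass
class BoneTemplate:
    """A triangulated bone mesh in its element's canonical frame."""

    frame: AnatomicalFrame
    side: str
    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array of mm coordinates")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex indices")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face references a vertex index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def x_extent(self) -> float:
        """Longitudinal bounding-box extent, mm."""
        return float(self.vertices[:, 0].max() - self.vertices[:, 0].min())

    def bounding_box(self) -> np.ndarray:
        """(2, 3) array of per-axis min/max, mm."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def validate_length(self, rel_tol: float = 0.10) -> None:
        """Check the x-extent against the element's canonical length."""
        L = self.frame.canonical_length
        if abs(self.x_extent - L) > rel_tol * L:
            raise ValueError(
                f"mesh x-extent {self.x_extent:.1f} mm deviates more than "
                f"{rel_tol:.0%} from canonical {L:.0f} mm for {self.frame.element}"
            )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


@dataclass
class Mark:
    """A single recorded bone-surface modification."""

    mark_id: str
    kind: str
    label: str
    points: np.ndarray             # (1, 3) circular / (3, 3) linear, mm
    face_ids: list[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MARK_KINDS:
            raise ValueError(f"kind must be one of {MARK_KINDS}, got {self.kind!r}")
        if self.label not in MARK_LABELS:
            raise ValueError(
                f"label must be one of {MARK_LABELS}, got {self.label!r}"
            )
        if LABEL_KIND[self.label] != self.kind:
            raise ValueError(
                f"label {self.label!r} requires kind {LABEL_KIND[self.label]!r}, "
                f"got {self.kind!r}"
            )
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        expected = 1 if self.kind == "circular" else 3
        if self.points.shape != (expected, 3):
            raise ValueError(
                f"{self.kind} mark {self.mark_id!r} needs exactly {expected} "
                f"point(s), got shape {self.points.shape}"
            )

    @property
    def reference_point(self) -> np.ndarray:
        return mark_reference_point(self)


@dataclass
class SpecimenRecord:
    """One specimen (bone) with its metadata and marks."""

    item_id: str
    site: str = ""
    taxon: str = ""
    element: str = ""
    side: str = ""
    age: str = ""
    animal_size: str = ""
    marks: list[Mark] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValueError("item_id is mandatory and must be non-empty")


class MarkDatabase:
    """Collection of specimen records keyed by item_id (case-sensitive)."""

    def __init__(self, records: list[SpecimenRecord] | None = None):
        self._records: dict[str, SpecimenRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, record: SpecimenRecord) -> None:
        if record.item_id in self._records:
            raise ValueError(f"duplicate item_id {record.item_id!r}")
        self._records[record.item_id] = record

    def __getitem__(self, item_id: str) -> SpecimenRecord:
        return self._records[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    @property
    def item_ids(self) -> list[str]:
        return list(self._records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkDatabase):
            return NotImplemented
        if self.item_ids != other.item_ids:
            return False
        for a, b in zip(self, other):
            if (a.item_id, a.site, a.taxon, a.element, a.side, a.age,
                    a.animal_size) != (b.item_id, b.site, b.taxon, b.element,
                                       b.side, b.age, b.animal_size):
                return False
            if len(a.marks) != len(b.marks):
                return False
            for ma, mb in zip(a.marks, b.marks):
                if (ma.mark_id, ma.kind, ma.label) != (mb.mark_id, mb.kind,
                                                       mb.label):
                    return False
                if not np.allclose(ma.points, mb.points, atol=1e-6):
                    return False
        return True


# ---------------------------------------------------------------------------
# Mesh I/O


def _scan_face_arity(path: Path, fmt: str) -> None:
    """Reject non-triangular faces with the offending face index.

    The mesh loader would otherwise silently triangulate quads, so the
    contract check is done on the raw file.
    """
    if fmt == "OBJ":
        face_idx = 0
        for line in path.read_text().splitlines():
            if line.startswith("f ") or line.startswith("f\t"):
                nverts = len(line.split()) - 1
                if nverts != 3:
                    raise ValueError(
                        f"face {face_idx} in {path.name} has {nverts} vertices; "
                        "only triangles are supported"
                    )
                face_idx += 1
    elif fmt == "PLY":
        lines = path.read_text().splitlines()
        try:
            end = lines.index("end_header")
        except ValueError:
            raise ValueError(f"{path.name}: not an ASCII PLY (no end_header)")
        counts = {}
        order = []
        for ln in lines[:end]:
            parts = ln.split()
            if parts and parts[0] == "element":
                counts[parts[1]] = int(parts[2])
                order.append(parts[1])
        body = lines[end + 1:]
        offset = 0
        for name in order:
            if name == "face":
                for i in range(counts[name]):
                    nverts = int(body[offset + i].split()[0])
                    if nverts != 3:
                        raise ValueError(
                            f"face {i} in {path.name} has {nverts} vertices; "
                            "only triangles are supported"
                        )
            offset += counts.get(name, 0)


def load_mesh(
    path: str | Path,
    fmt: str | None = None,
    element: str = "humerus",
    side: str = "right",
) -> BoneTemplate:
    """Load a triangulated OBJ/PLY mesh (mm units, no rescaling).

    Parameters
    ----------
    path : file path
    fmt : "OBJ" or "PLY"; inferred from the suffix when omitted.
    element, side : anatomical identity to attach to the template.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    if fmt not in ("OBJ", "PLY"):
        raise ValueError(f"unsupported mesh format {fmt!r} (OBJ or PLY)")
    _scan_face_arity(path, fmt)
    mesh = trimesh.load(path, file_type=fmt.lower(), process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise ValueError(f"{path.name}: empty or unreadable mesh")
    if len(mesh.faces) == 0:
        raise ValueError(f"{path.name}: mesh has no faces")
    return BoneTemplate(
        frame=AnatomicalFrame(element),
        side=side,
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
    )


def save_mesh(template: BoneTemplate, path: str | Path) -> None:
    """Write a template as ASCII OBJ or PLY (suffix decides)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    mesh = template.as_trimesh()
    if fmt == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
        if isinstance(data, bytes):
            data = data.decode()
    else:
        data = mesh.export(file_type="obj")
    path.write_text(data)


# ---------------------------------------------------------------------------
# Geometry


def _closest_points_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle of ``tri`` ((m, 3, 3)).

    Vectorised version of the standard region-classification algorithm
    (Ericson, *Real-Time Collision Detection*).  Returns (points, sq_dists).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(tri[:, 0])
    done = np.zeros(len(tri), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if m.any():
        v = (d1[m] / (d1[m] - d3[m]))[:, None]
        out[m] = a[m] + v * ab[m]
    done |= m
    # edge AC
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if m.any():
        w = (d2[m] / (d2[m] - d6[m]))[:, None]
        out[m] = a[m] + w * ac[m]
    done |= m
    # edge BC
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    if m.any():
        w = ((d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m])))[:, None]
        out[m] = b[m] + w * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        v = (vb[m] / denom)[:, None]
        w = (vc[m] / denom)[:, None]
        out[m] = a[m] + v * ab[m] + w * ac[m]

    d2s = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2s


def snap_to_surface(
    point, mesh: BoneTemplate | trimesh.Trimesh
) -> tuple[np.ndarray, int, float]:
    """Closest point on the mesh surface to ``point``.

    Returns ``(surface_point, face_id, distance_mm)``.  Distance ties between
    faces are broken by the lowest face index.
    """
    if isinstance(mesh, BoneTemplate):
        verts, faces = mesh.vertices, mesh.faces
    else:
        verts, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    if len(faces) == 0:
        raise ValueError("cannot snap to an empty mesh")
    p = np.asarray(point, dtype=float)
    tri = verts[faces]
    pts, d2 = _closest_points_on_triangles(p, tri)
    # lowest face index among ties (within float rounding)
    dmin = d2.min()
    face_id = int(np.flatnonzero(d2 <= dmin + 1e-12)[0])
    return pts[face_id], face_id, float(np.sqrt(d2[face_id]))


def mark_reference_point(mark: Mark) -> np.ndarray:
    """Reference coordinate of a mark: its single point, or the middle point
    of a linear mark."""
    if mark.kind == "circular":
        if mark.points.shape[0] != 1:
            raise ValueError(f"circular mark {mark.mark_id!r} malformed")
        return mark.points[0].copy()
    if mark.points.shape[0] != 3:
        raise ValueError(
            f"linear mark {mark.mark_id!r} has {mark.points.shape[0]} points, "
            "expected 3 (begin/middle/end)"
        )
    return mark.points[1].copy()


def canonicalize_side(
    marks: list[Mark], side: str, frame: AnatomicalFrame | None = None
) -> list[Mark]:
    """Mirror left-side marks across the sagittal plane (y -> -y).

    Right-side marks are returned unchanged (copies).  Applying the function
    twice to left-side marks restores the original coordinates.
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    out = []
    for m in marks:
        pts = m.points.copy()
        if side == "left":
            pts[:, 1] = -pts[:, 1]
        out.append(Mark(m.mark_id, m.kind, m.label, pts,
                        list(m.face_ids) if m.face_ids else None))
    return out


def segment_region(
    mesh: BoneTemplate, x_range: tuple[float, float]
) -> BoneTemplate:
    """Submesh of faces whose centroid x lies in ``[lo, hi)``.

    The interval closes at ``hi`` when ``hi`` reaches the mesh's own maximal
    x, so the terminal segment owns the bone end.  Vertices are reindexed.
    """
    lo, hi = x_range
    if not hi > lo:
        raise ValueError(f"empty x_range {x_range}")
    cx = mesh.face_centroids()[:, 0]
    keep = (cx >= lo) & (cx < hi)
    if hi >= mesh.vertices[:, 0].max():
        keep |= cx == hi
    faces = mesh.faces[keep]
    if len(faces) == 0:
        warnings.warn(f"segment_region: no faces in x range {x_range}")
        return BoneTemplate(mesh.frame, mesh.side,
                            np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return BoneTemplate(mesh.frame, mesh.side,
                        mesh.vertices[used], remap[faces])


# ---------------------------------------------------------------------------
# Mark database I/O


def _database_to_frame(db: MarkDatabase) -> pd.DataFrame:
    rows = []
    for rec in db:
        for mark in rec.marks:
            roles = ["single"] if mark.kind == "circular" else list(POINT_ROLES_LINEAR)
            for role, pt in zip(roles, mark.points):
                rows.append({
                    "item_id": rec.item_id, "site": rec.site, "taxon": rec.taxon,
                    "element": rec.element, "side": rec.side, "age": rec.age,
                    "animal_size": rec.animal_size, "mark_id": mark.mark_id,
                    "label": mark.label, "kind": mark.kind, "point_role": role,
                    "x_mm": pt[0], "y_mm": pt[1], "z_mm": pt[2],
                })
        if not rec.marks:
            pass  # specimens without marks are represented only in JSON
    return pd.DataFrame(rows, columns=MARKS_CSV_COLUMNS)


def _frame_to_database(df: pd.DataFrame) -> MarkDatabase:
    missing = set(MARKS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marks table missing columns: {sorted(missing)}")
    if df["item_id"].isna().any() or (df["item_id"].astype(str) == "").any():
        raise ValueError("marks table contains rows without item_id")
    dup = df.duplicated(subset=["item_id", "mark_id", "point_role"])
    if dup.any():
        bad = df.loc[dup, ["item_id", "mark_id", "point_role"]].iloc[0]
        raise ValueError(
            f"duplicate (item_id, mark_id, point_role) = "
            f"({bad.item_id!r}, {bad.mark_id!r}, {bad.point_role!r})"
        )
    db = MarkDatabase()
    for item_id, grp in df.groupby("item_id", sort=False):
        meta = grp.iloc[0]
        rec = SpecimenRecord(
            item_id=str(item_id), site=str(meta.site), taxon=str(meta.taxon),
            element=str(meta.element), side=str(meta.side), age=str(meta.age),
            animal_size=str(meta.animal_size),
        )
        for mark_id, mg in grp.groupby("mark_id", sort=False):
            kind = mg.iloc[0]["kind"]
            label = mg.iloc[0]["label"]
            roles = list(mg["point_role"])
            if kind == "circular":
                if roles != ["single"]:
                    raise ValueError(
                        f"circular mark {mark_id!r} must have one 'single' row, "
                        f"got roles {roles}"
                    )
                pts = mg[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            elif kind == "linear":
                if sorted(roles) != sorted(POINT_ROLES_LINEAR):
                    raise ValueError(
                        f"linear mark {mark_id!r} must have begin/middle/end "
                        f"rows, got roles {roles}"
                    )
                mg = mg.set_index("point_role").loc[list(POINT_ROLES_LINEAR)]
                pts = mg[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            else:
                raise ValueError(f"mark {mark_id!r}: unknown kind {kind!r}")
            rec.marks.append(Mark(str(mark_id), kind, label, pts))
        db.add(rec)
    return db


def write_marks(db: MarkDatabase, path: str | Path, fmt: str | None = None) -> None:
    """Write a mark database as CSV (one row per landmark point) or JSON
    (one object per specimen)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    if fmt == "CSV":
        _database_to_frame(db).to_csv(path, index=False)
    elif fmt == "JSON":
        objs = []
        for rec in db:
            objs.append({
                "item_id": rec.item_id, "site": rec.site, "taxon": rec.taxon,
                "element": rec.element, "side": rec.side, "age": rec.age,
                "animal_size": rec.animal_size,
                "marks": [
                    {"mark_id": m.mark_id, "label": m.label, "kind": m.kind,
                     "points": m.points.tolist()}
                    for m in rec.marks
                ],
            })
        path.write_text(json.dumps(objs, indent=1))
    else:
        raise ValueError(f"unsupported marks format {fmt!r} (CSV or JSON)")


def read_marks(path: str | Path, fmt: str | None = None) -> MarkDatabase:
    """Read a mark database written by :func:`write_marks`."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    if fmt == "CSV":
        df = pd.read_csv(path, dtype={"item_id": str, "mark_id": str},
                         keep_default_na=False)
        if df.empty:
            return MarkDatabase()
        df[["x_mm", "y_mm", "z_mm"]] = df[["x_mm", "y_mm", "z_mm"]].astype(float)
        return _frame_to_database(df)
    if fmt == "JSON":
        db = MarkDatabase()
        for obj in json.loads(path.read_text()):
            rec = SpecimenRecord(
                item_id=obj["item_id"], site=obj.get("site", ""),
                taxon=obj.get("taxon", ""), element=obj.get("element", ""),
                side=obj.get("side", ""), age=obj.get("age", ""),
                animal_size=obj.get("animal_size", ""),
            )
            for m in obj.get("marks", []):
                rec.marks.append(
                    Mark(m["mark_id"], m["kind"], m["label"],
                         np.asarray(m["points"], dtype=float))
                )
            db.add(rec)
        return db
    raise ValueError(f"unsupported marks format {fmt!r} (CSV or JSON)")
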