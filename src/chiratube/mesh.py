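"""The polygonal tube surface: construction, measurement, serialization.

A :class:`TubeMesh` is a closed orientable polyhedral surface: the lateral
cell polygons plus two cap polygons closing the tube ends.  The tube long
axis is z (anterior-posterior; z increases anteriorly); all face loops wind
so that face normals point outward and the enclosed volume is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tessellation import PlanarTessellation

__all__ = ["TubeMesh", "wrap_to_cylinder", "unwrap_to_plane",
           "polygon_area", "enclosed_volume"]


@dataclass
class TubeMesh:
    """Vertices plus ordered polygonal faces of the tube surface.

    ``faces`` holds the lateral cell loops (outward-CCW); ``cap_top`` and
    ``cap_bottom`` are the two end-ring loops.  ``topology_version`` is
    bumped by every neighbour-exchange event so downstream consumers can
    cache derived structures.
    """

    positions: np.ndarray                 # (n_v, 3) float64
    faces: list                           # list[list[int]], lateral cells
    cap_top: list = field(default_factory=list)
    cap_bottom: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    topology_version: int = 0

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_cells(self) -> int:
        return len(self.faces)

    def all_faces(self) -> list:
        """Lateral faces followed by the two caps (closed-surface face set)."""
        return list(self.faces) + [list(self.cap_top), list(self.cap_bottom)]

    def face_centroid(self, loop) -> np.ndarray:
        return self.positions[list(loop)].mean(axis=0)

    def copy(self) -> "TubeMesh":
        return TubeMesh(self.positions.copy(),
                        [list(f) for f in self.faces],
                        list(self.cap_top), list(self.cap_bottom),
                        dict(self.meta), self.topology_version)

    # -- topology helpers ------------------------------------------------
    def edge_faces(self) -> dict:
        """Map frozenset{a, b} -> list of face ids (caps are n_cells, n_cells+1)."""
        out: dict = {}
        for fi, loop in enumerate(self.all_faces()):
            m = len(loop)
            for k in range(m):
                e = frozenset((loop[k], loop[(k + 1) % m]))
                out.setdefault(e, []).append(fi)
        return out

    def vertex_faces(self) -> list:
        out = [[] for _ in range(self.n_vertices)]
        for fi, loop in enumerate(self.all_faces()):
            for v in loop:
                out[v].append(fi)
        return out

    def validate(self) -> None:
        """Assert the closed-surface invariants; raise ValueError otherwise."""
        for loop in self.all_faces():
            if len(loop) < 3:
                raise ValueError("face with fewer than 3 vertices")
            if len(set(loop)) != len(loop):
                raise ValueError("face with repeated vertices")
        ef = self.edge_faces()
        for e, fs in ef.items():
            if len(fs) != 2:
                raise ValueError(f"edge {sorted(e)} shared by {len(fs)} faces")
        V = self.n_vertices
        E = len(ef)
        F = self.n_cells + 2
        if V - E + F != 2:
            raise ValueError(f"Euler characteristic {V - E + F} != 2")
        valence = np.zeros(V, dtype=int)
        for loop in self.all_faces():
            valence[list(loop)] += 1
        if np.any(valence != 3):
            bad = int(np.sum(valence != 3))
            raise ValueError(f"{bad} vertices are not 3-valent")
        if enclosed_volume(self) <= 0:
            raise ValueError("enclosed volume not positive (bad winding)")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "positions": self.positions.tolist(),
            "faces": [list(map(int, f)) for f in self.faces],
            "cap_top": list(map(int, self.cap_top)),
            "cap_bottom": list(map(int, self.cap_bottom)),
            "meta": self.meta,
            "topology_version": self.topology_version,
        })

    @classmethod
    def from_json(cls, text: str) -> "TubeMesh":
        d = json.loads(text)
        return cls(np.asarray(d["positions"], dtype=float),
                   [list(f) for f in d["faces"]],
                   list(d["cap_top"]), list(d["cap_bottom"]),
                   d.get("meta", {}), d.get("topology_version", 0))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TubeMesh":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def to_obj(self, path) -> None:
        """Wavefront OBJ export (faces as polygon loops, 1-based indices)."""
        with open(path, "w") as fh:
            for p in self.positions:
                fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for loop in self.all_faces():
                fh.write("f " + " ".join(str(v + 1) for v in loop) + "\n")

    def to_vtk(self, path) -> None:
        """Legacy ASCII VTK polydata export for visualization."""
        loops = self.all_faces()
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nchiratube surface\nASCII\n"
                     "DATASET POLYDATA\n")
            fh.write(f"POINTS {self.n_vertices} double\n")
            for p in self.positions:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            ntot = sum(len(l) + 1 for l in loops)
            fh.write(f"POLYGONS {len(loops)} {ntot}\n")
            for loop in loops:
                fh.write(str(len(loop)) + " " + " ".join(map(str, loop)) + "\n")


# ---------------------------------------------------------------------------
# construction

def wrap_to_cylinder(tess: PlanarTessellation, diameter: float = 5.0) -> TubeMesh:
    """Roll the periodic rectangle onto a cylinder of the given diameter.

    x maps to azimuth ``phi = 2*pi*x/rect_width`` at radius ``diameter/2``,
    y maps to z.  The two clipped rectangle boundaries become the end rings,
    from which the cap faces are built.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    w, h = tess.rect_width, tess.rect_height
    xy = tess.vertices
    if np.any(xy[:, 0] >= w) or np.any(xy[:, 0] < 0):
        raise ValueError("tessellation is not in canonical periodic form")
    # explicit duplicated seam (e.g. the 1-cell degenerate rectangle) is not
    # a stitched periodic tessellation
    seam_lo = np.where(np.abs(xy[:, 0]) < 1e-9)[0]
    seam_hi = np.where(np.abs(xy[:, 0] - w) < 1e-9)[0]
    if len(seam_lo) and len(seam_hi):
        raise ValueError("tessellation seam is not stitched (non-periodic input)")

    r = diameter / 2.0
    phi = 2.0 * np.pi * xy[:, 0] / w
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), xy[:, 1]])

    bottom = np.where(np.abs(xy[:, 1]) < 1e-9)[0]
    top = np.where(np.abs(xy[:, 1] - h) < 1e-9)[0]
    if len(bottom) < 3 or len(top) < 3:
        raise ValueError("boundary rings need at least 3 vertices each")
    cap_top = list(top[np.argsort(phi[top])])              # CCW from +z: outward
    cap_bottom = list(bottom[np.argsort(-phi[bottom])])    # CW from +z: outward -z

    mesh = TubeMesh(pos, [list(map(int, f)) for f in tess.faces],
                    list(map(int, cap_top)), list(map(int, cap_bottom)),
                    meta={"rect_width": w, "rect_height": h, "diameter": diameter})
    mesh.validate()
    return mesh


def unwrap_to_plane(mesh: TubeMesh) -> np.ndarray:
    """Inverse of :func:`wrap_to_cylinder` on vertex positions.

    Returns (n_v, 2) planar coordinates with x in [0, rect_width).  Exact
    round-trip (to floating point) for meshes produced by the wrap.
    """
    w = mesh.meta.get("rect_width")
    if w is None:
        raise ValueError("mesh carries no rect_width metadata")
    phi = np.mod(np.arctan2(mesh.positions[:, 1], mesh.positions[:, 0]),
                 2.0 * np.pi)
    return np.column_stack([phi * w / (2.0 * np.pi), mesh.positions[:, 2]])


# ---------------------------------------------------------------------------
# measurement

def polygon_area(loop, positions: np.ndarray) -> float:
    """Area of a generally non-planar polygon by centroid-fan triangulation.

    The loop is fanned from its vertex centroid; the area is the sum of the
    triangle areas, which reduces to the shoelace area for planar faces.
    """
    idx = list(loop)
    if len(idx) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    for k in range(len(idx)):
        if idx[k] == idx[(k + 1) % len(idx)]:
            raise ValueError("repeated consecutive vertex in polygon loop")
    p = positions[idx]
    c = p.mean(axis=0)
    u = p - c
    v = np.roll(p, -1, axis=0) - c
    return 0.5 * float(np.linalg.norm(np.cross(u, v), axis=1).sum())


def enclosed_volume(mesh: TubeMesh) -> float:
    """Signed enclosed volume by the divergence theorem.

    Every face (caps included) is fanned from its centroid; each triangle
    contributes the signed volume of its tetrahedron with the origin.
    Positive for outward-wound faces.
    """
    total = 0.0
    pos = mesh.positions
    for loop in mesh.all_faces():
        p = pos[list(loop)]
        c = p.mean(axis=0)
        q = np.roll(p, -1, axis=0)
        total += np.einsum("j,ij->", c, np.cross(p, q)) / 6.0
    return float(total)
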