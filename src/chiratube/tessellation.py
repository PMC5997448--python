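"""Periodic planar Voronoi tessellation used as the initial cell packing.

Seed points are placed by random sequential adsorption (RSA) of hard discs
in a rectangle that is periodic in its width direction only; the top and
bottom rectangle edges are clipping boundaries whose Voronoi vertices later
become the end rings of the tube.

The Dirichlet/Voronoi diagram is computed with scipy on an augmented
generator set: three periodic copies along x and, for each, mirror images
across the lines y = 0 and y = H.  The mirror copies make the boundary
lines exact Voronoi edges, so the central cells come out already clipped to
the rectangle with no polygon-clipping step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = ["PlanarTessellation", "generate_initial_tessellation", "rsa_disc_centers"]

_MERGE_TOL = 1e-6   # Voronoi vertices closer than this are identified
_SNAP_TOL = 1e-7    # snap-to-boundary tolerance for y ~ 0 / y ~ H


class PackingError(RuntimeError):
    """Raised when RSA cannot place the requested number of discs."""


@dataclass
class PlanarTessellation:
    """A cellwise tessellation of a rectangle, periodic in x.

    ``faces`` are CCW-ordered loops of indices into ``vertices``; vertex x
    coordinates are canonical representatives in [0, rect_width), so faces
    crossing the seam must be unwrapped locally (see :meth:`face_coords`)
    before any planar geometry is computed on them.
    """

    rect_width: float
    rect_height: float
    seed_points: np.ndarray        # (n, 2)
    vertices: np.ndarray           # (m, 2), canonical x in [0, W)
    faces: list                    # list of int arrays, CCW around each seed

    @property
    def n_cells(self) -> int:
        return len(self.faces)

    def face_coords(self, i: int) -> np.ndarray:
        """Vertex coordinates of face ``i`` unwrapped around its seed point."""
        w = self.rect_width
        xy = self.vertices[self.faces[i]].copy()
        dx = xy[:, 0] - self.seed_points[i, 0]
        xy[:, 0] -= w * np.round(dx / w)
        return xy

    def face_areas(self) -> np.ndarray:
        return np.array([_shoelace(self.face_coords(i)) for i in range(self.n_cells)])


def _shoelace(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def rsa_disc_centers(n: int, width: float, height: float, diameter: float,
                     rng: np.random.Generator, max_attempts: int = 1_000_000
                     ) -> np.ndarray:
    """Random sequential adsorption of ``n`` hard discs.

    Periodic in x only.  Uses a uniform grid for neighbour lookup; raises
    :class:`PackingError` when the attempt budget is exhausted.
    """
    if n * np.pi * (diameter / 2.0) ** 2 >= width * height:
        raise PackingError("requested packing exceeds the rectangle area")
    cell = diameter
    nx = max(1, int(np.floor(width / cell)))
    ny = max(1, int(np.floor(height / cell)))
    grid: dict = {}
    pts = np.empty((n, 2))
    count = 0
    d2 = diameter * diameter
    attempts = 0
    while count < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {count}/{n} discs after {max_attempts} attempts")
        attempts += 1
        x = rng.uniform(0.0, width)
        y = rng.uniform(0.0, height)
        gx, gy = int(x / width * nx), min(int(y / height * ny), ny - 1)
        ok = True
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for j in grid.get((ix % nx, iy), ()):
                    dx = abs(x - pts[j, 0])
                    dx = min(dx, width - dx)
                    dy = y - pts[j, 1]
                    if dx * dx + dy * dy < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[count] = (x, y)
            grid.setdefault((gx, gy), []).append(count)
            count += 1
    return pts


def _augmented_generators(pts: np.ndarray, width: float, height: float) -> np.ndarray:
    """Nine images: x shifts {-W, 0, +W} times y in {mirror down, id, mirror up}."""
    blocks = []
    for sx in (0.0, -width, width):
        p = pts + np.array([sx, 0.0])
        blocks.append(p)                                     # identity
        blocks.append(p * np.array([1.0, -1.0]))             # mirror across y=0
        blocks.append(np.column_stack([p[:, 0], 2 * height - p[:, 1]]))
    return np.vstack(blocks)


def generate_initial_tessellation(n_cells: int = 452, rect_width: float = 15.75,
                                  rect_height: float = 28.7,
                                  disc_diameter: float = 0.82,
                                  seed: int = 0,
                                  max_attempts: int = 1_000_000,
                                  ) -> PlanarTessellation:
    """Seed discs by RSA and Voronoi-tessellate the periodic rectangle.

    Returns exactly ``n_cells`` faces whose areas sum to the rectangle area.
    """
    rng = np.random.default_rng(seed)
    pts = rsa_disc_centers(n_cells, rect_width, rect_height, disc_diameter,
                           rng, max_attempts=max_attempts)
    return tessellate_points(pts, rect_width, rect_height)


def tessellate_points(pts: np.ndarray, rect_width: float, rect_height: float
                      ) -> PlanarTessellation:
    """Periodic-in-x Voronoi tessellation of given seed points."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if n == 1:
        # degenerate but well-defined: the single cell is the whole rectangle
        w, h = rect_width, rect_height
        verts = np.array([[0.0, 0.0], [w - 1e-12, 0.0], [w - 1e-12, h], [0.0, h]])
        # the seam would identify x=0 with x=W; keep explicit corners instead
        return PlanarTessellation(rect_width, rect_height, pts, verts,
                                  [np.array([0, 1, 2, 3])])
    gen = _augmented_generators(pts, rect_width, rect_height)
    vor = Voronoi(gen)

    loops_xy = []       # per central cell: raw vertex coordinates (local frame)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi region for a central generator")
        xy = vor.vertices[np.asarray(region)]
        # order CCW around the generator (regions of Voronoi cells are convex)
        ang = np.arctan2(xy[:, 1] - pts[i, 1], xy[:, 0] - pts[i, 0])
        xy = xy[np.argsort(ang)]
        # snap onto the clipping boundaries
        xy[np.abs(xy[:, 1]) < _SNAP_TOL, 1] = 0.0
        xy[np.abs(xy[:, 1] - rect_height) < _SNAP_TOL, 1] = rect_height
        loops_xy.append(xy)

    vertices, faces = _merge_vertices(loops_xy, rect_width)
    tess = PlanarTessellation(rect_width, rect_height, pts, vertices, faces)
    _check_tessellation(tess)
    return tess


def _merge_vertices(loops_xy, width):
    """Identify shared vertices across faces (tolerance + x-periodic merge)."""
    allpts = np.vstack(loops_xy)
    canon = allpts.copy()
    canon[:, 0] = np.mod(canon[:, 0], width)
    tree = cKDTree(canon)
    parent = np.arange(len(canon))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in tree.query_pairs(_MERGE_TOL):
        union(a, b)
    # seam: points with x ~ 0 must merge with points at x ~ W
    near0 = np.where(canon[:, 0] < _MERGE_TOL)[0]
    for a in near0:
        for b in tree.query_ball_point(canon[a] + np.array([width, 0.0]), _MERGE_TOL):
            union(a, b)
    nearW = np.where(canon[:, 0] > width - _MERGE_TOL)[0]
    for a in nearW:
        for b in tree.query_ball_point(canon[a] - np.array([width, 0.0]), _MERGE_TOL):
            union(a, b)

    roots = np.array([find(i) for i in range(len(canon))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    vertices = canon[uniq]
    vertices[:, 0] = np.mod(vertices[:, 0], width)

    faces = []
    k = 0
    for xy in loops_xy:
        ids = inverse[k:k + len(xy)]
        k += len(xy)
        # drop consecutive duplicates created by the merge
        keep = [j for j in range(len(ids)) if ids[j] != ids[(j + 1) % len(ids)]]
        loop = ids[keep]
        if len(loop) < 3:
            raise RuntimeError("degenerate face after vertex merge")
        faces.append(np.asarray(loop, dtype=np.int64))
    return vertices, faces


def _check_tessellation(tess: PlanarTessellation) -> None:
    areas = tess.face_areas()
    if np.any(areas <= 0):
        raise RuntimeError("non-CCW or degenerate face in tessellation")
    total = tess.rect_width * tess.rect_height
    if abs(areas.sum() - total) > 1e-9 * total:
        raise RuntimeError(
            f"tessellation areas sum to {areas.sum():.12g}, expected {total:.12g}")
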