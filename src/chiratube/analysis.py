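"""Quantification of simulated tube geometry and cell behaviour.

All planar statistics are computed on the cylinder projection: vertices are
projected onto a geometrical cylinder of the nominal tube diameter and the
cylinder surface is unrolled, x = (diameter/2) * azimuth (circumferential,
rightward for an observer outside the tube), y = z (axial, anterior up).
With this orientation a leftward-slanted structure has a negative angle
measured from the tube axis, matching the -90..0 degree convention used
for the cell-axis and edge-angle distributions.

Sign contract for twist: positive = counterclockwise as viewed from the
posterior (bottom, -z) end, i.e. the handedness of the wild-type organ.  A
helical deformation ``phi += c*z`` therefore reports ``-c*(z_top-z_bot)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh import TubeMesh

__all__ = ["project_and_unroll", "polygon_axis_and_deviation", "shape_stats",
           "angle_histograms", "angle_bias", "twist_angle", "centroid_tracks",
           "axial_pairs", "cell_sliding", "boundary_angles",
           "classify_boundary_tilt", "detect_intercalations"]

_EIG_TIE_RTOL = 1e-9


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _fold_deg(theta):
    """Fold an axis angle (degrees) into (-90, 90]."""
    t = (theta + 90.0) % 180.0 - 90.0
    return np.where(t == -90.0, 90.0, t)


# ---------------------------------------------------------------------------
# cylinder projection

def face_rows_from_ends(mesh: TubeMesh) -> np.ndarray:
    """Per-cell row number counted from the nearer tube end (1 = touches a
    cap ring), via breadth-first search on face adjacency."""
    ring = set(mesh.cap_top) | set(mesh.cap_bottom)
    nbrs = [set() for _ in range(mesh.n_cells)]
    ef = {}
    for fi, loop in enumerate(mesh.faces):
        m = len(loop)
        for k in range(m):
            e = frozenset((loop[k], loop[(k + 1) % m]))
            if e in ef:
                nbrs[ef[e]].add(fi)
                nbrs[fi].add(ef[e])
            else:
                ef[e] = fi
    row = np.full(mesh.n_cells, np.iinfo(np.int32).max, dtype=np.int64)
    frontier = [fi for fi, loop in enumerate(mesh.faces)
                if any(v in ring for v in loop)]
    row[frontier] = 1
    depth = 1
    while frontier:
        depth += 1
        nxt = []
        for fi in frontier:
            for g in nbrs[fi]:
                if row[g] > depth:
                    row[g] = depth
                    nxt.append(g)
        frontier = nxt
    return row


def project_and_unroll(mesh: TubeMesh, diameter: float = 5.0,
                       exclude_rows: int = 2) -> dict:
    """Project onto the nominal cylinder and unroll to the plane.

    Returns per-face planar polygons (each face unwrapped around its own
    centroid azimuth, so seam-crossing faces stay simple), global vertex
    plane coordinates, and the peripheral-exclusion mask (faces within
    ``exclude_rows`` cell rows of either end are flagged excluded).
    """
    pos = mesh.positions
    rho = np.hypot(pos[:, 0], pos[:, 1])
    if np.any(rho < 1e-12):
        raise ValueError("vertex on the tube axis; azimuth undefined")
    r = diameter / 2.0
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    polys = []
    for loop in mesh.faces:
        idx = list(loop)
        ph = phi[idx]
        ref = np.arctan2(np.sin(ph).mean(), np.cos(ph).mean())
        ph = ref + _wrap_angle(ph - ref)
        polys.append(np.column_stack([r * ph, pos[idx, 2]]))
    rows = face_rows_from_ends(mesh)
    included = rows > exclude_rows
    return {"polygons": polys, "phi": phi, "plane_xy":
            np.column_stack([r * phi, pos[:, 2]]), "included": included}


# ---------------------------------------------------------------------------
# momental ellipse

def polygon_axis_and_deviation(xy: np.ndarray) -> tuple:
    """Cell-axis angle and circular-deviation index of a planar polygon.

    The polygon is approximated by its momental ellipse (ellipse of
    inertia, equal second area moments); the major-axis direction measured
    from the axial (+y) direction, folded into (-90, 90], is the cell axis,
    and (d_max - d_min)/(d_max + d_min) with the ellipse axis lengths is
    the deviation from a circle.  Near-isotropic polygons report angle 0.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * cross.sum()
    if abs(A) < 1e-300:
        raise ValueError("zero-area polygon")
    if A < 0:        # accept either winding
        x, y = x[::-1], y[::-1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y1 - x1 * y
        A = -A
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    x, y = x - cx, y - cy
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    mxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    myy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    mxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    M = np.array([[mxx, mxy], [mxy, myy]]) / A
    lam, vec = np.linalg.eigh(M)       # ascending
    d_min, d_max = 2.0 * np.sqrt(np.maximum(lam, 0.0))
    deviation = (d_max - d_min) / (d_max + d_min)
    if lam[1] - lam[0] <= _EIG_TIE_RTOL * lam[1]:
        theta = 0.0
    else:
        ex, ey = vec[:, 1]
        theta = float(_fold_deg(np.degrees(np.arctan2(ex, ey))))
    return theta, float(deviation)


def shape_stats(mesh: TubeMesh, diameter: float = 5.0,
                exclude_rows: int = 2) -> dict:
    """Per-cell axis/deviation and per-edge angles on the unrolled pattern.

    Returns {'cells': DataFrame(cell, theta_deg, deviation, included),
    'edges': DataFrame(v1, v2, angle_deg, included)}.
    """
    un = project_and_unroll(mesh, diameter, exclude_rows)
    rows = []
    for i, poly in enumerate(un["polygons"]):
        theta, dev = polygon_axis_and_deviation(poly)
        rows.append({"cell": i, "theta_deg": theta, "deviation": dev,
                     "included": bool(un["included"][i])})
    cells = pd.DataFrame(rows)

    r = diameter / 2.0
    phi, z = un["phi"], mesh.positions[:, 2]
    seen = set()
    erows = []
    for i, loop in enumerate(mesh.faces):
        m = len(loop)
        for k in range(m):
            a, b = loop[k], loop[(k + 1) % m]
            e = frozenset((a, b))
            if e in seen:
                continue
            seen.add(e)
            dx = r * _wrap_angle(phi[b] - phi[a])
            dy = z[b] - z[a]
            ang = float(_fold_deg(np.degrees(np.arctan2(dx, dy))))
            erows.append({"v1": min(a, b), "v2": max(a, b), "angle_deg": ang,
                          "face": i})
    edges = pd.DataFrame(erows)
    inc_faces = set(np.where(un["included"])[0])
    edges["included"] = edges["face"].isin(inc_faces)
    edges = edges.drop(columns=["face"])
    return {"cells": cells, "edges": edges}


def angle_bias(angles_deg: np.ndarray) -> float:
    """Fraction of angles in (-90, 0) minus fraction in (0, 90)."""
    a = np.asarray(angles_deg, dtype=float)
    n = len(a)
    if n == 0:
        return 0.0
    return float(((a < 0) & (a > -90)).sum() - ((a > 0) & (a < 90)).sum()) / n


def angle_histograms(angles_deg: np.ndarray, bin_width: float = 10.0) -> dict:
    """Percentage histogram over (-90, 90] plus the leftward-bias statistic."""
    a = np.asarray(angles_deg, dtype=float)
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    pct = 100.0 * counts / max(len(a), 1)
    return {"bin_edges": edges, "percent": pct, "bias": angle_bias(a)}


# ---------------------------------------------------------------------------
# twist

def twist_angle(mesh: TubeMesh, ref_mesh: TubeMesh) -> float:
    """End-ring twist of ``mesh`` relative to the reference state, degrees.

    Mean azimuthal displacement of the top ring minus the bottom ring
    (each per-vertex difference wrapped to (-180, 180]), with positive =
    counterclockwise viewed from the posterior end.  Invariant under rigid
    rotations applied to the deformed state.
    """
    if mesh.n_vertices != ref_mesh.n_vertices or \
            list(mesh.cap_top) != list(ref_mesh.cap_top) or \
            list(mesh.cap_bottom) != list(ref_mesh.cap_bottom):
        raise ValueError("meshes do not share ring topology")

    def dphi(ring):
        idx = list(ring)
        p0 = ref_mesh.positions[idx]
        p1 = mesh.positions[idx]
        a0 = np.arctan2(p0[:, 1], p0[:, 0])
        a1 = np.arctan2(p1[:, 1], p1[:, 0])
        return _wrap_angle(a1 - a0).mean()

    return float(-np.degrees(dphi(mesh.cap_top) - dphi(mesh.cap_bottom)))


def twist_slope(mesh: TubeMesh, ref_mesh: TubeMesh) -> float:
    """Cross-check statistic: least-squares slope of azimuth change vs z,
    converted to total degrees over the tube height (same sign contract)."""
    p0, p1 = ref_mesh.positions, mesh.positions
    a = _wrap_angle(np.arctan2(p1[:, 1], p1[:, 0]) -
                    np.arctan2(p0[:, 1], p0[:, 0]))
    z = p0[:, 2]
    zc = z - z.mean()
    slope = float(zc @ (a - a.mean()) / (zc @ zc))
    return float(-np.degrees(slope * (z.max() - z.min())))


# ---------------------------------------------------------------------------
# centroid tracks, sliding, tilt, intercalation

def centroid_tracks(traj, diameter: float = 5.0) -> pd.DataFrame:
    """Tidy (t, cell, x, y) table of unrolled cell-centroid tracks.

    x is the circumferential coordinate r*phi with phi unwrapped over time
    per cell, so sliding across the seam stays continuous; y is axial.
    """
    r = diameter / 2.0
    rows = []
    prev_phi = None
    acc = None
    for (t, pos, ver) in traj.snapshots:
        faces, _caps = traj.topologies[ver]
        n = len(faces)
        phi = np.empty(n)
        zc = np.empty(n)
        for i, loop in enumerate(faces):
            c = pos[list(loop)].mean(axis=0)
            phi[i] = np.arctan2(c[1], c[0])
            zc[i] = c[2]
        if acc is None:
            acc = phi.copy()
        else:
            acc = acc + _wrap_angle(phi - prev_phi)
        prev_phi = phi
        for i in range(n):
            rows.append({"t": t, "cell": i, "x": r * acc[i], "y": zc[i]})
    return pd.DataFrame(rows)


def axial_pairs(mesh: TubeMesh) -> list:
    """(upper, subjacent) cell pairs that are adjacent and axially aligned.

    A neighbour pair is axial when the centroid separation is dominated by
    its z component on the unrolled surface (within 45 degrees of the
    axis); the anterior cell (larger z) is the 'upper' member.
    """
    cents = np.array([mesh.face_centroid(f) for f in mesh.faces])
    phi = np.arctan2(cents[:, 1], cents[:, 0])
    rho = np.hypot(cents[:, 0], cents[:, 1]).mean()
    ef = {}
    pairs = set()
    for fi, loop in enumerate(mesh.faces):
        m = len(loop)
        for k in range(m):
            e = frozenset((loop[k], loop[(k + 1) % m]))
            if e in ef and ef[e] != fi:
                pairs.add(tuple(sorted((ef[e], fi))))
            ef[e] = fi
    out = []
    for i, j in sorted(pairs):
        dz = cents[j, 2] - cents[i, 2]
        dx = rho * _wrap_angle(phi[j] - phi[i])
        if abs(dz) > abs(dx):
            upper, lower = (j, i) if dz > 0 else (i, j)
            out.append((upper, lower))
    return out


def cell_sliding(tracks: pd.DataFrame, pairs: list,
                 interval: float) -> pd.DataFrame:
    """Relative circumferential displacement of each (upper, subjacent) pair.

    For every pair and every start time with a sample one ``interval``
    later: (x_upper - x_sub) at the end minus at the start.  The subjacent
    cell is the origin, so negative values are leftward sliding.  Pairs
    with a missing time point are skipped.
    """
    times = np.sort(tracks["t"].unique())
    wide = tracks.pivot(index="t", columns="cell", values="x")
    rows = []
    for t0 in times:
        t1 = t0 + interval
        j = np.argmin(np.abs(times - t1))
        if abs(times[j] - t1) > 1e-9 + 1e-6 * max(abs(t1), 1.0):
            continue
        t1 = times[j]
        if t1 <= t0:
            continue
        for upper, lower in pairs:
            if upper not in wide.columns or lower not in wide.columns:
                continue
            rel0 = wide.at[t0, upper] - wide.at[t0, lower]
            rel1 = wide.at[t1, upper] - wide.at[t1, lower]
            if np.isnan(rel0) or np.isnan(rel1):
                continue
            rows.append({"t0": t0, "t1": t1, "upper": upper, "lower": lower,
                         "dx": rel1 - rel0})
    return pd.DataFrame(rows, columns=["t0", "t1", "upper", "lower", "dx"])


def boundary_angles(traj, pairs: list, diameter: float = 5.0) -> pd.DataFrame:
    """Angle series of the shared boundary of each axial pair.

    The boundary angle is measured from the circumferential (+x) direction
    on the unrolled plane, folded into (-90, 90]; an angle increase is a
    counterclockwise tilt for the outside observer.  Boundaries absent at a
    time point (removed by a neighbour exchange) are simply not reported.
    """
    r = diameter / 2.0
    rows = []
    for (t, pos, ver) in traj.snapshots:
        faces, _caps = traj.topologies[ver]
        edge_sets = []
        for loop in faces:
            m = len(loop)
            edge_sets.append({frozenset((loop[k], loop[(k + 1) % m]))
                              for k in range(m)})
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        for bid, (upper, lower) in enumerate(pairs):
            shared = edge_sets[upper] & edge_sets[lower]
            if len(shared) != 1:
                continue
            a, b = sorted(next(iter(shared)))
            dx = r * _wrap_angle(phi[b] - phi[a])
            dy = pos[b, 2] - pos[a, 2]
            ang = np.degrees(np.arctan2(dy, dx))
            ang = (ang + 90.0) % 180.0 - 90.0
            rows.append({"t": t, "boundary": bid, "angle_deg": float(ang)})
    return pd.DataFrame(rows, columns=["t", "boundary", "angle_deg"])


def classify_boundary_tilt(angles: pd.DataFrame, interval: float,
                           tol_deg: float = 2.0) -> dict:
    """Classify each boundary's net angle change as ccw / uc / cw.

    The change is taken between the first sample and the sample one
    ``interval`` later (nearest available), wrapped to (-90, 90].
    """
    counts = {"ccw": 0, "uc": 0, "cw": 0}
    for bid, grp in angles.groupby("boundary"):
        grp = grp.sort_values("t")
        t0 = grp["t"].iloc[0]
        tgt = t0 + interval
        j = int(np.argmin(np.abs(grp["t"].to_numpy() - tgt)))
        if j == 0:
            continue
        d = grp["angle_deg"].iloc[j] - grp["angle_deg"].iloc[0]
        d = (d + 90.0) % 180.0 - 90.0
        if d > tol_deg:
            counts["ccw"] += 1
        elif d < -tol_deg:
            counts["cw"] += 1
        else:
            counts["uc"] += 1
    return counts


def detect_intercalations(traj, pairs: list | None = None,
                          window: float | None = None,
                          diameter: float = 5.0,
                          side_eps: float = 1e-6) -> list:
    """Cell-intercalation events among axially adjacent pairs.

    An event is recorded when a pair in contact loses its shared boundary
    and an intervening cell adjacent to both members appears within
    ``window`` (default: by the next saved state).  The direction is the
    side the intervening cell came from, judged by its circumferential
    position relative to the pair midline just before separation;
    within ``side_eps`` of the midline it is 'undetermined'.
    """
    snaps = traj.snapshots
    if pairs is None:
        pairs = axial_pairs(traj.mesh_at(snaps[0][0]))

    def adjacency(ver):
        faces, _ = traj.topologies[ver]
        es = []
        for loop in faces:
            m = len(loop)
            es.append({frozenset((loop[k], loop[(k + 1) % m]))
                       for k in range(m)})
        return es

    adj_cache = {}
    events = []
    r = diameter / 2.0
    for si in range(1, len(snaps)):
        t0, pos0, v0 = snaps[si - 1]
        t1, pos1, v1 = snaps[si]
        if v0 == v1:
            continue
        if v0 not in adj_cache:
            adj_cache[v0] = adjacency(v0)
        if v1 not in adj_cache:
            adj_cache[v1] = adjacency(v1)
        e0, e1 = adj_cache[v0], adj_cache[v1]
        for upper, lower in pairs:
            had = bool(e0[upper] & e0[lower])
            has = bool(e1[upper] & e1[lower])
            if not (had and not has):
                continue
            if window is not None and t1 - t0 > window:
                continue
            # intervening cell: adjacent to both members afterwards
            inter = [c for c in range(len(e1))
                     if c not in (upper, lower)
                     and (e1[c] & e1[upper]) and (e1[c] & e1[lower])]
            if not inter:
                continue
            faces0, _ = traj.topologies[v0]
            phi = np.arctan2(pos0[:, 1], pos0[:, 0])

            def cphi(ci):
                ids = list(faces0[ci])
                ph = phi[ids]
                ref = np.arctan2(np.sin(ph).mean(), np.cos(ph).mean())
                return ref + _wrap_angle(ph - ref).mean()

            mid = 0.5 * (cphi(upper) + cphi(lower))
            best = min(inter, key=lambda c: abs(_wrap_angle(cphi(c) - mid)))
            off = r * _wrap_angle(cphi(best) - mid)
            if off < -side_eps:
                direction = "left"
            elif off > side_eps:
                direction = "right"
            else:
                direction = "undetermined"
            events.append({"t": t1, "upper": upper, "lower": lower,
                           "intervening": best, "direction": direction})
    return events
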