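"""Neighbour exchange (T1 transition) on the curved tube surface.

When a cell-cell edge shrinks below the critical length ``delta`` the two
3-valent endpoints swap neighbour relationships: the two faces flanking the
edge lose it, the two side faces gain it, and the vertex pair is re-seated
perpendicular to the old edge within the local tangent plane.  Vertex,
edge and face counts are conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import TubeMesh

__all__ = ["ReconnectionEvent", "detect_short_edges", "reconnect",
           "apply_reconnections", "count_intercalations"]

log = logging.getLogger(__name__)

#: separation of the reseated vertex pair, in units of delta; slightly above
#: 1 so a fresh junction cannot immediately re-trigger
SEPARATION_FACTOR = 1.05


@dataclass
class ReconnectionEvent:
    time: float
    v1: int
    v2: int
    faces_lost: tuple      # the two faces that lost the edge
    faces_gained: tuple    # the two faces that gained it
    length_before: float


def _ring_edge_set(mesh: TubeMesh) -> set:
    out = set()
    for ring in (mesh.cap_top, mesh.cap_bottom):
        m = len(ring)
        for k in range(m):
            out.add(frozenset((ring[k], ring[(k + 1) % m])))
    return out


def detect_short_edges(mesh: TubeMesh, delta: float = 0.3) -> list:
    """Cell-cell edges shorter than ``delta``, ascending by length.

    Cap-ring edges are excluded: the end rings are held on their circles
    and never remodel.  Returns (length, a, b) tuples.
    """
    ring = _ring_edge_set(mesh)
    seen = set()
    out = []
    pos = mesh.positions
    for loop in mesh.faces:
        m = len(loop)
        for k in range(m):
            a, b = loop[k], loop[(k + 1) % m]
            e = frozenset((a, b))
            if e in seen or e in ring:
                continue
            seen.add(e)
            L = float(np.linalg.norm(pos[a] - pos[b]))
            if L < delta:
                out.append((L, min(a, b), max(a, b)))
    out.sort()
    return out


def _loop_edges(loop: list) -> set:
    m = len(loop)
    return {frozenset((loop[k], loop[(k + 1) % m])) for k in range(m)}


def _neighbor_on(loop: list, anchor: int, edges: set):
    """The neighbour of ``anchor`` in ``loop`` whose shared edge with the
    anchor belongs to ``edges``; None when not unique."""
    i = loop.index(anchor)
    cand = [n for n in (loop[i - 1], loop[(i + 1) % len(loop)])
            if frozenset((anchor, n)) in edges]
    return cand[0] if len(cand) == 1 else None


def _insert_between(loop: list, anchor: int, nbr: int, newv: int) -> None:
    """Insert ``newv`` between the adjacent pair (anchor, nbr)."""
    i = loop.index(anchor)
    if loop[(i + 1) % len(loop)] == nbr:
        loop.insert(i + 1, newv)
    else:
        loop.insert(i, newv)


def reconnect(mesh: TubeMesh, a: int, b: int, delta: float = 0.3,
              time: float = 0.0, vfaces: list | None = None
              ) -> ReconnectionEvent | None:
    """Apply one T1 swap to edge (a, b).  Returns None when the event must
    be skipped (cap involvement, a face that would drop below 3 sides, or a
    non-generic neighbourhood).  ``vfaces`` is an optional precomputed
    vertex->faces incidence (from :meth:`TubeMesh.vertex_faces`)."""
    pos = mesh.positions
    n_lat = mesh.n_cells

    if vfaces is None:
        vfaces = mesh.vertex_faces()
    inc_a = vfaces[a]
    inc_b = vfaces[b]
    if len(inc_a) != 3 or len(inc_b) != 3:
        log.debug("T1 skipped: endpoint not 3-valent")
        return None
    flank = [fi for fi in inc_a if fi in inc_b]      # share the edge
    side_a = [fi for fi in inc_a if fi not in inc_b]
    side_b = [fi for fi in inc_b if fi not in inc_a]
    if len(flank) != 2 or len(side_a) != 1 or len(side_b) != 1:
        log.debug("T1 skipped: edge (%d,%d) lacks a 4-face neighbourhood", a, b)
        return None
    F1, F2 = flank
    # deterministic role assignment: F1 is the flank traversing the edge as
    # the ordered pair (a, b); with consistently wound faces this makes the
    # swap an involution (a second T1 on the re-shortened edge restores the
    # original adjacency)
    lp = mesh.all_faces()[F1]
    i = lp.index(a)
    if lp[(i + 1) % len(lp)] == b:
        F1, F2 = F2, F1
    Fa, Fb = side_a[0], side_b[0]
    if any(fi >= n_lat for fi in (F1, F2, Fa, Fb)):
        log.debug("T1 skipped: edge (%d,%d) touches an end cap", a, b)
        return None
    if len(mesh.faces[F1]) <= 3 or len(mesh.faces[F2]) <= 3:
        log.debug("T1 skipped: flanking face (%d,%d) would drop below 3 sides",
                  F1, F2)
        return None

    length_before = float(np.linalg.norm(pos[a] - pos[b]))

    # orient: F1 keeps a (loses b), F2 keeps b (loses a).  The new edge in
    # Fa goes between a and a's neighbour on the F2 side (the vertex whose
    # shared edge with a belongs to F2); symmetric for Fb.
    loop1 = mesh.faces[F1]
    loop2 = mesh.faces[F2]
    loopA = mesh.faces[Fa]
    loopB = mesh.faces[Fb]
    edges1 = _loop_edges(loop1)
    edges2 = _loop_edges(loop2)
    v = _neighbor_on(loopA, a, edges2)
    s = _neighbor_on(loopB, b, edges1)
    if v is None or s is None:
        log.debug("T1 skipped: non-generic face contacts around (%d,%d)", a, b)
        return None

    loop1.remove(b)
    loop2.remove(a)
    _insert_between(loopA, a, v, b)
    _insert_between(loopB, b, s, a)

    # reseat the pair perpendicular to the old edge in the tangent plane:
    # a toward F1's centroid, b toward F2's
    mid = 0.5 * (pos[a] + pos[b])
    d = pos[b] - pos[a]
    dn = d / max(np.linalg.norm(d), 1e-300)
    c1 = pos[loop1].mean(axis=0)
    perp = c1 - mid
    perp -= (perp @ dn) * dn
    nrm = np.linalg.norm(perp)
    if nrm < 1e-12:
        perp = np.cross(dn, mid / max(np.linalg.norm(mid), 1e-300))
        nrm = max(np.linalg.norm(perp), 1e-300)
    perp /= nrm
    half = 0.5 * SEPARATION_FACTOR * delta
    pos[a] = mid + half * perp
    pos[b] = mid - half * perp

    mesh.topology_version += 1
    return ReconnectionEvent(time, a, b, (F1, F2), (Fa, Fb), length_before)


def apply_reconnections(mesh: TubeMesh, delta: float, time: float,
                        candidates: list | None = None,
                        max_passes: int = 10) -> list:
    """Resolve sub-delta edges, shortest first, rescanning until none remain
    (bounded number of passes).

    ``candidates`` optionally restricts the first pass to specific vertex
    pairs (the edges that actually crossed the threshold); subsequent
    passes after a successful event rescan those pairs only.
    """
    events = []
    pos = mesh.positions
    for _ in range(max_passes):
        if candidates is None:
            short = detect_short_edges(mesh, delta)
        else:
            short = []
            for a, b in candidates:
                L = float(np.linalg.norm(pos[a] - pos[b]))
                if L < delta:
                    short.append((L, min(a, b), max(a, b)))
            short.sort()
        if not short:
            break
        vfaces = mesh.vertex_faces()
        progressed = False
        for _, a, b in short:
            ev = reconnect(mesh, a, b, delta, time, vfaces=vfaces)
            if ev is not None:
                events.append(ev)
                progressed = True
                break   # topology changed; rescan
        if not progressed:
            break       # only skippable events remain
    return events


def count_intercalations(events: list, n_cells: int) -> tuple:
    """Number of neighbour-exchange events and the events-per-cell fraction."""
    k = len(events)
    return k, k / n_cells if n_cells else 0.0
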