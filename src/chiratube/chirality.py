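"""Imprinting handed cell shapes via polarity-directed edge contraction.

Each lateral cell carries a polarity unit vector lying in its local tangent
plane, rotated ``deflection_deg`` away from the tube axis (+z).  Positive
deflection tilts toward decreasing azimuth, which is leftward for an
observer outside the tube with anterior up; this is the package's
orientation contract, chosen so that a +30 degree protocol produces a
left-handed screw twist.

The plane through the cell centre normal to the polarity crosses exactly
two of the cell's edges (generic position); those edges receive an
elevated tension weight and contract most strongly, elongating the cell
along the polarity and thereby giving it a chiral shape.
"""

from __future__ import annotations

import logging

import numpy as np

from .mesh import TubeMesh
from .params import ChiralityProtocol, ModelParams, RunOptions
from .dynamics import EdgeWeights, run, Trajectory

__all__ = ["assign_polarity", "select_special_edges", "PolarityWeights",
           "build_chiral_tube"]

log = logging.getLogger(__name__)

_PLANE_NUDGE = 1e-9


def assign_polarity(mesh: TubeMesh, deflection_deg: float) -> np.ndarray:
    """Per-cell polarity unit vectors in the local tangent plane.

    The tangent plane at a cell is orthogonal to the outward radial
    direction at its centroid; the polarity is the +z direction rotated by
    ``deflection_deg`` toward -azimuth within that plane.
    """
    if not abs(deflection_deg) < 90.0:
        raise ValueError("|deflection_deg| must be < 90")
    th = np.radians(deflection_deg)
    out = np.empty((mesh.n_cells, 3))
    for i, loop in enumerate(mesh.faces):
        c = mesh.face_centroid(loop)
        rho = np.hypot(c[0], c[1])
        if rho < 1e-12:
            raise ValueError(f"cell {i} centroid lies on the tube axis")
        phi_hat = np.array([-c[1], c[0], 0.0]) / rho
        out[i] = np.cos(th) * np.array([0.0, 0.0, 1.0]) - np.sin(th) * phi_hat
    return out


def select_special_edges(loop, polarity: np.ndarray, positions: np.ndarray):
    """The two cell edges crossed by the plane normal to the polarity
    through the cell centroid.

    Returns a list of two frozenset vertex pairs, or None for a degenerate
    configuration (after one nudge-retry of the plane offset).
    """
    idx = list(loop)
    pts = positions[idx]
    c = pts.mean(axis=0)
    base = (pts - c) @ polarity
    for offset in (0.0, _PLANE_NUDGE):
        s = np.sign(base - offset)
        if np.any(s == 0.0):
            continue
        crossed = [frozenset((idx[k], idx[(k + 1) % len(idx)]))
                   for k in range(len(idx))
                   if s[k] * s[(k + 1) % len(idx)] < 0]
        if len(crossed) == 2:
            return crossed
    return None


class PolarityWeights(EdgeWeights):
    """Weight field: ``w_special`` on each cell's two special edges, 1 elsewhere.

    Special edges are selected once from the initial geometry and kept for
    the whole induction run; a cell whose special edge is destroyed by a
    neighbour exchange gets a fresh selection (same stored polarity vector,
    current geometry).
    """

    def __init__(self, mesh: TubeMesh, deflection_deg: float,
                 w_special: float = 3.5):
        self.polarity = assign_polarity(mesh, deflection_deg)
        self.w_special = w_special
        self.special: dict = {}
        self.degenerate: list = []
        for i, loop in enumerate(mesh.faces):
            sel = select_special_edges(loop, self.polarity[i], mesh.positions)
            if sel is None:
                self.degenerate.append(i)
                log.warning("cell %d: degenerate special-edge selection; "
                            "cell left isotropic", i)
            else:
                self.special[i] = sel

    def weight_map(self, mesh: TubeMesh) -> dict:
        return {i: {e: self.w_special for e in edges}
                for i, edges in self.special.items()}

    def on_reconnection(self, mesh: TubeMesh, event) -> bool:
        changed = False
        for fi in (*event.faces_lost, *event.faces_gained):
            if fi >= mesh.n_cells or fi not in self.special:
                continue
            loop = mesh.faces[fi]
            edges = {frozenset((loop[k], loop[(k + 1) % len(loop)]))
                     for k in range(len(loop))}
            if all(e in edges for e in self.special[fi]):
                continue
            sel = select_special_edges(loop, self.polarity[fi], mesh.positions)
            if sel is None:
                del self.special[fi]
                self.degenerate.append(fi)
            else:
                self.special[fi] = sel
            changed = True
        return changed


def build_chiral_tube(mesh: TubeMesh, protocol: ChiralityProtocol,
                      params: ModelParams, reconnect: bool = False,
                      save_every: float = 0.5, progress: bool = False
                      ) -> tuple[TubeMesh, Trajectory, PolarityWeights]:
    """Run the chirality-induction dynamics on a symmetric wrapped tube.

    Applies ``w_special`` to the polarity-selected edges and integrates to
    ``protocol.t_end_induction``; the returned mesh (mutated in place) is
    the t = 0 initial state of the main experiments.

    Induction runs without neighbour exchange: under sustained strong
    contraction a T1-swapped special edge is immediately re-selected and
    re-collapsed, which degenerates into a neighbour-exchange treadmill
    instead of a quasi-static shape change; the imprinting step therefore
    deforms cells at fixed topology.
    """
    weights = PolarityWeights(mesh, protocol.deflection_deg, protocol.w_special)
    frac = len(weights.degenerate) / max(mesh.n_cells, 1)
    if frac > 0.02:
        log.warning("%.1f%% of cells degenerate at special-edge selection",
                    100 * frac)
    options = RunOptions(t_end=protocol.t_end_induction, reconnect=reconnect,
                         fix_end_rotation=False, save_every=save_every)
    traj = run(mesh, params, options, weights=weights, progress=progress)
    return mesh, traj, weights
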