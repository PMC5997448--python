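"""Overdamped vertex dynamics on the tube surface.

Vertices follow the gradient flow ``dr_i/dt = -grad_i U`` (drag coefficient
and length unit absorbed by rescaling), with

    U = U_L + U_ES + U_EV + U_B

summed over the lateral cells (edge tension and area elasticity), the whole
tube (volume elasticity) and the two end rings (circular restraint).  The
gradient is computed analytically and integrated with the classical
fourth-order Runge-Kutta scheme at fixed step ``h``.

All per-edge quantities are evaluated on a flattened half-edge structure
(one directed edge per face per side), which makes a full force evaluation
a handful of vectorized numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TubeMesh
from .params import ModelParams, RunOptions
from . import reconnection as recon

__all__ = ["Kernel", "potential_energy", "force", "step_rk4", "run",
           "Trajectory", "EdgeWeights"]


class EdgeWeights:
    """Per-(cell, edge) tension weight supplier.

    Subclasses override :meth:`weight_map` (mapping lateral face index ->
    {frozenset{a, b}: weight}) and may react to neighbour exchanges via
    :meth:`on_reconnection` (return True when weights changed so the solver
    rebuilds its kernel).  The base class is the uniform ``w = 1`` field.
    """

    def weight_map(self, mesh: TubeMesh) -> dict:
        return {}

    def on_reconnection(self, mesh: TubeMesh, event) -> bool:
        return False


class Kernel:
    """Flattened half-edge arrays bound to one mesh topology + weight field."""

    def __init__(self, mesh: TubeMesh, params: ModelParams,
                 weights: EdgeWeights | None = None,
                 fix_end_rotation: bool = False,
                 area_mode: str | None = None):
        if area_mode is None:
            area_mode = getattr(params, "area_mode", "fan")
        if area_mode not in ("fan", "vector"):
            raise ValueError("area_mode must be 'fan' or 'vector'")
        self.area_mode = area_mode
        self.params = params
        n_lat = mesh.n_cells
        loops = mesh.all_faces()
        wmap = weights.weight_map(mesh) if weights is not None else {}

        A, B, F, W = [], [], [], []
        size = np.empty(len(loops))
        for fi, loop in enumerate(loops):
            m = len(loop)
            size[fi] = m
            fw = wmap.get(fi, {}) if fi < n_lat else None
            for k in range(m):
                a, b = loop[k], loop[(k + 1) % m]
                A.append(a)
                B.append(b)
                F.append(fi)
                if fi < n_lat:
                    W.append(fw.get(frozenset((a, b)), 1.0) if fw else 1.0)
                else:
                    W.append(0.0)   # caps carry no edge energy
        self.A = np.asarray(A, dtype=np.intp)
        self.B = np.asarray(B, dtype=np.intp)
        self.F = np.asarray(F, dtype=np.intp)
        self.w = np.asarray(W)
        self.size = size
        self.n_faces = len(loops)
        self.n_v = mesh.n_vertices
        self.is_lat = np.zeros(self.n_faces, dtype=bool)
        self.is_lat[:n_lat] = True

        self.ring_top = np.asarray(mesh.cap_top, dtype=np.intp)
        self.ring_bottom = np.asarray(mesh.cap_bottom, dtype=np.intp)

        # degrees of freedom: end-ring z is always held at the cap height
        # (the rings are restricted to circles at the tube ends); optionally
        # their x,y too (the stopped-rotation variant)
        self.free = np.ones((self.n_v, 3))
        self.free[self.ring_top, 2] = 0.0
        self.free[self.ring_bottom, 2] = 0.0
        if fix_end_rotation:
            self.free[self.ring_top, :2] = 0.0
            self.free[self.ring_bottom, :2] = 0.0

        # half-edges usable for reconnection checks: lateral, not on a ring
        ring_edges = set()
        for ring in (mesh.cap_top, mesh.cap_bottom):
            m = len(ring)
            for k in range(m):
                ring_edges.add(frozenset((ring[k], ring[(k + 1) % m])))
        lat = self.is_lat[self.F] & (self.A < self.B)
        keep = np.array([lat[i] and frozenset((A[i], B[i])) not in ring_edges
                         for i in range(len(A))])
        self.check_idx = np.where(keep)[0]

        # flattened scatter indices: one bincount per gather instead of three
        comp = np.arange(3)
        self._F3 = (self.F[:, None] * 3 + comp).ravel()
        self._A3 = (self.A[:, None] * 3 + comp).ravel()
        self._B3 = (self.B[:, None] * 3 + comp).ravel()

    # -- internals -------------------------------------------------------
    def _scatter_faces(self, vals: np.ndarray) -> np.ndarray:
        return np.bincount(self._F3, vals.ravel(),
                           minlength=3 * self.n_faces).reshape(-1, 3)

    def _scatter_vertices(self, idx3, vals) -> np.ndarray:
        return np.bincount(idx3, vals.ravel(),
                           minlength=3 * self.n_v).reshape(-1, 3)

    def edge_lengths(self, pos: np.ndarray) -> np.ndarray:
        d = pos[self.A] - pos[self.B]
        return np.sqrt((d * d).sum(axis=1))

    def _ring_terms(self, pos, ring, R):
        rho = pos[ring, :2]
        cen = rho.mean(axis=0)
        dv = rho - cen
        s = (dv * dv).sum(axis=1) - R * R
        return dv, s

    # -- energy ----------------------------------------------------------
    def energy(self, pos: np.ndarray) -> dict:
        p = self.params
        pa, pb = pos[self.A], pos[self.B]
        L = np.sqrt(((pa - pb) ** 2).sum(axis=1))
        U_L = p.sigma_L * float((self.w * L).sum())

        c = self._scatter_faces(pa) / self.size[:, None]
        u = pa - c[self.F]
        v = pb - c[self.F]
        nrm = np.cross(u, v)
        if self.area_mode == "fan":
            tri = 0.5 * np.sqrt((nrm * nrm).sum(axis=1))
            S = np.bincount(self.F, tri, minlength=self.n_faces)
        else:   # magnitude of the summed triangle area vectors
            nf = 0.5 * self._scatter_faces(nrm)
            S = np.sqrt((nf * nf).sum(axis=1))
        U_ES = p.kappa_S * float(((S[self.is_lat] - p.S_o) ** 2).sum())

        V = float((c[self.F] * np.cross(pa, pb)).sum()) / 6.0
        U_EV = p.kappa_V * (V - p.V_o) ** 2

        U_B = 0.0
        for ring, R in ((self.ring_top, p.R_top), (self.ring_bottom, p.R_bottom)):
            _, s = self._ring_terms(pos, ring, R)
            U_B += p.kappa_B * float((s * s).sum())

        return {"U_L": U_L, "U_ES": U_ES, "U_EV": U_EV, "U_B": U_B,
                "U": U_L + U_ES + U_EV + U_B, "V": V, "S": S}

    # -- force -----------------------------------------------------------
    def force(self, pos: np.ndarray) -> np.ndarray:
        """-grad U, with frozen degrees of freedom zeroed."""
        p = self.params
        pa, pb = pos[self.A], pos[self.B]

        # shared geometry
        c = self._scatter_faces(pa) / self.size[:, None]
        cf = c[self.F]
        u = pa - cf
        v = pb - cf
        nrm = np.cross(u, v)
        if self.area_mode == "fan":
            nn = np.sqrt((nrm * nrm).sum(axis=1))
            S = np.bincount(self.F, 0.5 * nn, minlength=self.n_faces)
        else:
            nf = 0.5 * self._scatter_faces(nrm)
            Sv = np.sqrt((nf * nf).sum(axis=1))
            S = Sv
        V = float((cf * np.cross(pa, pb)).sum()) / 6.0

        # edge tension
        d = pa - pb
        L = np.sqrt((d * d).sum(axis=1))
        coef = p.sigma_L * self.w / np.maximum(L, 1e-300)
        gA = coef[:, None] * d
        gB = -gA

        # area elasticity (lateral faces only)
        q = 2.0 * p.kappa_S * (S - p.S_o) * self.is_lat
        qh = q[self.F][:, None]
        if self.area_mode == "fan":
            nhat = np.zeros_like(nrm)
            ok = nn > 1e-300
            nhat[ok] = nrm[ok] / nn[ok, None]
        else:
            nfh = np.zeros_like(nf)
            okf = Sv > 1e-300
            nfh[okf] = nf[okf] / Sv[okf, None]
            nhat = nfh[self.F]
        gu = 0.5 * np.cross(v, nhat)
        gv = 0.5 * np.cross(nhat, u)
        gA += qh * gu
        gB += qh * gv
        gCh = -qh * (gu + gv)           # centroid dependence, chain rule

        # volume elasticity (all faces close the surface)
        qV = 2.0 * p.kappa_V * (V - p.V_o)
        gA += qV / 6.0 * np.cross(pb, cf)
        gB += qV / 6.0 * np.cross(cf, pa)
        gCh += qV / 6.0 * np.cross(pa, pb)

        # redistribute centroid gradients to face vertices (1/m each)
        Gf = self._scatter_faces(gCh) / self.size[:, None]
        gA += Gf[self.F]

        grad = self._scatter_vertices(self._A3, gA)
        grad += self._scatter_vertices(self._B3, gB)

        # end-ring restraint (in-plane, about the instantaneous ring centroid)
        for ring, R in ((self.ring_top, p.R_top), (self.ring_bottom, p.R_bottom)):
            dv, s = self._ring_terms(pos, ring, R)
            g = 4.0 * p.kappa_B * (s[:, None] * dv - (s[:, None] * dv).mean(axis=0))
            grad[ring, :2] += g

        return -grad * self.free


# ---------------------------------------------------------------------------
# module-level conveniences (build a throwaway kernel)

def potential_energy(mesh: TubeMesh, params: ModelParams,
                     weights: EdgeWeights | None = None) -> dict:
    """Total potential and its per-term breakdown for the current state."""
    k = Kernel(mesh, params, weights)
    e = k.energy(mesh.positions)
    return {key: e[key] for key in ("U", "U_L", "U_ES", "U_EV", "U_B")}


def force(mesh: TubeMesh, params: ModelParams,
          weights: EdgeWeights | None = None,
          fix_end_rotation: bool = False) -> np.ndarray:
    k = Kernel(mesh, params, weights, fix_end_rotation=fix_end_rotation)
    return k.force(mesh.positions)


def step_rk4(pos: np.ndarray, kernel: Kernel, h: float) -> np.ndarray:
    """One classical RK4 step of the gradient flow."""
    k1 = kernel.force(pos)
    k2 = kernel.force(pos + (0.5 * h) * k1)
    k3 = kernel.force(pos + (0.5 * h) * k2)
    k4 = kernel.force(pos + h * k3)
    new = pos + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("non-finite vertex coordinates after RK4 step")
    return new


# ---------------------------------------------------------------------------
# trajectories

def _ring_phi(pos: np.ndarray, ring: np.ndarray) -> np.ndarray:
    return np.arctan2(pos[ring, 1], pos[ring, 0])


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class Trajectory:
    """Saved states, twist trace, energies and reconnection events."""

    times: list = field(default_factory=list)
    twist_deg: list = field(default_factory=list)
    energies: list = field(default_factory=list)      # dict per save point
    events: list = field(default_factory=list)        # ReconnectionEvent
    snapshots: list = field(default_factory=list)     # (t, positions, topo ver)
    topologies: dict = field(default_factory=dict)    # ver -> (faces, caps)
    mesh: TubeMesh | None = None
    h: float = 0.0

    def twist_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        if abs(self.times[i] - t) > 1e-6 + self.h:
            raise KeyError(f"no saved state near t={t}")
        return self.twist_deg[i]

    def positions_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(np.asarray(self.snapshots_times) - t)))
        return self.snapshots[i][1]

    @property
    def snapshots_times(self):
        return [s[0] for s in self.snapshots]

    def faces_at(self, t: float):
        i = int(np.argmin(np.abs(np.asarray(self.snapshots_times) - t)))
        ver = self.snapshots[i][2]
        return self.topologies[ver]

    def mesh_at(self, t: float) -> TubeMesh:
        i = int(np.argmin(np.abs(np.asarray(self.snapshots_times) - t)))
        tt, pos, ver = self.snapshots[i]
        faces, (cap_t, cap_b) = self.topologies[ver]
        return TubeMesh(pos.copy(), [list(f) for f in faces],
                        list(cap_t), list(cap_b),
                        dict(self.mesh.meta) if self.mesh is not None else {})

    def trace_df(self) -> pd.DataFrame:
        rows = []
        for t, tw, e in zip(self.times, self.twist_deg, self.energies):
            rows.append({"t": t, "twist_deg": tw, "U": e["U"], "U_L": e["U_L"],
                         "U_ES": e["U_ES"], "U_EV": e["U_EV"], "U_B": e["U_B"]})
        return pd.DataFrame(rows)

    def events_df(self) -> pd.DataFrame:
        cols = ["t", "v1", "v2", "faces_lost_edge", "faces_gained_edge",
                "length_before"]
        rows = [{"t": ev.time, "v1": ev.v1, "v2": ev.v2,
                 "faces_lost_edge": "|".join(map(str, ev.faces_lost)),
                 "faces_gained_edge": "|".join(map(str, ev.faces_gained)),
                 "length_before": ev.length_before} for ev in self.events]
        return pd.DataFrame(rows, columns=cols)


def run(mesh: TubeMesh, params: ModelParams, options: RunOptions,
        weights: EdgeWeights | None = None, t_offset: float = 0.0,
        progress: bool = False) -> Trajectory:
    """Integrate the equation of motion for ``options.t_end`` time units.

    Mutates ``mesh`` in place (positions and, if reconnections fire, the
    face loops) and returns the trajectory record.  ``t_offset`` only
    shifts the reported timestamps.
    """
    h = params.h
    n_steps = int(round(options.t_end / h))
    save_stride = max(1, int(round(options.save_every / h)))

    kernel = Kernel(mesh, params, weights,
                    fix_end_rotation=options.fix_end_rotation)
    pos = mesh.positions

    traj = Trajectory(mesh=mesh, h=h)
    phi_top = _ring_phi(pos, kernel.ring_top)
    phi_bot = _ring_phi(pos, kernel.ring_bottom)
    acc_top = phi_top.copy()
    acc_bot = phi_bot.copy()
    twist0 = acc_top.mean() - acc_bot.mean()

    def record(t):
        nonlocal phi_top, phi_bot, acc_top, acc_bot
        new_top = _ring_phi(pos, kernel.ring_top)
        new_bot = _ring_phi(pos, kernel.ring_bottom)
        acc_top = acc_top + _wrap_angle(new_top - phi_top)
        acc_bot = acc_bot + _wrap_angle(new_bot - phi_bot)
        phi_top, phi_bot = new_top, new_bot
        # positive twist = counterclockwise viewed from the posterior (-z) end
        twist = -np.degrees((acc_top.mean() - acc_bot.mean()) - twist0)
        traj.times.append(t)
        traj.twist_deg.append(float(twist))
        traj.energies.append(kernel.energy(pos))
        ver = mesh.topology_version
        if ver not in traj.topologies:
            traj.topologies[ver] = ([list(f) for f in mesh.faces],
                                    (list(mesh.cap_top), list(mesh.cap_bottom)))
        traj.snapshots.append((t, pos.copy(), ver))

    record(t_offset)

    # reconnection bookkeeping: an edge triggers a T1 when its length
    # *becomes* less than delta, i.e. crosses the threshold downward; edges
    # already below delta at run start (or exempted after a skipped event)
    # re-arm only by first recovering above delta.  A short per-pair
    # cooldown suppresses numerical flip-flop at a freshly swapped junction.
    d2 = params.delta ** 2

    def _check_arrays():
        ckA = kernel.A[kernel.check_idx]
        ckB = kernel.B[kernel.check_idx]
        return ckA, ckB

    ckA, ckB = _check_arrays()
    dd = pos[ckA] - pos[ckB]
    eligible = (dd * dd).sum(axis=1) >= d2
    cooldown_until: dict = {}

    for step in range(1, n_steps + 1):
        pos = step_rk4(pos, kernel, h)
        mesh.positions = pos
        t = t_offset + step * h
        if options.reconnect:
            dd = pos[ckA] - pos[ckB]
            l2 = (dd * dd).sum(axis=1)
            below = l2 < d2
            trig = eligible & below
            eligible = eligible | ~below
            if trig.any():
                cand = [(int(a), int(b)) for a, b in zip(ckA[trig], ckB[trig])
                        if cooldown_until.get(frozenset((int(a), int(b))),
                                              -np.inf) <= t]
                events = recon.apply_reconnections(mesh, params.delta, t,
                                                   candidates=cand)
                if events:
                    for ev in events:
                        cooldown_until[frozenset((ev.v1, ev.v2))] = \
                            t + options.reconnect_cooldown
                        if weights is not None:
                            weights.on_reconnection(mesh, ev)
                    traj.events.extend(events)
                    kernel = Kernel(mesh, params, weights,
                                    fix_end_rotation=options.fix_end_rotation)
                    pos = mesh.positions
                    ckA, ckB = _check_arrays()
                    dd = pos[ckA] - pos[ckB]
                    # after surgery: everything currently below delta must
                    # recover above it before it can trigger again
                    eligible = (dd * dd).sum(axis=1) >= d2
                else:
                    eligible[trig] = False
        if step % save_stride == 0 or step == n_steps:
            record(t)
            if progress and step % (save_stride * 10) == 0:
                e = traj.energies[-1]
                print(f"  t={t:8.2f}  U={e['U']:.4f}  "
                      f"twist={traj.twist_deg[-1]:7.2f} deg", flush=True)
    mesh.positions = pos
    return traj
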