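"""Parameter containers for the tube-twisting vertex model.

All defaults are the dimensionless values of the published parameter set:
lengths are measured in units of the relaxed cell size ``R_o = sqrt(S_o)``
and time in units of ``1/(eta * R_o)``, so neither the drag coefficient nor
an absolute length scale appears as a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of the initial cell packing and the cylinder it wraps onto.

    The planar rectangle (periodic in its width direction) is seeded with
    hard discs, Voronoi-tessellated and rolled into a tube whose long axis
    is z (anterior-posterior; z increases anteriorly).
    """

    n_cells: int = 452
    rect_width: float = 15.75      # becomes the circumference direction
    rect_height: float = 28.7      # becomes the tube height (AP length)
    disc_diameter: float = 0.82    # hard-core exclusion between seed points
    tube_diameter: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("rect_width", "rect_height", "disc_diameter", "tube_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def radius(self) -> float:
        return self.tube_diameter / 2.0


@dataclass(frozen=True)
class ModelParams:
    """Energy densities, geometry targets and solver constants.

    U = U_L + U_ES + U_EV + U_B with
      U_L  = sigma_L * sum_cells sum_edges w * L        (edge tension)
      U_ES = kappa_S * sum_cells (S - S_o)**2           (area elasticity)
      U_EV = kappa_V * (V - V_o)**2                     (tube-volume elasticity)
      U_B  = kappa_B * sum_rings [(r - r_ring)^2 - R^2]^2  (end-ring restraint)

    The sums run over the lateral cells only; each interior edge therefore
    contributes once per incident lateral cell (twice in total).
    """

    sigma_L: float = 2.2
    kappa_S: float = 10.0
    kappa_V: float = 0.2
    kappa_B: float = 1.0
    S_o: float = 1.0
    V_o: float = 566.64
    R_top: float = 2.5
    R_bottom: float = 2.5
    h: float = 0.005          # Runge-Kutta step
    delta: float = 0.3        # reconnection (T1) critical edge length
    area_mode: str = "fan"    # non-planar polygon area: "fan" or "vector"

    def __post_init__(self) -> None:
        if self.area_mode not in ("fan", "vector"):
            raise ValueError("area_mode must be 'fan' or 'vector'")
        for name in ("sigma_L", "kappa_S", "kappa_V", "kappa_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("S_o", "V_o", "R_top", "R_bottom", "h", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ChiralityProtocol:
    """How handed cell shapes are imprinted before the relaxation run.

    Each cell receives a polarity vector tilted ``deflection_deg`` from the
    tube axis in its local tangent plane (positive = leftward as seen from
    outside, i.e. toward decreasing azimuth).  The two cell edges crossed by
    the plane normal to the polarity through the cell centre contract with
    weight ``w_special``; dynamics run to ``t_end_induction``, after which
    the clock is reset to zero and all weights return to 1.
    """

    deflection_deg: float = 30.0
    w_special: float = 3.5
    t_end_induction: float = 5.0
    reset_time_to_zero: bool = True

    def __post_init__(self) -> None:
        if not abs(self.deflection_deg) < 90.0:
            raise ValueError("deflection_deg must satisfy |deflection| < 90")
        if self.w_special < 1.0:
            raise ValueError("w_special must be >= 1")
        if self.t_end_induction <= 0:
            raise ValueError("t_end_induction must be positive")


@dataclass(frozen=True)
class RunOptions:
    """Options for a dynamics run."""

    t_end: float = 80.0
    reconnect: bool = True
    fix_end_rotation: bool = False   # freeze x,y of both end rings
    save_every: float = 1.0
    seed: int = 0
    reconnect_cooldown: float = 1.0  # per-edge refractory time after a T1

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.save_every <= 0:
            raise ValueError("save_every must be positive")


#: Presets for the four published in-silico experiments.
PRESETS: Mapping[str, dict] = {
    "wildtype": dict(
        protocol=ChiralityProtocol(deflection_deg=30.0, w_special=3.5,
                                   t_end_induction=5.0),
        reconnect=True, fix_end_rotation=False,
    ),
    "inverted": dict(
        protocol=ChiralityProtocol(deflection_deg=-35.0, w_special=3.5,
                                   t_end_induction=10.0),
        reconnect=True, fix_end_rotation=False,
    ),
    "no-reconnect": dict(
        protocol=ChiralityProtocol(deflection_deg=30.0, w_special=3.5,
                                   t_end_induction=5.0),
        reconnect=False, fix_end_rotation=False,
    ),
    "fixed-ends": dict(
        protocol=ChiralityProtocol(deflection_deg=30.0, w_special=3.5,
                                   t_end_induction=5.0),
        reconnect=True, fix_end_rotation=True,
    ),
}


def params_to_dict(p) -> dict:
    return asdict(p)
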