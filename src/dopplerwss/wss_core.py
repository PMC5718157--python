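"""Near-wall shear rate, wall shear stress, and Hagen-Poiseuille references.

The estimator follows the two-layer near-wall difference: with the vessel
horizontal, let V_slow be the speed of the flow pixel adjacent to the wall
and V_fast the speed of the next flow pixel inward, one radial layer (d cm)
apart.  Then

    gamma_w = du/dr ~= (V_fast - V_slow) / d        [1/s]
    tau_w   = mu * gamma_w                          [dyne/cm2]

with mu the dynamic viscosity in poise.  Speeds enter as magnitudes; the
sign of the column's flow (toward/away from the probe) is carried separately
as a diagnostic.

For steady laminar tube flow (parabolic profile u(r) = u_M (1 - r^2/R^2))
the analytic references are

    tau_w = 4 mu Q / (pi R^3)      (flow-rate form)
    tau_w = 2 mu u_M / R           (centerline-velocity form)

which coincide exactly when Q = pi R^2 u_M / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .doppler_io import FluidParams
from .exceptions import CalibrationError
from .geometry import WallBoundary
from .velocity_decode import VelocityField

__all__ = [
    "ShearRates",
    "WSSMap",
    "VesselGeometry",
    "WSSSummary",
    "near_wall_gradient",
    "wall_shear_stress",
    "poiseuille_wss_flowrate",
    "poiseuille_wss_maxvel",
    "wss_summary",
    "wss_surface_export",
]


@dataclass(eq=False)
class ShearRates:
    """Per-column near-wall shear rates (1/s) for upper and lower wall."""

    columns: np.ndarray
    gamma_upper: np.ndarray
    gamma_lower: np.ndarray
    flow_direction: np.ndarray  # +1 toward probe, -1 away, 0 mixed/still
    d: float

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.gamma_upper = np.asarray(self.gamma_upper, dtype=float)
        self.gamma_lower = np.asarray(self.gamma_lower, dtype=float)
        self.flow_direction = np.asarray(self.flow_direction, dtype=int)


@dataclass(eq=False)
class WSSMap:
    """Per-column wall shear stress (dyne/cm2) on both walls.

    tau = mu * gamma holds elementwise by construction.
    """

    columns: np.ndarray
    gamma_upper: np.ndarray
    gamma_lower: np.ndarray
    tau_upper: np.ndarray
    tau_lower: np.ndarray
    mu: float
    flow_direction: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        for name in ("gamma_upper", "gamma_lower", "tau_upper", "tau_lower"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.flow_direction is None:
            self.flow_direction = np.zeros_like(self.columns)

    @property
    def n_columns(self) -> int:
        return int(self.columns.size)

    def to_dataframe(self) -> pd.DataFrame:
        upper = pd.DataFrame(
            {
                "col": self.columns,
                "wall": "upper",
                "gamma_s_inv": self.gamma_upper,
                "tau_dyne_cm2": self.tau_upper,
            }
        )
        lower = upper.copy()
        lower["wall"] = "lower"
        lower["gamma_s_inv"] = self.gamma_lower
        lower["tau_dyne_cm2"] = self.tau_lower
        return pd.concat([upper, lower], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class VesselGeometry:
    """Idealized tube geometry: radius R (cm), centerline velocity u_M (cm/s),
    volumetric flow rate Q (cm3/s).  Unused fields may be None."""

    R: float | None = None
    u_M: float | None = None
    Q: float | None = None

    def __post_init__(self) -> None:
        for name in ("R", "u_M", "Q"):
            val = getattr(self, name)
            if val is not None and (not np.isfinite(val) or val < 0):
                raise ValueError(f"{name} must be non-negative and finite, got {val!r}")


@dataclass(frozen=True)
class WSSSummary:
    """Spatial (and optionally temporal) aggregate of a WSS map."""

    mean_tau: float
    max_tau: float
    n_columns: int
    mean_tau_upper: float
    mean_tau_lower: float
    per_frame_mean: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        out = {
            "mean_tau": self.mean_tau,
            "max_tau": self.max_tau,
            "n_columns": self.n_columns,
            "per_wall": {"upper": self.mean_tau_upper, "lower": self.mean_tau_lower},
        }
        if self.per_frame_mean is not None:
            out["per_frame_mean"] = list(self.per_frame_mean)
        return out


def near_wall_gradient(
    field: VelocityField,
    boundary: WallBoundary,
    use_boundary_zero: bool = False,
    three_point: bool = False,
) -> ShearRates:
    """Two-layer near-wall shear rate per column and wall.

    Default stencil: V_slow = |v| at the flow pixel adjacent to the wall,
    V_fast = |v| one layer further in; gamma = (V_fast - V_slow) / d.
    ``use_boundary_zero`` instead anchors V_slow = 0 at the grayscale wall
    pixel itself.  ``three_point`` switches to a second-order one-sided
    stencil (-3 f0 + 4 f1 - f2) / (2 d) for convergence studies.

    Columns lacking enough valid flow pixels on a wall side are dropped;
    only columns valid on both walls are returned.
    """
    d = boundary.d
    if not d > 0:
        raise CalibrationError(f"layer spacing d must be positive, got {d}")
    speed = np.abs(field.v)
    cols, g_up, g_lo, direction = [], [], [], []
    n_layers = 3 if three_point else 2
    for c, up, lo in zip(boundary.columns, boundary.upper_row, boundary.lower_row):
        lumen = slice(up + 1, lo)  # flow rows
        if lo - up - 1 < n_layers:
            continue
        rows_up = [up + 1 + i for i in range(n_layers)]
        rows_lo = [lo - 1 - i for i in range(n_layers)]
        if not (field.valid[rows_up, c].all() and field.valid[rows_lo, c].all()):
            continue
        gu = _one_sided(speed[rows_up, c], d, use_boundary_zero, three_point)
        gl = _one_sided(speed[rows_lo, c], d, use_boundary_zero, three_point)
        cols.append(c)
        g_up.append(gu)
        g_lo.append(gl)
        vcol = field.v[lumen, c][field.valid[lumen, c]]
        direction.append(int(np.sign(vcol.mean())) if vcol.size else 0)
    return ShearRates(
        columns=np.asarray(cols, dtype=int),
        gamma_upper=np.asarray(g_up),
        gamma_lower=np.asarray(g_lo),
        flow_direction=np.asarray(direction, dtype=int),
        d=d,
    )


def _one_sided(speeds: np.ndarray, d: float, from_zero: bool, three_point: bool) -> float:
    """One-sided difference of wall-ordered speeds (element 0 nearest the wall)."""
    if three_point:
        f0, f1, f2 = speeds[:3]
        return float((-3 * f0 + 4 * f1 - f2) / (2 * d))
    if from_zero:
        return float(speeds[0] / d)
    v_slow, v_fast = speeds[:2]
    return float((v_fast - v_slow) / d)


def wall_shear_stress(gammas: ShearRates, fluid: FluidParams) -> WSSMap:
    """tau = mu * gamma per column and wall (dyne/cm2 = poise * 1/s)."""
    mu = fluid.mu
    return WSSMap(
        columns=gammas.columns,
        gamma_upper=gammas.gamma_upper,
        gamma_lower=gammas.gamma_lower,
        tau_upper=mu * gammas.gamma_upper,
        tau_lower=mu * gammas.gamma_lower,
        mu=mu,
        flow_direction=gammas.flow_direction,
    )


def poiseuille_wss_flowrate(geom: VesselGeometry, fluid: FluidParams) -> float:
    """Wall shear stress of Poiseuille flow from volumetric rate: 4 mu Q / (pi R^3)."""
    if geom.R is None or geom.Q is None:
        raise ValueError("geometry must set R and Q")
    if geom.R == 0:
        raise ValueError("vessel radius R must be positive")
    return 4.0 * fluid.mu * geom.Q / (np.pi * geom.R**3)


def poiseuille_wss_maxvel(geom: VesselGeometry, fluid: FluidParams) -> float:
    """Wall shear stress of Poiseuille flow from centerline velocity: 2 mu u_M / R.

    Equals the flow-rate form exactly under Q = pi R^2 u_M / 2.
    """
    if geom.R is None or geom.u_M is None:
        raise ValueError("geometry must set R and u_M")
    if geom.R == 0:
        raise ValueError("vessel radius R must be positive")
    return 2.0 * fluid.mu * geom.u_M / geom.R


def wss_summary(wss_map: WSSMap, frames: list[WSSMap] | None = None) -> WSSSummary:
    """Mean/max over retained columns and both walls.

    With ``frames`` given (a per-frame stack including or excluding
    ``wss_map``), per-frame means are reported alongside their arithmetic
    time average, which becomes ``mean_tau``.
    """
    maps = list(frames) if frames else [wss_map]
    if wss_map not in maps:
        maps = [wss_map] + maps
    per_frame = []
    all_vals = []
    for m in maps:
        if m.n_columns < 1:
            raise ValueError("WSS map has no retained columns")
        vals = np.concatenate([m.tau_upper, m.tau_lower])
        per_frame.append(float(vals.mean()))
        all_vals.append(vals)
    mean_tau = float(np.mean(per_frame))
    max_tau = float(np.max([v.max() for v in all_vals]))
    up = float(np.mean([m.tau_upper.mean() for m in maps]))
    lo = float(np.mean([m.tau_lower.mean() for m in maps]))
    return WSSSummary(
        mean_tau=mean_tau,
        max_tau=max_tau,
        n_columns=int(np.max([m.n_columns for m in maps])),
        mean_tau_upper=up,
        mean_tau_lower=lo,
        per_frame_mean=tuple(per_frame) if len(maps) > 1 else None,
    )


def wss_surface_export(
    maps: WSSMap | list[WSSMap],
    path: str | Path | None = None,
    collapse: str = "max",
) -> pd.DataFrame:
    """Rectangular column x frame grid of wall shear stress (the 3-D surface).

    Each cell holds the per-column stress collapsed across the two walls
    (``collapse`` in {"max", "mean", "upper", "lower"}; the default "max"
    preserves the global peak, so the grid maximum equals the summary's
    max_tau).  Columns missing from a frame appear as explicit NaN gaps.
    """
    if isinstance(maps, WSSMap):
        maps = [maps]
    if not maps:
        raise ValueError("at least one WSS map required")
    reducers = {
        "max": lambda m: np.maximum(m.tau_upper, m.tau_lower),
        "mean": lambda m: 0.5 * (m.tau_upper + m.tau_lower),
        "upper": lambda m: m.tau_upper,
        "lower": lambda m: m.tau_lower,
    }
    if collapse not in reducers:
        raise ValueError(f"collapse must be one of {sorted(reducers)}")
    all_cols = np.unique(np.concatenate([m.columns for m in maps]))
    grid = pd.DataFrame(index=all_cols, dtype=float)
    grid.index.name = "col"
    for i, m in enumerate(maps):
        series = pd.Series(reducers[collapse](m), index=m.columns)
        grid[f"frame_{i}"] = series
    if path is not None:
        grid.to_csv(path)
    return grid
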