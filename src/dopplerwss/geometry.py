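"""Vessel geometry: flow-axis estimation, rotation, ROI, wall detection.

The shear-rate discretization needs the vessel horizontal so that the
radial direction is the image's vertical; these routines automate what an
operator would otherwise do by hand: estimate the flow axis, rotate the
decoded velocity field (never the raw colors — interpolating RGB through a
nonlinear LUT corrupts velocities), crop a region of interest, and locate
per column the grayscale wall pixels bounding the lumen.

Coordinates are image convention: row 0 at the top, 0-based indices; the
geometric angle of the flow axis is measured counterclockwise from the
horizontal with the vertical axis pointing up (i.e. -row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import SegmentationError
from .velocity_decode import BACKGROUND, FLOW, WALL_GRAY, PixelMask, VelocityField

__all__ = [
    "WallBoundary",
    "estimate_flow_axis",
    "rotate_to_horizontal",
    "select_roi",
    "detect_wall_boundary",
    "DEFAULT_MIN_LUMEN_PX",
]

DEFAULT_MIN_LUMEN_PX = 5

#: minimum flow pixels for a meaningful principal-axis fit
_MIN_FLOW_PX = 100
#: eigenvalue ratio below which the flow blob has no preferred direction
_DEGENERATE_RATIO = 1.2


@dataclass(eq=False)
class WallBoundary:
    """Per-column lumen-wall interface.

    For every retained column, ``upper_row``/``lower_row`` index the
    grayscale wall pixel immediately above/below the lumen's flow run;
    ``d`` is the constant radial layer spacing in cm (the axial pixel
    spacing once the vessel is horizontal).
    """

    columns: np.ndarray
    upper_row: np.ndarray
    lower_row: np.ndarray
    d: float

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.upper_row = np.asarray(self.upper_row, dtype=int)
        self.lower_row = np.asarray(self.lower_row, dtype=int)
        if not (self.columns.size == self.upper_row.size == self.lower_row.size):
            raise ValueError("columns, upper_row, lower_row must have equal length")
        if self.columns.size and not np.all(self.upper_row < self.lower_row):
            raise ValueError("upper_row must be strictly above lower_row")
        if not self.d > 0:
            raise ValueError(f"layer spacing d must be positive, got {self.d}")

    @property
    def n_columns(self) -> int:
        return int(self.columns.size)


def estimate_flow_axis(mask: PixelMask) -> float:
    """Angle (degrees, in (-90, 90]) of the principal axis of the flow pixels.

    Uses the second-moment eigen-axis of the FLOW pixel cloud.  A nearly
    isotropic cloud (eigenvalue ratio below 1.2) has no preferred direction;
    0 degrees is returned with a warning.
    """
    rows, cols = np.nonzero(mask.labels == FLOW)
    if rows.size < _MIN_FLOW_PX:
        raise SegmentationError(
            f"only {rows.size} flow pixels; at least {_MIN_FLOW_PX} required for axis fit"
        )
    x = cols.astype(float)
    y = -rows.astype(float)  # vertical axis up
    cov = np.cov(np.stack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    ratio = evals[1] / max(evals[0], 1e-30)  # a zero minor axis means maximal elongation
    if ratio < _DEGENERATE_RATIO:
        warnings.warn(
            "flow pixel cloud is nearly isotropic; flow axis set to 0 degrees",
            stacklevel=2,
        )
        return 0.0
    vx, vy = evecs[:, 1]  # eigenvector of the largest eigenvalue
    angle = np.degrees(np.arctan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def _inverse_coords(shape: tuple[int, int], angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Source (row, col) coordinates that rotate image content by -angle_deg
    about the image center (bringing a feature at +angle_deg to horizontal)."""
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    x = cols - cc
    y = -(rr - cr)
    th = np.deg2rad(angle_deg)
    xs = np.cos(th) * x - np.sin(th) * y
    ys = np.sin(th) * x + np.cos(th) * y
    return cr - ys, xs + cc


def rotate_to_horizontal(
    field: VelocityField, mask: PixelMask, angle_degrees: float
) -> tuple[VelocityField, PixelMask]:
    """Rotate field and mask so content at ``angle_degrees`` becomes horizontal.

    Velocities are resampled with bilinear interpolation restricted to valid
    pixels (invalid neighbors are excluded from the weighted average; an
    output pixel stays invalid when less than half its interpolation weight
    comes from valid sources).  The mask is resampled nearest-neighbor.
    A rotation by 0 degrees is the exact identity.
    """
    if abs(angle_degrees) > 90:
        raise ValueError(f"|angle| must be <= 90 degrees, got {angle_degrees}")
    if angle_degrees == 0.0:
        return (
            VelocityField(
                v=field.v.copy(),
                valid=field.valid.copy(),
                spacing_axial=field.spacing_axial,
                spacing_lateral=field.spacing_lateral,
            ),
            PixelMask(labels=mask.labels.copy()),
        )
    if field.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    h, w = field.shape
    r_src, c_src = _inverse_coords((h, w), angle_degrees)

    # nearest-neighbor mask
    rn = np.round(r_src).astype(int)
    cn = np.round(c_src).astype(int)
    inb = (rn >= 0) & (rn < h) & (cn >= 0) & (cn < w)
    new_labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    new_labels[inb] = mask.labels[rn[inb], cn[inb]]

    # masked bilinear velocities
    r0 = np.floor(r_src).astype(int)
    c0 = np.floor(c_src).astype(int)
    fr = r_src - r0
    fc = c_src - c0
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        ri = r0 + dr
        ci = c0 + dc
        ok = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        ric = np.clip(ri, 0, h - 1)
        cic = np.clip(ci, 0, w - 1)
        vsrc = field.v[ric, cic]
        vok = ok & field.valid[ric, cic]
        num += np.where(vok, wgt * vsrc, 0.0)
        den += np.where(vok, wgt, 0.0)
    new_valid = den >= 0.5
    new_v = np.zeros((h, w))
    new_v[new_valid] = num[new_valid] / den[new_valid]
    return (
        VelocityField(
            v=new_v,
            valid=new_valid,
            spacing_axial=field.spacing_axial,
            spacing_lateral=field.spacing_lateral,
        ),
        PixelMask(labels=new_labels),
    )


def select_roi(mask: PixelMask, roi: tuple[int, int, int, int]) -> PixelMask:
    """Restrict the mask to a rectangle (col0, row0, col1, row1), half-open.

    Labels outside the rectangle become BACKGROUND; inside unchanged.
    """
    c0, r0, c1, r1 = (int(v) for v in roi)
    h, w = mask.shape
    if not (0 <= c0 < c1 <= w and 0 <= r0 < r1 <= h):
        raise ValueError(
            f"ROI (col0={c0}, row0={r0}, col1={c1}, row1={r1}) is empty or outside "
            f"the {h}x{w} image"
        )
    out = np.full_like(mask.labels, BACKGROUND)
    out[r0:r1, c0:c1] = mask.labels[r0:r1, c0:c1]
    return PixelMask(labels=out)


def detect_wall_boundary(
    mask: PixelMask,
    field: VelocityField,
    min_lumen_px: int = DEFAULT_MIN_LUMEN_PX,
) -> WallBoundary:
    """Find, per column, the grayscale wall rows bounding the lumen.

    In each column the longest contiguous vertical FLOW run is taken as the
    lumen; the column is retained when the run is at least ``min_lumen_px``
    pixels long and is bordered by a WALL_GRAY pixel on both sides.  Runs
    touching the image edge have no wall pixel there and are dropped.
    """
    labels = mask.labels
    h, w = labels.shape
    cols: list[int] = []
    uppers: list[int] = []
    lowers: list[int] = []
    flow = labels == FLOW
    for c in range(w):
        col = flow[:, c]
        if not col.any():
            continue
        # run-length encode the FLOW column
        edges = np.diff(col.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        stops = np.flatnonzero(edges == -1) + 1
        if col[0]:
            starts = np.r_[0, starts]
        if col[-1]:
            stops = np.r_[stops, h]
        lengths = stops - starts
        k = int(np.argmax(lengths))
        start, stop = int(starts[k]), int(stops[k])  # flow rows [start, stop)
        if stop - start < min_lumen_px:
            continue
        if start == 0 or stop == h:
            continue  # run touches image edge: no wall pixel on that side
        if labels[start - 1, c] != WALL_GRAY or labels[stop, c] != WALL_GRAY:
            continue
        cols.append(c)
        uppers.append(start - 1)
        lowers.append(stop)
    if not cols:
        raise SegmentationError(
            "no column has a wall-bounded flow run of at least "
            f"{min_lumen_px} pixels"
        )
    return WallBoundary(
        columns=np.asarray(cols),
        upper_row=np.asarray(uppers),
        lower_row=np.asarray(lowers),
        d=field.spacing_axial,
    )
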