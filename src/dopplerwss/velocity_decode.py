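"""Pixel classification and colormap inversion.

In a color Doppler frame the lumen is rendered as chromatic flow pixels,
the vessel wall as grayscale pixels (whose velocity is zero by definition),
and everything else is dark background.  Classification uses two 8-bit
thresholds: a pixel is FLOW when its chroma (max - min channel) exceeds
``chroma_tol``; otherwise it is WALL_GRAY when its luminance (max channel)
reaches ``lum_min``, else BACKGROUND.

Decoding inverts the color LUT by nearest neighbor in RGB space and scales
by the Nyquist velocity, producing a signed axial velocity field in cm/s.
Flow pixels whose color is farther than ``max_rgb_dist`` from every LUT
entry are marked invalid and counted in the decode report, as are pixels
within one LUT step of the Nyquist limit (a hint of aliasing, which this
package detects but never unwraps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colormap import ColorMapSpec, DEFAULT_CHROMA_TOL
from .doppler_io import DopplerFrame

__all__ = [
    "BACKGROUND",
    "WALL_GRAY",
    "FLOW",
    "PixelMask",
    "VelocityField",
    "DecodeReport",
    "classify_pixels",
    "decode_velocity",
    "DEFAULT_LUM_MIN",
]

BACKGROUND = np.uint8(0)
WALL_GRAY = np.uint8(1)
FLOW = np.uint8(2)

DEFAULT_LUM_MIN = 40


@dataclass(eq=False)
class PixelMask:
    """Per-pixel label array over {BACKGROUND, WALL_GRAY, FLOW}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_flow(self) -> int:
        return int(np.count_nonzero(self.labels == FLOW))


@dataclass(eq=False)
class VelocityField:
    """Signed axial velocity per pixel (cm/s) with a validity mask.

    v is zero and valid False outside flow pixels; wall pixels carry
    velocity zero by the boundary definition.
    """

    v: np.ndarray
    valid: np.ndarray
    spacing_axial: float
    spacing_lateral: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.v.shape != self.valid.shape or self.v.ndim != 2:
            raise ValueError("v and valid must be 2-D arrays of the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape


@dataclass(frozen=True)
class DecodeReport:
    """Decode quality log: unmatched flow pixels and near-Nyquist fraction."""

    n_flow: int
    n_unmatched: int
    n_near_nyquist: int
    aliasing_suspected: bool
    max_rgb_dist: float

    @property
    def near_nyquist_fraction(self) -> float:
        return self.n_near_nyquist / self.n_flow if self.n_flow else 0.0


def classify_pixels(
    frame: DopplerFrame,
    chroma_tol: int = DEFAULT_CHROMA_TOL,
    lum_min: int = DEFAULT_LUM_MIN,
) -> PixelMask:
    """Label each pixel FLOW, WALL_GRAY or BACKGROUND (total function).

    FLOW: chroma = max(R,G,B) - min(R,G,B) > chroma_tol.
    WALL_GRAY: not FLOW and max(R,G,B) >= lum_min.
    BACKGROUND: everything else.
    """
    px = frame.pixels.astype(np.int16)
    chroma = px.max(axis=2) - px.min(axis=2)
    lum = px.max(axis=2)
    labels = np.full(px.shape[:2], BACKGROUND, dtype=np.uint8)
    labels[lum >= lum_min] = WALL_GRAY
    labels[chroma > chroma_tol] = FLOW
    return PixelMask(labels=labels)


def decode_velocity(
    frame: DopplerFrame,
    cmap: ColorMapSpec,
    mask: PixelMask,
    max_rgb_dist: float = 60.0,
    angle_correction_deg: float | None = None,
) -> tuple[VelocityField, DecodeReport]:
    """Invert the color LUT over FLOW pixels into signed velocities (cm/s).

    Non-flow pixels get v = 0 and valid = False.  Flow pixels farther than
    ``max_rgb_dist`` (Euclidean RGB) from every LUT entry are marked invalid
    and counted.  ``angle_correction_deg``, when given, divides velocities by
    cos(angle) for a beam-to-flow Doppler angle the scanner did not correct.
    """
    if mask.shape != frame.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frame.shape}")
    flow = mask.labels == FLOW
    v = np.zeros(frame.shape, dtype=float)
    valid = np.zeros(frame.shape, dtype=bool)
    n_flow = int(flow.sum())
    n_unmatched = 0
    n_near = 0
    if n_flow:
        rgb = frame.pixels[flow]
        v_norm, dist = cmap.decode(rgb)
        matched = dist <= max_rgb_dist
        n_unmatched = int((~matched).sum())
        vel = v_norm * frame.v_nyquist
        vel[~matched] = 0.0
        v[flow] = vel
        good = np.zeros(frame.shape, dtype=bool)
        good[flow] = matched
        valid = good
        step = cmap.quantization_step * frame.v_nyquist
        n_near = int((np.abs(np.abs(vel[matched]) - frame.v_nyquist) <= step).sum())
    if angle_correction_deg is not None:
        v = v / np.cos(np.deg2rad(angle_correction_deg))
    n_matched = n_flow - n_unmatched
    report = DecodeReport(
        n_flow=n_flow,
        n_unmatched=n_unmatched,
        n_near_nyquist=n_near,
        aliasing_suspected=bool(n_matched and n_near / n_matched > 0.01),
        max_rgb_dist=max_rgb_dist,
    )
    return (
        VelocityField(
            v=v,
            valid=valid,
            spacing_axial=frame.spacing_axial,
            spacing_lateral=frame.spacing_lateral,
        ),
        report,
    )
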