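"""Model/Results surface over the wall-shear-stress pipeline.

:class:`WallShearStress` bundles the full estimation chain — pixel
classification, LUT inversion, rotation to horizontal, wall detection,
near-wall shear rate, tau = mu * gamma — behind a fit() call that returns a
:class:`WallShearStressResults` carrying the per-column stress map, spatial
and temporal aggregates, decode/segmentation diagnostics, and a printable
summary table.

    >>> model = WallShearStress(frame, colormap="red-blue-brightness", mu=0.03)
    >>> res = model.fit(angle="auto")
    >>> print(res.summary())

Multiple frames of the same acquisition are averaged arithmetically (mean
of per-frame spatial means).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colormap import ColorMapSpec, DEFAULT_CHROMA_TOL
from .doppler_io import DopplerFrame, FluidParams, FrameCalibration, load_colormap, read_frame
from .geometry import (
    DEFAULT_MIN_LUMEN_PX,
    detect_wall_boundary,
    estimate_flow_axis,
    rotate_to_horizontal,
    select_roi,
)
from .velocity_decode import DEFAULT_LUM_MIN, classify_pixels, decode_velocity
from .wss_core import (
    WSSMap,
    WSSSummary,
    near_wall_gradient,
    wall_shear_stress,
    wss_summary,
    wss_surface_export,
)

__all__ = ["WallShearStress", "WallShearStressResults"]


class WallShearStress:
    """Wall-shear-stress estimator for one or more color Doppler frames.

    Parameters
    ----------
    frames : DopplerFrame or sequence of DopplerFrame
    colormap : str or ColorMapSpec
        Color LUT of the acquisition (built-in name, JSON path, or spec).
    mu : float
        Dynamic viscosity in poise (default 0.03 = 3 cP, whole blood).
    chroma_tol, lum_min : int
        8-bit classification thresholds (flow chroma / wall luminance).
    min_lumen_px : int
        Minimum contiguous flow run accepted as lumen in a column.
    max_rgb_dist : float
        Maximum RGB distance for a flow pixel to decode as valid.
    """

    def __init__(
        self,
        frames: DopplerFrame | Sequence[DopplerFrame],
        colormap: str | ColorMapSpec = "red-blue-brightness",
        mu: float = 0.03,
        chroma_tol: int = DEFAULT_CHROMA_TOL,
        lum_min: int = DEFAULT_LUM_MIN,
        min_lumen_px: int = DEFAULT_MIN_LUMEN_PX,
        max_rgb_dist: float = 60.0,
    ) -> None:
        if isinstance(frames, DopplerFrame):
            frames = [frames]
        if not frames:
            raise ValueError("at least one frame is required")
        self.frames = list(frames)
        self.cmap = colormap if isinstance(colormap, ColorMapSpec) else load_colormap(colormap)
        self.fluid = FluidParams(mu=mu)
        self.chroma_tol = chroma_tol
        self.lum_min = lum_min
        self.min_lumen_px = min_lumen_px
        self.max_rgb_dist = max_rgb_dist

    @classmethod
    def from_files(
        cls,
        paths: str | Path | Sequence[str | Path],
        calib: FrameCalibration | None = None,
        **kwargs,
    ) -> "WallShearStress":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        frames = [read_frame(p, calib=calib) for p in paths]
        return cls(frames, **kwargs)

    def fit(
        self,
        angle: str | float = "auto",
        roi: tuple[int, int, int, int] | None = None,
        use_boundary_zero: bool = False,
        three_point: bool = False,
    ) -> "WallShearStressResults":
        """Run the pipeline on every frame and aggregate.

        ``angle`` is "auto" (principal-axis estimate per frame) or a fixed
        angle in degrees; ``roi`` an optional (col0, row0, col1, row1)
        rectangle applied after rotation.
        """
        maps: list[WSSMap] = []
        reports = []
        boundaries = []
        fields = []
        masks = []
        for frame in self.frames:
            mask = classify_pixels(frame, self.chroma_tol, self.lum_min)
            field, report = decode_velocity(
                frame, self.cmap, mask, max_rgb_dist=self.max_rgb_dist
            )
            theta = estimate_flow_axis(mask) if angle == "auto" else float(angle)
            field, mask = rotate_to_horizontal(field, mask, theta)
            if roi is not None:
                mask = select_roi(mask, roi)
            boundary = detect_wall_boundary(mask, field, self.min_lumen_px)
            rates = near_wall_gradient(
                field, boundary, use_boundary_zero=use_boundary_zero, three_point=three_point
            )
            maps.append(wall_shear_stress(rates, self.fluid))
            reports.append(report)
            boundaries.append(boundary)
            fields.append(field)
            masks.append(mask)
        summary = wss_summary(maps[0], maps if len(maps) > 1 else None)
        return WallShearStressResults(
            model=self,
            wss_maps=maps,
            summary_=summary,
            decode_reports=reports,
            boundaries=boundaries,
            fields=fields,
            masks=masks,
        )


class WallShearStressResults:
    """Fitted wall-shear-stress estimates and diagnostics."""

    def __init__(self, model, wss_maps, summary_, decode_reports, boundaries, fields, masks):
        self.model = model
        self.wss_maps = wss_maps
        self.summary_ = summary_
        self.decode_reports = decode_reports
        self.boundaries = boundaries
        self.fields = fields
        self.masks = masks

    # -- headline estimates ----------------------------------------------
    @property
    def wss_map(self) -> WSSMap:
        return self.wss_maps[0]

    @property
    def mean_tau(self) -> float:
        """Spatial (and, over frames, temporal) mean wall shear stress, dyne/cm2."""
        return self.summary_.mean_tau

    @property
    def max_tau(self) -> float:
        return self.summary_.max_tau

    @property
    def tau_se(self) -> float:
        """Standard error of the spatial mean across retained columns/walls."""
        vals = np.concatenate(
            [np.r_[m.tau_upper, m.tau_lower] for m in self.wss_maps]
        )
        return float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan

    # -- exports ----------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        parts = []
        for i, m in enumerate(self.wss_maps):
            df = m.to_dataframe()
            df.insert(0, "frame", i)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    def surface(self, path: str | Path | None = None, collapse: str = "max") -> pd.DataFrame:
        """Column x frame WSS grid (the 3-D spatial distribution surface)."""
        return wss_surface_export(self.wss_maps, path=path, collapse=collapse)

    def plot_surface(self, path: str | Path | None = None, collapse: str = "max"):
        """3-D surface plot of the WSS spatial distribution; the highest peak
        is the maximum wall shear stress."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = self.surface(collapse=collapse)
        X, Y = np.meshgrid(np.arange(grid.shape[1]), grid.index.to_numpy())
        fig = plt.figure()
        ax = fig.add_subplot(111, projection="3d")
        ax.plot_surface(X, Y, grid.to_numpy(), cmap="viridis")
        ax.set_xlabel("frame")
        ax.set_ylabel("column")
        ax.set_zlabel("WSS (dyne/cm$^2$)")
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return ax

    def summary(self) -> str:
        """Printable summary of the fit."""
        s = self.summary_
        rep = self.decode_reports[0]
        lines = [
            "Wall Shear Stress Estimation",
            "=" * 46,
            f"{'Frames analyzed':<30}{len(self.wss_maps):>16}",
            f"{'Retained columns':<30}{s.n_columns:>16}",
            f"{'Viscosity mu (poise)':<30}{self.model.fluid.mu:>16.4f}",
            "-" * 46,
            f"{'Mean WSS (dyne/cm2)':<30}{s.mean_tau:>16.4f}",
            f"{'SE of mean':<30}{self.tau_se:>16.4f}",
            f"{'Max WSS (dyne/cm2)':<30}{s.max_tau:>16.4f}",
            f"{'Mean WSS, upper wall':<30}{s.mean_tau_upper:>16.4f}",
            f"{'Mean WSS, lower wall':<30}{s.mean_tau_lower:>16.4f}",
            "-" * 46,
            f"{'Flow pixels decoded':<30}{rep.n_flow - rep.n_unmatched:>16}",
            f"{'Unmatched flow pixels':<30}{rep.n_unmatched:>16}",
            f"{'Aliasing suspected':<30}{str(rep.aliasing_suspected):>16}",
            "=" * 46,
        ]
        if s.per_frame_mean is not None:
            means = ", ".join(f"{m:.4f}" for m in s.per_frame_mean)
            lines.insert(-1, f"Per-frame mean WSS: {means}")
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        return self.summary_.to_dict()
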