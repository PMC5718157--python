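"""Synthetic Doppler phantoms and cohort tables with known ground truth.

Two generators make every stage of the package testable without any
acquisition hardware:

* :func:`generate_poiseuille_frame` renders a steady laminar (parabolic)
  flow profile u(r) = u_M (1 - r^2/R^2) into a horizontal color-flow frame
  through a given LUT, with grayscale wall bands and dark background.  The
  analytic wall shear stress 2 mu u_M / R and the true wall rows are
  returned, so the decode -> segment -> shear pipeline can be checked
  against a closed form.  An optional plaque narrows the lumen over a
  column range; lesion columns carry a locally reduced centerline velocity
  (scaled by (R_local/R)^2) so that, as observed in diseased vessels, the
  plaque region is a low-WSS region.  This mimics the disturbed,
  separation-prone flow of a lesion rather than conserving volumetric rate
  (a mass-conserving stenosis would instead raise local WSS).

* :func:`generate_cohort` draws per-animal weekly observations (WSS, IMT,
  total cholesterol, LDL) from the per-week, per-group normal distributions
  of a rabbit high-fat-diet atherosclerosis study, with a sacrifice
  schedule shrinking the groups every two weeks and histology stage labels
  following the lesion timeline (fatty streaks from week 6, fibrous
  plaques from week 8, dense fibrous plaques at week 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colormap import ColorMapSpec
from .doppler_io import DopplerFrame
from .exceptions import ResolutionError

__all__ = [
    "PlaqueSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_poiseuille_frame",
    "CohortSpec",
    "generate_cohort",
    "sample_measurements",
    "COHORT_TABLES",
    "STAGE_TIMELINE",
    "STAGES",
]

_WALL_GRAY_VALUE = 150  # 8-bit gray used for the wall bands


@dataclass(frozen=True)
class PlaqueSpec:
    """Lumen narrowing over a column range: ``narrowing`` is the fraction of
    the radius lost at the plaque apex (0 < narrowing < 1)."""

    col_start: int
    col_stop: int
    narrowing: float

    def __post_init__(self) -> None:
        if not 0.0 < self.narrowing < 1.0:
            raise ValueError(f"narrowing fraction must be in (0, 1), got {self.narrowing}")
        if self.col_stop <= self.col_start:
            raise ValueError("plaque column range is empty")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the laminar-flow phantom.

    Defaults model a rabbit common carotid on a high-frequency linear probe:
    centerline velocity 20 cm/s, lumen radius 0.3 cm, 30 um pixels
    (R/100), Doppler speed range 25 cm/s, noise-free.
    """

    u_M: float = 20.0  # centerline velocity, cm/s
    R: float = 0.3  # lumen radius, cm
    wall_thickness_px: int = 3
    spacing: float = 0.003  # cm per pixel, isotropic
    v_nyquist: float = 25.0  # cm/s
    noise_sd: float = 0.0  # additive velocity noise, cm/s
    n_columns: int = 128
    margin_px: int = 4
    plaque: PlaqueSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u_M > self.v_nyquist:
            raise ValueError(
                f"u_M={self.u_M} exceeds v_nyquist={self.v_nyquist}: the phantom is "
                "alias-free by construction (speed range set to cover the flow)"
            )
        for name in ("u_M", "R", "spacing", "v_nyquist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.wall_thickness_px < 1 or self.margin_px < 0 or self.n_columns < 1:
            raise ValueError("invalid phantom layout")


@dataclass(eq=False)
class PhantomTruth:
    """Ground truth accompanying a generated phantom frame."""

    u_M: float
    R: float
    upper_wall_row: np.ndarray  # per column: last gray row above the lumen
    lower_wall_row: np.ndarray  # per column: first gray row below the lumen
    columns: np.ndarray
    R_local: np.ndarray  # per-column lumen radius, cm
    u_M_local: np.ndarray  # per-column centerline velocity, cm/s
    plaque_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def analytic_tau(self, mu: float) -> float:
        """Uniform-vessel wall shear stress 2 mu u_M / R (dyne/cm2)."""
        return 2.0 * mu * self.u_M / self.R

    def analytic_tau_per_column(self, mu: float) -> np.ndarray:
        """Per-column wall shear stress 2 mu u_M_local / R_local (dyne/cm2)."""
        return 2.0 * mu * self.u_M_local / self.R_local


def generate_poiseuille_frame(
    spec: PhantomSpec, cmap: ColorMapSpec
) -> tuple[DopplerFrame, PhantomTruth]:
    """Render a horizontal laminar-flow phantom through a color LUT.

    The lumen spans 2R/spacing pixel rows; each flow pixel's velocity is the
    parabolic profile evaluated at the pixel-center radius (plus seeded
    Gaussian noise when noise_sd > 0), encoded to the nearest LUT color.
    Gray wall bands of ``wall_thickness_px`` rows flank the lumen; the rest
    is black background.
    """
    d = spec.spacing
    lumen_px = int(round(2 * spec.R / d))
    if lumen_px < 4:
        raise ResolutionError(
            f"lumen of {lumen_px} pixels (< 4) cannot support the two-layer stencil; "
            "decrease the pixel spacing"
        )
    w = spec.n_columns
    margin = spec.margin_px
    wall = spec.wall_thickness_px
    h = lumen_px + 2 * wall + 2 * margin
    top_lumen = margin + wall  # first flow row
    bottom_lumen = top_lumen + lumen_px  # one past last flow row

    cols = np.arange(w)
    r_frac = np.ones(w)
    if spec.plaque is not None:
        p = spec.plaque
        if not (0 <= p.col_start < p.col_stop <= w):
            raise ValueError("plaque column range outside the frame")
        pc = np.arange(p.col_start, p.col_stop)
        # smooth cosine bump peaking at the plaque center
        window = 0.5 * (1 - np.cos(2 * np.pi * (pc - p.col_start + 0.5) / (p.col_stop - p.col_start)))
        r_frac[pc] = 1.0 - p.narrowing * window
    R_local = spec.R * r_frac
    u_M_local = spec.u_M * r_frac**2

    rng = np.random.default_rng(spec.seed)
    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    upper_rows = np.empty(w, dtype=int)
    lower_rows = np.empty(w, dtype=int)

    # radius at each lumen-row pixel center, measured from the vessel axis
    row_idx = np.arange(lumen_px)
    r_center = (row_idx + 0.5) * d - spec.R

    for c in cols:
        Rl = R_local[c]
        inside = np.abs(r_center) < Rl
        n_inside = int(inside.sum())
        if n_inside < 4:
            raise ResolutionError(
                f"narrowed lumen at column {c} is {n_inside} pixels (< 4)"
            )
        u = u_M_local[c] * (1.0 - (r_center[inside] / Rl) ** 2)
        if spec.noise_sd > 0:
            u = u + rng.normal(0.0, spec.noise_sd, size=u.shape)
        v_norm = np.clip(u / spec.v_nyquist, -1.0, 1.0)
        rows = top_lumen + row_idx[inside]
        pixels[rows, c] = cmap.encode(v_norm)
        # gray: wall bands plus any plaque tissue filling the narrowed part
        gray_rows = np.concatenate(
            [
                np.arange(margin, top_lumen),
                top_lumen + row_idx[~inside],
                np.arange(bottom_lumen, bottom_lumen + wall),
            ]
        )
        pixels[gray_rows, c] = _WALL_GRAY_VALUE
        upper_rows[c] = rows[0] - 1
        lower_rows[c] = rows[-1] + 1

    frame = DopplerFrame(
        pixels=pixels,
        spacing_axial=d,
        spacing_lateral=d,
        v_nyquist=spec.v_nyquist,
    )
    plaque_cols = (
        np.arange(spec.plaque.col_start, spec.plaque.col_stop)
        if spec.plaque is not None
        else np.array([], dtype=int)
    )
    truth = PhantomTruth(
        u_M=spec.u_M,
        R=spec.R,
        upper_wall_row=upper_rows,
        lower_wall_row=lower_rows,
        columns=cols,
        R_local=R_local,
        u_M_local=u_M_local,
        plaque_columns=plaque_cols,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

STAGES = ("normal", "fatty_streak", "fibrous_plaque", "dense_fibrous_plaque")

#: experimental-group histology stage by week; weeks 7 and 9 inherit the
#: preceding biweekly histology finding.  Controls are always "normal".
STAGE_TIMELINE: dict[int, str] = {
    1: "normal",
    2: "normal",
    3: "normal",
    4: "normal",
    5: "normal",
    6: "fatty_streak",
    7: "fatty_streak",
    8: "fibrous_plaque",
    9: "fibrous_plaque",
    10: "dense_fibrous_plaque",
}

#: per-variable, per-group (mean, sd) for weeks 1..10.
#: wss in dyne/cm2, imt in mm, tc and ldl in mmol/L.
COHORT_TABLES: dict[str, dict[str, list[tuple[float, float]]]] = {
    "tc": {
        "experimental": [
            (14.45, 1.99), (27.52, 3.96), (37.40, 7.30), (44.92, 11.47), (48.38, 12.21),
            (48.52, 9.96), (47.19, 9.35), (50.46, 10.78), (46.04, 9.89), (52.77, 11.25),
        ],
        "control": [
            (1.17, 0.40), (1.29, 0.42), (1.35, 0.45), (1.29, 0.43), (1.37, 0.38),
            (1.37, 0.43), (1.19, 0.37), (1.32, 0.41), (1.25, 0.40), (1.40, 0.43),
        ],
    },
    "ldl": {
        "experimental": [
            (13.02, 1.89), (25.31, 3.71), (34.06, 6.18), (39.63, 9.99), (43.85, 9.98),
            (44.96, 9.15), (43.76, 8.77), (47.94, 9.35), (43.69, 7.07), (50.69, 7.47),
        ],
        "control": [
            (0.41, 0.67), (0.43, 0.57), (0.42, 0.60), (0.45, 0.63), (0.42, 0.60),
            (0.45, 0.58), (0.46, 0.63), (0.50, 0.53), (0.49, 0.58), (0.65, 0.64),
        ],
    },
    "imt": {
        "experimental": [
            (0.179, 0.003), (0.179, 0.003), (0.181, 0.006), (0.184, 0.006), (0.203, 0.011),
            (0.254, 0.018), (0.337, 0.053), (0.405, 0.069), (0.448, 0.052), (0.491, 0.043),
        ],
        "control": [
            (0.178, 0.004), (0.178, 0.004), (0.179, 0.007), (0.180, 0.006), (0.179, 0.003),
            (0.188, 0.004), (0.200, 0.005), (0.202, 0.005), (0.208, 0.006), (0.214, 0.007),
        ],
    },
    "wss": {
        "experimental": [
            (1.90, 0.31), (1.64, 0.16), (1.54, 0.16), (1.42, 0.16), (1.34, 0.16),
            (1.30, 0.12), (1.21, 0.11), (1.17, 0.11), (1.13, 0.12), (0.97, 0.08),
        ],
        "control": [
            (2.54, 0.09), (2.74, 0.05), (2.61, 0.07), (2.39, 0.08), (2.89, 0.13),
            (2.49, 0.03), (2.49, 0.16), (2.47, 0.05), (2.51, 0.08), (2.64, 0.10),
        ],
    },
}

_VARIABLES = ("wss", "imt", "tc", "ldl")


@dataclass(frozen=True)
class CohortSpec:
    """Design of the synthetic rabbit cohort.

    60 animals: 40 experimental (high-fat diet) and 20 controls; after each
    even week 8 experimental and 4 control animals are sacrificed for
    histology, so group sizes shrink 40/20 -> 32/16 -> 24/12 -> 16/8 -> 8/4.
    Measurements are drawn independently per variable from the per-week
    group normals (truncated at 0 by resampling).
    """

    n_experimental: int = 40
    n_control: int = 20
    sacrifice_experimental: int = 8
    sacrifice_control: int = 4
    weeks: tuple[int, ...] = tuple(range(1, 11))
    tables: dict = field(default_factory=lambda: COHORT_TABLES)
    stage_timeline: dict = field(default_factory=lambda: STAGE_TIMELINE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experimental < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        for var, groups in self.tables.items():
            for grp, rows in groups.items():
                for wk_idx, (mean, sd) in enumerate(rows):
                    if sd < 0:
                        raise ValueError(
                            f"negative SD for {var}/{grp} week {wk_idx + 1}"
                        )
        sev = {s: i for i, s in enumerate(STAGES)}
        ordered = [self.stage_timeline[w] for w in sorted(self.stage_timeline)]
        if any(sev[a] > sev[b] for a, b in zip(ordered, ordered[1:])):
            raise ValueError("stage timeline must be monotone in lesion severity")

    def group_size(self, group: str, week: int) -> int:
        """Surviving animals of ``group`` measured in ``week``."""
        n0 = self.n_experimental if group == "experimental" else self.n_control
        per = self.sacrifice_experimental if group == "experimental" else self.sacrifice_control
        n_sacrificed = per * ((week - 1) // 2)
        return max(n0 - n_sacrificed, 0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) by resampling (not clipping)."""
    if sd == 0.0:
        if mean < 0:
            raise ValueError("degenerate draw with negative mean cannot be truncated")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sample_measurements(
    variable: str,
    group: str,
    week: int,
    n: int,
    rng: np.random.Generator,
    tables: dict | None = None,
) -> np.ndarray:
    """Draw ``n`` values of ``variable`` for ``group`` at ``week`` from the
    study's per-week normal (truncated at 0)."""
    tables = COHORT_TABLES if tables is None else tables
    mean, sd = tables[variable][group][week - 1]
    return _truncated_normal(rng, mean, sd, n)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate the per-animal weekly observation table.

    Returns a DataFrame with columns: animal_id, group, week, wss_dyne_cm2,
    imt_mm, tc_mmol_l, ldl_mmol_l, stage.  Deterministic under a fixed
    ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group, prefix in (("experimental", "E"), ("control", "C")):
        for week in spec.weeks:
            n = spec.group_size(group, week)
            if n == 0:
                continue
            draws = {
                var: sample_measurements(var, group, week, n, rng, spec.tables)
                for var in _VARIABLES
            }
            stage = spec.stage_timeline[week] if group == "experimental" else "normal"
            for i in range(n):
                rows.append(
                    {
                        "animal_id": f"{prefix}{i + 1:02d}",
                        "group": group,
                        "week": week,
                        "wss_dyne_cm2": draws["wss"][i],
                        "imt_mm": draws["imt"][i],
                        "tc_mmol_l": draws["tc"][i],
                        "ldl_mmol_l": draws["ldl"][i],
                        "stage": stage,
                    }
                )
    return pd.DataFrame(rows)


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
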