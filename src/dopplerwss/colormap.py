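"""Color-flow lookup tables and their inversion.

Color Doppler imaging encodes signed axial blood velocity as a color overlay:
by convention flow toward the transducer is drawn in reds and flow away in
blues, with brightness increasing with speed.  A :class:`ColorMapSpec` is an
ordered lookup table (LUT) from normalized velocity in [-1, 1] (units of the
Nyquist velocity) to an RGB triple.  Encoding picks the entry nearest in
velocity; decoding picks the entry nearest in RGB space, so that
decode(encode(v)) is the identity on every LUT entry.

Every entry must be chromatic (max channel minus min channel above the wall
classification tolerance) so that flow colors can never collide with the
grayscale pixels that render the vessel wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ColorMapError

__all__ = ["ColorMapSpec", "load_colormap", "builtin_colormap_names"]

#: default chroma tolerance (8-bit counts) separating colored flow from gray wall
DEFAULT_CHROMA_TOL = 20


@dataclass(eq=False)
class ColorMapSpec:
    """Ordered lookup table from normalized velocity to RGB.

    Parameters
    ----------
    name : str
        Identifier of the map.
    velocities : ndarray of float
        Strictly increasing normalized velocities in [-1, 1].
    colors : ndarray of uint8, shape (n, 3)
        RGB triple for each velocity; all distinct, all chromatic.
    """

    name: str
    velocities: np.ndarray
    colors: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self, chroma_tol: int = DEFAULT_CHROMA_TOL) -> None:
        v, c = self.velocities, self.colors
        if v.ndim != 1 or c.shape != (v.size, 3):
            raise ColorMapError("colormap entries must be (n,) velocities and (n, 3) colors")
        if v.size < 2:
            raise ColorMapError("colormap needs at least two entries")
        if not np.all(np.diff(v) > 0):
            raise ColorMapError("normalized velocities must be strictly increasing")
        if v.min() < -1 or v.max() > 1:
            raise ColorMapError("normalized velocities must lie in [-1, 1]")
        chroma = c.astype(int).max(axis=1) - c.astype(int).min(axis=1)
        if np.any(chroma <= chroma_tol):
            bad = int(np.argmax(chroma <= chroma_tol))
            raise ColorMapError(
                f"achromatic colormap entry {tuple(int(x) for x in c[bad])}: "
                f"chroma {int(chroma[bad])} <= tolerance {chroma_tol}"
            )
        packed = self._pack(c)
        if np.unique(packed).size != packed.size:
            raise ColorMapError("duplicate RGB triples in colormap")

    @staticmethod
    def _pack(colors: np.ndarray) -> np.ndarray:
        c = colors.astype(np.uint32)
        return (c[:, 0] << 16) | (c[:, 1] << 8) | c[:, 2]

    # -- properties -------------------------------------------------------
    @property
    def n_entries(self) -> int:
        return int(self.velocities.size)

    @property
    def quantization_step(self) -> float:
        """Largest velocity gap between adjacent LUT entries (normalized units),
        ignoring the sign-change gap around zero."""
        dv = np.diff(self.velocities)
        if np.any(self.velocities > 0) and np.any(self.velocities < 0):
            gap = int(np.searchsorted(self.velocities, 0.0))
            dv = np.delete(dv, gap - 1) if 0 < gap < self.velocities.size else dv
        return float(dv.max())

    # -- encode / decode --------------------------------------------------
    def encode(self, v_norm: np.ndarray) -> np.ndarray:
        """Map normalized velocities to the RGB of the nearest LUT entry."""
        v_norm = np.asarray(v_norm, dtype=float)
        idx = self._nearest_velocity_index(v_norm)
        return self.colors[idx]

    def _nearest_velocity_index(self, v_norm: np.ndarray) -> np.ndarray:
        v = self.velocities
        pos = np.searchsorted(v, v_norm)
        lo = np.clip(pos - 1, 0, v.size - 1)
        hi = np.clip(pos, 0, v.size - 1)
        pick_hi = np.abs(v[hi] - v_norm) < np.abs(v_norm - v[lo])
        return np.where(pick_hi, hi, lo)

    def decode(self, rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Invert the LUT by nearest neighbor in RGB space.

        Parameters
        ----------
        rgb : ndarray, shape (..., 3)

        Returns
        -------
        v_norm : ndarray
            Normalized velocity of the nearest LUT entry.
        dist : ndarray
            Euclidean RGB distance to that entry (0 for exact LUT colors).
        """
        if self._tree is None:
            self._tree = cKDTree(self.colors.astype(float))
        flat = np.asarray(rgb, dtype=float).reshape(-1, 3)
        dist, idx = self._tree.query(flat, k=1)
        shape = np.asarray(rgb).shape[:-1]
        return self.velocities[idx].reshape(shape), dist.reshape(shape)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        entries = [
            [float(v), [int(r), int(g), int(b)]]
            for v, (r, g, b) in zip(self.velocities, self.colors)
        ]
        Path(path).write_text(json.dumps({"name": self.name, "entries": entries}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorMapSpec":
        obj = json.loads(Path(path).read_text())
        try:
            entries = obj["entries"]
            v = [e[0] for e in entries]
            c = [e[1] for e in entries]
            name = obj.get("name", Path(path).stem)
        except (KeyError, TypeError, IndexError) as exc:
            raise ColorMapError(f"malformed colormap JSON {path}: {exc}") from exc
        return cls(name=name, velocities=np.asarray(v), colors=np.asarray(c))


def _red_blue_ramp(levels: int, name: str) -> ColorMapSpec:
    """Classic red/blue brightness ramp: ``levels`` entries per sign.

    Positive velocity k/levels maps to (127 + 128*k/levels, 0, 0) rounded,
    darkest red for slow forward flow up to pure bright red (255, 0, 0) at the
    Nyquist limit; negative velocities mirror in blue down to (0, 0, 255).
    Requires levels <= 128 for distinct 8-bit ramps.
    """
    if not 2 <= levels <= 128:
        raise ColorMapError("red-blue brightness ramp supports 2..128 levels per side")
    k = np.arange(1, levels + 1)
    v_pos = k / levels
    r = np.round(127 + 128 * k / levels).astype(np.uint8)
    colors_pos = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=1)
    colors_neg = colors_pos[::-1][:, ::-1]  # mirror red ramp into blue channel
    velocities = np.concatenate([-v_pos[::-1], v_pos])
    colors = np.concatenate([colors_neg, colors_pos], axis=0)
    return ColorMapSpec(name=name, velocities=velocities, colors=colors)


def _red_blue_fine(levels: int, name: str) -> ColorMapSpec:
    """High-resolution variant: ``levels`` entries per sign (up to 16384).

    The dominant channel (red for forward, blue for reverse) carries the
    coarse brightness ramp; the green channel carries 128 fine sub-levels, so
    the LUT velocity step can be made far smaller than one 8-bit brightness
    count.  Intended as a test instrument where color quantization must be
    negligible next to the spatial discretization under study.
    """
    if not 2 <= levels <= 16384:
        raise ColorMapError("fine ramp supports 2..16384 levels per side")
    k = np.arange(levels)
    coarse = (128 + (k * 128) // levels).astype(np.uint8)
    fine = (k % 128).astype(np.uint8)
    zeros = np.zeros_like(coarse)
    colors_pos = np.stack([coarse, fine, zeros], axis=1)
    colors_neg = np.stack([zeros, fine, coarse], axis=1)[::-1]
    v_pos = (k + 1) / levels
    velocities = np.concatenate([-v_pos[::-1], v_pos])
    colors = np.concatenate([colors_neg, colors_pos], axis=0)
    return ColorMapSpec(name=name, velocities=velocities, colors=colors)


_BUILTINS = {
    "red-blue-brightness": lambda: _red_blue_ramp(128, "red-blue-brightness"),
    "red-blue-fine": lambda: _red_blue_fine(16384, "red-blue-fine"),
}


def builtin_colormap_names() -> list[str]:
    return sorted(_BUILTINS)


def load_colormap(spec_path_or_name: str | Path) -> ColorMapSpec:
    """Load a built-in colormap by name or a JSON specification from disk."""
    key = str(spec_path_or_name)
    if key in _BUILTINS:
        return _BUILTINS[key]()
    path = Path(spec_path_or_name)
    if not path.exists():
        raise ColorMapError(
            f"unknown colormap {key!r}: not a built-in "
            f"({', '.join(builtin_colormap_names())}) and no such file"
        )
    return ColorMapSpec.from_json(path)
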