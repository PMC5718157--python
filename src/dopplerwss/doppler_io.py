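"""Frame I/O and physical-unit calibration.

A color Doppler frame is an 8-bit RGB image plus the physical calibration
needed to turn pixels into hemodynamics: the axial/lateral pixel spacing
(cm per pixel) and the Nyquist velocity (cm/s), i.e. the scanner's Doppler
speed-range setting, which sets the scale of the color LUT.

All quantities inside the package are CGS (cm, cm/s, poise, dyne/cm2);
conversions (DICOM pixel spacing is stored in mm) happen here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colormap import ColorMapSpec, builtin_colormap_names, load_colormap  # noqa: F401
from .exceptions import CalibrationError, FormatError

__all__ = [
    "DopplerFrame",
    "FrameCalibration",
    "FluidParams",
    "read_frame",
    "write_frame",
    "load_colormap",
    "ColorMapSpec",
]

_PRIVATE_CREATOR = "DOPPLERWSS"


@dataclass(frozen=True)
class FrameCalibration:
    """Physical calibration for a frame; any field may be None to mean
    'take it from file metadata'."""

    spacing_axial_cm: float | None = None
    spacing_lateral_cm: float | None = None
    v_nyquist_cm_s: float | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameCalibration":
        import json

        obj = json.loads(Path(path).read_text())
        return cls(
            spacing_axial_cm=obj.get("spacing_axial_cm"),
            spacing_lateral_cm=obj.get("spacing_lateral_cm"),
            v_nyquist_cm_s=obj.get("v_nyquist_cm_s"),
        )


@dataclass(eq=False)
class DopplerFrame:
    """One RGB color Doppler frame with physical calibration.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
    spacing_axial : float
        cm per pixel row (depth direction).
    spacing_lateral : float
        cm per pixel column.
    v_nyquist : float
        Maximum encodable axial speed, cm/s (the Doppler speed range).
    frame_index : int
        Index of this frame within a multi-frame acquisition.
    """

    pixels: np.ndarray
    spacing_axial: float
    spacing_lateral: float
    v_nyquist: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"frame pixels must be HxWx3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        for name in ("spacing_axial", "spacing_lateral", "v_nyquist"):
            val = getattr(self, name)
            if val is None or not np.isfinite(val) or val <= 0:
                raise CalibrationError(f"{name} must be a positive finite number, got {val!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid parameters; mu is dynamic viscosity in poise.

    Whole blood is conventionally taken as 3 cP = 0.03 poise.
    """

    mu: float = 0.03

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise CalibrationError(f"viscosity mu must be positive, got {self.mu!r}")


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_frame(
    path: str | Path,
    calib: FrameCalibration | None = None,
    frame_index: int = 0,
) -> DopplerFrame:
    """Read a Doppler frame from a DICOM secondary-capture or an 8-bit PNG.

    For DICOM, pixel spacing is taken from the PixelSpacing attribute
    (mm, converted to cm) unless overridden; the Nyquist velocity comes from
    ``calib`` or, when present, from the frame's private calibration tag.
    For PNG, all three calibration fields must come from ``calib``.
    Multi-frame DICOM files yield the frame at ``frame_index``.
    """
    path = Path(path)
    if _is_dicom(path):
        return _read_dicom(path, calib, frame_index)
    return _read_png(path, calib)


def _read_png(path: Path, calib: FrameCalibration | None) -> DopplerFrame:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        raise FormatError(f"{path} is grayscale; an RGB color-flow frame is required")
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if calib is None or None in (
        calib.spacing_axial_cm,
        calib.spacing_lateral_cm,
        calib.v_nyquist_cm_s,
    ):
        raise CalibrationError(
            f"PNG {path} carries no calibration; spacing_axial_cm, "
            "spacing_lateral_cm and v_nyquist_cm_s must all be supplied"
        )
    return DopplerFrame(
        pixels=arr.astype(np.uint8),
        spacing_axial=float(calib.spacing_axial_cm),
        spacing_lateral=float(calib.spacing_lateral_cm),
        v_nyquist=float(calib.v_nyquist_cm_s),
    )


def _read_dicom(path: Path, calib: FrameCalibration | None, frame_index: int) -> DopplerFrame:
    import pydicom

    ds = pydicom.dcmread(path)
    photometric = getattr(ds, "PhotometricInterpretation", "")
    if photometric != "RGB":
        raise FormatError(
            f"{path}: photometric interpretation {photometric!r} is not RGB; "
            "color-flow secondary captures are required"
        )
    arr = ds.pixel_array
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1 or arr.ndim == 4:
        if not 0 <= frame_index < arr.shape[0]:
            raise FormatError(f"frame_index {frame_index} out of range for {arr.shape[0]} frames")
        arr = arr[frame_index]
    elif frame_index != 0:
        raise FormatError(f"frame_index {frame_index} requested from a single-frame file")

    spacing_ax = calib.spacing_axial_cm if calib else None
    spacing_lat = calib.spacing_lateral_cm if calib else None
    if spacing_ax is None or spacing_lat is None:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is None:
            raise CalibrationError(f"{path} has no PixelSpacing and no spacing override")
        # DICOM PixelSpacing is [row spacing, column spacing] in mm
        if spacing_ax is None:
            spacing_ax = float(ps[0]) / 10.0
        if spacing_lat is None:
            spacing_lat = float(ps[1]) / 10.0

    v_nyq = calib.v_nyquist_cm_s if calib else None
    if v_nyq is None:
        try:
            block = ds.private_block(0x0011, _PRIVATE_CREATOR)
            v_nyq = float(block[0x01].value)
        except KeyError:
            v_nyq = None
    if v_nyq is None:
        raise CalibrationError(
            f"{path}: Nyquist velocity absent from metadata and no override given"
        )

    return DopplerFrame(
        pixels=np.asarray(arr, dtype=np.uint8),
        spacing_axial=float(spacing_ax),
        spacing_lateral=float(spacing_lat),
        v_nyquist=float(v_nyq),
        frame_index=frame_index,
    )


def write_frame(frame: DopplerFrame, path: str | Path) -> Path:
    """Write a frame to PNG (pixels only) or DICOM secondary capture
    (pixels + spacing + Nyquist velocity in a private tag)."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        _write_dicom(frame, path)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, frame.pixels)
    return path


def _write_dicom(frame: DopplerFrame, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = frame.pixels.shape[:2]
    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{frame.spacing_axial * 10:.6f}", f"{frame.spacing_lateral * 10:.6f}"]
    block = ds.private_block(0x0011, _PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "DS", f"{frame.v_nyquist:.6f}")
    ds.PixelData = np.ascontiguousarray(frame.pixels).tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
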