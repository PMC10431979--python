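"""Reading and writing the tool's on-disk formats.

Inputs are a DSC-MRI time series stored as a DICOM series directory and
binary masks stored as PNG or NPY rasters; outputs are 32-bit floating point
TIFF parametric maps, one file per slice.  The module also contains the
DICOM writer used by the digital phantom so that phantom fixtures exercise
the exact same reader as scanner data.

All times are seconds internally.  DICOM stores TE/TR in milliseconds; the
reader converts on ingest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from ._errors import (
    EmptyMaskError,
    GeometryError,
    MetadataError,
    OrderingError,
)

__all__ = [
    "DSCSeries",
    "MaskRaster",
    "MapStack",
    "MAP_UNITS",
    "read_dsc_dicom",
    "read_mask",
    "write_map_tiff",
    "write_dsc_dicom",
]

#: Physical units of each parametric map.
MAP_UNITS = {
    "CBF": "ml/100g/min",
    "CBV": "ml/100g",
    "MTT": "s",
    "SR": "%",
    "PSR": "%",
}


@dataclass
class DSCSeries:
    """A 4-D dynamic susceptibility contrast acquisition.

    Attributes
    ----------
    signal : ndarray, shape (n_slices, n_frames, rows, cols)
        Signal intensity in arbitrary units, >= 0.
    te_s, tr_s : float
        Echo time and repetition time in seconds.
    """

    signal: np.ndarray
    te_s: float
    tr_s: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise GeometryError(
                f"signal must be 4-D (slice, time, row, col); got {self.signal.ndim}-D"
            )
        if self.te_s <= 0 or self.tr_s <= 0:
            raise MetadataError(f"TE and TR must be positive seconds; got te_s={self.te_s}, tr_s={self.tr_s}")

    @property
    def n_slices(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.signal.shape[2:]

    @property
    def frame_times_s(self) -> np.ndarray:
        """Uniform acquisition grid t_i = i * TR."""
        return np.arange(self.n_frames, dtype=float) * self.tr_s


@dataclass
class MaskRaster:
    """Binary raster selecting brain tissue or the AIF/VOF reference vessel."""

    pixels: np.ndarray  # 2-D binary {0,1}; broadcast across slices by consumers
    role: str = "brain"  # one of {"brain", "aif", "vof"}

    def __post_init__(self) -> None:
        self.pixels = (np.asarray(self.pixels) != 0).astype(np.uint8)
        if self.pixels.ndim not in (2, 3):
            raise GeometryError(f"mask must be 2-D or per-slice 3-D; got {self.pixels.ndim}-D")
        if not self.pixels.any():
            raise EmptyMaskError(f"{self.role} mask has no nonzero pixel")

    def for_slice(self, slice_index: int) -> np.ndarray:
        """2-D boolean plane for a slice (a 2-D mask is shared by all slices)."""
        plane = self.pixels if self.pixels.ndim == 2 else self.pixels[slice_index]
        return plane.astype(bool)


@dataclass
class MapStack:
    """Per-slice stack of one parametric map with its physical unit."""

    name: str
    values: np.ndarray  # (n_slices, rows, cols), float
    units: str = field(default="")

    def __post_init__(self) -> None:
        if self.name not in MAP_UNITS:
            raise ValueError(f"unknown map name {self.name!r}; expected one of {sorted(MAP_UNITS)}")
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise GeometryError("map values must be (slice, row, col)")
        if not self.units:
            self.units = MAP_UNITS[self.name]


# --------------------------------------------------------------------------
# DICOM series
# --------------------------------------------------------------------------

def _read_float_attr(ds: pydicom.Dataset, keyword: str) -> float | None:
    value = getattr(ds, keyword, None)
    if value in (None, ""):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def read_dsc_dicom(
    directory: str | os.PathLike,
    override_te_s: float | None = None,
    override_tr_s: float | None = None,
) -> DSCSeries:
    """Read a DSC-MRI DICOM series directory into a :class:`DSCSeries`.

    Files are grouped into slices by ``SliceLocation`` and ordered in time by
    ``TemporalPositionIdentifier`` (falling back to ``InstanceNumber``).
    TE/TR are taken from the headers (ms, converted to seconds) unless
    overridden.

    Raises
    ------
    OrderingError
        If the temporal ordering is missing or ambiguous, or the series has
        fewer than two time points.
    GeometryError
        If in-plane dimensions differ across files or slices have unequal
        frame counts.
    MetadataError
        If TE or TR cannot be read and no override is supplied.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue  # non-DICOM clutter in the directory is ignored
    if not datasets:
        raise MetadataError(f"no readable DICOM files in {directory}")

    shape = (int(datasets[0].Rows), int(datasets[0].Columns))
    for ds in datasets:
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise GeometryError("inconsistent image dimensions across series files")

    by_slice: dict[float, list[pydicom.Dataset]] = {}
    for ds in datasets:
        loc = _read_float_attr(ds, "SliceLocation")
        if loc is None:
            loc = 0.0
        by_slice.setdefault(round(loc, 6), []).append(ds)

    def time_key(ds: pydicom.Dataset) -> int:
        for kw in ("TemporalPositionIdentifier", "InstanceNumber"):
            v = getattr(ds, kw, None)
            if v not in (None, ""):
                return int(v)
        raise OrderingError(
            "cannot order frames in time: neither TemporalPositionIdentifier "
            "nor InstanceNumber present"
        )

    slice_locs = sorted(by_slice)
    frames_per_slice = {len(by_slice[loc]) for loc in slice_locs}
    if len(frames_per_slice) != 1:
        raise GeometryError(f"slices have unequal frame counts: {sorted(frames_per_slice)}")
    n_frames = frames_per_slice.pop()
    if n_frames < 2:
        raise OrderingError(
            f"series has {n_frames} time point(s); a DSC series needs baseline + bolus frames"
        )

    planes = []
    for loc in slice_locs:
        group = sorted(by_slice[loc], key=time_key)
        keys = [time_key(ds) for ds in group]
        if len(set(keys)) != len(keys):
            raise OrderingError(f"ambiguous temporal ordering at slice location {loc}: duplicate indices")
        planes.append(np.stack([ds.pixel_array for ds in group]))
    signal = np.stack(planes)  # (slice, time, row, col)

    ref = datasets[0]
    te_s = override_te_s if override_te_s is not None else _read_ms(ref, "EchoTime")
    tr_s = override_tr_s if override_tr_s is not None else _read_ms(ref, "RepetitionTime")
    if te_s is None or tr_s is None:
        missing = [n for n, v in (("TE", te_s), ("TR", tr_s)) if v is None]
        raise MetadataError(f"cannot read {'/'.join(missing)} from headers and no override given")
    return DSCSeries(signal=signal, te_s=te_s, tr_s=tr_s)


def _read_ms(ds: pydicom.Dataset, keyword: str) -> float | None:
    ms = _read_float_attr(ds, keyword)
    return None if ms is None else ms / 1000.0


def write_dsc_dicom(
    signal: np.ndarray,
    te_s: float,
    tr_s: float,
    directory: str | os.PathLike,
) -> list[Path]:
    """Write a (slice, time, row, col) float array as a DICOM series.

    Used by the phantom fixture writer.  Pixel data is stored as 32-bit
    Float Pixel Data so the write -> :func:`read_dsc_dicom` round trip is
    bit-identical on the signal array.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signal = np.asarray(signal, dtype=np.float32)
    if signal.ndim != 4:
        raise GeometryError("signal must be 4-D (slice, time, row, col)")
    n_slices, n_frames, rows, cols = signal.shape
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths: list[Path] = []
    instance = 1
    for s in range(n_slices):
        for t in range(n_frames):
            ds = Dataset()
            fm = FileMetaDataset()
            fm.TransferSyntaxUID = ExplicitVRLittleEndian
            fm.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
            fm.MediaStorageSOPInstanceUID = generate_uid()
            ds.file_meta = fm
            ds.SOPClassUID = fm.MediaStorageSOPClassUID
            ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = study_uid
            ds.Modality = "MR"
            ds.Rows, ds.Columns = rows, cols
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 32
            ds.SliceLocation = f"{s * 1.5:.4f}"  # 1.5 mm slice spacing
            ds.InstanceNumber = instance
            ds.TemporalPositionIdentifier = t + 1
            ds.NumberOfTemporalPositions = n_frames
            ds.EchoTime = f"{te_s * 1000.0:g}"
            ds.RepetitionTime = f"{tr_s * 1000.0:g}"
            ds.FloatPixelData = np.ascontiguousarray(signal[s, t]).tobytes()
            path = directory / f"slice{s:02d}_frame{t:04d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
            instance += 1
    return paths


# --------------------------------------------------------------------------
# Masks
# --------------------------------------------------------------------------

def read_mask(
    path: str | os.PathLike,
    expected_shape: tuple[int, int] | None = None,
    role: str = "brain",
) -> MaskRaster:
    """Read a PNG or NPY mask; any nonzero source pixel maps to 1."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        raw = np.load(path)
    else:
        with Image.open(path) as img:
            raw = np.asarray(img)
    if raw.ndim == 3 and raw.shape[-1] in (2, 3, 4):  # RGB(A)/LA PNG: any channel on
        raw = raw.any(axis=-1)
    if expected_shape is not None and tuple(raw.shape[-2:]) != tuple(expected_shape):
        raise GeometryError(
            f"mask shape {raw.shape[-2:]} does not match expected {tuple(expected_shape)}"
        )
    return MaskRaster(pixels=raw, role=role)


def write_mask_png(pixels: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a binary mask as an 8-bit PNG (nonzero -> 255)."""
    path = Path(path)
    img = Image.fromarray(((np.asarray(pixels) != 0) * np.uint8(255)))
    img.save(path)
    return path


# --------------------------------------------------------------------------
# TIFF maps
# --------------------------------------------------------------------------

def write_map_tiff(map_stack: MapStack, directory: str | os.PathLike) -> list[Path]:
    """Write one uncompressed 32-bit float TIFF per slice.

    Files are named ``<name>_slice<k>.tiff``.  Non-finite voxels (outside
    the brain mask or flagged degenerate) are serialized as 0, matching the
    zero background of displayed maps; finite values round-trip exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(map_stack.values.shape[0]):
        plane = map_stack.values[k].astype(np.float32)
        plane = np.where(np.isfinite(plane), plane, np.float32(0.0))
        path = directory / f"{map_stack.name}_slice{k}.tiff"
        tifffile.imwrite(path, plane, compression=None)
        paths.append(path)
    return paths


def read_map_tiff(name: str, directory: str | os.PathLike) -> MapStack:
    """Read back a per-slice TIFF stack written by :func:`write_map_tiff`."""
    directory = Path(directory)
    paths = sorted(
        directory.glob(f"{name}_slice*.tiff"),
        key=lambda p: int(p.stem.rsplit("slice", 1)[1]),
    )
    if not paths:
        raise FileNotFoundError(f"no {name}_slice*.tiff in {directory}")
    return MapStack(name=name, values=np.stack([tifffile.imread(p) for p in paths]))
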