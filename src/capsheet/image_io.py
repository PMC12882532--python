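"""Typed containers and file I/O for micrographs, diffraction images and tables.

Images travel as MRC2014 (mode 2 float32 for intensities, mode 6 uint16 for
label masks) or TIFF. Calibration metadata — real-space pixel size in Å/px,
reciprocal-space Nyquist spatial frequency in Å⁻¹ — is stored in the MRC
header (cell dimensions, plus a ``KEY=VALUE`` header label for the Nyquist
frequency) or in a JSON TIFF image description. Tables are plain CSV.

Coordinate convention: arrays are indexed (row, col), origin at the top-left,
0-based; the geometric center of an N×N image is ((N−1)/2, (N−1)/2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._mrc import MrcError, read_mrc, write_mrc

__all__ = [
    "Micrograph", "DiffractionImage", "DiffractionCalibration", "LabelMask",
    "ContingencyTable", "read_image", "write_image", "read_table",
    "write_table", "AREA_TABLE_COLUMNS", "CONTINGENCY_COLUMNS",
    "DEFAULT_PIXEL_SIZE_A", "DEFAULT_NYQUIST_Q",
]

#: Pixel size (Å/px) of the acquisition protocol used for area measurements;
#: applied as a fallback when a file carries no calibration.
DEFAULT_PIXEL_SIZE_A = 3.21
#: Nyquist spatial frequency (Å⁻¹) at the detector edge for the 670 mm
#: camera-distance diffraction geometry; fallback for uncalibrated files.
DEFAULT_NYQUIST_Q = 1.75

AREA_TABLE_COLUMNS = ["aggregate_id", "condition", "region_pixel_count",
                      "threshold", "above_threshold_pixels", "area_nm2"]
CONTINGENCY_COLUMNS = ["extracellular_positive", "extracellular_negative",
                       "intracellular_positive", "intracellular_negative"]


@dataclass
class Micrograph:
    """2D real-space intensity image with its pixel size in Å/px."""

    values: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_A
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("micrograph must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class DiffractionCalibration:
    """Reciprocal-space calibration of a square diffraction image.

    The spatial frequency at the edge-center of the detector equals
    ``nyquist_q``; one pixel-radius therefore spans
    ``q_per_pixel = nyquist_q / (image_size / 2)`` Å⁻¹.
    """

    nyquist_q: float = DEFAULT_NYQUIST_Q
    image_size: int = 512

    def __post_init__(self):
        if not self.nyquist_q > 0:
            raise ValueError("nyquist_q must be positive")
        if self.image_size < 2:
            raise ValueError("image_size must be at least 2")

    @property
    def q_per_pixel(self) -> float:
        return self.nyquist_q / (self.image_size / 2.0)


@dataclass
class DiffractionImage:
    """2D reciprocal-space intensity image with q-calibration."""

    values: np.ndarray
    calibration: DiffractionCalibration
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("diffraction image must be a non-empty 2D array")
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("diffraction image must be square")
        if self.calibration.image_size != self.values.shape[0]:
            raise ValueError("calibration image_size inconsistent with array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = aggregate k."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ValueError("mask contains non-integer values")
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.labels = arr.astype(np.int64)

    @property
    def ids(self) -> np.ndarray:
        """Sorted distinct positive labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts of aggregate location × marker status.

    ``a``/``b`` are extracellular marker-positive/-negative aggregates,
    ``c``/``d`` intracellular marker-positive/-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name}={v} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def extracellular_positive_fraction(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def intracellular_positive_fraction(self) -> float:
        return self.c / (self.c + self.d)


# ---------------------------------------------------------------------------
# image files

_NYQUIST_LABEL = "NYQUIST_Q"


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def write_image(image, path, fmt: str | None = None) -> None:
    """Write a :class:`Micrograph`, :class:`DiffractionImage` or
    :class:`LabelMask` to MRC2014 or TIFF (chosen from ``fmt`` or the suffix).

    Intensity images are written as 32-bit float (lossless for float32 data);
    masks as unsigned 16-bit integers. Calibration goes into the MRC header or
    a JSON TIFF description.
    """
    path = Path(path)
    fmt = (fmt or ("tiff" if _is_tiff(path) else "mrc")).lower()
    if fmt not in {"mrc", "tiff", "tif"}:
        raise ValueError(f"unsupported image format {fmt!r}")

    desc: dict = {}
    if isinstance(image, LabelMask):
        if image.labels.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("mask labels exceed uint16 range")
        data = image.labels.astype(np.uint16)
        pixel_size = 1.0
        labels: tuple[str, ...] = ("capsheet label mask",)
        desc["kind"] = "mask"
    elif isinstance(image, Micrograph):
        data = image.values.astype(np.float32)
        pixel_size = image.pixel_size
        labels = ()
        desc = {"kind": "micrograph", "pixel_size_angstrom": image.pixel_size,
                **image.metadata}
    elif isinstance(image, DiffractionImage):
        data = image.values.astype(np.float32)
        pixel_size = 1.0
        labels = (f"{_NYQUIST_LABEL}={image.calibration.nyquist_q:.6f}",)
        desc = {"kind": "diffraction",
                "nyquist_q": image.calibration.nyquist_q, **image.metadata}
    else:
        raise TypeError(f"cannot write object of type {type(image).__name__}")

    if fmt == "mrc":
        write_mrc(path, data, pixel_size=pixel_size, labels=labels)
    else:
        tifffile.imwrite(path, data, description=json.dumps(desc))


def _read_raw(path: Path):
    """Return (data, pixel_size_or_None, nyquist_or_None) from MRC or TIFF."""
    if _is_tiff(path):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        return data, meta.get("pixel_size_angstrom"), meta.get("nyquist_q")
    data, pixel_size, labels = read_mrc(path)
    nyquist = None
    for lab in labels:
        if lab.startswith(_NYQUIST_LABEL + "="):
            try:
                nyquist = float(lab.split("=", 1)[1])
            except ValueError:
                pass
    return data, (pixel_size if pixel_size > 0 else None), nyquist


def read_image(path, kind: str, *,
               default_pixel_size: float = DEFAULT_PIXEL_SIZE_A,
               default_nyquist_q: float = DEFAULT_NYQUIST_Q):
    """Read an image file as the requested kind.

    ``kind`` is one of ``"micrograph"``, ``"diffraction"``, ``"mask"``.
    Missing calibration falls back to the supplied defaults with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data, pixel_size, nyquist = _read_raw(path)
    except MrcError:
        raise
    data = np.squeeze(data)
    if kind == "micrograph":
        if pixel_size is None:
            warnings.warn(f"{path.name}: no pixel size found; assuming "
                          f"{default_pixel_size} Å/px", stacklevel=2)
            pixel_size = default_pixel_size
        return Micrograph(values=data, pixel_size=float(pixel_size))
    if kind == "diffraction":
        if nyquist is None:
            warnings.warn(f"{path.name}: no Nyquist calibration found; "
                          f"assuming {default_nyquist_q} Å⁻¹", stacklevel=2)
            nyquist = default_nyquist_q
        cal = DiffractionCalibration(nyquist_q=float(nyquist),
                                     image_size=data.shape[0])
        return DiffractionImage(values=data, calibration=cal)
    if kind == "mask":
        if np.issubdtype(np.asarray(data).dtype, np.floating) and \
                not np.all(np.mod(data, 1) == 0):
            raise ValueError(f"{path.name}: mask contains non-integer values")
        return LabelMask(labels=np.asarray(data))
    raise ValueError(f"unknown image kind {kind!r}")


# ---------------------------------------------------------------------------
# tables

def write_table(table, path) -> None:
    """Write an area table (DataFrame) or :class:`ContingencyTable` as CSV."""
    path = Path(path)
    if isinstance(table, ContingencyTable):
        pd.DataFrame([dict(zip(CONTINGENCY_COLUMNS, table.counts))]).to_csv(
            path, index=False)
        return
    if isinstance(table, pd.DataFrame):
        missing = [c for c in AREA_TABLE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"area table missing required columns: {missing}")
        table.to_csv(path, index=False)
        return
    raise TypeError(f"cannot write table of type {type(table).__name__}")


def read_table(path, kind: str):
    """Read a CSV as ``kind`` = ``"areas"`` (DataFrame) or ``"contingency"``
    (:class:`ContingencyTable`). Missing required columns raise a
    :class:`ValueError` naming the column."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path.name}: empty CSV") from exc
    if kind == "areas":
        missing = [c for c in AREA_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required columns {missing}")
        return df
    if kind == "contingency":
        missing = [c for c in CONTINGENCY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required columns {missing}")
        row = df.iloc[0]
        return ContingencyTable(*(int(row[c]) for c in CONTINGENCY_COLUMNS))
    raise ValueError(f"unknown table kind {kind!r}")
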