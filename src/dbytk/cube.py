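"""Core data types and I/O for hyperspectral cubes and detection labels.

A scene on the tobacco sorting belt is captured as a reflectance cube
(height x width x bands) on a 400-900 nm grid at 5 nm resolution (101
bands).  Cubes are stored in an ENVI-dialect format: a plain-text ``.hdr``
file describing dimensions, interleave and the wavelength grid, next to a
raw little-endian float32 binary file.  Detection annotations use the
common normalized center-format text dialect, one box per line::

    <class_id> <cx> <cy> <w> <h>

with all coordinates in [0, 1].
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np

#: NTRM classes in the fixed label order used throughout the package.
CLASS_NAMES = ("weed", "rubber_ring", "feather")

#: Default wavelength grid: 400..900 nm in 5 nm steps -> 101 bands.
DEFAULT_WAVELENGTHS = np.arange(400.0, 900.0 + 1e-9, 5.0)

#: Reflectance above this is rejected at load (small glint tolerance above 1).
REFLECTANCE_MAX = 1.5

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclasses.dataclass
class SpectralCube:
    """An H x W x B reflectance cube with its wavelength grid (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_WAVELENGTHS.copy()
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count mismatch: data has {self.data.shape[2]} bands, "
                f"wavelength grid has {self.wavelengths.size}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite reflectance values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength: float, tol: float = 2.5) -> int:
        """Index of the band nearest ``wavelength``, within ``tol`` nm.

        The tolerance defaults to half the 5 nm grid step so snapping is
        unambiguous.
        """
        wl = self.wavelengths
        if wavelength < wl[0] - tol or wavelength > wl[-1] + tol:
            raise ValueError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}] nm"
            )
        idx = int(np.argmin(np.abs(wl - wavelength)))
        if abs(wl[idx] - wavelength) > tol:
            raise ValueError(
                f"no band within {tol} nm of {wavelength} nm (nearest: {wl[idx]} nm)"
            )
        return idx


def band_slice(
    cube: SpectralCube, wavelength: float, as_uint8: bool = False
) -> np.ndarray:
    """Single-band grayscale plane at the band nearest ``wavelength``.

    Returns the raw float32 reflectance plane; with ``as_uint8`` the plane is
    min-max scaled to [0, 255] for export (a constant plane maps to zeros).
    """
    plane = cube.data[:, :, cube.band_index(wavelength)]
    if as_uint8:
        return minmax_to_uint8(plane)
    return plane


def minmax_to_uint8(plane: np.ndarray) -> np.ndarray:
    """Min-max scale a float image to uint8; constant input maps to zeros."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    return np.round((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)


@dataclasses.dataclass
class BoundingBox:
    """Normalized center-format detection box (class, cx, cy, w, h)."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0,1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0,1]")
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")

    def to_xyxy(self) -> tuple[float, float, float, float]:
        """Corners (x1, y1, x2, y2) in normalized coordinates, clipped."""
        return (
            max(self.cx - self.w / 2, 0.0),
            max(self.cy - self.h / 2, 0.0),
            min(self.cx + self.w / 2, 1.0),
            min(self.cy + self.h / 2, 1.0),
        )

    def to_pixels(self, height: int, width: int) -> tuple[int, int, int, int]:
        x1, y1, x2, y2 = self.to_xyxy()
        return (
            int(round(x1 * width)),
            int(round(y1 * height)),
            int(round(x2 * width)),
            int(round(y2 * height)),
        )


@dataclasses.dataclass
class AnnotatedScene:
    """A belt scene: images, boxes and (optionally) the source cube.

    ``rgb`` is the true-color render, ``dcs`` the decorrelation-stretched
    enhanced image when present.  ``label_map`` is the per-pixel material
    index for synthetic scenes (-1 where undefined), used for ROI extraction
    and tests.  ``scene_id``/``source_id`` carry provenance through
    augmentation (``source_id`` names the original scene a variant came from).
    """

    rgb: np.ndarray
    boxes: list[BoundingBox] = dataclasses.field(default_factory=list)
    cube: SpectralCube | None = None
    dcs: np.ndarray | None = None
    split_tag: str | None = None
    scene_id: str = ""
    source_id: str = ""
    label_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.dcs is not None and self.dcs.shape[:2] != self.rgb.shape[:2]:
            raise ValueError("rgb and dcs must share H x W")
        if self.split_tag is not None and self.split_tag not in (
            "train",
            "val",
            "test",
        ):
            raise ValueError(f"unknown split tag {self.split_tag!r}")
        if not self.source_id:
            self.source_id = self.scene_id

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @property
    def width(self) -> int:
        return self.rgb.shape[1]


# ---------------------------------------------------------------------------
# ENVI-dialect cube I/O

def write_cube(cube: SpectralCube, path_header, path_data=None, interleave="bsq"):
    """Write ``cube`` as an ENVI-style header + raw float32 binary.

    ``path_data`` defaults to the header path with its suffix replaced by
    ``.raw``.  Any of the three standard interleaves may be requested.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    path_header = Path(path_header)
    path_data = Path(path_data) if path_data else path_header.with_suffix(".raw")
    h, w, b = cube.shape
    if interleave == "bsq":
        arr = np.transpose(cube.data, (2, 0, 1))  # (bands, lines, samples)
    elif interleave == "bil":
        arr = np.transpose(cube.data, (0, 2, 1))  # (lines, bands, samples)
    else:  # bip
        arr = cube.data  # (lines, samples, bands)
    arr.astype("<f4").tofile(path_data)
    wl = ", ".join(f"{x:g}" for x in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {dbytk reflectance cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    path_header.write_text(header)
    return path_header, path_data


def _parse_envi_header(text: str) -> dict:
    # Collapse brace-delimited blocks (possibly multi-line) onto one line.
    fields: dict[str, str] = {}
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path_header, path_data=None) -> SpectralCube:
    """Read an ENVI-style cube written by :func:`write_cube` (or compatible).

    Handles BSQ/BIL/BIP interleaves and returns data in H x W x B order
    regardless of the on-disk layout.
    """
    path_header = Path(path_header)
    path_data = Path(path_data) if path_data else path_header.with_suffix(".raw")
    fields = _parse_envi_header(path_header.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise ValueError("no wavelength metadata in ENVI header")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise ValueError("malformed wavelength block in ENVI header")
    wavelengths = np.array(
        [float(x) for x in wl_text[1:-1].replace(",", " ").split()]
    )
    if wavelengths.size != b:
        raise ValueError(
            f"header declares {b} bands but lists {wavelengths.size} wavelengths"
        )
    dtype = {"4": "<f4", "5": "<f8"}.get(fields.get("data type", "4"))
    if dtype is None:
        raise ValueError(f"unsupported data type {fields.get('data type')!r}")
    raw = np.fromfile(path_data, dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError(
            f"data size mismatch: header implies {h * w * b} values, file has {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(h, b, w).transpose(0, 2, 1)
    else:
        data = raw.reshape(h, w, b)
    data = np.ascontiguousarray(data, dtype=np.float32)
    if data.size and (data.min() < 0.0 or data.max() > REFLECTANCE_MAX):
        raise ValueError(
            f"reflectance outside [0, {REFLECTANCE_MAX}]; cube does not look calibrated"
        )
    return SpectralCube(data, wavelengths)


# ---------------------------------------------------------------------------
# Label I/O

def write_labels(boxes: list[BoundingBox], path) -> Path:
    path = Path(path)
    lines = [f"{b.class_id} {b.cx:.8f} {b.cy:.8f} {b.w:.8f} {b.h:.8f}" for b in boxes]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_labels(path, n_classes: int = len(CLASS_NAMES)) -> list[BoundingBox]:
    """Parse a normalized-label file, validating every line."""
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(x) for x in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable value ({exc})") from exc
        if cls >= n_classes:
            raise ValueError(
                f"{path}:{lineno}: class {cls} out of range (n_classes={n_classes})"
            )
        try:
            boxes.append(BoundingBox(cls, cx, cy, w, h))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return boxes
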