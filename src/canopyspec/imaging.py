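"""Cube handling: radiometric calibration, segmentation, ROI extraction.

The central object is the :class:`ReflectanceCube`, produced from a raw
digital-number cube and concurrently acquired white (Teflon, ~99%
reflective) and dark (lens-cap) reference frames via

    R = (raw - dark) / (white - dark)

clipped to ``[0, clip_max]`` (default 1.5: slightly super-white pixels do
occur against a ~99% reference).  Plant/background separation runs on a
pseudo-color composite of three discriminative bands converted to HSV,
with closed threshold ranges on each channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import color as skcolor
from skimage import morphology

from .errors import CalibrationError
from .grids import WavelengthGrid
from .preprocess import SpectraTable

__all__ = [
    "RawCube",
    "ReferenceFrame",
    "ReflectanceCube",
    "PlantMask",
    "DEFAULT_HSV_RANGES",
    "PSEUDOCOLOR_BANDS_NM",
    "calibrate_cube",
    "nearest_band",
    "build_pseudocolor",
    "segment_plant",
    "apply_mask",
    "extract_roi_spectra",
    "read_envi",
    "write_envi",
    "read_tiff_cube",
    "write_tiff_cube",
    "read_mask_png",
    "write_mask_png",
]

log = logging.getLogger(__name__)

#: HSV threshold ranges (each on [0, 1]) used for plant segmentation.
DEFAULT_HSV_RANGES = {
    "h": (0.223, 0.412),
    "s": (0.762, 1.000),
    "v": (0.001, 1.000),
}

#: Red/green/blue channel wavelengths of the pseudo-color composite.
PSEUDOCOLOR_BANDS_NM = (679.7, 790.9, 871.7)


@dataclass
class RawCube:
    """H×W×B digital numbers (12-bit scale) plus the wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.grid.count:
            raise ValueError("data must be H x W x grid.count")
        if self.data.min() < 0:
            raise ValueError("digital numbers must be >= 0")


@dataclass
class ReferenceFrame:
    """White or dark reference, full-frame or 1×1×B broadcastable."""

    data: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.role not in ("white", "dark"):
            raise ValueError("role must be 'white' or 'dark'")
        if self.data.ndim != 3:
            raise ValueError("reference must be H x W x B (or 1 x 1 x B)")


@dataclass
class PlantMask:
    """Boolean foreground mask of a cube."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be H x W")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class ReflectanceCube:
    """Calibrated H×W×B reflectance, optionally carrying a plant mask and
    a preprocessing provenance trace (empty = plain reflectance)."""

    data: np.ndarray
    grid: WavelengthGrid
    mask: PlantMask | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.grid.count:
            raise ValueError("data must be H x W x grid.count")
        if not np.isfinite(self.data).all():
            raise ValueError("reflectance must be finite everywhere")
        self.provenance = tuple(self.provenance)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def calibrate_cube(raw: RawCube, white: ReferenceFrame, dark: ReferenceFrame,
                   clip_max: float = 1.5) -> ReflectanceCube:
    """Radiometric calibration of a raw cube to reflectance.

    Every element becomes ``(raw - dark) / (white - dark)`` and is clipped
    to ``[0, clip_max]``.  Raises :class:`CalibrationError`, naming the
    first offending pixel/band, if the references are degenerate anywhere.
    """
    try:
        denom = np.broadcast_to(white.data - dark.data, raw.data.shape)
    except ValueError as e:
        raise CalibrationError(f"shape mismatch: {e}") from e
    bad = denom <= 0
    if bad.any():
        i, j, k = np.argwhere(bad)[0]
        raise CalibrationError(
            f"white - dark <= 0 at pixel ({i}, {j}), band {k} "
            f"({raw.grid.wavelengths_nm[k]:.1f} nm)"
        )
    refl = (raw.data - np.broadcast_to(dark.data, raw.data.shape)) / denom
    refl = np.clip(refl, 0.0, clip_max)
    return ReflectanceCube(refl, raw.grid)


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Band index whose center is closest to ``target_nm`` (ties toward
    the lower wavelength)."""
    return grid.nearest_band(target_nm)


def build_pseudocolor(cube: ReflectanceCube,
                      wl_r: float = PSEUDOCOLOR_BANDS_NM[0],
                      wl_g: float = PSEUDOCOLOR_BANDS_NM[1],
                      wl_b: float = PSEUDOCOLOR_BANDS_NM[2]) -> np.ndarray:
    """Three-channel composite in [0, 1] from per-channel min–max rescaled
    planes at the nearest bands to the requested wavelengths.  A constant
    plane rescales to 0."""
    idx = [nearest_band(cube.grid, w) for w in (wl_r, wl_g, wl_b)]
    if len(set(idx)) < 3:
        log.warning("pseudocolor: duplicate bands %s — degenerate composite",
                    idx)
    channels = []
    for k in idx:
        plane = cube.data[:, :, k]
        lo, hi = plane.min(), plane.max()
        channels.append(np.zeros_like(plane) if hi == lo
                        else (plane - lo) / (hi - lo))
    return np.stack(channels, axis=-1)


def segment_plant(composite: np.ndarray,
                  h_range: tuple[float, float] = DEFAULT_HSV_RANGES["h"],
                  s_range: tuple[float, float] = DEFAULT_HSV_RANGES["s"],
                  v_range: tuple[float, float] = DEFAULT_HSV_RANGES["v"],
                  min_object_px: int = 64) -> PlantMask:
    """Threshold the HSV transform of a pseudo-color composite.

    A pixel is foreground when hue, saturation and value (each on [0, 1])
    all fall inside their closed ranges; connected components smaller than
    ``min_object_px`` are then removed.  An empty result warns instead of
    raising, so pipelines can report segmentation failure.
    """
    comp = np.asarray(composite, dtype=float)
    if comp.ndim != 3 or comp.shape[2] != 3:
        raise ValueError("composite must be H x W x 3")
    hsv = skcolor.rgb2hsv(comp)
    mask = np.ones(comp.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate((h_range, s_range, v_range)):
        mask &= (hsv[:, :, c] >= lo) & (hsv[:, :, c] <= hi)
    if min_object_px > 1:
        try:      # scikit-image >= 0.26 renamed the threshold parameter
            mask = morphology.remove_small_objects(
                mask, max_size=min_object_px - 1)
        except TypeError:  # pragma: no cover - older scikit-image
            mask = morphology.remove_small_objects(
                mask, min_size=min_object_px)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return PlantMask(mask)


def apply_mask(cube: ReflectanceCube, mask: PlantMask) -> ReflectanceCube:
    """Zero the background in every band and attach the mask."""
    if mask.data.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match cube H x W")
    out = cube.data * mask.data[:, :, None]
    return ReflectanceCube(out, cube.grid, mask=mask,
                           provenance=cube.provenance)


def extract_roi_spectra(cube: ReflectanceCube, n_rois: int = 3,
                        roi_size: int = 3, seed: int = 0,
                        label: str = "unknown") -> SpectraTable:
    """Mean spectra of seeded random non-overlapping square foreground ROIs.

    Each of the ``n_rois`` rows is the mean over a ``roi_size``×``roi_size``
    patch lying entirely inside the plant mask.  Three replicates per cube
    is the default sampling scheme.
    """
    if cube.mask is None:
        raise ValueError("cube has no mask; call apply_mask first")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    fg = cube.mask.data
    if fg.sum() < n_rois * roi_size * roi_size:
        raise ValueError("foreground smaller than the requested ROIs")

    # candidate top-left corners whose full square is foreground
    ok = np.ones_like(fg)
    s = roi_size
    for di in range(s):
        for dj in range(s):
            shifted = np.zeros_like(fg)
            shifted[: fg.shape[0] - di, : fg.shape[1] - dj] = fg[di:, dj:]
            ok &= shifted
    candidates = np.argwhere(ok)
    if len(candidates) == 0:
        raise ValueError(f"no {s}x{s} patch fits inside the foreground")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    taken = np.zeros_like(fg)
    rows, pixels_used = [], 0
    for idx in order:
        i, j = candidates[idx]
        if taken[i:i + s, j:j + s].any():
            continue
        patch = cube.data[i:i + s, j:j + s, :]
        rows.append(patch.reshape(-1, cube.grid.count).mean(axis=0))
        taken[i:i + s, j:j + s] = True
        pixels_used += s * s
        if len(rows) == n_rois:
            break
    if len(rows) < n_rois:
        raise ValueError("could not place non-overlapping ROIs; "
                         "foreground too fragmented")
    X = np.vstack(rows)
    n = X.shape[0]
    return SpectraTable(X, np.full(n, label), np.full(n, "unassigned"),
                        cube.grid, provenance=cube.provenance)


# ---------------------------------------------------------------------------
# I/O: ENVI header + band-sequential raw, multi-page TIFF, PNG masks

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5,
               np.dtype(np.uint16): 12}


def write_envi(path, data: np.ndarray, grid: WavelengthGrid,
               dtype=np.float32) -> None:
    """Write an H×W×B array as ENVI band-sequential raw + text header.

    ``path`` is the raw-file path; the header goes to ``path + '.hdr'``.
    """
    path = Path(path)
    arr = np.ascontiguousarray(
        np.asarray(data, dtype=dtype).transpose(2, 0, 1))  # BSQ
    h, w, b = data.shape
    code = _ENVI_CODES[np.dtype(dtype)]
    wl = ", ".join(f"{x:.1f}" for x in grid.wavelengths_nm)
    hdr = (
        "ENVI\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {code}\ninterleave = bsq\nbyte order = 0\n"
        f"wavelength units = Nanometers\nwavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    arr.tofile(path)


def read_envi(path) -> tuple[np.ndarray, WavelengthGrid]:
    """Read an ENVI BSQ cube written by :func:`write_envi`."""
    path = Path(path)
    fields: dict[str, str] = {}
    text = path.with_suffix(path.suffix + ".hdr").read_text()
    # headers are "key = value"; the wavelength block is brace-delimited
    body = text.replace("\n", " ")
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        val = body.split(key + " =")[1].strip().split(" ")[0]
        fields[key] = val
    if fields["interleave"].lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    wl_str = body.split("wavelength = {")[1].split("}")[0]
    wl = np.array([float(x) for x in wl_str.split(",")])
    h, w, b = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    arr = np.fromfile(path, dtype=dtype).reshape(b, h, w)
    return arr.transpose(1, 2, 0).astype(float), WavelengthGrid(wl)


def write_tiff_cube(path, data: np.ndarray, grid: WavelengthGrid) -> None:
    """Multi-page float32 TIFF, one page per band; wavelengths stored in
    the ImageDescription tag."""
    wl = ",".join(f"{x:.1f}" for x in grid.wavelengths_nm)
    tifffile.imwrite(path, np.asarray(data, np.float32).transpose(2, 0, 1),
                     description=f"wavelengths_nm={wl}")


def read_tiff_cube(path) -> tuple[np.ndarray, WavelengthGrid]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    wl = np.array([float(x) for x in
                   desc.split("wavelengths_nm=")[1].split(",")])
    return arr.transpose(1, 2, 0).astype(float), WavelengthGrid(wl)


def write_mask_png(path, mask: PlantMask) -> None:
    iio.imwrite(path, (mask.data.astype(np.uint8) * 255))


def read_mask_png(path) -> PlantMask:
    return PlantMask(np.asarray(iio.imread(path)) > 127)
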