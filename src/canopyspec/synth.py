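"""Seeded synthetic VNIR scenes and labeled spectra tables.

The greenhouse imagery this pipeline was designed around is not publicly
deposited, so every downstream stage is exercised on synthetic data that
carries the statistical structure the analysis assumes:

* a plant-canopy endmember with low visible reflectance (pigment absorption
  around 670 nm, a green bump near 550 nm), a logistic red edge between
  ~690 and 740 nm, a high NIR plateau, and Gaussian water-overtone
  absorptions near 742 and 842 nm;
* stress severity expressed as a multiplicative visible lift (pigment
  loss), a shallower 670 nm absorption dip, a multiplicative NIR drop
  (tissue/water loss), a small red-edge blue shift, and shallower water
  bands;
* per-pixel / per-spectrum multiplicative-plus-additive scatter and
  Gaussian noise, so scatter-correction preprocessing has something real
  to remove;
* a spectrally distinct soil/bench background that is brighter than
  vegetation in the red and beyond ~800 nm but darker on the NIR plateau,
  which is what makes the pseudo-color HSV segmentation thresholds work.

The forward model of a raw frame is ``raw = dark + R * (white - dark)``
(per pixel and band, plus optional scatter/noise on ``R``), so radiometric
calibration inverts it exactly when noise is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidProfileError
from .grids import WavelengthGrid, default_grid
from .preprocess import SpectraTable

__all__ = [
    "StressProfile",
    "SceneSpec",
    "DEFAULT_PROFILES",
    "EXPERIMENT_DESIGNS",
    "make_endmember",
    "soil_spectrum",
    "make_scene",
    "render_scene",
    "sample_spectra_table",
    "total_images",
]

# -- leaf model constants (reflectance units / nm) --------------------------
_VIS_FLOOR = 0.05          # broadband visible baseline
_GREEN_BUMP = (0.04, 550.0, 30.0)    # amplitude, center, sigma
_PIGMENT_BAND = (670.0, 18.0)        # center, sigma of the red Chl dip
_RED_EDGE_CENTER = 715.0
_RED_EDGE_WIDTH = 10.0
_NIR_PLATEAU = 0.45
_NIR_ROLLOFF = 0.50        # fractional plateau decline from 800 to 900 nm
WATER_BAND_CENTERS_NM = (742.0, 842.0)
_WATER_BAND_SIGMAS = (6.0, 7.0)
# vis_gain applies fully at <=700 nm and ramps out by 740 nm
_VIS_GAIN_FULL_NM = 700.0
_VIS_GAIN_ZERO_NM = 740.0


@dataclass(frozen=True)
class StressProfile:
    """Severity-dependent deformation of the healthy canopy endmember.

    ``vis_gain`` multiplies the whole spectrum at wavelengths <= 700 nm
    (ramping out by 740 nm), ``nir_loss`` multiplies the NIR plateau
    component, ``rededge_shift_nm`` moves the red-edge inflection (negative
    = blue shift, as with chlorophyll loss), ``water_band_depth`` is the
    depth of the 742/842 nm absorptions and ``pigment_depth`` the depth of
    the 670 nm chlorophyll dip (stress makes it shallower).
    """

    category_label: str
    vis_gain: float = 1.0
    nir_loss: float = 1.0
    rededge_shift_nm: float = 0.0
    water_band_depth: float = 0.05
    pigment_depth: float = 0.035

    def __post_init__(self) -> None:
        if self.vis_gain <= 0 or self.nir_loss <= 0:
            raise InvalidProfileError(
                f"profile {self.category_label!r}: vis_gain and nir_loss "
                "must be positive"
            )
        if self.water_band_depth < 0 or self.pigment_depth < 0:
            raise InvalidProfileError(
                f"profile {self.category_label!r}: absorption depths must "
                "be non-negative"
            )


#: The three severity categories the classification study distinguishes.
#: Control is the untouched canopy model; "early" is a mild pigment loss
#: barely separable from control; "severe" shows strong visible brightening,
#: a collapsed 670 nm dip and a 30% NIR drop.
DEFAULT_PROFILES: tuple[StressProfile, ...] = (
    StressProfile("control", 1.0, 1.0, 0.0,
                  water_band_depth=0.05, pigment_depth=0.035),
    StressProfile("early", 1.25, 0.92, -1.0,
                  water_band_depth=0.04, pigment_depth=0.026),
    StressProfile("severe", 1.60, 0.75, -2.0,
                  water_band_depth=0.035, pigment_depth=0.018),
)

#: Greenhouse acquisition designs (greenhouses x rows x images/week x weeks).
EXPERIMENT_DESIGNS: dict[str, dict[str, int]] = {
    "potato_drought": dict(greenhouses=2, rows=6, images_per_week=30, weeks=5),
    "potato_heat": dict(greenhouses=6, rows=1, images_per_week=30, weeks=4),
    "sweetpotato_drought": dict(greenhouses=1, rows=3, images_per_week=30,
                                weeks=11),
    "sweetpotato_excess_water": dict(greenhouses=1, rows=3,
                                     images_per_week=30, weeks=11),
}


def total_images(design: Mapping[str, int]) -> int:
    """Total hyperspectral images an acquisition design yields."""
    return (design["greenhouses"] * design["rows"]
            * design["images_per_week"] * design["weeks"])


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def make_endmember(profile: StressProfile, grid: WavelengthGrid) -> np.ndarray:
    """Noise-free canopy reflectance spectrum for one stress profile.

    Returns a vector of length ``grid.count`` clipped to [0, 1].
    """
    wl = grid.wavelengths_nm
    amp, c, s = _GREEN_BUMP
    bump = amp * _gauss(wl, c, s)
    pc, ps = _PIGMENT_BAND
    dip = profile.pigment_depth * _gauss(wl, pc, ps)
    edge = expit((wl - (_RED_EDGE_CENTER + profile.rededge_shift_nm))
                 / _RED_EDGE_WIDTH)
    rolloff = 1.0 - _NIR_ROLLOFF * np.clip((wl - 800.0) / 100.0, 0.0, 1.0)
    plateau = _NIR_PLATEAU * edge * rolloff
    water = np.zeros_like(wl)
    for wc, ws in zip(WATER_BAND_CENTERS_NM, _WATER_BAND_SIGMAS):
        water += profile.water_band_depth * _gauss(wl, wc, ws)
    base = _VIS_FLOOR + bump - dip + profile.nir_loss * plateau - water
    gain = 1.0 + (profile.vis_gain - 1.0) * np.clip(
        (_VIS_GAIN_ZERO_NM - wl) / (_VIS_GAIN_ZERO_NM - _VIS_GAIN_FULL_NM),
        0.0, 1.0)
    return np.clip(gain * base, 0.0, 1.0)


def soil_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Dry soil/bench background: ~0.26 in the visible with a slight tilt,
    rising toward ~0.6 above 800 nm.  Brighter than vegetation in the red
    and past ~840 nm, darker on the NIR plateau."""
    wl = grid.wavelengths_nm
    base = 0.26 + 0.02 * (wl - wl[0]) / (wl[-1] - wl[0])
    nir_rise = 0.35 * np.clip((wl - 800.0) / 100.0, 0.0, 1.0)
    return base + nir_rise


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and statistics of one synthetic greenhouse scene.

    ``label_map`` is an H×W integer image: 0 = background, k >= 1 indexes
    ``profiles[k-1]``.  Scatter is a per-pixel affine distortion
    ``R -> offset + slope * R`` applied before noise.
    """

    label_map: np.ndarray
    profiles: tuple[StressProfile, ...]
    background: np.ndarray | None = None
    scatter_slope_range: tuple[float, float] = (0.98, 1.02)
    scatter_offset_range: tuple[float, float] = (-0.005, 0.005)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_map, dtype=np.int64)
        object.__setattr__(self, "label_map", lab)
        if lab.ndim != 2:
            raise ValueError("label_map must be H x W")
        if lab.min() < 0 or lab.max() > len(self.profiles):
            raise ValueError("label_map values must be in 0..len(profiles)")
        fg = lab > 0
        if not fg.any():
            raise ValueError("plant region is empty")
        border = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        if border.any():
            raise ValueError("plant region must lie strictly inside the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def height(self) -> int:
        return int(self.label_map.shape[0])

    @property
    def width(self) -> int:
        return int(self.label_map.shape[1])


def make_scene(height: int, width: int,
               profiles: Sequence[StressProfile] = DEFAULT_PROFILES,
               layout: str = "bands", **kwargs) -> SceneSpec:
    """Build a SceneSpec with an elliptical plant on a soil background.

    layout:
      * ``"uniform"`` — the whole plant carries ``profiles[0]``;
      * ``"bands"``   — horizontal stripes, one per profile, top to bottom;
      * ``"apical"``  — like bands but with severity increasing toward the
        apex (top rows get the last = most severe profile), emulating
        stress expression in newly emerging apical leaves.
    """
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ellipse = (((yy - cy) / (0.42 * height)) ** 2
               + ((xx - cx) / (0.38 * width)) ** 2) <= 1.0
    ellipse[0, :] = ellipse[-1, :] = False
    ellipse[:, 0] = ellipse[:, -1] = False
    label = np.zeros((height, width), dtype=np.int64)
    if layout == "uniform":
        label[ellipse] = 1
        profiles = tuple(profiles[:1])
    elif layout in ("bands", "apical"):
        rows = np.nonzero(ellipse.any(axis=1))[0]
        k = len(profiles)
        edges = np.linspace(rows[0], rows[-1] + 1, k + 1)
        stripe = np.clip(np.searchsorted(edges, yy[:, 0], side="right") - 1,
                         0, k - 1)
        if layout == "apical":            # most severe at the top
            stripe = (k - 1) - stripe
        label[ellipse] = stripe[:, None].repeat(width, axis=1)[ellipse] + 1
        profiles = tuple(profiles)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SceneSpec(label_map=label, profiles=profiles, **kwargs)


# DN model of the 12-bit sensor: smooth illumination profile for the white
# (Teflon) reference, small wavelength-dependent dark current.  References
# are noise-free so calibration is an exact inverse of the forward model.
def _reference_frames(grid: WavelengthGrid, height: int, width: int):
    wl = grid.wavelengths_nm
    illum = 0.85 + 0.15 * np.exp(-(((wl - 650.0) / 250.0) ** 2))
    white_dn = 3600.0 * illum
    dark_dn = 96.0 + 8.0 * (wl - wl[0]) / (wl[-1] - wl[0])
    white = np.broadcast_to(white_dn, (height, width, grid.count)).copy()
    dark = np.broadcast_to(dark_dn, (height, width, grid.count)).copy()
    return white, dark


def render_scene(spec: SceneSpec, grid: WavelengthGrid | None = None):
    """Render a raw DN cube plus references and ground truth.

    Returns ``(raw, white, dark, truth_mask, truth_labels)`` where ``raw``
    is H×W×B digital numbers, the references share that shape, the mask is
    the boolean plant region and ``truth_labels`` is the severity label map
    (0 = background).  Deterministic for a fixed ``spec.seed``.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(spec.seed)
    h, w, b = spec.height, spec.width, grid.count
    white, dark = _reference_frames(grid, h, w)
    if np.any(white <= dark):
        raise ValueError("degenerate references: white <= dark somewhere")

    endmembers = [make_endmember(p, grid) for p in spec.profiles]
    background = (np.asarray(spec.background, dtype=float)
                  if spec.background is not None else soil_spectrum(grid))
    if background.shape != (b,):
        raise ValueError("background spectrum length must match the grid")

    refl = np.empty((h, w, b), dtype=float)
    refl[spec.label_map == 0] = background
    for k, em in enumerate(endmembers, start=1):
        refl[spec.label_map == k] = em

    lo, hi = spec.scatter_slope_range
    slope = rng.uniform(lo, hi, size=(h, w, 1))
    lo, hi = spec.scatter_offset_range
    offset = rng.uniform(lo, hi, size=(h, w, 1))
    refl = offset + slope * refl
    if spec.noise_sd > 0:
        refl = refl + rng.normal(0.0, spec.noise_sd, size=refl.shape)

    raw = dark + refl * (white - dark)
    return raw, white, dark, spec.label_map > 0, spec.label_map.copy()


def sample_spectra_table(
    design: Mapping[str, int],
    profiles: Sequence[StressProfile] = DEFAULT_PROFILES,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
    noise_sd: float = 0.004,
    scatter_slope_range: tuple[float, float] = (0.8, 1.2),
    scatter_offset_range: tuple[float, float] = (-0.05, 0.05),
) -> SpectraTable:
    """Draw a labeled spectra table, one row per ROI spectrum.

    ``design`` maps category label -> row count; each category must name a
    profile in ``profiles``.  Rows are the category endmember distorted by
    a per-row affine scatter (slope/offset) and then Gaussian noise, so SNV
    and MSC have real structure to remove.  Deterministic given ``seed``.
    """
    if not design:
        raise ValueError("empty design")
    for n in design.values():
        if n < 1:
            raise ValueError("per-category counts must be >= 1")
    grid = grid or default_grid()
    by_label = {p.category_label: p for p in profiles}
    rng = np.random.default_rng(seed)

    rows, labels = [], []
    for cat, n in design.items():
        if cat not in by_label:
            raise KeyError(f"no profile named {cat!r}")
        em = make_endmember(by_label[cat], grid)
        slope = rng.uniform(*scatter_slope_range, size=(n, 1))
        offset = rng.uniform(*scatter_offset_range, size=(n, 1))
        block = offset + slope * em[None, :]
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        rows.append(block)
        labels.extend([cat] * n)

    X = np.vstack(rows)
    n_total = X.shape[0]
    ids = np.array([f"s{i:05d}" for i in range(n_total)])
    return SpectraTable(
        X=X,
        labels=np.array(labels),
        split=np.full(n_total, "unassigned"),
        grid=grid,
        sample_ids=ids,
    )
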