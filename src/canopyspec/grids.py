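"""Band-center wavelength grids for VNIR hyperspectral cubes.

Two grids matter in practice:

* :func:`default_grid` — 194 evenly spaced band centers from 511 to 900 nm,
  used by the synthetic-scene generator.
* :func:`senop_grid` — the Senop HSC-2 camera's published band-center set,
  194 centers from 510 to 900 nm rounded to 0.1 nm.  Band addressing is
  always by wavelength, never by vendor band index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "default_grid", "senop_grid"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths of a hyperspectral sensor.

    Parameters
    ----------
    wavelengths_nm : array-like of float
        Strictly increasing band centers in nanometres.  At least two
        bands, all within the VNIR window (400–1000 nm).
    """

    wavelengths_nm: np.ndarray = field()

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least two band centers")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 400.0 or wl[-1] > 1000.0:
            raise ValueError("grid must lie within 400–1000 nm (VNIR)")

    @property
    def count(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def mean_spacing_nm(self) -> float:
        return float(np.mean(np.diff(self.wavelengths_nm)))

    def nearest_band(self, target_nm: float) -> int:
        """Index of the band center closest to ``target_nm``.

        Ties are broken toward the lower wavelength.  Targets farther than
        half the mean band spacing outside the grid span are rejected.
        """
        wl = self.wavelengths_nm
        half = 0.5 * self.mean_spacing_nm
        if target_nm < wl[0] - half or target_nm > wl[-1] + half:
            raise ValueError(
                f"target {target_nm:g} nm outside grid range "
                f"[{wl[0]:g}, {wl[-1]:g}] by more than {half:g} nm"
            )
        # argmin returns the first minimum: with increasing wavelengths this
        # is the lower-wavelength band on an exact tie.
        return int(np.argmin(np.abs(wl - target_nm)))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.count


def default_grid(count: int = 194, start_nm: float = 511.0,
                 stop_nm: float = 900.0) -> WavelengthGrid:
    """Evenly spaced synthetic grid (194 bands, 511–900 nm by default)."""
    return WavelengthGrid(np.linspace(start_nm, stop_nm, count))


def senop_grid() -> WavelengthGrid:
    """The Senop HSC-2 band-center set: 510–900 nm, 194 bands, 0.1 nm print
    precision.  Every published band list of the instrument (e.g. 669.6,
    671.7, 699.9, 702.0, 742.4, 841.8 nm) lies on this grid."""
    return WavelengthGrid(np.round(np.linspace(510.0, 900.0, 194), 1))
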