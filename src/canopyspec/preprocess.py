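"""Spectral preprocessing for tables of ROI spectra and, pixel-wise, cubes.

Every operator acts row-independently on an N×B matrix of spectra, so the
same fitted chain can be replayed on a flattened hypercube — which is what
keeps chemical imaging consistent with the model it visualizes.  Operators
with fitted state (MSC's reference spectrum) freeze it on the calibration
rows and reuse it everywhere else to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA as _SkPCA

from .errors import PreprocessError
from .grids import WavelengthGrid

__all__ = [
    "SpectraTable",
    "PreprocessSpec",
    "Preprocessor",
    "snv",
    "msc",
    "savgol",
    "normalize",
    "pca",
]

_SPLIT_VALUES = ("cal", "val", "test", "unassigned")


@dataclass
class SpectraTable:
    """N labeled reflectance spectra on a common wavelength grid.

    ``provenance`` records the ordered preprocessing operators already
    applied to ``X`` (empty for raw reflectance).
    """

    X: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    grid: WavelengthGrid
    sample_ids: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.split = np.asarray(self.split)
        if self.X.ndim != 2:
            raise ValueError("X must be N x B")
        if self.X.shape[1] != self.grid.count:
            raise ValueError("column count must equal grid.count")
        if np.isnan(self.X).any():
            raise ValueError("X contains NaN")
        n = self.X.shape[0]
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels/split must have one entry per row")
        bad = set(np.unique(self.split)) - set(_SPLIT_VALUES)
        if bad:
            raise ValueError(f"unknown split values: {sorted(bad)}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(n)])
        self.provenance = tuple(self.provenance)

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    def rows(self, split: str) -> "SpectraTable":
        """Subtable of one split partition."""
        m = self.split == split
        return SpectraTable(self.X[m], self.labels[m], self.split[m],
                            self.grid, self.sample_ids[m], self.provenance)

    def with_X(self, X: np.ndarray, step: str | None = None) -> "SpectraTable":
        prov = self.provenance + ((step,) if step else ())
        return SpectraTable(X, self.labels, self.split, self.grid,
                            self.sample_ids, prov)

    def to_csv(self, path) -> None:
        cols = [f"{w:.1f}" for w in self.grid.wavelengths_nm]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "split", self.split)
        df.insert(0, "category", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = ["sample_id", "category", "split"]
        wl = np.array([float(c) for c in df.columns if c not in meta])
        return cls(
            X=df.drop(columns=meta).to_numpy(dtype=float),
            labels=df["category"].to_numpy(),
            split=df["split"].to_numpy(),
            grid=WavelengthGrid(wl),
            sample_ids=df["sample_id"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# row-wise operators


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centered and scaled to unit sample
    (n-1) standard deviation.  Removes per-spectrum multiplicative scatter
    and additive offsets exactly."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise PreprocessError(f"snv: zero-variance row(s) {zero.tolist()}")
    return (X - mu) / sd


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against ``reference``.

    Each row ``x`` is replaced by ``(x - a) / b`` where ``(a, b)`` solve the
    least-squares fit ``x ≈ a + b * reference``.  Rows generated as affine
    distortions of the reference are recovered exactly.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(reference, dtype=float)
    if r.shape != (X.shape[1],):
        raise PreprocessError("msc: reference length must equal band count")
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise PreprocessError("msc: constant reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.nonzero(np.abs(b) < 1e-8)[0]
    if bad.size:
        raise PreprocessError(f"msc: near-zero slope for row(s) {bad.tolist()}")
    a = X.mean(axis=1) - b * r.mean()
    return (X - a[:, None]) / b[:, None]


def savgol(X: np.ndarray, window: int = 11, polyorder: int = 2,
           deriv: int = 0) -> np.ndarray:
    """Savitzky–Golay filtering along the band axis.

    ``deriv=0`` smooths, ``deriv=2`` takes the second derivative (in
    per-band-index units).  Edges are handled by evaluating the boundary
    polynomial fits (scipy's ``mode="interp"``), which keeps polynomials of
    degree <= ``polyorder`` exact everywhere.
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise PreprocessError("savgol: window must be odd and > polyorder")
    if deriv > polyorder:
        raise PreprocessError("savgol: deriv must be <= polyorder")
    if X.shape[1] < window:
        raise PreprocessError("savgol: fewer bands than window")
    return savgol_filter(X, window, polyorder, deriv=deriv, axis=1,
                         mode="interp")


def normalize(X: np.ndarray, mode: str) -> np.ndarray:
    """Per-row normalization: ``max`` (x/max), ``mean`` (x/mean) or
    ``range`` ((x-min)/(max-min), mapping each row onto [0, 1])."""
    X = np.asarray(X, dtype=float)
    if mode == "max":
        d = X.max(axis=1)
        bad = np.nonzero(d == 0)[0]
        if bad.size:
            raise PreprocessError(f"normalize(max): zero max row(s) {bad.tolist()}")
        return X / d[:, None]
    if mode == "mean":
        d = X.mean(axis=1)
        bad = np.nonzero(d == 0)[0]
        if bad.size:
            raise PreprocessError(f"normalize(mean): zero mean row(s) {bad.tolist()}")
        return X / d[:, None]
    if mode == "range":
        lo, hi = X.min(axis=1), X.max(axis=1)
        bad = np.nonzero(hi == lo)[0]
        if bad.size:
            raise PreprocessError(f"normalize(range): constant row(s) {bad.tolist()}")
        return (X - lo[:, None]) / (hi - lo)[:, None]
    raise PreprocessError(f"normalize: unknown mode {mode!r}")


def pca(X: np.ndarray, n_components: int):
    """Column-mean-centered PCA.

    Returns ``(scores, loadings, explained_fractions)`` with orthonormal
    loadings (components as columns) and variance fractions that sum to 1
    over all ``min(N-1, B)`` components.
    """
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    if not (1 <= n_components <= min(n - 1, b)):
        raise ValueError("n_components must be in [1, min(N-1, B)]")
    fit = _SkPCA(n_components=n_components, svd_solver="full").fit(X)
    scores = fit.transform(X)
    loadings = fit.components_.T
    return scores, loadings, fit.explained_variance_ratio_.copy()


# ---------------------------------------------------------------------------
# named specs and fitted chains

_KNOWN = ("raw", "snv", "msc", "sg_smooth", "sg_2nd",
          "max_norm", "mean_norm", "range_norm")


@dataclass(frozen=True)
class PreprocessSpec:
    """A named preprocessing operator plus its parameters.

    ``sg_smooth``/``sg_2nd`` take ``window`` and ``polyorder``; ``msc``
    carries its frozen ``reference`` once fitted.
    """

    name: str
    window: int = 11
    polyorder: int | None = None
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in _KNOWN:
            raise PreprocessError(f"unknown preprocessing {self.name!r}")
        if self.name.startswith("sg_"):
            po = self.effective_polyorder
            if self.window % 2 == 0 or self.window <= po:
                raise PreprocessError("SG window must be odd and > polyorder")

    @property
    def effective_polyorder(self) -> int:
        if self.polyorder is not None:
            return self.polyorder
        return 3 if self.name == "sg_2nd" else 2

    def tag(self) -> str:
        if self.name.startswith("sg_"):
            return f"{self.name}(w={self.window},p={self.effective_polyorder})"
        return self.name


class Preprocessor:
    """An ordered, fittable chain of preprocessing operators.

    ``fit`` freezes any data-dependent state (the MSC reference = mean
    calibration spectrum unless one was supplied); ``transform`` replays
    the chain on any row matrix, including flattened cube pixels.
    """

    def __init__(self, specs: Sequence[PreprocessSpec | str]):
        self.specs = [PreprocessSpec(s) if isinstance(s, str) else s
                      for s in specs]
        self.fitted_ = False

    def fit(self, X_cal: np.ndarray) -> "Preprocessor":
        X = np.asarray(X_cal, dtype=float)
        fitted = []
        for spec in self.specs:
            if spec.name == "msc" and spec.reference is None:
                spec = replace(spec, reference=X.mean(axis=0))
            X = _apply_one(spec, X)
            fitted.append(spec)
        self.specs = fitted
        self.fitted_ = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted_:
            raise PreprocessError("Preprocessor used before fit()")
        X = np.asarray(X, dtype=float)
        for spec in self.specs:
            X = _apply_one(spec, X)
        return X

    def fit_transform(self, X_cal: np.ndarray) -> np.ndarray:
        return self.fit(X_cal).transform(X_cal)

    @property
    def provenance(self) -> tuple[str, ...]:
        return tuple(s.tag() for s in self.specs if s.name != "raw")

    # round-trip serialization so model artifacts can replay the chain
    def to_dict(self) -> dict:
        out = []
        for s in self.specs:
            d = {"name": s.name, "window": s.window, "polyorder": s.polyorder}
            if s.reference is not None:
                d["reference"] = np.asarray(s.reference).tolist()
            out.append(d)
        return {"specs": out, "fitted": self.fitted_}

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        specs = []
        for s in d["specs"]:
            ref = np.asarray(s["reference"]) if "reference" in s else None
            specs.append(PreprocessSpec(s["name"], window=s["window"],
                                        polyorder=s["polyorder"],
                                        reference=ref))
        p = cls(specs)
        p.fitted_ = bool(d.get("fitted", False))
        return p


def _apply_one(spec: PreprocessSpec, X: np.ndarray) -> np.ndarray:
    if spec.name == "raw":
        return X
    if spec.name == "snv":
        return snv(X)
    if spec.name == "msc":
        if spec.reference is None:
            raise PreprocessError("msc spec has no fitted reference")
        return msc(X, spec.reference)
    if spec.name == "sg_smooth":
        return savgol(X, spec.window, spec.effective_polyorder, deriv=0)
    if spec.name == "sg_2nd":
        return savgol(X, spec.window, spec.effective_polyorder, deriv=2)
    if spec.name == "max_norm":
        return normalize(X, "max")
    if spec.name == "mean_norm":
        return normalize(X, "mean")
    if spec.name == "range_norm":
        return normalize(X, "range")
    raise PreprocessError(f"unknown preprocessing {spec.name!r}")


def apply_to_table(pre: Preprocessor, table: SpectraTable) -> SpectraTable:
    """Transform a table through a fitted chain, extending its provenance."""
    X = pre.transform(table.X)
    out = table.with_X(X)
    out.provenance = table.provenance + pre.provenance
    return out
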