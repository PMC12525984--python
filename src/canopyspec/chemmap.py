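"""Pixel-wise chemical imaging from PLS-DA beta coefficients.

A fitted (typically SPA-reduced) PLS-DA model is replayed on every
foreground pixel of a masked reflectance cube: the cube is preprocessed
with the model's own chain, restricted to the model's band subset,
flattened to pixels × bands, multiplied by the beta coefficients and
reshaped back to an H×W×C score image.  The arg-max category with a 0.5
decision threshold gives the label map; rendering uses a blue → green/
yellow gradient (low → high severity) with black background and gray
"uncertain" pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .errors import ProvenanceError
from .imaging import ReflectanceCube
from .models import PLSDAModel

__all__ = ["ChemicalMap", "BACKGROUND_LABEL", "UNCERTAIN_LABEL",
           "chemical_map", "classify_map", "render_map"]

BACKGROUND_LABEL = -1
UNCERTAIN_LABEL = -2


@dataclass
class ChemicalMap:
    """Per-pixel category scores plus the thresholded label map."""

    score_map: np.ndarray        # H x W x C, NaN on background
    categories: list[str]
    threshold: float
    mask: np.ndarray             # boolean foreground
    colormap: str = "viridis"
    label_map: np.ndarray | None = None
    fractions: dict | None = None


def chemical_map(cube: ReflectanceCube, model: PLSDAModel) -> ChemicalMap:
    """Apply a PLS-DA model pixel-wise to a masked reflectance cube.

    The cube must be plain masked reflectance (empty provenance) so the
    model's stored preprocessing chain can be replayed on it; a cube that
    already carries a different preprocessing trace is rejected outright
    to prevent silently invalid maps.
    """
    if cube.mask is None:
        raise ValueError("cube must be masked (apply_mask) first")
    model_prov = (model.preprocess.provenance if model.preprocess is not None
                  else ())
    if cube.provenance and tuple(cube.provenance) != tuple(model_prov):
        raise ProvenanceError(
            f"cube preprocessing {cube.provenance} does not match the "
            f"model's {tuple(model_prov)}")

    fg = cube.mask.data
    pixels = cube.data[fg]                      # Nfg x B
    if not cube.provenance and model.preprocess is not None:
        pixels = model.preprocess.transform(pixels)
    if model.selected_bands is not None:
        pixels = pixels[:, model.selected_bands]
    if pixels.shape[1] != model.beta.shape[0]:
        raise ValueError("band count after preprocessing does not match "
                         "the model")
    scores = pixels @ model.beta + model.intercepts

    h, w = fg.shape
    c = len(model.categories)
    smap = np.full((h, w, c), np.nan)
    smap[fg] = scores
    return ChemicalMap(score_map=smap, categories=list(model.categories),
                       threshold=model.threshold, mask=fg)


def classify_map(cmap: ChemicalMap, threshold: float | None = None
                 ) -> ChemicalMap:
    """Threshold the score map into a label map and pixel fractions.

    Foreground label = arg-max category index when the winning score
    exceeds the threshold (default the model's 0.5), else the "uncertain"
    sentinel; background keeps its own sentinel.  Fractions (including
    "uncertain") sum to 1 over the foreground.
    """
    thr = cmap.threshold if threshold is None else threshold
    fg = cmap.mask
    h, w, _ = cmap.score_map.shape
    labels = np.full((h, w), BACKGROUND_LABEL, dtype=int)
    scores = cmap.score_map[fg]
    win = scores.argmax(axis=1)
    confident = scores.max(axis=1) > thr
    vals = np.where(confident, win, UNCERTAIN_LABEL)
    labels[fg] = vals

    n_fg = int(fg.sum())
    fractions = {c: float((vals == i).sum()) / n_fg
                 for i, c in enumerate(cmap.categories)}
    fractions["uncertain"] = float((vals == UNCERTAIN_LABEL).sum()) / n_fg
    cmap.label_map = labels
    cmap.fractions = fractions
    cmap.threshold = thr
    return cmap


def render_map(cmap: ChemicalMap, out_path,
               score_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Write an 8-bit color rendering of the severity map.

    The displayed scalar is the severity rank of the arg-max category
    normalized to [0, 1] (categories are ordered from healthiest to most
    severe in ``cmap.categories``), drawn with a blue → green/yellow
    gradient; background is black, uncertain pixels neutral gray.  The
    colormap and scaling go to a JSON sidecar.  Rendering is
    deterministic: identical maps give byte-identical files.
    """
    if cmap.label_map is None:
        classify_map(cmap)
    lut = colormaps[cmap.colormap]
    k = len(cmap.categories)
    rank = cmap.label_map.astype(float)
    sev = np.clip(rank / max(k - 1, 1), 0.0, 1.0)
    lo, hi = score_range
    sev = np.clip((sev - lo) / (hi - lo), 0.0, 1.0)
    rgb = (np.asarray(lut(sev))[:, :, :3] * 255).astype(np.uint8)
    rgb[cmap.label_map == BACKGROUND_LABEL] = 0
    rgb[cmap.label_map == UNCERTAIN_LABEL] = 128

    out_path = Path(out_path)
    iio.imwrite(out_path, rgb)
    sidecar = {
        "colormap": cmap.colormap,
        "score_range": list(score_range),
        "threshold": cmap.threshold,
        "categories": cmap.categories,
        "fractions": cmap.fractions,
    }
    out_path.with_suffix(out_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return rgb
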