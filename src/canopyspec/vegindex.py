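"""Narrowband vegetation indices and ANOVA with Duncan's multiple range test.

Four indices summarize pigment and structural status from reflectance at
the classic narrowbands (green 550, red 670, red-edge 700, NIR 800 nm, each
resolved to the nearest grid band):

    NDVI  = (NIR - Red) / (NIR + Red)
    RDVI  = (NIR - Red) / sqrt(NIR + Red)
    GNDVI = (NIR - Green) / (NIR + Green)
    MCARI = [(R700 - R670) - 0.2 (R700 - R550)] * (R700 / R670)

Treatment effects on an index are assessed by one-way ANOVA followed by
Duncan's multiple range test (DMRT): treatments sharing a letter are not
significantly different at the chosen alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import WavelengthGrid

__all__ = ["INDEX_NAMES", "compute_indices", "compute_index_maps",
           "DuncanResult", "anova_duncan", "assumption_checks"]

INDEX_NAMES = ("NDVI", "RDVI", "GNDVI", "MCARI")

#: Nominal band positions (nm) used by the indices.
INDEX_BANDS_NM = {"green": 550.0, "red": 670.0, "rededge": 700.0,
                  "nir": 800.0}


def _index_values(green, red, re700, nir, rdvi_as_printed: bool):
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / (nir + red)
        if rdvi_as_printed:
            rdvi = ndvi.copy()          # the duplicated-formula variant
        else:
            rdvi = (nir - red) / np.sqrt(nir + red)
        gndvi = (nir - green) / (nir + green)
        mcari = ((re700 - red) - 0.2 * (re700 - green)) * (re700 / red)
    return ndvi, rdvi, gndvi, mcari


def compute_indices(X: np.ndarray, grid: WavelengthGrid,
                    labels=None, rdvi_as_printed: bool = False
                    ) -> pd.DataFrame:
    """Per-sample vegetation indices from an N×B spectra matrix.

    Samples with a zero denominator get NaN (with a warning); they are
    excluded later from ANOVA.  ``rdvi_as_printed`` reproduces the
    typographic variant where RDVI duplicates the NDVI formula.
    """
    X = np.asarray(X, dtype=float)
    b = {k: grid.nearest_band(v) for k, v in INDEX_BANDS_NM.items()}
    vals = _index_values(X[:, b["green"]], X[:, b["red"]],
                         X[:, b["rededge"]], X[:, b["nir"]],
                         rdvi_as_printed)
    df = pd.DataFrame(dict(zip(INDEX_NAMES, vals)))
    if df.isna().any().any():
        warnings.warn("zero denominators produced NaN index values",
                      stacklevel=2)
    if labels is not None:
        df.insert(0, "treatment", np.asarray(labels))
    return df


def compute_index_maps(cube_data: np.ndarray, grid: WavelengthGrid,
                       rdvi_as_printed: bool = False) -> dict[str, np.ndarray]:
    """The four index maps (H×W each) of a reflectance cube."""
    b = {k: grid.nearest_band(v) for k, v in INDEX_BANDS_NM.items()}
    vals = _index_values(cube_data[:, :, b["green"]],
                         cube_data[:, :, b["red"]],
                         cube_data[:, :, b["rededge"]],
                         cube_data[:, :, b["nir"]], rdvi_as_printed)
    return dict(zip(INDEX_NAMES, vals))


@dataclass
class DuncanResult:
    """One-way ANOVA F/p plus Duncan letter groups over treatment means."""

    table: pd.DataFrame          # treatment, n, mean, letters
    f_statistic: float
    p_value: float
    alpha: float
    mse: float
    df_error: int

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["treatment"], self.table["letters"]))


def anova_duncan(values_by_treatment: dict[str, np.ndarray],
                 alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA followed by Duncan's multiple range grouping.

    Duncan's test compares the ordered means with studentized-range
    critical values at the protection level ``1 - (1-alpha)**(p-1)`` for a
    span of ``p`` means, using the ANOVA mean-square error.  NaN values are
    dropped per group.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in
              values_by_treatment.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two treatments")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each treatment needs n >= 2")

    ns = np.array([len(v) for v in groups.values()])
    means = np.array([v.mean() for v in groups.values()])
    n_total = int(ns.sum())
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((v - v.mean()) ** 2).sum()
                          for v in groups.values()))
    df_b, df_w = len(groups) - 1, n_total - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance in every treatment")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f_stat = ms_b / ms_w
    p_val = float(stats.f.sf(f_stat, df_b, df_w))

    # order means ascending; harmonic mean handles unequal group sizes
    order = np.argsort(means)
    names = np.array(list(groups.keys()))[order]
    m = means[order]
    n_h = len(ns) / np.sum(1.0 / ns)
    se = math.sqrt(ms_w / n_h)

    k = len(m)
    nonsig = np.zeros((k, k), dtype=bool)  # range i..j declared homogeneous

    def critical_range(p: int) -> float:
        level = (1 - alpha) ** (p - 1)
        return float(stats.studentized_range.ppf(level, p, df_w)) * se

    def test_range(i: int, j: int) -> None:
        # step-down multiple-range procedure: a non-significant span
        # protects every sub-span inside it
        if i >= j or nonsig[i, j]:
            return
        p = j - i + 1
        if m[j] - m[i] <= critical_range(p):
            for a in range(i, j + 1):
                for b_ in range(a, j + 1):
                    nonsig[a, b_] = True
        else:
            test_range(i, j - 1)
            test_range(i + 1, j)

    test_range(0, k - 1)

    # letters from maximal homogeneous runs over the ordered means
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not any(r[0] <= i and j <= r[1] for r in runs):
            runs.append((i, j))
    letters = ["" for _ in range(k)]
    for r, (i, j) in enumerate(sorted(runs)):
        ch = chr(ord("a") + r)
        for t in range(i, j + 1):
            letters[t] += ch

    table = pd.DataFrame({
        "treatment": names,
        "n": ns[order],
        "mean": m,
        "letters": letters,
    })
    return DuncanResult(table, f_stat, p_val, alpha, ms_w, df_w)


def assumption_checks(values_by_treatment: dict[str, np.ndarray]) -> dict:
    """Optional normality (Shapiro–Wilk on residuals) and variance
    homogeneity (Levene) reports.  Informational only; they never gate the
    ANOVA."""
    groups = [np.asarray(v, dtype=float) for v in values_by_treatment.values()]
    resid = np.concatenate([g - g.mean() for g in groups])
    sw = stats.shapiro(resid) if 3 <= len(resid) <= 5000 else None
    lev = stats.levene(*groups)
    return {
        "shapiro_w": None if sw is None else float(sw.statistic),
        "shapiro_p": None if sw is None else float(sw.pvalue),
        "levene_w": float(lev.statistic),
        "levene_p": float(lev.pvalue),
    }
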