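"""Successive Projections Algorithm (SPA) for wavelength selection.

SPA is a forward selection that fights collinearity: starting from one
band, it repeatedly projects all remaining band columns onto the orthogonal
complement of the span of the bands already chosen and appends the column
with the largest residual norm.  Chains are built for every possible start
band and a range of subset sizes; each candidate subset is scored by the
validation accuracy of a discriminant model restricted to those bands, and
the best-scoring (smallest, lowest-start on ties) subset wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import WavelengthGrid

__all__ = ["SelectionResult", "spa_chain", "spa_select"]

log = logging.getLogger(__name__)

_RANK_TOL = 1e-12


@dataclass
class SelectionResult:
    """Outcome of an SPA search.

    ``criterion_trace`` holds one ``(k, start, score)`` triple per evaluated
    candidate, so the full search surface can be inspected.
    """

    selected_indices: list[int]
    selected_wavelengths_nm: list[float]
    k: int
    start: int
    score: float
    criterion_name: str
    criterion_trace: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_wavelengths_nm": [float(w) for w in
                                        self.selected_wavelengths_nm],
            "k": int(self.k),
            "start": int(self.start),
            "score": float(self.score),
            "criterion_name": self.criterion_name,
            "criterion_trace": [[int(k), int(s), float(v)]
                                for k, s, v in self.criterion_trace],
        }


def spa_chain(X: np.ndarray, start: int, k: int) -> list[int]:
    """Build one SPA chain of ``k`` column indices starting at ``start``.

    ``X`` should have centered columns.  At each step every remaining
    column is replaced by its component orthogonal to the span of the
    chosen columns and the column of maximal Euclidean norm is appended;
    ties break toward the lowest index.  If the attainable rank is
    exhausted the chain is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    if not (0 <= start < b):
        raise ValueError("start out of range")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, b)

    P = X.copy()                      # columns projected out of chosen span
    chain = [start]
    chosen = np.zeros(b, dtype=bool)
    chosen[start] = True
    for _ in range(k - 1):
        c = P[:, chain[-1]].copy()
        c2 = float(c @ c)
        if c2 <= _RANK_TOL:
            break
        P = P - np.outer(c, (c @ P) / c2)
        norms = np.einsum("ij,ij->j", P, P)
        norms[chosen] = -1.0
        j = int(np.argmax(norms))     # first max = lowest index on ties
        if norms[j] <= _RANK_TOL:
            warnings.warn(
                f"SPA chain truncated at {len(chain)} bands: rank exhausted",
                stacklevel=2)
            break
        chain.append(j)
        chosen[j] = True
    return chain


def _column_stats(Xcal: np.ndarray, scale: bool):
    mu = Xcal.mean(axis=0)
    if not scale:
        return mu, np.ones_like(mu)
    sd = Xcal.std(axis=0, ddof=0)
    return mu, np.where(sd == 0, 1.0, sd)


def spa_select(Xcal: np.ndarray, ycal: np.ndarray,
               Xval: np.ndarray, yval: np.ndarray,
               k_min: int = 2, k_max: int = 32,
               grid: WavelengthGrid | None = None,
               starts: list[int] | None = None,
               n_lv: int = 10,
               criterion: str = "val_accuracy",
               scale: bool = False) -> SelectionResult:
    """Search SPA chains over all starts and subset sizes.

    Columns are centered on calibration statistics before the projections
    (``scale=True`` additionally divides by the column SD, but that
    inflates noise-dominated bands into spuriously "orthogonal" columns
    and lets chains collect uninformative wavelengths, so centering alone
    is the default).  Every ``(start, k)`` candidate in ``starts ×
    [k_min, k_max]`` is scored — by validation accuracy of a PLS-DA fitted
    on the candidate bands (``criterion="val_accuracy"``, the default) or
    by the validation RMSE of the one-hot response block (``"val_rmse"``).
    Ties break toward smaller k, then lower start.
    """
    from .models import fit_plsda, predict_plsda  # deferred: cyclic import

    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    ycal = np.asarray(ycal)
    yval = np.asarray(yval)
    n, b = Xcal.shape
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max > n - 1:
        warnings.warn(f"k_max clipped from {k_max} to Ncal-1 = {n - 1}",
                      stacklevel=2)
        k_max = n - 1
    k_max = min(k_max, b)
    if k_min > k_max:
        raise ValueError("k_min exceeds attainable k_max")
    starts = list(range(b)) if starts is None else list(starts)

    mu, sd = _column_stats(Xcal, scale)
    Z = (Xcal - mu) / sd

    best = None     # (-score, k, start, chain)
    trace: list[tuple[int, int, float]] = []
    for start in starts:
        chain = spa_chain(Z, start, k_max)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            bands = sorted(chain[:k])
            model = fit_plsda(Xcal[:, bands], ycal,
                              n_lv=min(n_lv, k, n - 1))
            scores, pred = predict_plsda(model, Xval[:, bands])
            if criterion == "val_accuracy":
                score = float(np.mean(pred == yval))
            elif criterion == "val_rmse":
                Y = np.array([[1.0 if c == y else 0.0
                               for c in model.categories] for y in yval])
                score = -float(np.sqrt(np.mean((scores - Y) ** 2)))
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            trace.append((k, start, score))
            cand = (-score, k, start, bands)
            if best is None or cand < best:
                best = cand
    neg_score, k, start, bands = best
    wl = (grid.wavelengths_nm[bands].tolist() if grid is not None
          else [float(i) for i in bands])
    return SelectionResult(
        selected_indices=[int(i) for i in bands],
        selected_wavelengths_nm=wl,
        k=k,
        start=start,
        score=-neg_score,
        criterion_name=criterion,
        criterion_trace=trace,
    )
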