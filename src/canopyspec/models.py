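"""Severity classifiers: stratified splitting, PLS-DA / LDA / SVM, metrics.

The discriminant models all consume preprocessed N×B spectra:

* **PLS-DA** — partial least squares regression of a one-hot class block Y
  on X (latent variables maximize X–Y covariance); the regression
  coefficients ("beta") map a spectrum to continuous per-category scores.
  Class = arg-max score; a score above the +0.5 decision threshold marks
  the assignment as confident.
* **LDA** — Gaussian classes with a shared covariance; the discriminant of
  class i is  δ_i(x) = xᵀΣ⁻¹μ_i − ½μ_iᵀΣ⁻¹μ_i + log π_i,  with Σ shrunk
  toward (tr Σ / p)·I by a weight chosen by stratified 5-fold CV.
* **SVM** — one RBF-kernel maximum-margin binary classifier per category
  (one vs rest), decision f(x) = Σ α_i y_i K(x_i, x) + b; class = arg-max
  decision value; (C, γ) chosen by stratified 5-fold CV.

Splitting is stratified 60/20/20 (calibration/validation/test) with
largest-remainder rounding per category.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import Preprocessor, SpectraTable

__all__ = [
    "SplitSpec", "allocate_split_counts", "stratified_split",
    "PLSDAModel", "fit_plsda", "predict_plsda", "select_n_lv",
    "LDAModel", "fit_lda",
    "SVMModel", "fit_svm_ovr",
    "EvalReport", "evaluate",
    "save_model", "load_model",
]

log = logging.getLogger(__name__)

PLSDA_SCORE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def allocate_split_counts(n: int, fractions=(0.6, 0.2, 0.2)) -> tuple[int, ...]:
    """Largest-remainder allocation of ``n`` samples to the partitions.

    Remainder ties break in partition order (calibration first), e.g.
    6558 -> (3935, 1312, 1311).
    """
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = [(-(e - b), i) for i, (e, b) in enumerate(zip(exact, base))]
    for _, i in sorted(remainders)[:short]:
        base[i] += 1
    return tuple(base)


def stratified_split(table: SpectraTable, spec: SplitSpec = SplitSpec()
                     ) -> SpectraTable:
    """Assign cal/val/test labels per category with a seeded shuffle.

    Per-category counts follow :func:`allocate_split_counts`; the result
    is a disjoint, exhaustive partition.  Categories with fewer than 5
    members are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    split = np.full(table.n, "unassigned", dtype=object)
    names = ("cal", "val", "test")
    cats = np.unique(table.labels)
    for cat in cats:
        idx = np.nonzero(table.labels == cat)[0]
        if len(idx) < 5:
            raise ValueError(f"category {cat!r} has fewer than 5 members")
        if spec.stratified:
            rng.shuffle(idx)
        counts = allocate_split_counts(len(idx), spec.fractions)
        pos = 0
        for name, c in zip(names, counts):
            split[idx[pos:pos + c]] = name
            pos += c
    return SpectraTable(table.X, table.labels, split.astype(str), table.grid,
                        table.sample_ids, table.provenance)


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    """Fitted PLS-DA: latent-variable decomposition plus the beta map.

    ``beta`` has shape (bands used) × (categories); prediction is
    ``X @ beta + intercepts``.
    """

    n_lv: int
    categories: list[str]
    beta: np.ndarray
    intercepts: np.ndarray
    x_scores: np.ndarray        # T
    x_loadings: np.ndarray      # P
    y_scores: np.ndarray        # U
    y_loadings: np.ndarray      # Q
    weights: np.ndarray         # W
    threshold: float = PLSDA_SCORE_THRESHOLD
    preprocess: Preprocessor | None = None
    selected_bands: list[int] | None = None

    kind = "plsda"


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cats = sorted(set(labels.tolist()))
    Y = np.array([[1.0 if lab == c else 0.0 for c in cats] for lab in labels])
    return Y, cats


def fit_plsda(Xcal: np.ndarray, labels: np.ndarray, n_lv: int = 10,
              preprocess: Preprocessor | None = None,
              selected_bands: list[int] | None = None) -> PLSDAModel:
    """Fit a PLS-DA model with ``n_lv`` latent variables.

    The one-hot Y block is regressed on column-centered X (no scaling).
    If X cannot support ``n_lv`` components the effective count is reduced
    with a warning.
    """
    X = np.asarray(Xcal, dtype=float)
    labels = np.asarray(labels)
    Y, cats = _one_hot(labels)
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    n, b = X.shape
    max_lv = min(n - 1, b)
    if n_lv > max_lv:
        raise ValueError(f"n_lv={n_lv} exceeds min(Ncal-1, bands)={max_lv}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    eff = n_lv
    if rank < n_lv:
        warnings.warn(f"rank-deficient X: using {rank} latent variables "
                      f"instead of {n_lv}", stacklevel=2)
        eff = int(rank)
    pls = PLSRegression(n_components=eff, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    beta = np.asarray(pls.coef_).T.copy()
    # fold the column centering into a flat affine form:
    # scores = X @ beta + (y_mean - x_mean @ beta)
    intercepts = Y.mean(axis=0) - X.mean(axis=0) @ beta
    return PLSDAModel(
        n_lv=eff,
        categories=cats,
        beta=beta,
        intercepts=intercepts,
        x_scores=pls.x_scores_.copy(),
        x_loadings=pls.x_loadings_.copy(),
        y_scores=pls.y_scores_.copy(),
        y_loadings=pls.y_loadings_.copy(),
        weights=pls.x_weights_.copy(),
        preprocess=preprocess,
        selected_bands=(list(selected_bands) if selected_bands is not None
                        else None),
    )


def predict_plsda(model: PLSDAModel, X: np.ndarray):
    """Continuous category scores and arg-max class predictions.

    Returns ``(scores, predicted)``; ``scores`` additionally exposes a
    per-sample confidence flag via :func:`plsda_confident` (winning score
    above the +0.5 threshold).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.beta.shape[0]:
        raise ValueError(
            f"band-count mismatch: model expects {model.beta.shape[0]}, "
            f"got {X.shape[1]}")
    scores = X @ model.beta + model.intercepts
    pred = np.array([model.categories[i] for i in np.argmax(scores, axis=1)])
    return scores, pred


def plsda_confident(model: PLSDAModel, scores: np.ndarray) -> np.ndarray:
    """True where the winning score exceeds the model's decision threshold."""
    return scores.max(axis=1) > model.threshold


def select_n_lv(Xcal, ycal, Xval, yval, max_lv: int = 15,
                default: int = 10) -> int:
    """Choose the latent-variable count by validation accuracy.

    Among the LV counts tied at the best validation accuracy the default
    (10) is preferred when eligible, otherwise the smallest; so when
    accuracy plateaus early the conventional 10-LV model is returned.
    """
    X = np.asarray(Xcal, dtype=float)
    max_lv = min(max_lv, X.shape[0] - 1, X.shape[1])
    accs = {}
    for lv in range(1, max_lv + 1):
        model = fit_plsda(X, ycal, n_lv=lv)
        _, pred = predict_plsda(model, Xval)
        accs[lv] = float(np.mean(pred == np.asarray(yval)))
    best = max(accs.values())
    eligible = [lv for lv, a in accs.items() if a == best]
    return default if default in eligible else min(eligible)


# ---------------------------------------------------------------------------
# LDA

@dataclass
class LDAModel:
    """Linear discriminant classifier with shrunk pooled covariance."""

    categories: list[str]
    means: np.ndarray            # C x B
    covariance: np.ndarray       # shrunk pooled B x B
    priors: np.ndarray
    shrinkage: float
    coef: np.ndarray = field(init=False)        # Σ⁻¹ μ_i per class
    const: np.ndarray = field(init=False)       # −½ μΣ⁻¹μ + log π

    kind = "lda"

    def __post_init__(self) -> None:
        sol = np.linalg.solve(self.covariance, self.means.T)  # B x C
        self.coef = sol
        self.const = (-0.5 * np.einsum("cb,bc->c", self.means, sol)
                      + np.log(self.priors))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """δ_i(x) for every sample and class."""
        return np.asarray(X, float) @ self.coef + self.const

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.array([self.categories[i] for i in np.argmax(d, axis=1)])


def _pooled_cov(X, labels, cats):
    n, p = X.shape
    means = np.vstack([X[labels == c].mean(axis=0) for c in cats])
    S = np.zeros((p, p))
    for c, mu in zip(cats, means):
        D = X[labels == c] - mu
        S += D.T @ D
    return means, S / (n - len(cats))


def _shrunk(S: np.ndarray, lam: float) -> np.ndarray:
    p = S.shape[0]
    return (1 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)


def fit_lda(Xcal: np.ndarray, labels: np.ndarray,
            shrinkages=(0.0, 0.01, 0.1, 0.3, 0.5),
            folds: int = 5, seed: int = 0) -> LDAModel:
    """Fit LDA, tuning the covariance shrinkage by stratified k-fold CV.

    A grid point whose shrunk covariance is numerically singular is
    skipped with a warning.  Ties prefer the smaller shrinkage.
    """
    X = np.asarray(Xcal, dtype=float)
    labels = np.asarray(labels)
    cats = sorted(set(labels.tolist()))
    if len(cats) < 2:
        raise ValueError("need at least two categories")

    def build(Xtr, ytr, lam):
        means, S = _pooled_cov(Xtr, ytr, cats)
        cov = _shrunk(S, lam)
        priors = np.array([(ytr == c).mean() for c in cats])
        # reject near-singular covariances up front
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError("singular covariance")
        return LDAModel(cats, means, cov, priors, lam)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_acc = {}
    for lam in shrinkages:
        accs = []
        try:
            for tr, te in skf.split(X, labels):
                m = build(X[tr], labels[tr], lam)
                accs.append(float(np.mean(m.predict(X[te]) == labels[te])))
        except np.linalg.LinAlgError:
            warnings.warn(f"shrinkage {lam}: singular covariance, skipped",
                          stacklevel=2)
            continue
        cv_acc[lam] = float(np.mean(accs))
    if not cv_acc:
        raise np.linalg.LinAlgError("all shrinkage grid points singular")
    best = max(cv_acc.values())
    lam = min(l for l, a in cv_acc.items() if a == best)
    return build(X, labels, lam)


# ---------------------------------------------------------------------------
# SVM (one vs rest, RBF kernel)

@dataclass
class SVMModel:
    """One-vs-rest RBF SVM ensemble with exported kernel expansions."""

    categories: list[str]
    support_vectors: list[np.ndarray]    # per class
    dual_coef: list[np.ndarray]          # α_i y_i per class
    bias: list[float]
    gamma: float
    C: float

    kind = "svm"

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        for sv, a, b in zip(self.support_vectors, self.dual_coef, self.bias):
            d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            cols.append(np.exp(-self.gamma * d2) @ a + b)
        return np.stack(cols, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.array([self.categories[i] for i in np.argmax(d, axis=1)])


def _fit_binary_svms(X, labels, cats, C, gamma):
    machines = []
    for c in cats:
        y = np.where(labels == c, 1, -1)
        if (y == -1).sum() == 0:
            raise ValueError(f"one-vs-rest: empty rest class for {c!r}")
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X, y)
        machines.append(clf)
    return machines


def _ovr_decision(machines, X):
    # SVC orders classes [-1, +1]; decision_function is positive for +1
    return np.stack([m.decision_function(X) for m in machines], axis=1)


def fit_svm_ovr(Xcal: np.ndarray, labels: np.ndarray,
                Cs=(0.1, 1.0, 10.0, 100.0),
                gamma_factors=(0.1, 1.0, 10.0),
                folds: int = 5, seed: int = 0) -> SVMModel:
    """Fit the one-vs-rest RBF ensemble, tuning (C, γ) by stratified CV.

    γ candidates are multiples of the inverse feature-count/variance scale
    ``1 / (p · var(X))``.  Ties prefer smaller C then smaller γ.
    """
    X = np.asarray(Xcal, dtype=float)
    labels = np.asarray(labels)
    cats = sorted(set(labels.tolist()))
    g0 = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
    gammas = [g0 * f for f in gamma_factors]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best = None
    for C in Cs:
        for gamma in gammas:
            accs = []
            for tr, te in skf.split(X, labels):
                machines = _fit_binary_svms(X[tr], labels[tr], cats, C, gamma)
                d = _ovr_decision(machines, X[te])
                pred = np.array([cats[i] for i in np.argmax(d, axis=1)])
                accs.append(float(np.mean(pred == labels[te])))
            cand = (-float(np.mean(accs)), C, gamma)
            if best is None or cand < best:
                best = cand
    _, C, gamma = best
    machines = _fit_binary_svms(X, labels, cats, C, gamma)
    return SVMModel(
        categories=cats,
        support_vectors=[m.support_vectors_.copy() for m in machines],
        dual_coef=[m.dual_coef_.ravel().copy() for m in machines],
        bias=[float(m.intercept_[0]) for m in machines],
        gamma=gamma,
        C=C,
    )


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Confusion matrix and the derived classification metrics.

    Accuracy is trace/total; precision, recall and F1 are per-category
    with macro averages (weighted averages available via ``weighted``);
    AUC is the macro mean of one-vs-rest areas from continuous scores.
    """

    set_name: str
    categories: list[str]
    confusion: np.ndarray
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    per_category: dict
    auc_macro: float | None
    undefined_precision: list[str]

    def as_row(self, percent: bool = True) -> dict:
        acc = round(self.accuracy * 100, 2) if percent else self.accuracy
        return {
            "set": self.set_name,
            "accuracy": acc,
            "precision": round(self.precision_macro, 3),
            "recall": round(self.recall_macro, 3),
            "f1": round(self.f1_macro, 3),
            "auc": None if self.auc_macro is None
                   else round(self.auc_macro, 3),
        }


def evaluate(y_true, y_pred, scores: np.ndarray | None = None,
             categories: list[str] | None = None,
             set_name: str = "test") -> EvalReport:
    """Confusion-matrix metrics for one evaluation set.

    A category never predicted gets precision 0 and is flagged in
    ``undefined_precision``.  AUC needs ``scores`` (one column per
    category, same order) and at least two categories present in truth.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth/prediction length mismatch")
    cats = (categories if categories is not None
            else sorted(set(y_true.tolist()) | set(y_pred.tolist())))
    k = len(cats)
    pos = {c: i for i, c in enumerate(cats)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1

    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    support = cm.sum(axis=1).astype(float)

    undefined = [cats[i] for i in range(k) if tp[i] + fp[i] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec
                      / np.maximum(prec + rec, 1e-300), 0.0)

    w = support / support.sum() if support.sum() else np.full(k, 1 / k)
    per_cat = {c: {"precision": float(prec[i]), "recall": float(rec[i]),
                   "f1": float(f1[i]), "support": int(support[i])}
               for i, c in enumerate(cats)}

    auc = None
    if scores is not None and len(np.unique(y_true)) > 1:
        aucs = []
        for i, c in enumerate(cats):
            yt = (y_true == c).astype(int)
            if 0 < yt.sum() < len(yt):
                aucs.append(roc_auc_score(yt, scores[:, i]))
        auc = float(np.mean(aucs)) if aucs else None

    return EvalReport(
        set_name=set_name,
        categories=list(cats),
        confusion=cm,
        accuracy=accuracy,
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        precision_weighted=float(prec @ w),
        recall_weighted=float(rec @ w),
        f1_weighted=float(f1 @ w),
        per_category=per_cat,
        auc_macro=auc,
        undefined_precision=undefined,
    )


# ---------------------------------------------------------------------------
# model artifact serialization (JSON: metadata + flat arrays)

def save_model(model, path) -> None:
    """Serialize a fitted model (plus any preprocessing chain) to JSON."""
    d: dict = {"kind": model.kind}
    if model.kind == "plsda":
        d.update({
            "n_lv": model.n_lv,
            "categories": model.categories,
            "beta": model.beta.tolist(),
            "intercepts": model.intercepts.tolist(),
            "threshold": model.threshold,
            "selected_bands": model.selected_bands,
        })
        if model.preprocess is not None:
            d["preprocess"] = model.preprocess.to_dict()
    elif model.kind == "lda":
        d.update({
            "categories": model.categories,
            "means": model.means.tolist(),
            "covariance": model.covariance.tolist(),
            "priors": model.priors.tolist(),
            "shrinkage": model.shrinkage,
        })
    elif model.kind == "svm":
        d.update({
            "categories": model.categories,
            "support_vectors": [sv.tolist() for sv in model.support_vectors],
            "dual_coef": [a.tolist() for a in model.dual_coef],
            "bias": model.bias,
            "gamma": model.gamma,
            "C": model.C,
        })
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    Path(path).write_text(json.dumps(d))


def load_model(path):
    d = json.loads(Path(path).read_text())
    kind = d["kind"]
    if kind == "plsda":
        z = np.zeros((0, 0))
        pre = (Preprocessor.from_dict(d["preprocess"])
               if "preprocess" in d else None)
        return PLSDAModel(
            n_lv=d["n_lv"], categories=d["categories"],
            beta=np.asarray(d["beta"]),
            intercepts=np.asarray(d["intercepts"]),
            x_scores=z, x_loadings=z, y_scores=z, y_loadings=z, weights=z,
            threshold=d["threshold"], preprocess=pre,
            selected_bands=d.get("selected_bands"),
        )
    if kind == "lda":
        return LDAModel(d["categories"], np.asarray(d["means"]),
                        np.asarray(d["covariance"]),
                        np.asarray(d["priors"]), d["shrinkage"])
    if kind == "svm":
        return SVMModel(d["categories"],
                        [np.asarray(sv) for sv in d["support_vectors"]],
                        [np.asarray(a) for a in d["dual_coef"]],
                        list(d["bias"]), d["gamma"], d["C"])
    raise ValueError(f"unknown model kind {kind!r}")
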