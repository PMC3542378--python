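"""RBF-SVM diagnostic score: training, panel pruning, scoring, cutoff.

The diagnostic model combines the normalized intensities of a marker
panel into a single score: the signed distance, in the RBF kernel
feature space, of the sample from the maximum-margin hyperplane
separating cases from controls.  Distances are obtained by dividing the
kernel decision value by the norm of the separating direction,

    ||w||^2 = sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j),

so scores are in margin units and comparable across refits.  Features
are ln(1+x) transformed and min-max scaled with constants estimated on
the training samples only (the RBF width is scale sensitive).  Cost C
and kernel width gamma are chosen by cross-validated AUC over a grid;
"total" cross-validation is leave-one-out, with k-fold available for
speed.  Panel reduction is a take-one-out backward elimination driven
by the same cross-validated AUC.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import IntensityMatrix

log = logging.getLogger(__name__)

#: (C, gamma) printed for the published 142-peptide model, usable as a preset
PRESET_C = 640.0
PRESET_GAMMA = 3e-6

DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 14))
DEFAULT_GAMMA_GRID = tuple(float(10.0**k) for k in range(-7, 2))


def cv_auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """Midrank Mann-Whitney AUC of pooled cross-validated scores."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(scores)
    r1 = ranks[y == 1].sum()
    return float((r1 - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


@dataclass
class DiagnosticModel:
    """A trained diagnostic panel: features, scaling, kernel machine, cutoff."""

    marker_ids: list[int]
    feature_min: np.ndarray
    feature_range: np.ndarray
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    w_norm: float
    cutoff: float | None = None
    cv_auc: float | None = None
    class_weight: str | None = "balanced"

    def transform(self, matrix: IntensityMatrix | pd.DataFrame) -> np.ndarray:
        values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
        missing = [m for m in self.marker_ids if m not in values.columns]
        if missing:
            raise KeyError(f"matrix lacks model marker columns: {missing}")
        X = values[self.marker_ids].to_numpy(dtype=float)
        return (np.log1p(X) - self.feature_min) / self.feature_range

    def decision_values(self, Xt: np.ndarray) -> np.ndarray:
        K = rbf_kernel(Xt, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef + self.intercept

    def score_transformed(self, Xt: np.ndarray) -> np.ndarray:
        return self.decision_values(Xt) / self.w_norm

    def to_json(self, path) -> None:
        doc = dict(
            marker_ids=self.marker_ids,
            feature_min=self.feature_min.tolist(),
            feature_range=self.feature_range.tolist(),
            C=self.C,
            gamma=self.gamma,
            support_vectors=self.support_vectors.tolist(),
            dual_coef=self.dual_coef.tolist(),
            intercept=self.intercept,
            w_norm=self.w_norm,
            cutoff=self.cutoff,
            cv_auc=self.cv_auc,
            class_weight=self.class_weight,
        )
        with open(path, "wt") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiagnosticModel":
        with open(path, "rt") as fh:
            doc = json.load(fh)
        doc["feature_min"] = np.asarray(doc["feature_min"], float)
        doc["feature_range"] = np.asarray(doc["feature_range"], float)
        doc["support_vectors"] = np.asarray(doc["support_vectors"], float)
        doc["dual_coef"] = np.asarray(doc["dual_coef"], float)
        return cls(**doc)


def _as_binary(labels, positive: str = "ADPKD") -> np.ndarray:
    lab = pd.Series(labels)
    if set(pd.unique(lab)) <= {0, 1, True, False}:
        y = lab.astype(int).to_numpy()
    else:
        y = (lab == positive).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need samples from both classes")
    return y


def _fit_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ln(1+x) then min-max constants from training; constant features kept
    with unit range (they carry no information either way)."""
    L = np.log1p(X)
    lo = L.min(axis=0)
    rng = L.max(axis=0) - lo
    degenerate = rng <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature(s) in training panel",
            stacklevel=2,
        )
    rng = np.where(degenerate, 1.0, rng)
    return (L - lo) / rng, lo, rng, degenerate


def _svc(C: float, class_weight) -> SVC:
    return SVC(kernel="precomputed", C=C, class_weight=class_weight)


def resolve_gamma(gamma, Xt: np.ndarray) -> float:
    """Resolve a gamma spec to a value: numeric passes through; ``"scale"``
    uses the 1 / (n_features * variance) heuristic on the transformed data."""
    if gamma == "scale":
        v = Xt.var()
        return 1.0 / (Xt.shape[1] * v) if v > 0 else 1.0
    return float(gamma)


def _w_norm(svc: SVC, K: np.ndarray) -> float:
    sv = svc.support_
    dc = svc.dual_coef_.ravel()
    w2 = float(dc @ K[np.ix_(sv, sv)] @ dc)
    return float(np.sqrt(max(w2, 1e-300)))


def cross_val_scores(
    Xt: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    cv: str | int = "loo",
    class_weight: str | None = "balanced",
    seed: int = 0,
) -> np.ndarray:
    """Margin-distance scores under leave-one-out ('loo') or stratified
    k-fold (integer) cross-validation."""
    K = rbf_kernel(Xt, Xt, gamma=resolve_gamma(gamma, Xt))
    n = len(y)
    scores = np.empty(n)
    if cv == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        skf = StratifiedKFold(n_splits=int(cv), shuffle=True, random_state=seed)
        folds = list(skf.split(Xt, y))
    for tr, te in folds:
        clf = _svc(C, class_weight)
        clf.fit(K[np.ix_(tr, tr)], y[tr])
        wn = _w_norm(clf, K[np.ix_(tr, tr)])
        scores[te] = clf.decision_function(K[np.ix_(te, tr)]) / wn
    return scores


def cross_val_auc(
    Xt: np.ndarray, y: np.ndarray, C: float, gamma: float,
    cv: str | int = "loo", class_weight: str | None = "balanced", seed: int = 0,
) -> float:
    return cv_auc_from_scores(cross_val_scores(Xt, y, C, gamma, cv, class_weight, seed), y)


def train_svm(
    matrix: IntensityMatrix,
    labels: pd.Series | None = None,
    markers: Sequence[int] | None = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cv: str | int = "loo",
    class_weight: str | None = "balanced",
    positive: str = "ADPKD",
    seed: int = 0,
) -> tuple[DiagnosticModel, np.ndarray]:
    """Grid-search (C, gamma) by cross-validated AUC, refit on all training
    data, and return the model plus the pooled cross-validated scores of
    the winning parameters (the basis for cutoff selection).

    Ties in the grid break toward the smallest C, then the largest gamma.
    """
    labels = labels if labels is not None else matrix.labels
    y = _as_binary(labels.reindex(matrix.values.index), positive)
    markers = list(markers) if markers is not None else list(matrix.peptide_ids)
    if len(markers) == 0:
        raise ValueError("empty marker panel")
    X = matrix.values[markers].to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training samples")
    Xt, lo, rng, _ = _fit_transform(X)

    best = None  # (auc, -C rank handled explicitly)
    gammas = sorted({resolve_gamma(g, Xt) for g in gamma_grid}, reverse=True)
    for C in sorted(C_grid):
        for gamma in gammas:
            scores = cross_val_scores(Xt, y, C, gamma, cv, class_weight, seed)
            auc = cv_auc_from_scores(scores, y)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, C, gamma, scores)
    cv_auc_, C, gamma, cv_scores = best

    K = rbf_kernel(Xt, Xt, gamma=gamma)
    clf = _svc(C, class_weight)
    clf.fit(K, y)
    wn = _w_norm(clf, K)
    model = DiagnosticModel(
        marker_ids=[int(m) for m in markers],
        feature_min=lo,
        feature_range=rng,
        C=float(C),
        gamma=float(gamma),
        support_vectors=Xt[clf.support_],
        dual_coef=clf.dual_coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        w_norm=wn,
        cv_auc=float(cv_auc_),
        class_weight=class_weight,
    )
    return model, cv_scores


def score_samples(
    model: DiagnosticModel, matrix: IntensityMatrix
) -> pd.Series:
    """Margin-distance score per sample; absent marker columns are an error
    (a peptide absent in a *sample* is simply intensity 0)."""
    Xt = model.transform(matrix)
    return pd.Series(model.score_transformed(Xt), index=matrix.values.index, name="score")


def take_one_out_prune(
    matrix: IntensityMatrix,
    labels: pd.Series | None = None,
    markers: Sequence[int] | None = None,
    target_size: int | None = None,
    C: float = 10.0,
    gamma: float | str = "scale",
    cv: str | int = "loo",
    class_weight: str | None = "balanced",
    positive: str = "ADPKD",
    min_gain: float = 1e-4,
    seed: int = 0,
) -> tuple[list[int], list[tuple[int, float]]]:
    """Greedy backward elimination of the marker panel.

    At each step the marker whose removal yields the highest
    cross-validated AUC is dropped; exact AUC ties break toward removing
    the marker with the weakest univariate discrimination.  Without
    ``target_size``, elimination stops when no removal improves the AUC
    by more than ``min_gain``; with it, elimination continues to the
    requested size.  Returns the surviving panel and the
    (panel size, AUC) trajectory.
    """
    labels = labels if labels is not None else matrix.labels
    y = _as_binary(pd.Series(labels).reindex(matrix.values.index), positive)
    markers = list(markers) if markers is not None else list(matrix.peptide_ids)
    if len(markers) < 2:
        raise ValueError("need at least two candidate markers")
    if target_size is not None:
        if target_size > len(markers):
            raise ValueError(
                f"target_size {target_size} exceeds panel size {len(markers)}"
            )
        if target_size < 1:
            raise ValueError("target_size must be >= 1")

    def panel_auc(panel: list[int]) -> float:
        X = matrix.values[panel].to_numpy(dtype=float)
        Xt, *_ = _fit_transform(X)
        g = resolve_gamma(gamma, Xt)
        return cross_val_auc(Xt, y, C, g, cv, class_weight, seed)

    # univariate discrimination (|AUC - 0.5|) per marker, for tie-breaks
    marginal = {}
    for mk in markers:
        col = matrix.values[mk].to_numpy(dtype=float)
        marginal[mk] = abs(cv_auc_from_scores(col, y) - 0.5)

    panel = list(markers)
    current = panel_auc(panel)
    trajectory = [(len(panel), current)]
    while len(panel) > 1:
        if target_size is not None and len(panel) <= target_size:
            break
        best_auc, best_idx = -np.inf, None
        for idx in range(len(panel)):
            cand = panel[:idx] + panel[idx + 1:]
            auc = panel_auc(cand)
            if auc > best_auc + 1e-12 or (
                abs(auc - best_auc) <= 1e-12
                and marginal[panel[idx]] < marginal[panel[best_idx]]
            ):
                best_auc, best_idx = auc, idx
        if target_size is None and best_auc <= current + min_gain:
            break
        log.debug("pruning marker %s: AUC %.4f -> %.4f", panel[best_idx], current, best_auc)
        del panel[best_idx]
        current = best_auc
        trajectory.append((len(panel), current))
    return panel, trajectory


def choose_cutoff(
    scores, labels, positive: str = "ADPKD", method: str = "youden"
) -> float:
    """Operating cutoff maximizing the Youden index J = sens + spec - 1.

    Scores must come from cross-validation, not resubstitution.  The
    cutoff is the midpoint between the two adjacent sorted scores
    bracketing the maximum; J ties break toward higher specificity
    (higher cutoff).  Calls are score >= cutoff -> positive.
    """
    if method != "youden":
        raise ValueError(f"unknown cutoff method: {method}")
    s = np.asarray(scores, dtype=float)
    if isinstance(labels, pd.Series) and isinstance(scores, pd.Series):
        labels = labels.reindex(scores.index)
    y = _as_binary(pd.Series(np.asarray(labels)), positive)
    uniq = np.unique(s)
    edges = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_j, best_cut, best_spec = -np.inf, edges[0], -1.0
    n1, n0 = y.sum(), len(y) - y.sum()
    for cut in edges:
        call = s >= cut
        sens = (call & (y == 1)).sum() / n1
        spec = (~call & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and spec > best_spec):
            best_j, best_cut, best_spec = j, cut, spec
    return float(best_cut)
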