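"""Peptide-based severity score predicting height-adjusted kidney volume.

Two stages, mirroring how a progression marker panel is built from a
peptidome matrix:

1. *Screening*: every peptide's ln(1+intensity) is rank-correlated
   (Spearman) with htTKV across patients; absent peptides enter as the
   lowest midrank ties (absence is informative).  Peptides with
   |r| above a threshold (default 0.25) survive.
2. *Combination*: the survivors are combined in a linear model fit by
   least squares on standardized ln(1+intensity).  Because the survivor
   count is typically of the same order as the patient count, a ridge
   penalty chosen by generalized cross-validation is applied whenever
   the design is under-determined or ill-conditioned; otherwise the fit
   is plain OLS.  A signed-sum variant (sum of sign(r) * z-scored
   intensities) is available as a sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntensityMatrix


def screen_spearman(
    matrix: IntensityMatrix,
    response: pd.Series,
    r_threshold: float = 0.25,
) -> pd.DataFrame:
    """Spearman screen of every peptide against the response.

    Returns columns (peptide_id, r) for peptides with |r| > threshold,
    sorted by |r| descending.  Constant peptide columns have undefined
    rank correlation and are excluded.
    """
    response = pd.Series(response).dropna()
    common = matrix.values.index.intersection(response.index)
    if len(common) < 10:
        raise ValueError(f"need >= 10 paired samples, have {len(common)}")
    X = np.log1p(matrix.values.loc[common].to_numpy(dtype=float))
    y = response.loc[common].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    ry = stats.rankdata(y)
    rx = stats.rankdata(X, axis=0)
    n = len(y)
    sx = rx.std(axis=0)
    sy = ry.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = ((rx - rx.mean(0)) * (ry - ry.mean())[:, None]).mean(axis=0)
        r = cov / (sx * sy)
    ok = sx > 0
    table = pd.DataFrame(dict(peptide_id=matrix.peptide_ids, r=r))[ok]
    hits = table[np.abs(table["r"]) > r_threshold].copy()
    hits["abs_r"] = hits["r"].abs()
    hits = hits.sort_values(["abs_r", "peptide_id"], ascending=[False, True], kind="mergesort")
    return hits.drop(columns="abs_r").reset_index(drop=True)


@dataclass
class SeverityModel:
    """Screened peptide panel with linear coefficients on standardized
    ln(1+intensity); ridge_lambda is 0 for a plain least-squares fit."""

    peptide_ids: list[int]
    screening_r: list[float]
    intercept: float
    coef: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    ridge_lambda: float
    train_pearson: float | None = None
    train_spearman: float | None = None
    method: str = "ols"

    def transform(self, matrix: IntensityMatrix) -> np.ndarray:
        missing = [m for m in self.peptide_ids if m not in matrix.values.columns]
        if missing:
            raise KeyError(f"matrix lacks severity model columns: {missing}")
        X = np.log1p(matrix.values[self.peptide_ids].to_numpy(dtype=float))
        return (X - self.feature_mean) / self.feature_sd

    def to_json(self, path) -> None:
        doc = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "wt") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SeverityModel":
        with open(path, "rt") as fh:
            doc = json.load(fh)
        for k in ("coef", "feature_mean", "feature_sd"):
            doc[k] = np.asarray(doc[k], float)
        return cls(**doc)


def _gcv_ridge(Z: np.ndarray, yc: np.ndarray) -> tuple[float, np.ndarray]:
    """Ridge coefficients with the penalty chosen by leave-one-out
    generalized cross-validation, computed through the SVD."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uy = U.T @ yc
    n = len(yc)
    lambdas = np.logspace(-3, 4, 40) * np.maximum(s.max() ** 2, 1.0) / n
    best = (np.inf, lambdas[0])
    yy = yc @ yc
    for lam in lambdas:
        d = s**2 / (s**2 + lam)
        df = d.sum()
        rss = yy - 2 * (d * uy) @ uy + (d**2 * uy) @ uy
        gcv = (rss / n) / (1.0 - df / n) ** 2
        if gcv < best[0]:
            best = (gcv, lam)
    lam = best[1]
    coef = Vt.T @ (s / (s**2 + lam) * uy)
    return float(lam), coef


def fit_severity(
    matrix: IntensityMatrix,
    response: pd.Series,
    screened: pd.DataFrame | Sequence[int],
    method: str = "ols",
    ridge_lambda: float | None = None,
    cond_threshold: float = 1e8,
) -> SeverityModel:
    """Fit the linear severity model on the screened peptides.

    ``screened`` is the output of :func:`screen_spearman` (or a bare id
    list).  The ridge penalty (GCV-chosen) replaces plain OLS when the
    design has p >= n/2 or condition number above ``cond_threshold``.
    Passing ``ridge_lambda=0`` forces OLS, which is refused when p >= n.
    """
    if isinstance(screened, pd.DataFrame):
        ids = [int(i) for i in screened["peptide_id"]]
        rs = [float(v) for v in screened["r"]]
    else:
        ids = [int(i) for i in screened]
        rs = [float("nan")] * len(ids)
    if not ids:
        raise ValueError("no screened peptides to fit")
    response = pd.Series(response).dropna()
    common = matrix.values.index.intersection(response.index)
    n, p = len(common), len(ids)
    if n <= 2:
        raise ValueError("need n > 2 to fit")
    X = np.log1p(matrix.values.loc[common, ids].to_numpy(dtype=float))
    y = response.loc[common].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    yc = y - y.mean()

    if method == "signed-sum":
        coef = np.sign(np.nan_to_num(rs, nan=1.0))
        lam = 0.0
        pred = Z @ coef
        # affine-calibrate the signed sum to the response scale
        denom = float(pred @ pred) or 1.0
        scale = float(pred @ yc) / denom
        coef = coef * scale
    elif method == "ols":
        cond = np.linalg.cond(Z) if min(n, p) > 0 else np.inf
        needs_ridge = (p >= n / 2) or (cond > cond_threshold)
        if ridge_lambda == 0 or not needs_ridge:
            if p >= n and ridge_lambda == 0:
                raise ValueError(
                    f"p={p} >= n={n}: plain least squares is under-determined; "
                    "allow the ridge penalty"
                )
            coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
            lam = 0.0
        elif ridge_lambda is not None:
            lam = float(ridge_lambda)
            coef = np.linalg.solve(Z.T @ Z + lam * np.eye(p), Z.T @ yc)
        else:
            lam, coef = _gcv_ridge(Z, yc)
    else:
        raise ValueError(f"unknown method: {method}")

    fitted = Z @ coef + y.mean()
    pear = float(stats.pearsonr(fitted, y)[0]) if np.ptp(fitted) > 0 else float("nan")
    spear = float(stats.spearmanr(fitted, y)[0]) if np.ptp(fitted) > 0 else float("nan")
    return SeverityModel(
        peptide_ids=ids,
        screening_r=rs,
        intercept=float(y.mean()),
        coef=np.asarray(coef, float),
        feature_mean=mean,
        feature_sd=sd,
        ridge_lambda=float(lam),
        train_pearson=pear,
        train_spearman=spear,
        method=method,
    )


def predict_severity(model: SeverityModel, matrix: IntensityMatrix) -> pd.Series:
    """Affine prediction of htTKV for every sample in the matrix."""
    Z = model.transform(matrix)
    return pd.Series(
        Z @ model.coef + model.intercept, index=matrix.values.index, name="predicted_httkv"
    )


def evaluate_severity(
    model: SeverityModel, matrix: IntensityMatrix, response: pd.Series
) -> dict[str, float]:
    """Pearson and Spearman correlation (with p-values) of predicted vs
    observed htTKV on whichever samples have both."""
    response = pd.Series(response).dropna()
    pred = predict_severity(model, matrix)
    common = pred.index.intersection(response.index)
    obs = response.loc[common].to_numpy()
    est = pred.loc[common].to_numpy()
    pr, pp = stats.pearsonr(est, obs)
    sr, sp = stats.spearmanr(est, obs)
    return dict(
        n=int(len(common)),
        pearson_r=float(pr),
        pearson_p=float(pp),
        spearman_r=float(sr),
        spearman_p=float(sp),
    )
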