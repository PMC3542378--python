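"""Differential-excretion statistics and biomarker candidate selection.

For every consensus peptide detected often enough to be testable, the
two study groups are compared on the natural-log intensities of the
samples in which the peptide was detected, using a Welch (unequal
variance) statistic referred to the standard normal.  The regulation
factor (fold change) is the ratio of group mean intensities computed
over *all* samples, zeros included, matching the convention of
reporting mean signal intensity of cases over controls.  P-values are
adjusted by the Benjamini-Hochberg step-up procedure and markers are
the peptides significant at an FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntensityMatrix


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    For sorted p(1) <= ... <= p(m), adj(i) = min_{j>=i} min(1, (m/j) p(j)),
    returned in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class DiscoveryResult:
    """Per-peptide statistics table plus the settings that produced it."""

    stats: pd.DataFrame
    group_case: str
    group_control: str
    min_freq: float


def differential_stats(
    matrix: IntensityMatrix,
    labels: pd.Series | None = None,
    group_case: str | None = None,
    group_control: str | None = None,
    min_freq: float = 0.3,
) -> DiscoveryResult:
    """Welch-on-ln test, fold change and Mann-Whitney AUC per peptide.

    Peptides are *testable* when detected in >= ``min_freq`` of at least
    one group and at least twice per group.  Untestable peptides keep
    p_raw = 1.  The AUC is the midrank Mann-Whitney probability that a
    case intensity exceeds a control intensity, computed over all
    samples (zeros included).
    """
    labels = labels if labels is not None else matrix.labels
    if labels is None:
        raise ValueError("labels required")
    labels = pd.Series(labels).reindex(matrix.values.index)
    groups = pd.unique(labels.dropna())
    if group_case is None or group_control is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, found {list(groups)}")
        group_case, group_control = ("ADPKD", [g for g in groups if g != "ADPKD"][0]) \
            if "ADPKD" in set(groups) else (groups[0], groups[1])
    case_mask = (labels == group_case).to_numpy()
    ctrl_mask = (labels == group_control).to_numpy()
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValueError("each group needs n >= 2")

    X = matrix.values.to_numpy()
    case, ctrl = X[case_mask], X[ctrl_mask]
    n1, n0 = len(case), len(ctrl)
    d1, d0 = case > 0, ctrl > 0
    k1, k0 = d1.sum(0), d0.sum(0)
    freq1, freq0 = k1 / n1, k0 / n0

    with np.errstate(divide="ignore", invalid="ignore"):
        ln1 = np.where(d1, np.log(np.where(d1, case, 1.0)), np.nan)
        ln0 = np.where(d0, np.log(np.where(d0, ctrl, 1.0)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(d1, ln1, 0.0).sum(0) / np.maximum(k1, 1)
        m0 = np.where(d0, ln0, 0.0).sum(0) / np.maximum(k0, 1)
        m1 = np.where(k1 > 0, m1, np.nan)
        m0 = np.where(k0 > 0, m0, np.nan)
    v1 = _var_detected(ln1, d1, m1, k1)
    v0 = _var_detected(ln0, d0, m0, k0)

    testable = ((freq1 >= min_freq) | (freq0 >= min_freq)) & (k1 >= 2) & (k0 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(v1 / k1 + v0 / k0)
        z = (m1 - m0) / se
    # (near-)constant columns: float accumulation can leave se ~ 1e-16 with an
    # equally tiny mean difference; treat those as carrying no evidence
    eps = 1e-9 * (np.abs(m1) + np.abs(m0) + 1.0)
    degenerate = testable & (np.nan_to_num(se, nan=0.0) <= eps)
    equal_means = np.abs(np.nan_to_num(m1 - m0, nan=0.0)) <= eps
    p_raw = np.ones(X.shape[1])
    ok = testable & ~degenerate & np.isfinite(z)
    p_raw[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    p_raw[degenerate & ~equal_means] = 0.0
    testable = testable & (np.isfinite(z) | degenerate)

    mean1, mean0 = case.mean(0), ctrl.mean(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean0 > 0, mean1 / np.where(mean0 > 0, mean0, 1.0), np.nan)

    auc = _mannwhitney_auc(case, ctrl)

    p_bh = np.ones(X.shape[1])
    if testable.any():
        p_bh[testable] = bh_adjust(p_raw[testable])

    table = pd.DataFrame(
        dict(
            peptide_id=matrix.peptide_ids,
            freq_case=freq1,
            freq_control=freq0,
            fold_change=fold,
            p_raw=p_raw,
            p_bh=p_bh,
            auc=auc,
            direction=np.where(np.nan_to_num(fold, nan=1.0) >= 1.0, "up", "down"),
            testable=testable,
        )
    )
    return DiscoveryResult(
        stats=table, group_case=group_case, group_control=group_control,
        min_freq=min_freq,
    )


def _var_detected(
    lnx: np.ndarray, d: np.ndarray, mean: np.ndarray, k: np.ndarray
) -> np.ndarray:
    """Unbiased variance of detected ln-intensities per column."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(d, (lnx - mean) ** 2, 0.0).sum(0)
        return np.where(k > 1, ss / np.maximum(k - 1, 1), np.nan)


def _mannwhitney_auc(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Column-wise midrank Mann-Whitney AUC of case vs control."""
    n1, n0 = len(case), len(ctrl)
    both = np.concatenate([case, ctrl], axis=0)
    ranks = stats.rankdata(both, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def select_markers(
    result: DiscoveryResult, q_threshold: float = 0.05
) -> list[int]:
    """Peptide ids significant at the FDR threshold, best first."""
    t = result.stats
    hits = t[(t["p_bh"] < q_threshold) & t["testable"]]
    hits = hits.sort_values(["p_bh", "p_raw", "peptide_id"], kind="mergesort")
    return [int(i) for i in hits["peptide_id"]]
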