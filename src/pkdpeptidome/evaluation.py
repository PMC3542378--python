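"""Classifier evaluation: ROC/AUC, exact binomial operating points,
cohort pooling, subgroup tables, clinical correlations, TKV growth.

Conventions: a sample is called positive when score >= cutoff; AUC is
the midrank Mann-Whitney probability (equal to the trapezoidal area of
the midrank ROC curve) with a DeLong variance for its confidence
interval; sensitivity/specificity confidence intervals are exact
binomial (Clopper-Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _binary(labels, positive="ADPKD") -> np.ndarray:
    lab = pd.Series(labels)
    if set(pd.unique(lab)) <= {0, 1, True, False}:
        return lab.astype(int).to_numpy()
    return (lab == positive).astype(int).to_numpy()


def roc_auc(
    scores, labels, positive: str = "ADPKD", alpha: float = 0.05
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Midrank AUC with a DeLong 95% CI and the ROC curve points.

    The AUC equals Mann-Whitney U / (n1 * n0); the variance is DeLong's
    estimator from the per-observation placement values.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary(labels, positive)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # DeLong structural components (placements)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (ranks[y == 1] - r_pos) / n0          # P(score_neg < score_pos) per positive
    v01 = 1.0 - (ranks[y == 0] - r_neg) / n1    # per negative
    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01, ddof=1) / n0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    curve = pd.DataFrame(
        dict(
            threshold=thresholds,
            tpr=[(pos >= t).mean() for t in thresholds],
            fpr=[(neg >= t).mean() for t in thresholds],
        )
    )
    return float(auc), ci, curve


@dataclass
class OperatingPoint:
    """Sensitivity/specificity at a cutoff with exact binomial CIs."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    alpha: float = 0.05

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def sensitivity_ci(self) -> tuple[float, float]:
        return clopper_pearson(self.tp, self.tp + self.fn, self.alpha)

    @property
    def specificity_ci(self) -> tuple[float, float]:
        return clopper_pearson(self.tn, self.tn + self.fp, self.alpha)

    def as_dict(self) -> dict:
        se_ci, sp_ci = self.sensitivity_ci if self.tp + self.fn else (float("nan"),) * 2, \
            self.specificity_ci if self.tn + self.fp else (float("nan"),) * 2
        return dict(
            cutoff=self.cutoff, tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn,
            sensitivity=self.sensitivity, sensitivity_lo=se_ci[0], sensitivity_hi=se_ci[1],
            specificity=self.specificity, specificity_lo=sp_ci[0], specificity_hi=sp_ci[1],
        )


def operating_point(scores, labels, cutoff: float, positive: str = "ADPKD") -> OperatingPoint:
    """Counts and exact 95% CIs at ``cutoff`` (score >= cutoff -> positive)."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels, positive)
    call = s >= cutoff
    return OperatingPoint(
        cutoff=float(cutoff),
        tp=int((call & (y == 1)).sum()),
        fp=int((call & (y == 0)).sum()),
        tn=int((~call & (y == 0)).sum()),
        fn=int((~call & (y == 1)).sum()),
    )


def operating_point_from_counts(
    cutoff: float, tp: int = 0, fp: int = 0, tn: int = 0, fn: int = 0
) -> OperatingPoint:
    """Build an operating point directly from confusion counts (e.g. counts
    published for an external cohort)."""
    return OperatingPoint(cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class CohortResult:
    """One validation cohort's confusion counts at a shared cutoff."""

    name: str
    point: OperatingPoint

    @property
    def n(self) -> int:
        p = self.point
        return p.tp + p.fp + p.tn + p.fn


def pool_cohorts(results: Sequence[CohortResult]) -> OperatingPoint:
    """Sum confusion counts across disjoint cohorts sharing one cutoff and
    recompute the proportions."""
    if not results:
        raise ValueError("no cohorts to pool")
    cuts = {r.point.cutoff for r in results}
    if len(cuts) != 1:
        raise ValueError(f"cohorts use different cutoffs: {sorted(cuts)}")
    return OperatingPoint(
        cutoff=results[0].point.cutoff,
        tp=sum(r.point.tp for r in results),
        fp=sum(r.point.fp for r in results),
        tn=sum(r.point.tn for r in results),
        fn=sum(r.point.fn for r in results),
    )


def subgroup_report(
    scores: pd.Series,
    labels: pd.Series,
    metadata: pd.DataFrame,
    cutoffs: Sequence[float] = (-0.169, -0.250, -0.400),
    positive: str = "ADPKD",
    age_split: float = 30.0,
) -> pd.DataFrame:
    """Sensitivity/specificity per cutoff for all patients and the age and
    genotype subgroups (age dichotomized at 30, upper group inclusive).

    ``metadata`` needs columns age and genotype indexed by sample id.
    Specificity is computed once per cutoff on the full control set;
    sensitivity per subgroup on that subgroup's cases.  Unknown genotypes
    are excluded from genotype columns but count toward "all".
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).reindex(scores.index)
    meta = metadata.reindex(scores.index)
    y = _binary(labels, positive)
    case = pd.Series(y == 1, index=scores.index)
    subgroups = {
        "all": pd.Series(True, index=scores.index),
        f"age<{age_split:g}": meta["age"] < age_split,
        f"age>={age_split:g}": meta["age"] >= age_split,
        "PKD1": meta["genotype"] == "PKD1",
        "PKD2": meta["genotype"] == "PKD2",
    }
    rows = []
    for cut in cutoffs:
        call = scores >= cut
        ctrl = ~case
        spec = float((~call[ctrl]).mean()) if ctrl.any() else float("nan")
        row: dict[str, float] = {"cutoff": cut}
        for name, mask in subgroups.items():
            cases_in = case & mask.fillna(False)
            row[f"sens_{name}"] = (
                float(call[cases_in].mean()) if cases_in.any() else float("nan")
            )
            row[f"spec_{name}"] = spec
        rows.append(row)
    return pd.DataFrame(rows)


CLINICAL_VARIABLES = (
    "tkv", "httkv", "tkv_change_ml_yr", "tkv_change_pct_yr",
    "egfr", "proteinuria", "albuminuria",
)


def correlate_clinical(
    scores: pd.Series, clinical: pd.DataFrame, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Spearman rho and asymptotic p of the score against each clinical
    variable (>= 10 paired observations required; all-missing variables
    are skipped with a note column)."""
    scores = pd.Series(scores)
    variables = list(variables) if variables is not None else [
        v for v in CLINICAL_VARIABLES if v in clinical.columns
    ]
    rows = []
    for var in variables:
        col = clinical[var].reindex(scores.index)
        ok = col.notna() & scores.notna()
        if ok.sum() == 0:
            rows.append(dict(variable=var, n=0, rho=np.nan, p=np.nan, note="all missing"))
            continue
        if ok.sum() < 10:
            rows.append(dict(variable=var, n=int(ok.sum()), rho=np.nan, p=np.nan,
                             note="fewer than 10 paired observations"))
            continue
        rho, p = stats.spearmanr(scores[ok], col[ok])
        rows.append(dict(variable=var, n=int(ok.sum()), rho=float(rho), p=float(p), note=""))
    return pd.DataFrame(rows, columns=["variable", "n", "rho", "p", "note"])


def tkv_growth(
    tkv_series: Sequence[tuple[float, float]],
    height: float,
    min_points: int = 2,
) -> dict[str, float | None]:
    """Height-adjusted TKV plus absolute (ml/yr) and relative (%/yr) growth.

    The absolute rate is the least-squares slope of TKV on time; the
    relative rate is ``(exp(slope of ln TKV) - 1) * 100``.  Rates are
    None with fewer than ``min_points`` measurements; htTKV (first TKV
    over height) is returned regardless when derivable.
    """
    series = sorted((float(t), float(v)) for t, v in tkv_series)
    if not series or not height or height <= 0:
        raise ValueError("need a nonempty TKV series and a positive height")
    httkv = series[0][1] / height
    if len(series) < max(2, min_points):
        return dict(httkv=httkv, abs_rate=None, rel_rate=None)
    t = np.array([p[0] for p in series])
    v = np.array([p[1] for p in series])
    abs_rate = float(np.polyfit(t, v, 1)[0])
    rel_rate = float(np.expm1(np.polyfit(t, np.log(v), 1)[0]) * 100.0)
    return dict(httkv=httkv, abs_rate=abs_rate, rel_rate=rel_rate)
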