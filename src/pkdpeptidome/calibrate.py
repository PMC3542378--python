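"""Internal-standard calibration and cross-sample peptide matching.

CE migration times and electrospray intensities vary run to run, so each
sample is normalized against a panel of internal-standard peptides
("housekeeping" peptides present in essentially every urine):

* time: the least-squares line mapping the sample's observed standard
  times onto the reference times (``t_norm = a * t_raw + b``);
* intensity: the median ratio of reference to observed standard
  intensity, applied multiplicatively.

Calibrated samples are then pooled and clustered into consensus
peptides by a deterministic, mass-ordered greedy pass: a peak joins an
open cluster when it lies within the relative mass tolerance and the
absolute migration-time tolerance of the cluster's intensity-weighted
centroid.  The result is a :class:`~pkdpeptidome.core.PeptideCatalog`
and the samples x peptides :class:`~pkdpeptidome.core.IntensityMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IntensityMatrix, PeptideCatalog, SamplePeakList

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Too few internal standards matched to calibrate a sample."""


@dataclass
class MatchTolerances:
    """Matching windows: relative mass tolerance (default +/-100 ppm) and
    absolute migration-time tolerance in minutes (default +/-0.5 min)."""

    mass_rel: float = 1e-4
    time_abs: float = 0.5

    def __post_init__(self) -> None:
        if self.mass_rel <= 0 or self.time_abs <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class CalibrationRecord:
    sample_id: str
    time_slope: float
    time_intercept: float
    intensity_factor: float
    n_standards_matched: int
    residual_rmse: float


def _match_standards(
    peaks: pd.DataFrame, standards: pd.DataFrame, mass_rel: float
) -> tuple[np.ndarray, np.ndarray]:
    """For each reference standard, find the closest peak by mass within
    the relative tolerance (ties: most intense).  Returns parallel index
    arrays (standard row, peak row); unmatched standards are omitted."""
    mass = peaks["mass"].to_numpy()
    inten = peaks["intensity"].to_numpy()
    s_rows, p_rows = [], []
    for k, (_, srow) in enumerate(standards.iterrows()):
        m0 = srow["mass"]
        lo = np.searchsorted(mass, m0 * (1 - mass_rel))
        hi = np.searchsorted(mass, m0 * (1 + mass_rel), side="right")
        if hi <= lo:
            continue
        cand = np.arange(lo, hi)
        best = cand[np.lexsort((-inten[cand], np.abs(mass[cand] - m0)))][0]
        s_rows.append(k)
        p_rows.append(best)
    return np.asarray(s_rows, dtype=int), np.asarray(p_rows, dtype=int)


def normalize_sample(
    raw: SamplePeakList,
    standards: pd.DataFrame,
    tol: MatchTolerances | None = None,
    min_standards: int = 3,
) -> tuple[SamplePeakList, CalibrationRecord]:
    """Calibrate one sample against the internal-standard reference.

    ``standards`` needs columns mass, time, intensity (reference values).
    Raises :class:`CalibrationError` when fewer than ``min_standards``
    standards are matchable by mass.
    """
    tol = tol or MatchTolerances()
    s_rows, p_rows = _match_standards(raw.peaks, standards, tol.mass_rel)
    if len(s_rows) < min_standards:
        raise CalibrationError(
            f"sample {raw.sample_id}: only {len(s_rows)} internal standards "
            f"matched (need {min_standards})"
        )
    t_obs = raw.peaks["time"].to_numpy()[p_rows]
    t_ref = standards["time"].to_numpy()[s_rows]
    if np.ptp(t_obs) == 0:
        a, b = 1.0, float(t_ref.mean() - t_obs.mean())
    else:
        a, b = np.polyfit(t_obs, t_ref, 1)
    resid = t_ref - (a * t_obs + b)
    rmse = float(np.sqrt(np.mean(resid**2)))
    i_obs = raw.peaks["intensity"].to_numpy()[p_rows]
    i_ref = standards["intensity"].to_numpy()[s_rows]
    s = float(np.median(i_ref / i_obs))

    peaks = raw.peaks.copy()
    peaks["time"] = a * peaks["time"] + b
    peaks["intensity"] = s * peaks["intensity"]
    rec = CalibrationRecord(
        sample_id=raw.sample_id,
        time_slope=float(a),
        time_intercept=float(b),
        intensity_factor=s,
        n_standards_matched=int(len(s_rows)),
        residual_rmse=rmse,
    )
    return SamplePeakList(raw.sample_id, peaks, raw.metadata), rec


def calibrate_cohort(
    samples: Sequence[SamplePeakList],
    standards: pd.DataFrame,
    tol: MatchTolerances | None = None,
    min_standards: int = 3,
) -> tuple[list[SamplePeakList], list[CalibrationRecord], list[str]]:
    """Normalize every sample; samples failing calibration are excluded
    and their ids returned (and logged)."""
    out, recs, failed = [], [], []
    for s in samples:
        try:
            norm, rec = normalize_sample(s, standards, tol, min_standards)
        except CalibrationError as exc:
            log.warning("%s", exc)
            failed.append(s.sample_id)
            continue
        out.append(norm)
        recs.append(rec)
    return out, recs, failed


class _Cluster:
    __slots__ = ("mass", "time", "weight", "members")

    def __init__(self) -> None:
        self.mass = 0.0
        self.time = 0.0
        self.weight = 0.0
        self.members: list[tuple[int, float, float, float]] = []  # (sample, mass, time, int)

    def add(self, sample: int, mass: float, time: float, intensity: float) -> None:
        w = self.weight + intensity
        self.mass = (self.mass * self.weight + mass * intensity) / w
        self.time = (self.time * self.weight + time * intensity) / w
        self.weight = w
        self.members.append((sample, mass, time, intensity))


def match_peptides(
    samples: Sequence[SamplePeakList],
    tol: MatchTolerances | None = None,
) -> tuple[PeptideCatalog, IntensityMatrix]:
    """Cluster calibrated peaks across samples into consensus peptides.

    Peaks are pooled and visited in ascending mass order (ties broken by
    time, intensity, then sample id, so the result does not depend on
    the order samples are supplied in).  A peak joins the open cluster
    whose intensity-weighted centroid is within both tolerances —
    nearest in time when several qualify — otherwise it opens a new
    cluster.  A cluster takes at most one peak per sample; when a sample
    contributes several candidate peaks, the most intense wins.
    """
    tol = tol or MatchTolerances()
    order = np.argsort([s.sample_id for s in samples], kind="mergesort")
    samples = [samples[i] for i in order]
    if not samples or all(len(s) == 0 for s in samples):
        catalog = PeptideCatalog(
            pd.DataFrame(columns=["peptide_id", "mass", "time", "detection_count"]),
            provenance=dict(mass_rel=tol.mass_rel, time_abs=tol.time_abs),
        )
        matrix = IntensityMatrix(
            pd.DataFrame(index=[s.sample_id for s in samples], columns=[], dtype=float),
            labels=_labels_of(samples),
        )
        return catalog, matrix

    pooled = []
    for si, s in enumerate(samples):
        pk = s.peaks
        pooled.append(
            np.column_stack(
                [pk["mass"], pk["time"], pk["intensity"], np.full(len(pk), si)]
            )
        )
    pool = np.concatenate(pooled)
    pool = pool[np.lexsort((pool[:, 3], pool[:, 2], pool[:, 1], pool[:, 0]))]

    open_clusters: list[_Cluster] = []
    closed: list[_Cluster] = []
    for mass, time, inten, si in pool:
        # retire clusters that can no longer match anything (mass-sorted input)
        still_open = []
        for c in open_clusters:
            if mass - c.mass > tol.mass_rel * c.mass:
                closed.append(c)
            else:
                still_open.append(c)
        open_clusters = still_open
        best = None
        best_dt = None
        for c in open_clusters:
            if abs(mass - c.mass) <= tol.mass_rel * c.mass:
                dt = abs(time - c.time)
                if dt <= tol.time_abs and (best is None or dt < best_dt):
                    best, best_dt = c, dt
        if best is None:
            best = _Cluster()
            open_clusters.append(best)
        best.add(int(si), mass, time, inten)
    closed.extend(open_clusters)

    closed.sort(key=lambda c: (c.mass, c.time))
    rows = []
    data = np.zeros((len(samples), len(closed)))
    for pid, c in enumerate(closed, start=1):
        seen: dict[int, float] = {}
        for si, m, t, inten in c.members:
            if si in seen and inten <= seen[si]:
                log.debug("cluster %d: duplicate peak from sample %d dropped", pid, si)
                continue
            seen[si] = inten
        for si, inten in seen.items():
            data[si, pid - 1] = inten
        rows.append(
            dict(peptide_id=pid, mass=c.mass, time=c.time, detection_count=len(seen))
        )

    catalog = PeptideCatalog(
        pd.DataFrame(rows), provenance=dict(mass_rel=tol.mass_rel, time_abs=tol.time_abs)
    )
    matrix = IntensityMatrix(
        pd.DataFrame(
            data,
            index=[s.sample_id for s in samples],
            columns=np.arange(1, len(closed) + 1),
        ),
        labels=_labels_of(samples),
    )
    return catalog, matrix


def _labels_of(samples: Sequence[SamplePeakList]) -> pd.Series | None:
    if not samples or any(s.metadata is None for s in samples):
        return None
    return pd.Series(
        {s.sample_id: s.metadata.diagnosis for s in samples}, dtype=object
    )


def records_to_frame(records: Sequence[CalibrationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
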