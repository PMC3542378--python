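"""Sequence-level utilities for annotated peptides.

Naturally occurring urinary peptides are protease products; their N-
and C-terminal boundaries within the parent protein (cleavage sites)
carry mechanistic information, and two marker sets can be compared by
how many peptides share a parent region or an exact terminus.

Sequences use one-letter amino-acid codes plus lower-case modification
letters: ``p`` hydroxyproline, ``k`` hydroxylysine, ``m`` oxidized
methionine.  At pH 2 (CE running condition) acidic side chains are
protonated and neutral, so a peptide's net charge is the N-terminal
amine plus one per arginine, lysine (hydroxylysine included) and
histidine — and this charge correlates tightly with CE migration time,
which is exploited as a plausibility check on sequence assignments
(observed minus predicted time within +/-1 min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
MODIFIED_RESIDUES = {"p", "k", "m"}  # hydroxy-Pro, hydroxy-Lys, Met-ox
TIME_TOLERANCE_MIN = 1.0


@dataclass
class AnnotatedPeptide:
    """A sequenced peptide with its position in the parent protein."""

    peptide_id: int
    sequence: str
    parent_protein: str | None = None
    start: int | None = None
    stop: int | None = None
    mass: float | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.stop is not None:
            if self.stop < self.start:
                raise ValueError(f"stop {self.stop} < start {self.start}")
            if self.sequence and len(self.sequence) != self.stop - self.start + 1:
                raise ValueError(
                    f"sequence length {len(self.sequence)} inconsistent with "
                    f"positions {self.start}-{self.stop}"
                )

    @property
    def annotated(self) -> bool:
        return (
            self.parent_protein is not None
            and self.start is not None
            and self.stop is not None
        )


def charge_at_ph2(sequence: str) -> int:
    """Net charge at pH 2: the N-terminal amine plus one per R, K/k and H.

    Acidic side chains (D, E) are neutral at pH 2; histidine (pKa ~ 6)
    is fully protonated.  Unknown characters raise a ValueError naming
    the offending position.
    """
    charge = 1  # N-terminal amine
    for i, ch in enumerate(sequence):
        if ch not in STANDARD_RESIDUES and ch not in MODIFIED_RESIDUES:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")
        if ch in ("R", "K", "k", "H"):
            charge += 1
    return charge


@dataclass
class CleavageOverlap:
    n_shared_parent_region: int
    n_shared_terminus: int
    pairs: pd.DataFrame
    n_skipped_a: int
    n_skipped_b: int


def cleavage_overlap(
    set_a: Sequence[AnnotatedPeptide], set_b: Sequence[AnnotatedPeptide]
) -> CleavageOverlap:
    """Compare two annotated marker sets by parent-region and terminus.

    A pair overlaps when the parent proteins match and the [start, stop]
    intervals intersect; a terminus is shared when additionally the
    start (N) or stop (C) positions are equal.  The overlap count is the
    number of peptides of ``set_a`` overlapping at least one peptide of
    ``set_b``; the terminus count is the subset of those sharing a
    terminus.  Unannotated peptides are skipped and counted.
    """
    a_ok = [p for p in set_a if p.annotated]
    b_ok = [p for p in set_b if p.annotated]
    by_parent: dict[str, list[AnnotatedPeptide]] = {}
    for p in b_ok:
        by_parent.setdefault(p.parent_protein, []).append(p)
    rows = []
    overlapped_ids = set()
    terminus_ids = set()
    for p in a_ok:
        for q in by_parent.get(p.parent_protein, ()):
            if p.start <= q.stop and q.start <= p.stop:
                shared_n = p.start == q.start
                shared_c = p.stop == q.stop
                overlapped_ids.add(p.peptide_id)
                if shared_n or shared_c:
                    terminus_ids.add(p.peptide_id)
                rows.append(
                    dict(
                        peptide_id_a=p.peptide_id,
                        peptide_id_b=q.peptide_id,
                        parent_protein=p.parent_protein,
                        shared_n_terminus=shared_n,
                        shared_c_terminus=shared_c,
                    )
                )
    return CleavageOverlap(
        n_shared_parent_region=len(overlapped_ids),
        n_shared_terminus=len(terminus_ids),
        pairs=pd.DataFrame(
            rows,
            columns=[
                "peptide_id_a", "peptide_id_b", "parent_protein",
                "shared_n_terminus", "shared_c_terminus",
            ],
        ),
        n_skipped_a=len(set_a) - len(a_ok),
        n_skipped_b=len(set_b) - len(b_ok),
    )


@dataclass
class MigrationCalibration:
    """Coefficients of ln(time) = b0 + b1 ln(mass) + b2 ln(charge)."""

    beta0: float
    beta1: float
    beta2: float
    residual_rmse: float
    n_calibrants: int


def fit_migration_calibration(
    mass: Sequence[float], charge: Sequence[int], time: Sequence[float]
) -> MigrationCalibration:
    """Least-squares log-log fit of migration time on mass and charge from
    >= 10 calibrant peptides."""
    m = np.asarray(mass, float)
    z = np.asarray(charge, float)
    t = np.asarray(time, float)
    if len(m) < 10:
        raise ValueError(f"need >= 10 calibrants, have {len(m)}")
    if (z < 1).any():
        raise ValueError("charge must be >= 1")
    A = np.column_stack([np.ones_like(m), np.log(m), np.log(z)])
    beta, *_ = np.linalg.lstsq(A, np.log(t), rcond=None)
    resid = np.log(t) - A @ beta
    return MigrationCalibration(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
        residual_rmse=float(np.sqrt(np.mean(resid**2))), n_calibrants=len(m),
    )


def predict_migration_time(
    mass: float, charge: int, calibration: MigrationCalibration
) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return float(
        np.exp(
            calibration.beta0
            + calibration.beta1 * np.log(mass)
            + calibration.beta2 * np.log(charge)
        )
    )


def check_migration_plausibility(
    peptides: Sequence[AnnotatedPeptide],
    calibration: MigrationCalibration,
    tolerance_min: float = TIME_TOLERANCE_MIN,
) -> pd.DataFrame:
    """Flag sequence assignments whose observed CE time deviates from the
    charge/mass prediction by more than the tolerance (default 1 min)."""
    rows = []
    for p in peptides:
        if p.mass is None or p.time is None:
            continue
        z = charge_at_ph2(p.sequence)
        pred = predict_migration_time(p.mass, z, calibration)
        rows.append(
            dict(
                peptide_id=p.peptide_id,
                sequence=p.sequence,
                charge=z,
                observed_time=p.time,
                predicted_time=pred,
                deviation=p.time - pred,
                plausible=abs(p.time - pred) <= tolerance_min,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "sequence", "charge", "observed_time",
            "predicted_time", "deviation", "plausible",
        ],
    )


def read_annotation_table(path) -> list[AnnotatedPeptide]:
    """Annotation TSV columns: peptide_id, sequence, parent_protein, start,
    stop and optionally mass, time."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            AnnotatedPeptide(
                peptide_id=int(row["peptide_id"]),
                sequence=str(row.get("sequence", "")),
                parent_protein=row["parent_protein"] if pd.notna(row.get("parent_protein")) else None,
                start=int(row["start"]) if pd.notna(row.get("start")) else None,
                stop=int(row["stop"]) if pd.notna(row.get("stop")) else None,
                mass=float(row["mass"]) if pd.notna(row.get("mass")) else None,
                time=float(row["time"]) if pd.notna(row.get("time")) else None,
            )
        )
    return out
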