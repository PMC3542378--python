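"""Domain containers and flat-file IO for urinary CE-MS peptide profiles.

A CE-MS run of one urine sample yields a *peak list*: one record per
deconvolved peptide ion, holding its monoisotopic mass (Da), capillary-
electrophoresis migration time (min, on the normalized 18-45 min scale)
and signal intensity (arbitrary units).  Cross-sample matching turns a
collection of calibrated peak lists into a :class:`PeptideCatalog` of
consensus peptides and an :class:`IntensityMatrix` of per-sample
normalized intensities, where 0 encodes "not detected".

All IO is plain TSV/CSV; peak files never contain zero-intensity rows.
Canonical ordering is peaks by (mass, time) and matrix columns by
peptide id, so that a write/read round trip is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: analyzed mass window in Da
MASS_WINDOW = (800.0, 20000.0)

PEAK_COLUMNS = ("sample_id", "mass", "time", "intensity")
METADATA_COLUMNS = ("sample_id", "diagnosis", "age", "sex", "genotype", "height", "egfr")


class PeakTableFormatError(ValueError):
    """A peak/metadata table is structurally invalid (e.g. missing column)."""


class PeakValidationError(ValueError):
    """A record violates a domain invariant; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class SampleMetadata:
    """Clinical annotations attached to one urine sample."""

    diagnosis: str
    age: float | None = None
    sex: str | None = None
    genotype: str = "unknown"
    height: float | None = None
    tkv_series: list[tuple[float, float]] = field(default_factory=list)
    egfr: float | None = None

    @property
    def httkv(self) -> float | None:
        """Height-adjusted total kidney volume (ml/m) from the first TKV
        measurement, or None when height or the TKV series is missing."""
        if not self.tkv_series or not self.height or self.height <= 0:
            return None
        first = min(self.tkv_series, key=lambda p: p[0])
        return first[1] / self.height


@dataclass
class SamplePeakList:
    """One sample's deconvolved peaks plus metadata.

    ``peaks`` is a DataFrame with columns mass/time/intensity, kept sorted
    by (mass, time).  Masses must lie in the analyzed 800-20,000 Da window
    and intensities must be strictly positive.
    """

    sample_id: str
    peaks: pd.DataFrame
    metadata: SampleMetadata | None = None

    def __post_init__(self) -> None:
        pk = pd.DataFrame(self.peaks, columns=["mass", "time", "intensity"], copy=True)
        pk = pk.astype(float)
        if len(pk):
            lo, hi = MASS_WINDOW
            if (pk["mass"] < lo).any() or (pk["mass"] > hi).any():
                bad = pk["mass"][(pk["mass"] < lo) | (pk["mass"] > hi)].iloc[0]
                raise PeakValidationError(
                    f"mass {bad:g} Da outside analyzed window {lo:g}-{hi:g} Da"
                )
            if (pk["intensity"] <= 0).any():
                bad = pk["intensity"][pk["intensity"] <= 0].iloc[0]
                raise PeakValidationError(f"non-positive intensity {bad:g}")
        pk = pk.sort_values(["mass", "time", "intensity"], kind="mergesort")
        self.peaks = pk.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PeptideCatalog:
    """Consensus peptides across samples.

    ``table`` columns: peptide_id (int, unique), mass (consensus Da),
    time (consensus min), detection_count.  ``provenance`` records the
    matching tolerances that produced the catalog.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table, copy=True)
        required = {"peptide_id", "mass", "time", "detection_count"}
        missing = required - set(t.columns)
        if missing:
            raise PeakTableFormatError(f"catalog missing columns: {sorted(missing)}")
        if t["peptide_id"].duplicated().any():
            raise PeakValidationError("duplicate peptide_id in catalog")
        t["peptide_id"] = t["peptide_id"].astype(int)
        t["detection_count"] = t["detection_count"].astype(int)
        self.table = t.sort_values("peptide_id", kind="mergesort").reset_index(drop=True)

    @property
    def peptide_ids(self) -> np.ndarray:
        return self.table["peptide_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class IntensityMatrix:
    """Samples x peptides matrix of normalized intensities (0 = not detected).

    ``values``: DataFrame indexed by sample_id with integer peptide_id
    columns.  ``labels``: diagnosis per sample, aligned with the rows.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        v = pd.DataFrame(self.values, copy=True).astype(float)
        if (v.to_numpy() < 0).any():
            raise PeakValidationError("negative intensity in matrix")
        v.columns = [int(c) for c in v.columns]
        v = v.reindex(columns=sorted(v.columns))
        v.index = v.index.astype(str)
        v.index.name = "sample_id"
        self.values = v
        if self.labels is not None:
            lab = pd.Series(self.labels)
            lab.index = lab.index.astype(str)
            self.labels = lab.reindex(v.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peptide_ids(self) -> list[int]:
        return list(self.values.columns)

    def detection_frequency(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        sub = self.values if sample_ids is None else self.values.loc[list(sample_ids)]
        return (sub > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------


def _sniff_sep(path: str | Path) -> str:
    with open(path, "rt") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{what} is missing required column(s): {missing}")


def read_metadata_table(
    path: str | Path, tkv_path: str | Path | None = None
) -> dict[str, SampleMetadata]:
    """Read per-sample clinical metadata (and optionally a long-format TKV
    series table with columns sample_id, time_years, tkv_ml)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    _require_columns(df, ("sample_id", "diagnosis"), "metadata table")
    tkv: dict[str, list[tuple[float, float]]] = {}
    if tkv_path is not None:
        tv = pd.read_csv(tkv_path, sep=_sniff_sep(tkv_path))
        _require_columns(tv, ("sample_id", "time_years", "tkv_ml"), "TKV table")
        for sid, grp in tv.groupby("sample_id"):
            tkv[str(sid)] = sorted(
                zip(grp["time_years"].astype(float), grp["tkv_ml"].astype(float))
            )

    def _opt(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col]) if col in ("age", "height", "egfr") else row[col]

    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        out[sid] = SampleMetadata(
            diagnosis=str(row["diagnosis"]),
            age=_opt(row, "age"),
            sex=_opt(row, "sex"),
            genotype=str(row["genotype"]) if "genotype" in row and pd.notna(row.get("genotype")) else "unknown",
            height=_opt(row, "height"),
            tkv_series=tkv.get(sid, []),
            egfr=_opt(row, "egfr"),
        )
    return out


def write_metadata_table(
    metadata: Mapping[str, SampleMetadata],
    path: str | Path,
    tkv_path: str | Path | None = None,
) -> None:
    rows = []
    tkv_rows = []
    for sid in metadata:
        md = metadata[sid]
        rows.append(
            dict(
                sample_id=sid,
                diagnosis=md.diagnosis,
                age=md.age,
                sex=md.sex,
                genotype=md.genotype,
                height=md.height,
                egfr=md.egfr,
            )
        )
        for t, v in md.tkv_series:
            tkv_rows.append(dict(sample_id=sid, time_years=t, tkv_ml=v))
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)
    if tkv_path is not None:
        pd.DataFrame(tkv_rows, columns=["sample_id", "time_years", "tkv_ml"]).to_csv(
            tkv_path, sep="\t", index=False
        )


def read_peak_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    tkv_path: str | Path | None = None,
) -> list[SamplePeakList]:
    """Read a long-format peak table into one :class:`SamplePeakList` per sample.

    The file must be tab- or comma-separated with a header naming the
    columns sample_id, mass, time, intensity.  Non-positive intensities
    raise a :class:`PeakValidationError` carrying the 1-based line number.
    Samples are returned sorted by sample_id; peaks in ascending mass.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, PEAK_COLUMNS, "peak table")
    bad = df.index[df["intensity"].astype(float) <= 0]
    if len(bad):
        # +2: 1-based plus header line
        raise PeakValidationError(
            f"non-positive intensity {df.loc[bad[0], 'intensity']}", line=int(bad[0]) + 2
        )
    metadata = (
        read_metadata_table(metadata_path, tkv_path) if metadata_path is not None else {}
    )
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        sid = str(sid)
        out.append(
            SamplePeakList(
                sample_id=sid,
                peaks=grp[["mass", "time", "intensity"]],
                metadata=metadata.get(sid),
            )
        )
    return out


def write_peak_table(samples: Sequence[SamplePeakList], path: str | Path) -> None:
    """Write samples to one long-format TSV (canonical row order)."""
    frames = []
    for s in sorted(samples, key=lambda s: s.sample_id):
        pk = s.peaks.copy()
        pk.insert(0, "sample_id", s.sample_id)
        frames.append(pk)
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(PEAK_COLUMNS))
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_catalog(catalog: PeptideCatalog, path: str | Path) -> None:
    catalog.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_catalog(path: str | Path) -> PeptideCatalog:
    return PeptideCatalog(pd.read_csv(path, sep=_sniff_sep(path)))


def write_matrix(
    matrix: IntensityMatrix,
    path: str | Path,
    catalog: PeptideCatalog | None = None,
    overwrite: bool = False,
) -> None:
    """Write the wide samples x peptides TSV plus an optional sidecar
    catalog TSV (``<path stem>.catalog.tsv``).  Refuses to clobber existing
    files unless ``overwrite`` is set."""
    path = Path(path)
    sidecar = path.with_suffix(".catalog.tsv")
    targets = [path] + ([sidecar] if catalog is not None else [])
    if not overwrite:
        existing = [str(p) for p in targets if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}")
    out = matrix.values.copy()
    if matrix.labels is not None:
        out.insert(0, "diagnosis", matrix.labels)
    out.to_csv(path, sep="\t", float_format="%.8g")
    if catalog is not None:
        write_catalog(catalog, sidecar)


def read_matrix(path: str | Path) -> IntensityMatrix:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    labels = None
    if "diagnosis" in df.columns:
        labels = df.pop("diagnosis")
    return IntensityMatrix(values=df, labels=labels)
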