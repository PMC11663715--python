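"""Data model and I/O for feature tables, MS2 spectra, and sample metadata.

A :class:`FeatureTable` is a validated pandas DataFrame (one row per LC-MS
feature: id, polarity, m/z, retention time in minutes, one intensity column
per sample) paired with :class:`Sample` metadata.  Both ionization modes can
live in one table because polarity is a per-feature column.  MS2 spectra
travel separately in MGF format (via pyteomics), keyed to feature ids.

QC filtering keeps features whose relative standard deviation across pooled
quality-control injections is strictly below a cutoff (default 25%);
weight normalization divides biological-sample intensities by per-sample
tissue weight and is guarded against double application.

Retention time is in minutes everywhere; MGF RTINSECONDS is converted on
read and write.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Sample",
    "FeatureTable",
    "Spectrum",
    "FeatureTableError",
    "read_metadata",
    "write_metadata",
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "qc_filter",
    "normalize_by_weight",
]

FEATURE_COLUMNS = ["id", "polarity", "mz", "rt"]


class FeatureTableError(ValueError):
    """Validation failure in a feature table, metadata, or MGF file."""


@dataclass(frozen=True)
class Sample:
    """One injection: a biological sample or a pooled QC injection.

    ``weight`` is the tissue mass used for extraction (mg); required only
    when weight normalization is applied.  QC injections carry no genotype
    or treatment.
    """

    id: str
    genotype: str | None = None
    treatment: str | None = None
    replicate: int | None = None
    is_qc: bool = False
    weight: float | None = None

    @property
    def group(self) -> str:
        """Composite genotype:treatment group label (biological samples)."""
        return f"{self.genotype}:{self.treatment}"


@dataclass
class Spectrum:
    """An MS2 peak list keyed to a feature.

    Peaks are stored as an (n, 2) float array sorted ascending by m/z, with
    at least one peak and non-negative intensities.
    """

    feature_id: str
    precursor_mz: float
    peaks: np.ndarray
    rt: float | None = None  # minutes

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.shape[0] < 1:
            raise FeatureTableError(f"spectrum {self.feature_id}: no peaks")
        if (peaks[:, 1] < 0).any():
            raise FeatureTableError(f"spectrum {self.feature_id}: negative intensity")
        self.peaks = peaks[np.argsort(peaks[:, 0], kind="stable")]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return self.peaks.shape[0]


@dataclass
class FeatureTable:
    """Feature rows plus the sample metadata their intensity columns map to."""

    data: pd.DataFrame
    samples: dict[str, Sample]
    normalized: bool = False

    def __post_init__(self):
        self.data = _validate(self.data, self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in FEATURE_COLUMNS]

    @property
    def qc_sample_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.samples[s].is_qc]

    @property
    def biological_sample_ids(self) -> list[str]:
        return [s for s in self.sample_ids if not self.samples[s].is_qc]

    @property
    def feature_ids(self) -> list[str]:
        return self.data["id"].tolist()

    def intensities(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Intensity matrix indexed by feature id (missing values are NaN)."""
        cols = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.data.set_index("id")[cols]

    def subset(self, feature_ids: Iterable[str]) -> "FeatureTable":
        keep = set(feature_ids)
        return replace(self, data=self.data[self.data["id"].isin(keep)].reset_index(drop=True))

    def split_polarity(self) -> dict[int, "FeatureTable"]:
        return {
            int(pol): replace(self, data=sub.reset_index(drop=True))
            for pol, sub in self.data.groupby("polarity", sort=True)
        }

    def __len__(self) -> int:
        return len(self.data)


def _validate(df: pd.DataFrame, samples: dict[str, Sample]) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(f"missing required column(s): {missing}")
    df = df.copy()
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FeatureTableError(f"duplicate feature id(s): {dupes[:5]}")
    df["id"] = df["id"].astype(str)
    df["polarity"] = df["polarity"].astype(int)
    if not df["polarity"].isin([1, -1]).all():
        raise FeatureTableError("polarity must be +1 or -1")
    for col in ("mz", "rt"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if len(df) and (df["mz"] <= 0).any():
        raise FeatureTableError("m/z must be positive")
    if len(df) and (df["rt"] < 0).any():
        raise FeatureTableError("retention time must be non-negative")
    sample_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    unknown = [c for c in sample_cols if c not in samples]
    if unknown:
        raise FeatureTableError(f"intensity column(s) without sample metadata: {unknown}")
    for col in sample_cols:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if len(df) and (df[col].dropna() < 0).any():
            raise FeatureTableError(f"negative intensity in sample column {col!r}")
    return df[FEATURE_COLUMNS + sample_cols]


# ---------------------------------------------------------------------------
# Delimited-text I/O

_METADATA_COLUMNS = ["sample_id", "genotype", "treatment", "replicate", "is_qc", "weight"]


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_metadata(path) -> dict[str, Sample]:
    """Read sample metadata CSV/TSV (columns ``sample_id, genotype,
    treatment, replicate, is_qc, weight``; all but sample_id optional)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample_id" not in df.columns:
        raise FeatureTableError("metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FeatureTableError("duplicate sample_id in metadata")
    samples: dict[str, Sample] = {}
    for _, row in df.iterrows():
        def _get(col, cast=lambda x: x):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)

        sid = str(row["sample_id"])
        samples[sid] = Sample(
            id=sid,
            genotype=_get("genotype", str),
            treatment=_get("treatment", str),
            replicate=_get("replicate", int),
            is_qc=bool(_get("is_qc", lambda v: str(v).strip().lower() in ("1", "true", "yes")) or False),
            weight=_get("weight", float),
        )
    return samples


def write_metadata(samples: dict[str, Sample], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.id,
                "genotype": s.genotype,
                "treatment": s.treatment,
                "replicate": s.replicate,
                "is_qc": s.is_qc,
                "weight": s.weight,
            }
            for s in samples.values()
        ]
    ).to_csv(path, index=False)


def read_feature_table(path, metadata_path) -> FeatureTable:
    """Read a delimited feature table plus its sample metadata.

    The delimiter (comma/tab/semicolon) is sniffed from the header line.
    Empty intensity cells become missing values; unparseable cells raise.
    """
    samples = read_metadata(metadata_path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return FeatureTable(df, samples)


def write_feature_table(table: FeatureTable, path, metadata_path=None) -> None:
    table.data.to_csv(path, index=False)
    if metadata_path is not None:
        write_metadata(table.samples, metadata_path)


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path) -> list[Spectrum]:
    """Read MS2 spectra from an MGF file, keyed to feature ids.

    The feature id is taken from a FEATURE_ID parameter if present, else
    TITLE.  RTINSECONDS is converted to minutes.  A block without PEPMASS or
    a repeated feature id is an error.
    """
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for block in reader:
            params = block.get("params", {})
            fid = params.get("feature_id") or params.get("title")
            if fid is None:
                raise FeatureTableError("MGF block without FEATURE_ID or TITLE")
            fid = str(fid)
            if fid in seen:
                raise FeatureTableError(f"duplicate feature id in MGF: {fid}")
            seen.add(fid)
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise FeatureTableError(f"MGF block {fid}: missing PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            rt_s = params.get("rtinseconds")
            rt = float(rt_s) / 60.0 if rt_s is not None else None
            peaks = np.column_stack([block["m/z array"], block["intensity array"]])
            if peaks.shape[0] == 0:
                raise FeatureTableError(f"MGF block {fid}: empty peak list")
            spectra.append(Spectrum(feature_id=fid, precursor_mz=precursor, peaks=peaks, rt=rt))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as standard BEGIN IONS/END IONS MGF blocks."""
    records = []
    for s in spectra:
        params = {"title": s.feature_id, "feature_id": s.feature_id, "pepmass": s.precursor_mz}
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        records.append(
            {"m/z array": s.mz, "intensity array": s.intensities, "params": params}
        )
    _mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# QC filtering and normalization


def qc_filter(
    table: FeatureTable, max_rsd: float = 0.25
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features reproducible across pooled QC injections.

    The relative standard deviation (sample SD with n-1 denominator divided
    by the mean) is computed over the raw QC intensities of each feature;
    a feature survives only if RSD is strictly below ``max_rsd``.  Features
    with zero QC mean, or with fewer than two non-missing QC values, are
    removed (conservatively: they cannot demonstrate reproducibility).

    Returns the filtered table and a report of removed features with their
    RSD and removal reason.
    """
    qc_cols = table.qc_sample_ids
    if len(qc_cols) < 2:
        raise FeatureTableError("qc_filter requires at least 2 QC samples")
    qc = table.data[qc_cols]
    n_obs = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1, skipna=True)
    sd = qc.std(axis=1, ddof=1, skipna=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsd = sd / mean

    reason = pd.Series("", index=table.data.index)
    removed = pd.Series(False, index=table.data.index)
    removed |= n_obs < 2
    reason[n_obs < 2] = "insufficient_qc_values"
    zero_mean = (~removed) & ~(mean > 0)
    removed |= zero_mean
    reason[zero_mean] = "zero_qc_mean"
    high = (~removed) & ~(rsd < max_rsd)
    removed |= high
    reason[high] = "rsd_above_threshold"

    report = pd.DataFrame(
        {
            "id": table.data.loc[removed, "id"],
            "qc_rsd": rsd[removed],
            "reason": reason[removed],
        }
    ).reset_index(drop=True)
    kept = replace(table, data=table.data[~removed].reset_index(drop=True))
    return kept, report


def normalize_by_weight(table: FeatureTable) -> FeatureTable:
    """Divide biological-sample intensities by per-sample tissue weight.

    QC injections (pooled aliquots, no tissue weight of their own) are left
    untouched.  The returned table carries ``normalized=True`` and a second
    application raises, guarding against accidental double normalization.
    """
    if table.normalized:
        raise FeatureTableError("table is already weight-normalized")
    missing = [s for s in table.biological_sample_ids if table.samples[s].weight is None]
    if missing:
        raise FeatureTableError(f"missing tissue weight for sample(s): {missing}")
    df = table.data.copy()
    for sid in table.biological_sample_ids:
        df[sid] = df[sid] / table.samples[sid].weight
    return FeatureTable(df, table.samples, normalized=True)
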