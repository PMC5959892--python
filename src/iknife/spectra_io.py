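"""Spectrum records and tabular / mzML readers.

The pipeline's atomic observation is one *burn*: a single diathermy cut
producing one centroided peak list. The exchange format is deliberately
simple — a long-form peak CSV (``burn_id, mz, intensity``) joined to a
metadata CSV keyed by ``burn_id`` — because the downstream model builder
consumes peak lists, not raw instrument files. mzML 1.1 is supported as a
convenience reader for centroided scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("burn_id", "patient_id", "sample_id", "tissue_class", "mode", "tumour_content")
_REQUIRED_METADATA = ("burn_id", "patient_id", "sample_id", "tissue_class")
PEAK_COLUMNS = ("burn_id", "mz", "intensity")


class PeaklistFormatError(ValueError):
    """A peak or metadata table violates the exchange format."""


@dataclass
class SpectrumRecord:
    """One burn's centroided peak list plus clinical/acquisition metadata.

    Parameters
    ----------
    mz, intensity
        Parallel arrays; m/z strictly increasing, intensities finite and
        non-negative.
    tumour_content
        Viable-tumour percentage from histopathology, in [0, 100];
        ``None`` when not assessed (e.g. non-tumour tissue).
    """

    mz: np.ndarray
    intensity: np.ndarray
    patient_id: str
    sample_id: str
    burn_id: str
    tissue_class: str = "unknown"
    mode: str = "cut"
    tumour_content: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"burn {self.burn_id!r}: m/z values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError(f"burn {self.burn_id!r}: intensities must be finite and non-negative")
        if self.mode not in ("cut", "coagulation"):
            raise ValueError(f"burn {self.burn_id!r}: unknown acquisition mode {self.mode!r}")
        if self.tumour_content is not None and not (0.0 <= self.tumour_content <= 100.0):
            raise ValueError(f"burn {self.burn_id!r}: tumour_content outside [0, 100]")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def replace_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "SpectrumRecord":
        """New record with the same metadata and different peaks."""
        return SpectrumRecord(
            mz=mz, intensity=intensity,
            patient_id=self.patient_id, sample_id=self.sample_id, burn_id=self.burn_id,
            tissue_class=self.tissue_class, mode=self.mode, tumour_content=self.tumour_content,
        )


@dataclass
class CohortTable:
    """A list of spectrum records plus provenance; burn ids are unique."""

    records: list[SpectrumRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.patient_id, r.sample_id, r.burn_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (patient_id, sample_id, burn_id) in cohort")
        burn_ids = [r.burn_id for r in self.records]
        if len(set(burn_ids)) != len(burn_ids):
            raise ValueError("burn_id values must be unique across the cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "burn_id": [r.burn_id for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "sample_id": [r.sample_id for r in self.records],
                "tissue_class": [r.tissue_class for r in self.records],
                "mode": [r.mode for r in self.records],
                "tumour_content": [r.tumour_content for r in self.records],
            }
        )


def read_peaklists(path, metadata_path) -> CohortTable:
    """Read a long-form peak CSV and its metadata CSV into a cohort.

    Every burn appearing in the peak file must have a metadata row; missing
    metadata is a hard error naming the burn ids. Non-numeric peak rows are
    reported with their 1-based line number (header = line 1).
    """
    peaks = pd.read_csv(path, dtype=str)
    meta = pd.read_csv(metadata_path, dtype=str)

    unknown = set(meta.columns) - set(METADATA_COLUMNS)
    if unknown:
        raise PeaklistFormatError(f"unknown metadata columns: {sorted(unknown)}")
    missing_cols = set(_REQUIRED_METADATA) - set(meta.columns)
    if missing_cols:
        raise PeaklistFormatError(f"metadata missing required columns: {sorted(missing_cols)}")
    if set(peaks.columns) != set(PEAK_COLUMNS):
        raise PeaklistFormatError(
            f"peak file columns must be {list(PEAK_COLUMNS)}, got {list(peaks.columns)}"
        )
    if peaks.empty:
        return CohortTable(records=[], provenance={"source": str(path)})

    for col in ("mz", "intensity"):
        numeric = pd.to_numeric(peaks[col], errors="coerce")
        bad = numeric.isna() & peaks[col].notna() | peaks[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise PeaklistFormatError(f"non-numeric {col!r} value at line {line} of {path}")
        peaks[col] = numeric

    meta = meta.set_index("burn_id", drop=False)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise PeaklistFormatError(f"duplicate metadata rows for burns: {dup}")

    missing = [b for b in peaks["burn_id"].unique() if b not in meta.index]
    if missing:
        raise PeaklistFormatError(f"no metadata for burns: {missing}")

    records = []
    for burn_id, grp in peaks.groupby("burn_id", sort=False):
        row = meta.loc[burn_id]
        order = np.argsort(grp["mz"].to_numpy(), kind="stable")
        tc = row.get("tumour_content")
        records.append(
            SpectrumRecord(
                mz=grp["mz"].to_numpy()[order],
                intensity=grp["intensity"].to_numpy()[order],
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                burn_id=str(burn_id),
                tissue_class=str(row["tissue_class"]),
                mode=str(row["mode"]) if "mode" in row and pd.notna(row["mode"]) else "cut",
                tumour_content=float(tc) if tc is not None and pd.notna(tc) else None,
            )
        )
    return CohortTable(records=records, provenance={"source": str(path), "metadata": str(metadata_path)})


def write_peaklists(cohort: CohortTable, path, metadata_path) -> None:
    """Write a cohort back to the long-form peak + metadata CSV pair."""
    rows = {
        "burn_id": np.concatenate([[r.burn_id] * r.n_peaks for r in cohort.records]) if len(cohort) else [],
        "mz": np.concatenate([r.mz for r in cohort.records]) if len(cohort) else [],
        "intensity": np.concatenate([r.intensity for r in cohort.records]) if len(cohort) else [],
    }
    pd.DataFrame(rows, columns=list(PEAK_COLUMNS)).to_csv(path, index=False, float_format="%.10g")
    cohort.metadata_frame().to_csv(metadata_path, index=False)


_MZML_ACCESSIONS = {
    "MS:1000127": "centroid",
    "MS:1000128": "profile",
    "MS:1000514": "mz_array",
    "MS:1000515": "intensity_array",
    "MS:1000521": "float32",
    "MS:1000523": "float64",
    "MS:1000574": "zlib",
    "MS:1000576": "no_compression",
}


def _decode_binary_array(elem, ns: str) -> tuple[str | None, np.ndarray]:
    import base64
    import zlib

    flags = {
        _MZML_ACCESSIONS[p.get("accession")]
        for p in elem.iter(f"{ns}cvParam")
        if p.get("accession") in _MZML_ACCESSIONS
    }
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "zlib" in flags:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "float32" in flags else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz_array" if "mz_array" in flags else (
        "intensity_array" if "intensity_array" in flags else None)
    return kind, values


def read_mzml(path) -> list[SpectrumRecord]:
    """Read centroided scans from an mzML 1.1 file (metadata-less records).

    A compact reader for the mzML subset the pipeline consumes: per-scan
    base64 (optionally zlib) 32/64-bit float m/z and intensity arrays.
    Each scan becomes one record with ids synthesised from the scan index;
    profile-mode scans are rejected — centroid upstream first.
    """
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    root = ET.parse(str(path)).getroot()
    spectra = root.iter(f"{ns}spectrum")
    records = []
    for i, spectrum in enumerate(spectra):
        modes = {
            _MZML_ACCESSIONS.get(p.get("accession"))
            for p in spectrum.findall(f"{ns}cvParam")
        }
        if "profile" in modes:
            raise PeaklistFormatError(
                f"scan {i} of {path} is profile-mode; centroid the data before import"
            )
        arrays = {}
        for array_elem in spectrum.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(array_elem, ns)
            if kind:
                arrays[kind] = values
        if "mz_array" not in arrays or "intensity_array" not in arrays:
            raise PeaklistFormatError(f"scan {i} of {path} lacks m/z or intensity arrays")
        mz = arrays["mz_array"]
        order = np.argsort(mz, kind="stable")
        records.append(
            SpectrumRecord(
                mz=mz[order], intensity=arrays["intensity_array"][order],
                patient_id="unknown", sample_id="unknown", burn_id=f"scan{i}",
            )
        )
    return records
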