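"""Raw peak lists -> binned, normalised feature matrix.

Per spectrum, in order: single-point lock-mass recalibration (constant
additive shift to the most intense peak near the reference mass),
low-quantile background subtraction, accumulation onto a fixed 0.1 Da
grid over the 600-1000 m/z analysis window, and total-ion-current (TIC)
normalisation. Spectra with essentially no in-window signal are
QC-rejected rather than normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import CohortTable, SpectrumRecord

logger = logging.getLogger(__name__)

#: internal phospholipid lock mass used for frozen-tissue work (m/z, negative mode)
INTERNAL_LOCK_MASS = 699.497
#: leucine-enkephalin external lock mass (negative mode)
EXTERNAL_LOCK_MASS = 554.2615

DEFAULT_SEARCH_WINDOW = 0.3
DEFAULT_BACKGROUND_QUANTILE = 0.05
DEFAULT_SIGNAL_FLOOR = 10.0


@dataclass(frozen=True)
class BinGrid:
    """Fixed m/z grid: left-closed right-open bins labelled by lower edge."""

    lower: float = 600.0
    upper: float = 1000.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if not (self.upper > self.lower and self.width > 0):
            raise ValueError("require upper > lower and width > 0")
        n = (self.upper - self.lower) / self.width
        if abs(n - round(n)) > 1e-6:
            raise ValueError("(upper - lower) / width must be an exact integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.upper - self.lower) / self.width))

    @property
    def labels(self) -> np.ndarray:
        """Lower bin edges, rounded to kill float noise in labels."""
        return np.round(self.lower + np.arange(self.n_bins) * self.width, 6)

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z; -1 for out-of-window peaks.

        A half-ulp nudge keeps values that are exactly on an edge (up to
        float representation error, ~1e-7 Da here) in the right-hand bin.
        """
        q = (np.asarray(mz, dtype=float) - self.lower) / self.width
        idx = np.floor(q + 1e-6).astype(int)
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx


@dataclass
class FeatureMatrix:
    """Binned, normalised spectra (rows) x m/z bins (columns) with metadata.

    ``intensities`` is indexed by burn_id with bin lower edges as columns;
    ``metadata`` shares the index. QC-rejected burns are absent from both
    and listed in ``rejected``.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    grid: BinGrid
    normalization: str = "tic"
    rejected: list = field(default_factory=list)
    lock_shifts: dict = field(default_factory=dict)

    @property
    def classes(self) -> list:
        return sorted(self.metadata["tissue_class"].unique())

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy()

    def to_csv(self, path) -> None:
        """Export metadata columns followed by bins labelled to one decimal."""
        out = self.metadata.copy()
        binned = self.intensities.copy()
        binned.columns = [f"{c:.1f}" for c in binned.columns]
        pd.concat([out, binned], axis=1).to_csv(path, index_label="burn_id")


def lock_mass_correct(
    spectrum: SpectrumRecord,
    reference: float = INTERNAL_LOCK_MASS,
    search_window: float = DEFAULT_SEARCH_WINDOW,
) -> tuple[SpectrumRecord, float | None]:
    """Recalibrate all m/z by the offset of the lock-mass peak.

    The most intense peak within ``reference +/- search_window`` is taken as
    the lock mass; ``observed - reference`` is subtracted from every m/z.
    Returns the corrected record and the applied shift (``None`` with a
    logged warning when no candidate peak is found — the spectrum is then
    returned unchanged).
    """
    if search_window <= 0:
        raise ValueError("search_window must be positive")
    near = np.abs(spectrum.mz - reference) <= search_window
    if not near.any():
        logger.warning("burn %s: no lock-mass peak within %.3f of %.4f; spectrum left uncorrected",
                       spectrum.burn_id, search_window, reference)
        return spectrum, None
    candidates = np.flatnonzero(near)
    observed = spectrum.mz[candidates[np.argmax(spectrum.intensity[candidates])]]
    shift = float(observed - reference)
    return spectrum.replace_peaks(spectrum.mz - shift, spectrum.intensity), shift


def subtract_background(
    spectrum: SpectrumRecord,
    quantile: float = DEFAULT_BACKGROUND_QUANTILE,
    window: tuple[float, float] = (600.0, 1000.0),
) -> SpectrumRecord:
    """Subtract a per-spectrum low-quantile baseline and drop emptied peaks.

    The baseline is the given quantile of intensities of peaks inside the
    analysis window; all intensities are reduced by it and clipped at zero,
    and zero-intensity peaks are removed.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must lie in [0, 1)")
    if spectrum.n_peaks == 0:
        return spectrum
    in_window = (spectrum.mz >= window[0]) & (spectrum.mz < window[1])
    if not in_window.any():
        return spectrum
    baseline = float(np.quantile(spectrum.intensity[in_window], quantile))
    reduced = np.clip(spectrum.intensity - baseline, 0.0, None)
    keep = reduced > 0
    return spectrum.replace_peaks(spectrum.mz[keep], reduced[keep])


def bin_spectrum(spectrum: SpectrumRecord, grid: BinGrid) -> np.ndarray:
    """Accumulate peak intensities onto the grid; out-of-window peaks are dropped."""
    vec = np.zeros(grid.n_bins)
    idx = grid.bin_index(spectrum.mz)
    keep = idx >= 0
    np.add.at(vec, idx[keep], spectrum.intensity[keep])
    return vec


def normalize_tic(vector: np.ndarray, signal_floor: float = DEFAULT_SIGNAL_FLOOR) -> tuple[np.ndarray, bool]:
    """Divide by total ion current; flag QC rejection when signal is too low.

    Returns ``(normalised_vector, rejected)``. A raw in-window total below
    ``signal_floor`` counts (default 10) marks the spectrum as having no
    interpretable signal; the vector is returned unscaled in that case.
    """
    vector = np.asarray(vector, dtype=float)
    if np.any(vector < 0):
        raise ValueError("binned intensities must be non-negative")
    total = float(vector.sum())
    if total < signal_floor:
        return vector.copy(), True
    return vector / total, False


def build_feature_matrix(
    cohort: CohortTable,
    grid: BinGrid | None = None,
    lockmass: float = INTERNAL_LOCK_MASS,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    background_quantile: float = DEFAULT_BACKGROUND_QUANTILE,
    signal_floor: float = DEFAULT_SIGNAL_FLOOR,
) -> FeatureMatrix:
    """Full preprocessing: lock-mass -> background -> binning -> TIC per spectrum."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    grid = grid or BinGrid()

    rows, index, rejected, shifts = [], [], [], {}
    for rec in cohort:
        corrected, shift = lock_mass_correct(rec, lockmass, search_window)
        shifts[rec.burn_id] = shift
        cleaned = subtract_background(corrected, background_quantile, (grid.lower, grid.upper))
        vec = bin_spectrum(cleaned, grid)
        normed, reject = normalize_tic(vec, signal_floor)
        if reject:
            logger.warning("burn %s: QC-rejected (in-window signal %.3g below floor %.3g)",
                           rec.burn_id, vec.sum(), signal_floor)
            rejected.append(rec.burn_id)
            continue
        rows.append(normed)
        index.append(rec.burn_id)

    if not rows:
        raise ValueError("all spectra were QC-rejected")
    intensities = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="burn_id"),
                               columns=grid.labels)
    metadata = cohort.metadata_frame().set_index("burn_id").loc[index]
    return FeatureMatrix(intensities=intensities, metadata=metadata, grid=grid,
                         normalization="tic", rejected=rejected, lock_shifts=shifts)
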