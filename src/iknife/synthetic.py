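"""Synthetic REIMS cohorts with known ground truth.

Real diathermy-aerosol spectra are dominated by a handful of abundant
glycerophospholipid peaks riding on a low chemical background, with
intensities that co-vary within a patient and drift slightly in mass
calibration between burns. The generator emulates exactly that structure
so every downstream stage (lock-mass correction, binning, PC-LDA, LOPOCV,
univariate discovery) can be tested against a planted truth:

  intensity(template t, class c) =
      base(t) * fold(t, c) * exp(patient effect) * exp(burn noise)

with a single shared log-normal patient offset (the source of
within-patient correlation that makes leave-one-patient-out CV strictly
harder than spectrum-level CV), i.i.d. log-normal burn noise per peak,
uniform low-amplitude background peaks, and a per-spectrum constant m/z
calibration offset that the lock-mass peak allows downstream code to undo
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import BinGrid
from .spectra_io import CohortTable, SpectrumRecord

#: discriminant peak locations used by default (Da); the five lipid ions
#: that separate ovarian cancer from non-cancer tissue classes
DISCRIMINANT_MASSES = (673.481, 685.517, 699.497, 742.539, 744.555)

DEFAULT_CLASSES = ("ovarian_cancer", "borderline", "normal")
DEFAULT_LOCK_MASS = 699.497
ANALYSIS_WINDOW = (600.0, 1000.0)


@dataclass(frozen=True)
class LipidTemplate:
    """One reproducible peak: location, abundance and per-class fold change."""

    mz: float
    base_intensity: float
    class_fold_change: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if any(f <= 0 for f in self.class_fold_change.values()):
            raise ValueError("fold changes must be positive")

    def fold(self, tissue_class: str) -> float:
        return float(self.class_fold_change.get(tissue_class, 1.0))

    @property
    def discriminant(self) -> bool:
        folds = set(self.class_fold_change.values())
        return len(folds - {1.0}) > 0


def default_templates(
    classes: tuple = DEFAULT_CLASSES,
    discriminant_fold: float = 4.0,
    high_class: str | None = None,
) -> list[LipidTemplate]:
    """Twenty templates: 5 discriminant (fold 4) + 15 flat.

    All five discriminant peaks are elevated in the cancer class; the two
    that separate cancer from borderline tumours in real spectra (685.517
    and 742.539) are also elevated in the borderline class, reflecting its
    intermediate biology — this gives each class its own lipid signature so
    all class pairs are separable. The 699.497 peak gets the highest base
    intensity: it doubles as the internal lock mass and must dominate its
    neighbourhood in every class.
    """
    high_class = classes[0] if high_class is None else high_class
    mid_class = classes[1] if len(classes) > 1 else None
    base = {673.481: 300.0, 685.517: 200.0, 699.497: 800.0, 742.539: 250.0, 744.555: 600.0}
    shared_with_mid = (685.517, 742.539)
    templates = []
    for m, b in base.items():
        folds = {high_class: discriminant_fold}
        if mid_class is not None and m in shared_with_mid:
            folds[mid_class] = discriminant_fold
        templates.append(LipidTemplate(mz=m, base_intensity=b, class_fold_change=folds))
    rng = np.random.default_rng(20140101)  # fixed: templates are part of the scenario
    flat_mz = np.sort(rng.uniform(605.0, 995.0, size=15))
    flat_mz = flat_mz[np.all(np.abs(flat_mz[:, None] - np.array(list(base))) > 0.5, axis=1)]
    while flat_mz.size < 15:  # unlikely; refill away from the discriminant peaks
        extra = rng.uniform(605.0, 995.0, size=15 - flat_mz.size)
        extra = extra[np.all(np.abs(extra[:, None] - np.array(list(base))) > 0.5, axis=1)]
        flat_mz = np.sort(np.concatenate([flat_mz, extra]))
    intensities = rng.uniform(50.0, 400.0, size=flat_mz.size)
    templates += [LipidTemplate(mz=float(m), base_intensity=float(i))
                  for m, i in zip(flat_mz, intensities)]
    return templates


@dataclass
class SyntheticConfig:
    """Scenario definition; the defaults are the package's standard test bed.

    3 classes x 10 patients x 2 samples x 3 burns, five discriminant lipids
    at fold change 4 in the cancer class, patient effect SD 0.2 and burn
    noise SD 0.1 on the log-intensity scale, calibration drift SD 0.02 Da
    and background amplitude 1% of the median template intensity.
    """

    classes: tuple = DEFAULT_CLASSES
    patients_per_class: int = 10
    samples_per_patient: int = 2
    burns_per_sample: int = 3
    templates: list = field(default_factory=default_templates)
    patient_sd: float = 0.2
    burn_sd: float = 0.1
    background_amplitude: float | None = None  # None -> 1% of median base intensity
    n_background_peaks: int = 100
    drift_sd: float = 0.02
    lock_mass: float = DEFAULT_LOCK_MASS
    seed: int = 0
    cancer_class: str | None = "ovarian_cancer"
    window: tuple = ANALYSIS_WINDOW

    def __post_init__(self) -> None:
        if min(self.patients_per_class, self.samples_per_patient, self.burns_per_sample) < 1:
            raise ValueError("patient/sample/burn counts must be >= 1")
        if min(self.patient_sd, self.burn_sd, self.drift_sd) < 0:
            raise ValueError("all SDs must be non-negative")
        if self.background_amplitude is not None and self.background_amplitude < 0:
            raise ValueError("background_amplitude must be >= 0")
        lo, hi = self.window
        bad = [t.mz for t in self.templates if not (lo <= t.mz < hi)]
        if bad:
            raise ValueError(f"template m/z outside analysis window [{lo}, {hi}): {bad}")

    @property
    def resolved_background_amplitude(self) -> float:
        if self.background_amplitude is not None:
            return self.background_amplitude
        return 0.01 * float(np.median([t.base_intensity for t in self.templates]))

    @property
    def n_spectra(self) -> int:
        return len(self.classes) * self.patients_per_class * self.samples_per_patient \
            * self.burns_per_sample


def _merge_sorted(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and sum intensities of exactly coincident peaks."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, intensity)
    return uniq, summed


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Simulate the full cohort; byte-for-byte reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    template_mz = np.array([t.mz for t in config.templates])
    base = np.array([t.base_intensity for t in config.templates])
    amp = config.resolved_background_amplitude
    lock_is_template = bool(np.any(np.abs(template_mz - config.lock_mass) < 1e-9))
    lock_intensity = 2.0 * float(base.max())
    lo, hi = config.window

    records = []
    for cls in config.classes:
        folds = np.array([t.fold(cls) for t in config.templates])
        for p in range(config.patients_per_class):
            patient_id = f"{cls}-P{p + 1:02d}"
            patient_effect = rng.normal(0.0, config.patient_sd) if config.patient_sd > 0 else 0.0
            tumour = float(rng.uniform(60.0, 100.0)) if cls == config.cancer_class else None
            for s in range(config.samples_per_patient):
                sample_id = f"{patient_id}-S{s + 1}"
                for b in range(config.burns_per_sample):
                    burn_id = f"{sample_id}-B{b + 1}"
                    noise = rng.normal(0.0, config.burn_sd, size=base.size) \
                        if config.burn_sd > 0 else np.zeros(base.size)
                    inten = base * folds * np.exp(patient_effect) * np.exp(noise)
                    mz = template_mz.copy()
                    if not lock_is_template:
                        mz = np.append(mz, config.lock_mass)
                        inten = np.append(inten, lock_intensity)
                    if amp > 0 and config.n_background_peaks > 0:
                        bg_mz = rng.uniform(lo, hi, size=config.n_background_peaks)
                        bg_int = rng.exponential(amp, size=config.n_background_peaks)
                        mz = np.concatenate([mz, bg_mz])
                        inten = np.concatenate([inten, bg_int])
                    drift = rng.normal(0.0, config.drift_sd) if config.drift_sd > 0 else 0.0
                    mz, inten = _merge_sorted(mz + drift, inten)
                    records.append(SpectrumRecord(
                        mz=mz, intensity=inten,
                        patient_id=patient_id, sample_id=sample_id, burn_id=burn_id,
                        tissue_class=cls, mode="cut", tumour_content=tumour,
                    ))
    return CohortTable(records=records,
                       provenance={"generator": "iknife.synthetic", "seed": config.seed})


def ground_truth(config: SyntheticConfig, class_a: str, class_b: str,
                 grid: BinGrid | None = None) -> dict:
    """Expected median log2 fold change per template bin, class_a over class_b."""
    for c in (class_a, class_b):
        if c not in config.classes:
            raise KeyError(f"unknown class label {c!r}")
    grid = grid or BinGrid()
    truth = {}
    for t in config.templates:
        idx = grid.bin_index(np.array([t.mz]))[0]
        if idx < 0:
            continue
        label = float(grid.labels[idx])
        truth[label] = float(np.log2(t.fold(class_a) / t.fold(class_b)))
    return truth


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """The same scenario with every stochastic term switched off."""
    return replace(config, patient_sd=0.0, burn_sd=0.0, drift_sd=0.0,
                   background_amplitude=0.0)
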