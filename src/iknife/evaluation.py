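"""Leave-one-patient-out cross-validation and headline metrics.

LOPOCV holds out *all* spectra of one patient per fold, so within-patient
correlation can never leak between training and test sets. Sample-level
calls aggregate a sample's burns by majority vote (ties broken by mean
posterior). Sensitivity/specificity are one-vs-rest; percentages are
reported half-up to one decimal, matching clinical reporting style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .preprocess import BinGrid, build_feature_matrix, FeatureMatrix, INTERNAL_LOCK_MASS, \
    DEFAULT_SEARCH_WINDOW, DEFAULT_BACKGROUND_QUANTILE, DEFAULT_SIGNAL_FLOOR
from .pclda import fit_pclda, predict, RecognitionResult, DEFAULT_N_PCS, DEFAULT_RIDGE
from .spectra_io import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_TUMOUR_CONTENT = 50.0


def round_pct(fraction: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding (38/39 -> 97.4, not banker's 97.44->97.4)."""
    return float(Decimal(str(fraction * 100)).quantize(Decimal(f"1.{'0' * decimals}"),
                                                       rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square true x predicted count table at a stated aggregation level."""

    table: pd.DataFrame  # rows = true class, cols = predicted class
    level: str = "sample"

    def __post_init__(self) -> None:
        if list(self.table.index) != list(self.table.columns):
            raise ValueError("confusion table must have identical row and column labels")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, true, predicted, classes=None, level="sample") -> "ConfusionMatrix":
        true = pd.Series(list(true))
        predicted = pd.Series(list(predicted))
        classes = sorted(set(true) | set(predicted)) if classes is None else list(classes)
        tab = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(true, predicted):
            tab.loc[t, p] += 1
        return cls(table=tab, level=level)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def sensitivity(self, cls_label) -> float | None:
        row = self.table.loc[cls_label]
        n = int(row.sum())
        return None if n == 0 else float(row[cls_label] / n)

    def specificity(self, cls_label) -> float | None:
        """True-negative rate with all other classes pooled (one-vs-rest)."""
        others = [c for c in self.table.index if c != cls_label]
        negatives = int(self.table.loc[others].to_numpy().sum())
        if negatives == 0:
            return None
        true_neg = int(self.table.loc[others, others].to_numpy().sum())
        return float(true_neg / negatives)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.table.to_numpy()) / self.total)


def metrics(confusion: ConfusionMatrix) -> dict:
    """Per-class sensitivity/specificity and overall accuracy.

    Returns raw fractions plus percentages rounded half-up to 1 decimal.
    Classes with zero true (or zero negative) instances report ``None``.
    """
    if confusion.total == 0:
        raise ValueError("empty confusion table")
    per_class = {}
    for c in confusion.table.index:
        sens = confusion.sensitivity(c)
        spec = confusion.specificity(c)
        per_class[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "sensitivity_pct": None if sens is None else round_pct(sens),
            "specificity_pct": None if spec is None else round_pct(spec),
        }
    acc = confusion.overall_accuracy
    return {"per_class": per_class, "overall_accuracy": acc,
            "overall_accuracy_pct": round_pct(acc), "level": confusion.level}


def filter_low_tumour(
    cohort: CohortTable,
    min_content: float = DEFAULT_MIN_TUMOUR_CONTENT,
    cancer_classes: tuple = ("ovarian_cancer",),
) -> tuple[CohortTable, list]:
    """Drop cancer-class burns whose viable-tumour content is below threshold.

    Strict inequality: exactly ``min_content`` is retained. Cancer burns with
    missing content fail with a warning; non-cancer classes are untouched.
    Returns the filtered cohort and the excluded burn ids.
    """
    if not (0.0 <= min_content <= 100.0):
        raise ValueError("min_content must lie in [0, 100]")
    kept, excluded = [], []
    for rec in cohort:
        if rec.tissue_class in cancer_classes:
            if rec.tumour_content is None:
                logger.warning("burn %s: cancer burn with missing tumour content excluded", rec.burn_id)
                excluded.append(rec.burn_id)
                continue
            if rec.tumour_content < min_content:
                excluded.append(rec.burn_id)
                continue
        kept.append(rec)
    if excluded:
        logger.info("excluded %d low-tumour-content burns", len(excluded))
    return CohortTable(records=kept, provenance=dict(cohort.provenance)), excluded


@dataclass
class CVReport:
    """Per-burn LOPOCV assignments plus spectrum- and sample-level confusion."""

    assignments: pd.DataFrame
    confusion_spectrum: ConfusionMatrix
    confusion_sample: ConfusionMatrix
    degenerate_folds: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    @property
    def sample_accuracy(self) -> float:
        return self.confusion_sample.overall_accuracy

    @property
    def spectrum_accuracy(self) -> float:
        return self.confusion_spectrum.overall_accuracy


def _sample_vote(group: pd.DataFrame, classes) -> str:
    """Majority vote over a sample's burns; ties broken by mean posterior."""
    counts = group["predicted"].value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1:
        return top[0]
    mean_post = {c: group[f"posterior_{c}"].mean() for c in top}
    return max(sorted(top), key=lambda c: mean_post[c])


def lopocv(
    cohort: CohortTable,
    grid: BinGrid | None = None,
    n_pcs: int = DEFAULT_N_PCS,
    ridge: float = DEFAULT_RIDGE,
    priors="equal",
    lockmass: float = INTERNAL_LOCK_MASS,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    background_quantile: float = DEFAULT_BACKGROUND_QUANTILE,
    signal_floor: float = DEFAULT_SIGNAL_FLOOR,
    threshold: float = 0.0,
) -> CVReport:
    """Leave-one-patient-out cross-validation of the PC-LDA model.

    One fold per patient: the model is refit on all other patients' spectra
    and the held-out patient's burns are predicted. Preprocessing is strictly
    per-spectrum, so the feature matrix is built once without leakage.
    A fold whose patient carries a class absent from its training set is
    logged as degenerate and those burns are excluded from the confusions.
    """
    matrix = build_feature_matrix(cohort, grid, lockmass, search_window,
                                  background_quantile, signal_floor)
    meta = matrix.metadata
    patients = sorted(meta["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError("LOPOCV needs at least 3 patients")
    class_patients = meta.groupby("tissue_class")["patient_id"].nunique()
    if (class_patients < 2).any():
        bad = class_patients[class_patients < 2].index.tolist()
        raise ValueError(f"every class needs >= 2 patients; offending: {bad}")

    X = matrix.values()
    rows = []
    degenerate = []
    for patient in patients:
        test_mask = (meta["patient_id"] == patient).to_numpy()
        train_meta = meta.loc[~test_mask]
        train = FeatureMatrix(
            intensities=matrix.intensities.loc[~test_mask],
            metadata=train_meta, grid=matrix.grid, normalization=matrix.normalization,
        )
        model = fit_pclda(train, n_pcs=n_pcs, ridge=ridge, priors=priors)
        train_classes = set(model.classes)
        held = meta.loc[test_mask]
        missing = set(held["tissue_class"]) - train_classes
        if missing:
            degenerate.append({"patient_id": patient, "missing_classes": sorted(missing)})
            logger.warning("fold %s degenerate: class(es) %s absent from training set",
                           patient, sorted(missing))
        for burn, x, (_, m) in zip(held.index, X[test_mask], held.iterrows()):
            res = predict(model, x, threshold=threshold, burn_id=str(burn))
            row = {
                "burn_id": burn, "patient_id": patient, "sample_id": m["sample_id"],
                "true": m["tissue_class"], "predicted": res.predicted,
                "reliability": res.reliability, "reported": res.reported,
                "degenerate": m["tissue_class"] in missing,
            }
            for c, p in res.posteriors.items():
                row[f"posterior_{c}"] = p
            rows.append(row)

    assignments = pd.DataFrame(rows)
    valid = assignments.loc[~assignments["degenerate"]]
    classes = sorted(meta["tissue_class"].unique())
    conf_spec = ConfusionMatrix.from_labels(valid["true"], valid["predicted"],
                                            classes=classes, level="spectrum")
    sample_rows = []
    for (pat, samp), grp in valid.groupby(["patient_id", "sample_id"]):
        sample_rows.append({"true": grp["true"].iloc[0],
                            "predicted": _sample_vote(grp.fillna(0.0), classes)})
    sample_df = pd.DataFrame(sample_rows)
    conf_samp = ConfusionMatrix.from_labels(sample_df["true"], sample_df["predicted"],
                                            classes=classes, level="sample")
    return CVReport(assignments=assignments, confusion_spectrum=conf_spec,
                    confusion_sample=conf_samp, degenerate_folds=degenerate,
                    excluded=matrix.rejected)


def recognition_summary(results: list[RecognitionResult], truth: dict | list,
                        threshold: float = 0.75) -> dict:
    """Reported fraction and accuracy among reported calls.

    ``truth`` maps burn_id -> true class (or is a parallel list). A call is
    reported when its reliability reaches the threshold; accuracy is
    computed over reported calls only (undefined when none are reported).
    """
    if not (0.0 <= threshold < 1.0 or threshold == 0):
        raise ValueError("threshold must lie in [0, 1)")
    if not isinstance(truth, dict):
        truth = {r.burn_id: t for r, t in zip(results, truth)}
    total = len(results)
    if total == 0:
        raise ValueError("no recognition results")
    reported = [r for r in results if r.reliability >= threshold]
    correct = sum(1 for r in reported if r.predicted == truth[r.burn_id])
    out = {
        "n_total": total,
        "n_reported": len(reported),
        "n_correct_reported": correct,
        "reported_fraction": len(reported) / total,
        "reported_fraction_pct": round_pct(len(reported) / total),
    }
    if reported:
        out["accuracy_among_reported"] = correct / len(reported)
        out["accuracy_among_reported_pct"] = round_pct(correct / len(reported))
    else:
        out["accuracy_among_reported"] = None
        out["accuracy_among_reported_pct"] = None
    return out
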