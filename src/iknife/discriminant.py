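"""Univariate discovery of class-separating m/z bins.

Each bin is tested with the Wilcoxon rank-sum test (two classes) or the
Kruskal-Wallis test (more), both tie-corrected asymptotic versions, on
per-sample mean spectra by default to avoid pseudo-replication across the
burns of one sample. P-values are FDR-adjusted with the Benjamini-Yekutieli
step-up, which is valid under arbitrary dependence between bins — spectral
bins are anything but independent. Effect size is the median log2 fold
change with a pseudo-count guarding against zero medians.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 0.001
DEFAULT_Q_MAX = 0.001
DEFAULT_TOP_N = 10


def _units(matrix: FeatureMatrix, classes, level: str) -> tuple[np.ndarray, np.ndarray]:
    """Analysis units: spectra rows, or per-(patient, sample) mean spectra."""
    meta = matrix.metadata
    mask = meta["tissue_class"].isin(classes).to_numpy()
    X = matrix.values()[mask]
    labels = meta["tissue_class"].to_numpy()[mask]
    if level == "spectrum":
        return X, labels
    if level != "sample":
        raise ValueError("level must be 'sample' or 'spectrum'")
    sub = meta.loc[mask]
    frame = pd.DataFrame(X)
    frame["_patient"] = sub["patient_id"].to_numpy()
    frame["_sample"] = sub["sample_id"].to_numpy()
    frame["_class"] = sub["tissue_class"].to_numpy()
    grouped = frame.groupby(["_patient", "_sample"], sort=False)
    means = grouped[list(range(X.shape[1]))].mean().to_numpy()
    unit_labels = grouped["_class"].first().to_numpy()
    return means, unit_labels


def adjust_by(pvalues, method: str = "by") -> np.ndarray:
    """FDR step-up adjustment: Benjamini-Yekutieli (default) or plain BH.

    Sorted ascending p(1..m), BY sets q(i) = min_{j >= i} m * c(m) * p(j) / j
    capped at 1, with c(m) = sum_{k=1..m} 1/k; BH is the same with c(m) = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    if method == "by":
        c = float(np.sum(1.0 / np.arange(1, m + 1)))
    elif method == "bh":
        c = 1.0
    else:
        raise ValueError("method must be 'by' or 'bh'")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _epsilon(matrix_values: np.ndarray) -> float:
    positive = matrix_values[matrix_values > 0]
    return float(positive.min()) / 10.0 if positive.size else 1e-12


def log2_fold_change(matrix: FeatureMatrix, bin_label: float, class_a, class_b,
                     level: str = "sample") -> float:
    """Signed log2 ratio of median normalised intensity, class_a over class_b."""
    X, labels = _units(matrix, [class_a, class_b], level)
    col = np.flatnonzero(np.isclose(matrix.intensities.columns.to_numpy(dtype=float),
                                    bin_label))
    if col.size == 0:
        raise KeyError(f"bin {bin_label} not on the grid")
    eps = _epsilon(matrix.values())
    med_a = float(np.median(X[labels == class_a, col[0]]))
    med_b = float(np.median(X[labels == class_b, col[0]]))
    return float(np.log2((med_a + eps) / (med_b + eps)))


def test_bins(matrix: FeatureMatrix, classes, level: str = "sample",
              fdr_method: str = "by") -> pd.DataFrame:
    """Per-bin rank test + FDR + median log2 fold change.

    Two classes use the Wilcoxon rank-sum (Mann-Whitney, tie-corrected
    normal approximation); three or more use Kruskal-Wallis. Bins constant
    across all units get P = 1 by convention. Fold changes are reported for
    the first two named classes (first over second).
    """
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X, labels = _units(matrix, classes, level)
    for c in classes:
        if int((labels == c).sum()) < 3:
            raise ValueError(f"class {c!r} has fewer than 3 units at level {level!r}")

    groups = [X[labels == c] for c in classes]
    n_bins = X.shape[1]
    pvals = np.ones(n_bins)
    constant = np.array([np.unique(X[:, j]).size == 1 for j in range(n_bins)])
    if constant.any():
        logger.info("%d bins constant across units; P set to 1", int(constant.sum()))

    test_name = "rank-sum" if len(classes) == 2 else "kruskal-wallis"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in np.flatnonzero(~constant):
            cols = [g[:, j] for g in groups]
            if len(classes) == 2:
                pvals[j] = stats.mannwhitneyu(cols[0], cols[1], alternative="two-sided",
                                              method="asymptotic", use_continuity=False).pvalue
            else:
                pvals[j] = stats.kruskal(*cols).pvalue
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    qvals = adjust_by(pvals, method=fdr_method)

    eps = _epsilon(matrix.values())
    med_a = np.median(groups[0], axis=0)
    med_b = np.median(groups[1], axis=0)
    results = pd.DataFrame({
        "bin": matrix.intensities.columns.to_numpy(dtype=float),
        "test": test_name,
        "P": pvals,
        "q": qvals,
        "log2_fold_change": np.log2((med_a + eps) / (med_b + eps)),
        "pooled_median_intensity": np.median(X, axis=0),
    })
    for c, g in zip(classes, groups):
        results[f"median_{c}"] = np.median(g, axis=0)
    return results


def top_discriminant(results: pd.DataFrame, n: int = DEFAULT_TOP_N,
                     p_max: float = DEFAULT_P_MAX,
                     q_max: float = DEFAULT_Q_MAX) -> pd.DataFrame:
    """The "top n significant and intense" shortlist.

    Filters to P < p_max and q < q_max, ranks by descending pooled median
    intensity and returns the first n rows (all survivors, with a warning,
    when fewer than n pass).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    passed = results.loc[(results["P"] < p_max) & (results["q"] < q_max)]
    if len(passed) < n:
        warnings.warn(f"only {len(passed)} bins pass P < {p_max}, q < {q_max} (asked for {n})",
                      stacklevel=2)
    return passed.sort_values("pooled_median_intensity", ascending=False,
                              kind="stable").head(n).reset_index(drop=True)
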