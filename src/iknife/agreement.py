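"""Cohen's kappa inter-rater agreement with significance and verbal bands.

Used to compare tissue-type calls from the surgeon, the recognition model
and the histopathologist over the same sampling points. Unweighted kappa:
tissue classes are nominal. Significance uses the classical null-hypothesis
asymptotic standard error computed from the marginal distributions, with a
two-sided normal P-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: verbal interpretation bands; upper edges inclusive ("good" covers (0.60, 0.80])
BANDS = (
    (0.00, "no agreement"),
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


@dataclass
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    se0: float
    z: float
    p_value: float
    band: str
    n: int


def kappa_band(kappa: float) -> str:
    """Map a kappa coefficient to its verbal band.

    0 -> "no agreement"; (0, 0.20] poor; (0.20, 0.40] fair; (0.40, 0.60]
    moderate; (0.60, 0.80] good; above 0.80 very good. Negative values are
    worse-than-chance disagreement and map to "no agreement" with a warning.
    """
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0:
        logger.warning("negative kappa %.3f (worse than chance); banded as 'no agreement'", kappa)
        return "no agreement"
    for upper, label in BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "very good"


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Chance-corrected agreement between two raters of the same items.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    product of marginals; z = kappa / SE0 with the marginal-based null
    standard error, two-sided P from the normal approximation.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated items")
    labels = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p = table / n
    p_o = float(np.trace(p))
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    p_e = float(pa @ pb)

    if p_e >= 1.0 - 1e-12:
        # both raters constant with the same label
        if p_o >= 1.0 - 1e-12:
            return KappaResult(kappa=1.0, p_o=1.0, p_e=1.0, se0=float("nan"),
                               z=float("inf"), p_value=0.0, band="very good", n=n)
        raise ValueError("expected agreement is 1 but raters disagree; kappa undefined")

    kappa = (p_o - p_e) / (1.0 - p_e)
    var0 = (p_e + p_e ** 2 - float(np.sum(pa * pb * (pa + pb)))) / (n * (1.0 - p_e) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    z = kappa / se0 if se0 > 0 else float("inf") * np.sign(kappa)
    p_value = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return KappaResult(kappa=float(kappa), p_o=p_o, p_e=p_e, se0=se0, z=float(z),
                       p_value=p_value, band=kappa_band(float(kappa)), n=n)
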