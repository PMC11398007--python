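"""Method-comparison statistics for paired gait measurements.

Built for validating one gait-measurement system against a reference
(instrumented walkway, optical motion capture, or the simulator's ground
truth): rank and product-moment correlation, percent error ("percent
variance" in the clinical gait literature: the relative absolute difference
of each test/reference pair), and Bland–Altman limits of agreement.

Spearman's rho uses average ranks for ties; its p-value is computed by
exhaustive permutation enumeration for n <= 9 and by the t approximation
otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "PercentVariance",
    "spearman_rho",
    "pearson_r",
    "percent_variance",
    "bland_altman",
    "EXACT_PERMUTATION_MAX_N",
]

EXACT_PERMUTATION_MAX_N = 9


@dataclass
class PairedMeasurements:
    """Label-aligned (reference, test) pairs for one metric."""

    metric: str
    reference: np.ndarray
    test: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.shape != self.test.shape or self.reference.ndim != 1:
            raise ValueError("reference and test must be equal-length 1-D vectors")
        if self.n < 2:
            raise ValueError("need at least 2 pairs")
        if self.labels and len(self.labels) != self.n:
            raise ValueError("labels must align with the measurement vectors")
        if not self.labels:
            self.labels = [str(i) for i in range(self.n)]

    @property
    def n(self) -> int:
        return int(self.reference.size)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(pairs: PairedMeasurements) -> tuple[float, float]:
    """Rank correlation with average-rank ties and an exact small-n p-value.

    p is two-sided: for n <= 9 the fraction of all n! rank permutations with
    |rho| at least the observed (within 1e-12); for larger n the t
    approximation with n-2 degrees of freedom.  Constant input is undefined:
    flagged with a warning, (nan, nan) returned.
    """
    x, y = pairs.reference, pairs.test
    n = pairs.n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"{pairs.metric}: constant vector, Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        perms_dot = ry_c[perms] @ rx_c
        denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        rhos = perms_dot / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
    return rho, p


def pearson_r(pairs: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation; p from the t distribution with n-2 df."""
    x, y = pairs.reference, pairs.test
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"{pairs.metric}: zero variance, Pearson r undefined", stacklevel=2)
        return float("nan"), float("nan")
    if pairs.n < 3:
        r = float(np.corrcoef(x, y)[0, 1])
        return r, float("nan")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PercentVariance:
    """Relative absolute differences |test - ref| / ref, in percent."""

    per_pair: np.ndarray
    max: float
    mean: float
    excluded: int  # pairs dropped for non-positive reference


def percent_variance(pairs: PairedMeasurements) -> PercentVariance:
    ref, test = pairs.reference, pairs.test
    ok = ref > 0
    if not ok.all():
        warnings.warn(
            f"{pairs.metric}: {int((~ok).sum())} pair(s) with non-positive reference excluded",
            stacklevel=2,
        )
    pv = np.abs(test[ok] - ref[ok]) / ref[ok] * 100.0
    if pv.size == 0:
        return PercentVariance(pv, float("nan"), float("nan"), int((~ok).sum()))
    return PercentVariance(pv, float(np.max(pv)), float(np.mean(pv)), int((~ok).sum()))


def bland_altman(pairs: PairedMeasurements) -> tuple[float, tuple[float, float]]:
    """Mean difference (test - reference) and 95% limits of agreement.

    Limits are bias +- 1.96 * sd of the differences (sample sd, ddof=1;
    zero-width when all differences are equal).
    """
    d = pairs.test - pairs.reference
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)
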