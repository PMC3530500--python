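"""Genomic inflation diagnostics for interaction scans.

The genomic inflation factor lambda is the median 1-df chi-square test
statistic divided by its null median (0.4549...). For a known-locus scan,
lambda computed over the locus's genome-wide interaction p-values reveals
main-effect misspecification: if the locus's own effect is not log-additive,
its residual leaks into every carrier-product interaction term and the scan
inflates. The guard reruns the locus with unrestricted (2-df indicator)
main-effect coding, which removes the residual and restores calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: median of the chi-square distribution with 1 df
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))
#: lambdas at or below this are considered calibrated
GUARD_THRESHOLD = 1.05


@dataclass
class InflationReport:
    lam: float
    n_tests: int
    locus_id: str | None = None
    coding_used: str = "additive"       # "additive" | "unrestricted_main"
    lam_after_recoding: float | None = None

    @property
    def inflated(self) -> bool:
        return self.coding_used == "unrestricted_main"


def genomic_lambda(pvalues: np.ndarray) -> float:
    """lambda = median(chi2_quantile(1 - p, df=1)) / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn(f"lambda from only {p.size} tests is noisy")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def inflation_guard(pvalues: np.ndarray, locus_id: str | None = None,
                    threshold: float = GUARD_THRESHOLD) -> InflationReport:
    """Decide the main-effect coding for a locus scan from its lambda.

    lambda <= threshold keeps the additive-main coding; a strictly larger
    lambda requests a rerun with unrestricted main effects (the caller then
    records both lambdas via :func:`record_recoding`).
    """
    lam = genomic_lambda(pvalues)
    coding = "additive" if lam <= threshold else "unrestricted_main"
    return InflationReport(lam=lam, n_tests=int(np.isfinite(
        np.asarray(pvalues, dtype=float)).sum()),
        locus_id=locus_id, coding_used=coding)


def record_recoding(report: InflationReport,
                    pvalues_after: np.ndarray) -> InflationReport:
    """Attach the post-recoding lambda to a guard report."""
    report.lam_after_recoding = genomic_lambda(pvalues_after)
    return report


def qq_data(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs for a QQ plot.

    Observed p-values sort ascending; expected are the uniform plotting
    quantiles (i - 0.5)/n on the same -log10 scale.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return expected, observed
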