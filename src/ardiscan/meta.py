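"""Inverse-variance meta-analysis of per-study interaction estimates.

Fixed-effect combination with Cochran's Q heterogeneity statistic and a
DerSimonian–Laird random-effects variant. Because the per-study standard
errors already inflate with imputation-dosage uncertainty, inverse-variance
weighting incorporates imputation quality automatically; no extra weighting
is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .interaction import EffectEstimate

logger = logging.getLogger(__name__)

#: per-study estimates with SE above this (log-OR scale) are separation
#: artifacts and are excluded with a logged count
MAX_SE = 10.0
_Z95 = 1.959963984540054


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    q: float
    p_het: float | None
    tau2: float
    k: int
    method: str  # "fixed" | "random"

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - _Z95 * self.se)),
                float(np.exp(self.beta + _Z95 * self.se)))

    @property
    def z(self) -> float:
        return self.beta / self.se


def _usable(estimates: list[EffectEstimate]) -> list[EffectEstimate]:
    ok = [e for e in estimates
          if e.converged and np.isfinite(e.beta) and np.isfinite(e.se)
          and 0 < e.se <= MAX_SE]
    dropped = len(estimates) - len(ok)
    if dropped:
        logger.info("meta-analysis: dropped %d unusable estimate(s)", dropped)
    return ok


def _combine(betas: np.ndarray, variances: np.ndarray, tau2: float,
             method: str, q: float, p_het: float | None, k: int) -> MetaResult:
    w = 1.0 / (variances + tau2)
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MetaResult(beta, se, max(p, np.nextafter(0, 1)),
                      q, p_het, tau2, k, method)


def _q_statistic(betas: np.ndarray, variances: np.ndarray) -> tuple[float, float | None]:
    k = betas.size
    if k < 2:
        return 0.0, None
    w = 1.0 / variances
    beta_fixed = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta_fixed) ** 2))
    return q, float(stats.chi2.sf(q, k - 1))


def fixed_effect_meta(estimates: list[EffectEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect combination: weights 1/se_i^2."""
    ok = _usable(estimates)
    if not ok:
        raise ValueError("no usable estimates to meta-analyze")
    betas = np.array([e.beta for e in ok])
    variances = np.array([e.se**2 for e in ok])
    q, p_het = _q_statistic(betas, variances)
    return _combine(betas, variances, 0.0, "fixed", q, p_het, len(ok))


def cochran_q(estimates: list[EffectEstimate]) -> tuple[float, float | None]:
    """Cochran's Q about the fixed-effect mean; heterogeneity p from
    chi-square with k-1 df (None when k < 2)."""
    ok = _usable(estimates)
    betas = np.array([e.beta for e in ok])
    variances = np.array([e.se**2 for e in ok])
    return _q_statistic(betas, variances)


def random_effect_meta(estimates: list[EffectEstimate]) -> MetaResult:
    """DerSimonian–Laird: tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2/sum w)),
    then inverse-variance with weights 1/(se_i^2 + tau2). Heterogeneity Q and
    its p-value are always those of the fixed-effect weights."""
    ok = _usable(estimates)
    if not ok:
        raise ValueError("no usable estimates to meta-analyze")
    betas = np.array([e.beta for e in ok])
    variances = np.array([e.se**2 for e in ok])
    k = len(ok)
    q, p_het = _q_statistic(betas, variances)
    if k < 2:
        tau2 = 0.0
    else:
        w = 1.0 / variances
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return _combine(betas, variances, tau2, "random", q, p_het, k)


def phase_meta(
    estimates: list[EffectEstimate],
    include_adenoma: bool = False,
    method: str = "fixed",
) -> dict[str, MetaResult | None]:
    """Combine per-study estimates by phase.

    Returns a dict with keys ``phase1``, ``phase2``, ``adenoma``, and
    ``combined``. Adenoma studies are shown separately and enter the
    combined analysis only when ``include_adenoma`` is set (by default they
    are displayed but not incorporated). A phase with no usable studies maps
    to None.
    """
    combiner = fixed_effect_meta if method == "fixed" else random_effect_meta

    def run(subset: list[EffectEstimate]) -> MetaResult | None:
        subset = _usable(subset)
        return combiner(subset) if subset else None

    by_phase = {
        "phase1": [e for e in estimates if e.phase == "phase1"],
        "phase2": [e for e in estimates if e.phase == "phase2"],
        "adenoma": [e for e in estimates if e.phase == "adenoma"],
    }
    combined = by_phase["phase1"] + by_phase["phase2"]
    if include_adenoma:
        combined = combined + by_phase["adenoma"]
    return {
        "phase1": run(by_phase["phase1"]),
        "phase2": run(by_phase["phase2"]),
        "adenoma": run(by_phase["adenoma"]),
        "combined": run(combined),
    }


def forest_data(estimates: list[EffectEstimate],
                meta: MetaResult | None = None):
    """Per-study rows for a forest plot: study, OR, CI, inverse-variance
    weight (percent), phase. Returns a pandas DataFrame."""
    import pandas as pd

    ok = _usable(estimates)
    w = np.array([1.0 / e.se**2 for e in ok])
    wpct = 100.0 * w / w.sum() if w.size else w
    rows = []
    for e, wp in zip(ok, wpct):
        lo, hi = e.ci95()
        rows.append({"study_id": e.study_id, "or": e.odds_ratio,
                     "ci_low": lo, "ci_high": hi,
                     "weight_pct": float(wp), "phase": e.phase})
    if meta is not None:
        lo, hi = meta.ci95
        rows.append({"study_id": f"meta_{meta.method}", "or": meta.odds_ratio,
                     "ci_low": lo, "ci_high": hi,
                     "weight_pct": 100.0, "phase": "combined"})
    return pd.DataFrame(rows)
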