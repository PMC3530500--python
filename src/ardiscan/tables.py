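"""Two-locus interaction-pattern tables.

Joint 3x3 genotype-combination odds-ratio tables relative to the
double-reference cell, stratified views (the odds ratios of one SNP within
each genotype stratum of the other), a carrier-collapsed 2x2 view, and the
cell-level interaction odds ratio — the joint OR divided by the product of
the two marginal ORs, i.e. the departure of a cell from the no-interaction
multiplicative expectation.

Dosages are hard-called by rounding to the nearest genotype: the tables
require discrete cells. Crude tables come straight from counts with Woolf
(log-method) confidence intervals; adjusted tables refit the saturated
indicator logistic model with covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import GenotypeDataset
from .logistic import fit_logistic

_Z95 = 1.959963984540054


@dataclass
class JointOrTable:
    """Genotype-combination odds ratios for one SNP pair.

    All arrays are indexed [g1][g2] over genotypes {0, 1, 2} (or {0, 1} for
    carrier-collapsed tables). The (0, 0) cell is the baseline with OR
    exactly 1.
    """

    snp1: str
    snp2: str
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n_case: np.ndarray
    n_control: np.ndarray
    adjusted: bool = False
    labels1: list[str] = field(default_factory=lambda: ["0", "1", "2"])
    labels2: list[str] = field(default_factory=lambda: ["0", "1", "2"])

    def render(self, digits: int = 2) -> str:
        """Aligned-text rendering: OR (CI) p over case/control counts."""
        lines = [f"{self.snp1} (rows) x {self.snp2} (columns); "
                 f"{'adjusted' if self.adjusted else 'crude'} odds ratios"]
        header = [""] + [f"{self.snp2}:{l}" for l in self.labels2]
        rows = [header]
        for i, l1 in enumerate(self.labels1):
            cells, counts = [f"{self.snp1}:{l1}"], [""]
            for j in range(len(self.labels2)):
                if i == j == 0:
                    cells.append("1 (ref)")
                elif np.isfinite(self.odds_ratio[i, j]):
                    cells.append(
                        f"{self.odds_ratio[i, j]:.{digits}f} "
                        f"({self.ci_low[i, j]:.{digits}f}-"
                        f"{self.ci_high[i, j]:.{digits}f}) "
                        f"p={self.p[i, j]:.2e}")
                else:
                    cells.append("--")
                counts.append(f"{int(self.n_case[i, j])}/"
                              f"{int(self.n_control[i, j])}")
            rows.append(cells)
            rows.append(counts)
        widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
        for r in rows:
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, l1 in enumerate(self.labels1):
            for j, l2 in enumerate(self.labels2):
                rows.append({
                    "g1": l1, "g2": l2,
                    "or": self.odds_ratio[i, j],
                    "ci_low": self.ci_low[i, j],
                    "ci_high": self.ci_high[i, j],
                    "p": self.p[i, j],
                    "n_case": int(self.n_case[i, j]),
                    "n_control": int(self.n_control[i, j]),
                })
        return pd.DataFrame(rows)


def joint_genotype_counts(data: GenotypeDataset, snp1: str,
                          snp2: str) -> tuple[np.ndarray, np.ndarray]:
    """3x3 case and control counts over hard-called genotype combinations."""
    g1 = np.round(data.dosage(snp1))
    g2 = np.round(data.dosage(snp2))
    mask = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[mask].astype(int), g2[mask].astype(int)
    y = data.phenotype[mask]
    cases = np.zeros((3, 3))
    controls = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            cell = (g1 == a) & (g2 == b)
            cases[a, b] = int((cell & (y == 1)).sum())
            controls[a, b] = int((cell & (y == 0)).sum())
    return cases, controls


def _crude_or_grid(cases: np.ndarray, controls: np.ndarray,
                   base: tuple[int, int] = (0, 0)):
    """Cross-product odds ratios of every cell against a baseline cell,
    with Woolf log-method CIs and normal-approximation p-values."""
    shape = cases.shape
    orr = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    a0, b0 = cases[base], controls[base]
    for i in range(shape[0]):
        for j in range(shape[1]):
            a, b = cases[i, j], controls[i, j]
            if (i, j) == base:
                orr[i, j], lo[i, j], hi[i, j], p[i, j] = 1.0, 1.0, 1.0, 1.0
                continue
            if min(a, b, a0, b0) == 0:
                continue  # OR undefined; counts still reported
            log_or = np.log((a * b0) / (b * a0))
            se = np.sqrt(1 / a + 1 / b + 1 / a0 + 1 / b0)
            orr[i, j] = np.exp(log_or)
            lo[i, j] = np.exp(log_or - _Z95 * se)
            hi[i, j] = np.exp(log_or + _Z95 * se)
            p[i, j] = 2.0 * stats.norm.sf(abs(log_or / se))
    return orr, lo, hi, p


def _adjusted_or_grid(data: GenotypeDataset, snp1: str, snp2: str,
                      cases: np.ndarray, controls: np.ndarray):
    """Cell ORs from a saturated indicator logistic fit with covariates."""
    g1 = np.round(data.dosage(snp1))
    g2 = np.round(data.dosage(snp2))
    mask = np.isfinite(g1) & np.isfinite(g2)
    if data.covariates is not None:
        mask &= np.isfinite(data.covariates).all(axis=1)
    g1m, g2m = g1[mask].astype(int), g2[mask].astype(int)
    y = data.phenotype[mask].astype(float)
    cells = [(i, j) for i in range(3) for j in range(3)
             if (i, j) != (0, 0) and cases[i, j] + controls[i, j] > 0]
    terms = [((g1m == i) & (g2m == j)).astype(float) for i, j in cells]
    names = [f"cell_{i}{j}" for i, j in cells]
    cols = [np.ones(int(mask.sum()))] + terms
    all_names = ["intercept"] + names
    if data.covariates is not None:
        cov = data.covariates[mask]
        cols.extend(cov.T)
        all_names.extend(data.covariate_names
                         or [f"cov{k}" for k in range(cov.shape[1])])
    fit = fit_logistic(np.column_stack(cols), y, names=all_names)
    orr = np.full((3, 3), np.nan)
    lo = np.full((3, 3), np.nan)
    hi = np.full((3, 3), np.nan)
    p = np.full((3, 3), np.nan)
    orr[0, 0] = lo[0, 0] = hi[0, 0] = p[0, 0] = 1.0
    if not fit.converged:
        return orr, lo, hi, p
    for (i, j), name in zip(cells, names):
        k = fit.names.index(name)
        beta, se = fit.beta[k], np.sqrt(fit.cov[k, k])
        orr[i, j] = np.exp(beta)
        lo[i, j] = np.exp(beta - _Z95 * se)
        hi[i, j] = np.exp(beta + _Z95 * se)
        p[i, j] = 2.0 * stats.norm.sf(abs(beta / se))
    return orr, lo, hi, p


def joint_or_table(data: GenotypeDataset, snp1: str, snp2: str,
                   adjusted: bool = False) -> JointOrTable:
    """3x3 odds ratios of every genotype combination against the
    double-reference cell; crude from counts or adjusted from the
    saturated logistic fit."""
    cases, controls = joint_genotype_counts(data, snp1, snp2)
    if adjusted:
        orr, lo, hi, p = _adjusted_or_grid(data, snp1, snp2, cases, controls)
    else:
        orr, lo, hi, p = _crude_or_grid(cases, controls)
    return JointOrTable(snp1, snp2, orr, lo, hi, p, cases, controls,
                        adjusted=adjusted)


def stratified_or(table: JointOrTable, stratify_by: str) -> JointOrTable:
    """Odds ratios of one SNP within each genotype stratum of the other.

    ``stratify_by="snp1"`` re-baselines every row at its first column
    (column-SNP ORs within each row stratum); ``"snp2"`` re-baselines every
    column at its first row. Crude tables only — stratified crude ORs
    recombine exactly: joint(g1, g2) = row_main(g1) * stratified(g2 | g1).
    """
    if stratify_by not in ("snp1", "snp2"):
        raise ValueError("stratify_by must be 'snp1' or 'snp2'")
    cases, controls = table.n_case, table.n_control
    shape = cases.shape
    orr = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    if stratify_by == "snp1":
        for i in range(shape[0]):
            o, l, h, pp = _crude_or_grid(cases[i:i + 1, :],
                                         controls[i:i + 1, :])
            orr[i], lo[i], hi[i], p[i] = o, l, h, pp
    else:
        for j in range(shape[1]):
            o, l, h, pp = _crude_or_grid(cases[:, j:j + 1],
                                         controls[:, j:j + 1])
            orr[:, j], lo[:, j], hi[:, j], p[:, j] = \
                o[:, 0], l[:, 0], h[:, 0], pp[:, 0]
    return JointOrTable(table.snp1, table.snp2, orr, lo, hi, p,
                        cases, controls, adjusted=False,
                        labels1=table.labels1, labels2=table.labels2)


def collapse_carriers(table: JointOrTable) -> JointOrTable:
    """Merge heterozygote and minor-homozygote cells of both SNPs into a
    2x2 carrier-by-carrier table and recompute crude ORs from the merged
    counts."""
    cases = np.array([
        [table.n_case[0, 0], table.n_case[0, 1:].sum()],
        [table.n_case[1:, 0].sum(), table.n_case[1:, 1:].sum()],
    ])
    controls = np.array([
        [table.n_control[0, 0], table.n_control[0, 1:].sum()],
        [table.n_control[1:, 0].sum(), table.n_control[1:, 1:].sum()],
    ])
    orr, lo, hi, p = _crude_or_grid(cases, controls)
    return JointOrTable(table.snp1, table.snp2, orr, lo, hi, p,
                        cases, controls, adjusted=False,
                        labels1=["0", "1+2"], labels2=["0", "1+2"])


def cell_interaction_or(joint_or: float, row_main_or: float,
                        col_main_or: float) -> float:
    """Interaction odds ratio of one genotype-combination cell: the joint
    OR divided by the product of the two marginal ORs. Equals 1 when the
    cell follows the no-interaction multiplicative expectation."""
    for v in (joint_or, row_main_or, col_main_or):
        if not v > 0:
            raise ValueError("odds ratios must be positive")
    return joint_or / (row_main_or * col_main_or)


def expected_joint_or(row_main_or: float, col_main_or: float) -> float:
    """Joint OR a cell would show under no interaction: the product of the
    marginal ORs."""
    for v in (row_main_or, col_main_or):
        if not v > 0:
            raise ValueError("odds ratios must be positive")
    return row_main_or * col_main_or
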