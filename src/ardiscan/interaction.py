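"""Two-locus interaction tests for case-control data.

Four models are provided, all covariate-adjusted logistic regressions fit
per study:

* ``test_marginal`` — single-SNP log-additive association (the screening
  test).
* ``test_ardi`` — Average Risk Due to Interaction: log-additive main
  effects plus a single interaction parameter on the product of carrier
  indicators, so one coefficient captures the average deviation of the four
  non-reference genotype-combination cells from the main effects. 1-df Wald.
* ``test_multiplicative`` — the usual log-additive interaction model whose
  interaction covariate is the product of the additive codings G1*G2; it
  assumes the double-homozygote interaction is four times the
  double-heterozygote one on the log scale. 1-df Wald.
* ``test_unrestricted`` — 2-df indicator main effects per SNP and four free
  interaction parameters, tested with a likelihood-ratio chi-square (4 df,
  fewer when cells are empty).
* ``test_ardi_unrestricted_main`` — the ARDI carrier-product interaction on
  top of 2-df indicator main effects; guards against main-effect
  misspecification (a non-additive main effect otherwise leaks into the
  interaction term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import GenotypeDataset
from .logistic import FitResult, fit_logistic, likelihood_ratio

#: minimum complete cases beyond the parameter count for any fit
MIN_EXTRA_CASES = 10


@dataclass
class EffectEstimate:
    """A fitted interaction (or main-effect) coefficient from one study.

    ``beta`` is a log odds ratio for 1-df Wald tests and NaN for multi-df
    likelihood-ratio tests, where only ``p`` and ``df`` are meaningful.
    """

    beta: float
    se: float
    z: float
    p: float
    df: int
    n_case: int
    n_control: int
    study_id: str
    model: str
    converged: bool = True
    message: str = ""
    phase: str = "phase1"

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return float(np.exp(self.beta - half)), float(np.exp(self.beta + half))


def carrier_score(dosage: np.ndarray, probs: np.ndarray | None = None) -> np.ndarray:
    """Probability of carrying at least one count allele.

    With genotype probabilities this is exactly P(1) + P(2). From a dosage
    alone it is min(d, 1): exact for hard calls and whenever the
    minor-homozygote probability is zero, a bounded approximation otherwise.
    """
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        return probs[..., 1] + probs[..., 2]
    return np.minimum(np.asarray(dosage, dtype=float), 1.0)


def _failed(study: GenotypeDataset, model: str, df: int, msg: str,
            n_case: int = 0, n_control: int = 0) -> EffectEstimate:
    return EffectEstimate(np.nan, np.nan, np.nan, np.nan, df,
                          n_case, n_control, study.study_id, model,
                          converged=False, message=msg, phase=study.phase)


def _complete_cases(data: GenotypeDataset, cols: list[np.ndarray]) -> np.ndarray:
    mask = np.ones(data.n_samples, dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    if data.covariates is not None:
        mask &= np.isfinite(data.covariates).all(axis=1)
    return mask


def _assemble(data: GenotypeDataset, mask: np.ndarray,
              terms: list[np.ndarray], term_names: list[str]):
    cols = [np.ones(int(mask.sum()))] + [t[mask] for t in terms]
    names = ["intercept"] + term_names
    if data.covariates is not None:
        cov = data.covariates[mask]
        cols.extend(cov.T)
        names.extend(data.covariate_names
                     or [f"cov{j}" for j in range(cov.shape[1])])
    return np.column_stack(cols), data.phenotype[mask].astype(float), names


def _wald_estimate(data: GenotypeDataset, fit: FitResult, term: str,
                   model: str, n_case: int, n_control: int) -> EffectEstimate:
    if not fit.converged:
        return _failed(data, model, 1, fit.message, n_case, n_control)
    j = fit.names.index(term)
    beta = float(fit.beta[j])
    se = float(np.sqrt(fit.cov[j, j]))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EffectEstimate(beta, se, z, max(p, np.nextafter(0, 1)), 1,
                          n_case, n_control, data.study_id, model,
                          phase=data.phase)


def _wald_fit(data: GenotypeDataset, terms, names, test_term, model,
              firth=False) -> EffectEstimate:
    mask = _complete_cases(data, terms)
    n_params = 1 + len(terms) + (0 if data.covariates is None
                                 else data.covariates.shape[1])
    if int(mask.sum()) < n_params + MIN_EXTRA_CASES:
        return _failed(data, model, 1, "too few complete cases")
    X, y, all_names = _assemble(data, mask, terms, names)
    fit = fit_logistic(X, y, names=all_names, firth=firth)
    return _wald_estimate(data, fit, test_term, model,
                          int(y.sum()), int((y == 0).sum()))


def test_marginal(data: GenotypeDataset, snp: str,
                  firth: bool = False) -> EffectEstimate:
    """Log-additive single-SNP association, 1-df Wald on the per-allele
    log odds ratio."""
    g = data.dosage(snp)
    return _wald_fit(data, [g], [snp], snp, "marginal", firth)


def test_ardi(data: GenotypeDataset, snp1: str, snp2: str,
              firth: bool = False) -> EffectEstimate:
    """ARDI: logit P(d=1) = b0 + b1 G1 + b2 G2 + gbar c(G1) c(G2) + d'X.

    G is the additive dosage and c(.) the carrier score, so exp(gbar) is the
    average interaction odds ratio shared by the four non-reference
    genotype-combination cells.
    """
    g1, g2 = data.dosage(snp1), data.dosage(snp2)
    c1 = carrier_score(g1, data.probs(snp1))
    c2 = carrier_score(g2, data.probs(snp2))
    return _wald_fit(data, [g1, g2, c1 * c2],
                     [snp1, snp2, "gxg"], "gxg", "ardi", firth)


def test_multiplicative(data: GenotypeDataset, snp1: str, snp2: str,
                        firth: bool = False) -> EffectEstimate:
    """Log-additive mains with interaction covariate G1*G2, 1-df Wald."""
    g1, g2 = data.dosage(snp1), data.dosage(snp2)
    return _wald_fit(data, [g1, g2, g1 * g2],
                     [snp1, snp2, "gxg"], "gxg", "multiplicative", firth)


def _genotype_indicators(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard-call a dosage by rounding and return (het, minor-hom) indicators."""
    hard = np.round(g)
    return (hard == 1).astype(float), (hard == 2).astype(float)


def test_ardi_unrestricted_main(data: GenotypeDataset, snp1: str, snp2: str,
                                firth: bool = False) -> EffectEstimate:
    """ARDI carrier-product interaction with 2-df indicator main effects
    per SNP, immune to additive-main misspecification. 1-df Wald."""
    g1, g2 = data.dosage(snp1), data.dosage(snp2)
    h1, m1 = _genotype_indicators(g1)
    h2, m2 = _genotype_indicators(g2)
    c1 = carrier_score(g1, data.probs(snp1))
    c2 = carrier_score(g2, data.probs(snp2))
    terms = [h1, m1, h2, m2, c1 * c2]
    names = [f"{snp1}_het", f"{snp1}_hom", f"{snp2}_het", f"{snp2}_hom", "gxg"]
    return _wald_fit(data, terms, names, "gxg", "ardi_umain", firth)


def test_unrestricted(data: GenotypeDataset, snp1: str, snp2: str,
                      firth: bool = False) -> EffectEstimate:
    """Unrestricted model: indicator mains plus four free cell interaction
    parameters gamma_jk, j,k in {1,2}; likelihood-ratio test against the
    mains-only model.

    Genotype-combination cells with no observations drop their gamma_jk and
    reduce the degrees of freedom, flagged in ``message``.
    """
    g1, g2 = data.dosage(snp1), data.dosage(snp2)
    mask = _complete_cases(data, [g1, g2])
    h1, m1 = _genotype_indicators(g1)
    h2, m2 = _genotype_indicators(g2)
    inter_all = {
        "g11": h1 * h2, "g12": h1 * m2, "g21": m1 * h2, "g22": m1 * m2,
    }
    kept = {k: v for k, v in inter_all.items() if v[mask].sum() > 0}
    df = len(kept)
    msg = "" if df == 4 else f"empty cells: df reduced to {df}"
    main_terms = [h1, m1, h2, m2]
    main_names = [f"{snp1}_het", f"{snp1}_hom", f"{snp2}_het", f"{snp2}_hom"]
    full_terms = main_terms + list(kept.values())
    full_names = main_names + list(kept.keys())
    n_params = 1 + len(full_terms) + (0 if data.covariates is None
                                      else data.covariates.shape[1])
    n = int(mask.sum())
    if n < n_params + MIN_EXTRA_CASES or df == 0:
        return _failed(data, "unrestricted", max(df, 1), "too few complete cases")
    Xf, y, names_f = _assemble(data, mask, full_terms, full_names)
    Xr, _, names_r = _assemble(data, mask, main_terms, main_names)
    full = fit_logistic(Xf, y, names=names_f, firth=firth)
    reduced = fit_logistic(Xr, y, names=names_r, firth=firth)
    if not (full.converged and reduced.converged):
        return _failed(data, "unrestricted", df,
                       full.message or reduced.message,
                       int(y.sum()), int((y == 0).sum()))
    lrt = likelihood_ratio(full, reduced)
    p = float(stats.chi2.sf(lrt, df))
    est = EffectEstimate(np.nan, np.nan, np.nan, max(p, np.nextafter(0, 1)),
                         df, int(y.sum()), int((y == 0).sum()),
                         data.study_id, "unrestricted",
                         message=msg, phase=data.phase)
    return est


MODEL_TESTS = {
    "ardi": test_ardi,
    "multiplicative": test_multiplicative,
    "unrestricted": test_unrestricted,
    "ardi_umain": test_ardi_unrestricted_main,
}
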