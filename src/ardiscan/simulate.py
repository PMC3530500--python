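"""Synthetic multi-study case-control genotype data.

Genotypes are drawn under Hardy-Weinberg equilibrium, optionally as an LD
pair with a target allelic r^2 built from haplotype frequencies. Disease
status follows either a 3x3 relative-risk penetrance table or an explicit
two-locus logistic model; case/control quotas are filled by rejection
sampling from the population model, which is exact at desk scale.
Covariates (age, sex) enter the disease model and are returned for
adjustment; imputation-dosage noise can be injected at a target quality
R^2. A consortium helper draws independent studies sharing a genetic model
with differing intercepts, reproducibly seeded from a master seed.

Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeDataset, SnpRecord, compute_maf

#: carrier indicator grid over genotypes 0/1/2
_CARRIER = np.array([0.0, 1.0, 1.0])


@dataclass
class PenetranceModel:
    """A two-locus disease model: relative risks R[g1][g2] with R[0][0]=1
    and a baseline probability for the double-reference genotype."""

    rr: np.ndarray
    baseline: float = 0.05
    name: str = "custom"

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.shape != (3, 3):
            raise ValueError("relative-risk table must be 3x3")
        if not (self.rr > 0).all():
            raise ValueError("relative risks must be positive")
        if not np.isclose(self.rr[0, 0], 1.0):
            raise ValueError("R[0][0] must be 1")
        if not 0 < self.baseline < 1:
            raise ValueError("baseline probability must lie in (0, 1)")

    def risk(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        p = self.baseline * self.rr[g1.astype(int), g2.astype(int)]
        return np.clip(p, 0.0, 0.99)

    # -- named presets -----------------------------------------------------
    @classmethod
    def null(cls, baseline: float = 0.05) -> "PenetranceModel":
        """No genetic effect at all: interaction-free by construction."""
        return cls(np.ones((3, 3)), baseline, "null")

    @classmethod
    def multiplicative(cls, theta: float, b1: float = 0.0, b2: float = 0.0,
                       baseline: float = 0.05) -> "PenetranceModel":
        """Log-additive mains b1, b2 with interaction theta * g1 * g2."""
        g = np.arange(3)
        log_rr = b1 * g[:, None] + b2 * g[None, :] + theta * g[:, None] * g[None, :]
        return cls(np.exp(log_rr), baseline, "multiplicative")

    @classmethod
    def ardi_carrier(cls, gbar: float, b1: float = 0.0, b2: float = 0.0,
                     baseline: float = 0.05) -> "PenetranceModel":
        """Log-additive mains plus a single carrier-product interaction:
        all four non-reference cells share the deviation gbar."""
        g = np.arange(3)
        log_rr = (b1 * g[:, None] + b2 * g[None, :]
                  + gbar * _CARRIER[:, None] * _CARRIER[None, :])
        return cls(np.exp(log_rr), baseline, "ardi_carrier")

    @classmethod
    def dominant_dominant(cls, effect: float,
                          baseline: float = 0.05) -> "PenetranceModel":
        """Risk raised only when both loci carry at least one minor allele."""
        log_rr = effect * _CARRIER[:, None] * _CARRIER[None, :]
        return cls(np.exp(log_rr), baseline, "dominant_dominant")

    @classmethod
    def recessive_recessive(cls, effect: float,
                            baseline: float = 0.05) -> "PenetranceModel":
        """Risk raised only for the double minor homozygote."""
        rr = np.ones((3, 3))
        rr[2, 2] = np.exp(effect)
        return cls(rr, baseline, "recessive_recessive")

    @classmethod
    def threshold(cls, effect: float, min_alleles: int = 3,
                  baseline: float = 0.05) -> "PenetranceModel":
        """Risk raised when the total minor-allele count reaches a cutoff."""
        g = np.arange(3)
        rr = np.where(g[:, None] + g[None, :] >= min_alleles,
                      np.exp(effect), 1.0)
        return cls(rr, baseline, "threshold")

    @classmethod
    def checkerboard(cls, effect: float,
                     baseline: float = 0.05) -> "PenetranceModel":
        """Alternating high/low risk cells (odd total allele count)."""
        g = np.arange(3)
        rr = np.where((g[:, None] + g[None, :]) % 2 == 1, np.exp(effect), 1.0)
        return cls(rr, baseline, "checkerboard")


@dataclass
class LogisticModel:
    """An explicit two-locus disease model on the logit scale.

    ``interaction_type`` selects the interaction covariate: the carrier
    product ("ardi"), the dosage product ("multiplicative"), or none.
    With ``main_coding="genotype"`` the mains are free per-genotype effects
    (het, hom log-ORs per SNP), used to simulate non-additive main effects.
    """

    intercept: float = -3.0
    beta1: float = 0.0
    beta2: float = 0.0
    interaction: float = 0.0
    interaction_type: str = "ardi"   # "ardi" | "multiplicative" | "none"
    main_coding: str = "additive"    # "additive" | "genotype"
    main1: tuple[float, float] = (0.0, 0.0)  # (het, hom) when genotype-coded
    main2: tuple[float, float] = (0.0, 0.0)
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def logit(self, g1: np.ndarray, g2: np.ndarray,
              covariates: dict[str, np.ndarray]) -> np.ndarray:
        eta = np.full(g1.shape, self.intercept, dtype=float)
        if self.main_coding == "additive":
            eta += self.beta1 * g1 + self.beta2 * g2
        else:
            het1, hom1 = self.main1
            het2, hom2 = self.main2
            eta += np.where(g1 == 1, het1, 0.0) + np.where(g1 == 2, hom1, 0.0)
            eta += np.where(g2 == 1, het2, 0.0) + np.where(g2 == 2, hom2, 0.0)
        if self.interaction_type == "ardi":
            eta += self.interaction * _CARRIER[g1.astype(int)] * _CARRIER[g2.astype(int)]
        elif self.interaction_type == "multiplicative":
            eta += self.interaction * g1 * g2
        elif self.interaction_type != "none":
            raise ValueError(f"unknown interaction_type {self.interaction_type!r}")
        for name, eff in self.covariate_effects.items():
            eta += eff * covariates[name]
        return eta


@dataclass
class SimStudySpec:
    """Design of one simulated study."""

    n_case: int
    n_control: int
    maf1: float = 0.3
    maf2: float = 0.25
    ld_r2: float = 0.0
    study_intercept_shift: float = 0.0
    imputation_r2: tuple[float, float] = (1.0, 1.0)
    seed: int | None = None
    study_id: str = "sim"
    phase: str = "phase1"

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("case/control counts must be positive")
        for maf in (self.maf1, self.maf2):
            if not 0.0 < maf <= 0.5:
                raise ValueError("MAF must lie in (0, 0.5]")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must lie in [0, 1]")


def simulate_genotypes(n: int, maf: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Hard genotypes under HWE: frequencies (1-q)^2, 2q(1-q), q^2."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(float)


def max_ld_r2(maf1: float, maf2: float) -> float:
    """Largest allelic r^2 achievable for two loci with the given MAFs."""
    d_max = min(maf1 * (1 - maf2), (1 - maf1) * maf2)
    return d_max**2 / (maf1 * (1 - maf1) * maf2 * (1 - maf2))


def simulate_ld_pair(n: int, maf1: float, maf2: float, target_r2: float,
                     seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two genotype vectors with population allelic correlation r^2 equal
    to the target, built by drawing two-locus haplotypes with positive
    disequilibrium D = sqrt(r^2 q1(1-q1) q2(1-q2))."""
    rng = np.random.default_rng(seed)
    r2max = max_ld_r2(maf1, maf2)
    if target_r2 > r2max + 1e-12:
        raise ValueError(
            f"target r^2 {target_r2} infeasible for MAFs {maf1}/{maf2}; "
            f"maximum achievable is {r2max:.4f}")
    d = np.sqrt(target_r2 * maf1 * (1 - maf1) * maf2 * (1 - maf2))
    # haplotype frequencies for (minor1, minor2) alleles
    p11 = maf1 * maf2 + d
    p10 = maf1 * (1 - maf2) - d
    p01 = (1 - maf1) * maf2 - d
    p00 = (1 - maf1) * (1 - maf2) + d
    freqs = np.clip([p11, p10, p01, p00], 0.0, 1.0)
    freqs = freqs / freqs.sum()
    haps = rng.choice(4, size=(n, 2), p=freqs)
    carries1 = np.isin(haps, (0, 1)).sum(axis=1)
    carries2 = np.isin(haps, (0, 2)).sum(axis=1)
    return carries1.astype(float), carries2.astype(float)


def _draw_population(n: int, spec: SimStudySpec,
                     rng: np.random.Generator):
    if spec.ld_r2 > 0:
        g1, g2 = simulate_ld_pair(n, spec.maf1, spec.maf2, spec.ld_r2, rng)
    else:
        g1 = simulate_genotypes(n, spec.maf1, rng)
        g2 = simulate_genotypes(n, spec.maf2, rng)
    covs = {
        "age": rng.normal(62.0, 8.0, size=n),
        "sex": rng.binomial(1, 0.5, size=n).astype(float),
    }
    return g1, g2, covs


def simulate_case_control(
    spec: SimStudySpec,
    model: PenetranceModel | LogisticModel,
) -> GenotypeDataset:
    """Rejection-sample a case-control study from a population model.

    Population individuals are drawn in batches; disease status is Bernoulli
    with probability given by the model (penetrance table on the probability
    scale, or logistic model on the logit scale, both shifted by the study
    intercept); sampling continues until both quotas are met. Covariates are
    standardized age and sex, returned for adjustment.
    """
    rng = np.random.default_rng(spec.seed)
    want_case, want_ctrl = spec.n_case, spec.n_control
    got: dict[str, list] = {k: [] for k in ("g1", "g2", "age", "sex", "y")}
    n_case = n_ctrl = 0
    for _ in range(200):
        batch = 2 * (want_case + want_ctrl)
        g1, g2, covs = _draw_population(batch, spec, rng)
        cov_std = {"age": (covs["age"] - 62.0) / 8.0, "sex": covs["sex"]}
        if isinstance(model, PenetranceModel):
            p = model.risk(g1, g2)
            eta = np.log(p / (1 - p)) + spec.study_intercept_shift
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            eta = model.logit(g1, g2, cov_std) + spec.study_intercept_shift
            p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.random(batch) < p
        take_case = np.flatnonzero(y)[: max(0, want_case - n_case)]
        take_ctrl = np.flatnonzero(~y)[: max(0, want_ctrl - n_ctrl)]
        take = np.concatenate([take_case, take_ctrl])
        got["g1"].append(g1[take])
        got["g2"].append(g2[take])
        got["age"].append(cov_std["age"][take])
        got["sex"].append(cov_std["sex"][take])
        got["y"].append(y[take].astype(int))
        n_case += take_case.size
        n_ctrl += take_ctrl.size
        if n_case >= want_case and n_ctrl >= want_ctrl:
            break
    else:
        raise RuntimeError(
            "case/control quotas not met; baseline probability makes "
            "ascertainment infeasible")
    g1 = np.concatenate(got["g1"])
    g2 = np.concatenate(got["g2"])
    dosages = np.column_stack([g1, g2])
    achieved = [1.0, 1.0]
    for j, target in enumerate(spec.imputation_r2):
        if target < 1.0:
            dosages[:, j], achieved[j] = add_imputation_noise(
                dosages[:, j], target, rng)
    snps = [
        SnpRecord("snp1", "1", 1000, "A", "C", maf=compute_maf(dosages[:, 0]),
                  imputation_r2=achieved[0],
                  genotyped=spec.imputation_r2[0] >= 1.0),
        SnpRecord("snp2", "2", 2000, "G", "T", maf=compute_maf(dosages[:, 1]),
                  imputation_r2=achieved[1],
                  genotyped=spec.imputation_r2[1] >= 1.0),
    ]
    n = dosages.shape[0]
    return GenotypeDataset(
        study_id=spec.study_id,
        dosages=dosages,
        snps=snps,
        phenotype=np.concatenate(got["y"]),
        covariates=np.column_stack([np.concatenate(got["age"]),
                                    np.concatenate(got["sex"])]),
        covariate_names=["age", "sex"],
        sample_ids=[f"{spec.study_id}_{i}" for i in range(n)],
        phase=spec.phase,
    )


def add_imputation_noise(dosages: np.ndarray, target_r2: float,
                         seed: int | np.random.Generator) -> tuple[np.ndarray, float]:
    """Degrade a dosage vector to a target imputation quality R^2.

    Imputed dosages are posterior means, so they shrink toward the
    population mean and their variance is R^2 times the true genotype
    variance. The degraded dosage is m + R^2 (d - m) + e with
    e ~ N(0, R^2 (1 - R^2) var(d)), which has both squared correlation with
    the truth and relative variance equal to R^2. Output is clamped to
    [0, 2]; the achieved (post-clamping) R^2 is returned.
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target R^2 must lie in (0, 1]")
    d = np.asarray(dosages, dtype=float)
    if target_r2 >= 1.0:
        return d.copy(), 1.0
    rng = np.random.default_rng(seed)
    mask = np.isfinite(d)
    mean = d[mask].mean()
    var = d[mask].var()
    noise = rng.normal(0.0, np.sqrt(target_r2 * (1.0 - target_r2) * var),
                       size=d.shape)
    noisy = np.clip(mean + target_r2 * (d - mean) + noise, 0.0, 2.0)
    achieved = float(np.corrcoef(d[mask], noisy[mask])[0, 1] ** 2)
    return noisy, achieved


def append_null_snps(data: GenotypeDataset, n_snps: int,
                     maf_range: tuple[float, float],
                     seed: int | np.random.Generator) -> GenotypeDataset:
    """Add HWE genotype columns independent of disease status — null
    partner SNPs for scan calibration experiments."""
    rng = np.random.default_rng(seed)
    n = data.n_samples
    cols, snps = [], list(data.snps)
    for k in range(n_snps):
        maf = rng.uniform(*maf_range)
        g = simulate_genotypes(n, maf, rng)
        cols.append(g)
        snps.append(SnpRecord(f"null{k}", "9", 10_000 + k, "A", "G",
                              maf=compute_maf(g), genotyped=True))
    return GenotypeDataset(
        study_id=data.study_id,
        dosages=np.column_stack([data.dosages] + cols),
        snps=snps,
        phenotype=data.phenotype,
        covariates=data.covariates,
        covariate_names=list(data.covariate_names),
        sample_ids=data.sample_ids,
        phase=data.phase,
    )


def simulate_consortium(
    specs: list[SimStudySpec],
    model: PenetranceModel | LogisticModel,
    master_seed: int | None = None,
) -> list[GenotypeDataset]:
    """Independent studies sharing one genetic model.

    Specs without an explicit seed get reproducible child seeds spawned
    from the master seed; study IDs default to study1..k.
    """
    if not specs:
        raise ValueError("need at least one study spec")
    children = np.random.SeedSequence(master_seed).spawn(len(specs))
    out = []
    for i, (spec, child) in enumerate(zip(specs, children)):
        if spec.seed is None:
            spec = SimStudySpec(**{**spec.__dict__,
                                   "seed": int(child.generate_state(1)[0] % (2**31))})
        if spec.study_id == "sim":
            spec = SimStudySpec(**{**spec.__dict__, "study_id": f"study{i + 1}"})
        out.append(simulate_case_control(spec, model))
    return out
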