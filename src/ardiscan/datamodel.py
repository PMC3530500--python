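"""Core data containers for multi-study case-control genotype data.

A :class:`GenotypeDataset` holds one study's expected allele-dosage matrix
(samples x SNPs, with NaN marking missing calls), optional per-genotype
probabilities, SNP metadata, the binary phenotype, and the adjustment
covariates. Coordinates are 1-based, matching VCF; a SNP's identity is the
triple (rsID, chromosome, position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Complementary bases, used to recognise strand flips during harmonization.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SnpRecord:
    """Metadata for one SNP.

    ``count_allele`` is the allele whose expected copy number the dosage
    column counts; ``imputation_r2`` is the imputation quality (squared
    correlation between imputed dosage and true genotype) and is ignored for
    directly genotyped SNPs, which are treated as quality 1.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    count_allele: str
    maf: float = float("nan")
    imputation_r2: float = 1.0
    genotyped: bool = False

    def __post_init__(self) -> None:
        if self.count_allele == self.ref_allele:
            raise ValueError(
                f"{self.snp_id}: count allele equals reference allele"
            )
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")
        if not np.isnan(self.imputation_r2) and not 0.0 <= self.imputation_r2 <= 1.05:
            raise ValueError(
                f"{self.snp_id}: imputation R2 {self.imputation_r2} outside [0, 1.05]"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.snp_id, self.chrom, self.pos)

    @property
    def effective_r2(self) -> float:
        """Imputation quality used in filters: genotyped counts as 1, and
        values slightly above 1 (some imputation tools emit them) clamp to 1."""
        if self.genotyped:
            return 1.0
        return min(float(self.imputation_r2), 1.0)

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
        return _COMPLEMENT.get(self.ref_allele) == self.count_allele


@dataclass
class GenotypeDataset:
    """One study's genotypes, phenotype, and covariates.

    dosages:
        (n_samples, n_snps) float array of expected count-allele dosage in
        [0, 2]; NaN marks missing.
    genotype_probs:
        optional (n_samples, n_snps, 3) array of P(0 copies), P(1), P(2).
    phenotype:
        (n_samples,) int array, 1 = case, 0 = control.
    covariates:
        (n_samples, n_cov) float array entered in every regression; study
        centers enter as indicator columns here (per-study fits never pool
        individuals across studies).
    """

    study_id: str
    dosages: np.ndarray
    snps: list[SnpRecord]
    phenotype: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None
    genotype_probs: np.ndarray | None = None
    phase: str = "phase1"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.snps) != m:
            raise ValueError(f"{m} dosage columns but {len(self.snps)} SNP records")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match sample count")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match sample count")
        if self.genotype_probs is not None:
            gp = np.asarray(self.genotype_probs, dtype=float)
            if gp.shape != (n, m, 3):
                raise ValueError("genotype_probs must be (n_samples, n_snps, 3)")
            sums = gp.sum(axis=2)
            ok = np.isnan(sums) | (np.abs(sums - 1.0) <= 1e-6)
            if not ok.all():
                raise ValueError("genotype probability triples must sum to 1")
            self.genotype_probs = gp

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return i
        raise KeyError(f"SNP {snp_id!r} not in study {self.study_id!r}")

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def probs(self, snp_id: str) -> np.ndarray | None:
        if self.genotype_probs is None:
            return None
        return self.genotype_probs[:, self.snp_index(snp_id), :]


def compute_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from a dosage vector: min(f, 1-f) with
    f = mean(dosage)/2 over non-missing samples."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("cannot compute MAF: all dosages missing")
    f = float(d.mean()) / 2.0
    return min(f, 1.0 - f)


def _match_alleles(ref: SnpRecord, other: SnpRecord) -> str | None:
    """How ``other``'s alleles relate to the reference record's.

    Returns "same", "swap" (other counts the reference record's ref allele),
    or None when the pairs cannot be reconciled even after strand
    complementation.
    """
    a = (other.ref_allele, other.count_allele)
    want_same = (ref.ref_allele, ref.count_allele)
    if a == want_same:
        return "same"
    if a == (ref.count_allele, ref.ref_allele):
        return "swap"
    comp = tuple(_COMPLEMENT.get(x, "?") for x in a)
    if comp == want_same:
        return "same"
    if comp == (ref.count_allele, ref.ref_allele):
        return "swap"
    return None


def harmonize_alleles(studies: list[GenotypeDataset]) -> list[GenotypeDataset]:
    """Align every study to count the same allele per shared SNP.

    The first study carrying a SNP defines its count allele; later studies
    counting the opposite allele have dosages flipped d -> 2 - d (and
    genotype-probability triples reversed). Allele pairs that cannot be
    reconciled drop the SNP from the offending study. Strand-ambiguous
    (A/T, C/G) SNPs are flagged via :attr:`SnpRecord.strand_ambiguous` and
    logged, never frequency-flipped.
    """
    if not studies:
        raise ValueError("harmonize_alleles needs at least one study")
    reference: dict[tuple[str, str, int], SnpRecord] = {}
    out: list[GenotypeDataset] = []
    for study in studies:
        keep: list[int] = []
        new_snps: list[SnpRecord] = []
        dosages = study.dosages.copy()
        probs = None if study.genotype_probs is None else study.genotype_probs.copy()
        for j, snp in enumerate(study.snps):
            ref = reference.get(snp.key)
            if ref is None:
                reference[snp.key] = snp
                if snp.strand_ambiguous:
                    logger.warning(
                        "%s: strand-ambiguous alleles %s/%s (flagged, not flipped)",
                        snp.snp_id, snp.ref_allele, snp.count_allele,
                    )
                keep.append(j)
                new_snps.append(snp)
                continue
            rel = _match_alleles(ref, snp)
            if rel is None:
                logger.warning(
                    "%s dropped from study %s: alleles %s/%s irreconcilable with %s/%s",
                    snp.snp_id, study.study_id, snp.ref_allele, snp.count_allele,
                    ref.ref_allele, ref.count_allele,
                )
                continue
            if rel == "swap":
                dosages[:, j] = 2.0 - dosages[:, j]
                if probs is not None:
                    probs[:, j, :] = probs[:, j, ::-1]
                snp = replace(
                    snp,
                    ref_allele=ref.ref_allele,
                    count_allele=ref.count_allele,
                    maf=snp.maf,
                )
            else:
                snp = replace(snp, ref_allele=ref.ref_allele,
                              count_allele=ref.count_allele)
            keep.append(j)
            new_snps.append(snp)
        out.append(
            GenotypeDataset(
                study_id=study.study_id,
                dosages=dosages[:, keep],
                snps=new_snps,
                phenotype=study.phenotype,
                covariates=study.covariates,
                covariate_names=list(study.covariate_names),
                sample_ids=study.sample_ids,
                genotype_probs=None if probs is None else probs[:, keep, :],
                phase=study.phase,
            )
        )
    return out
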