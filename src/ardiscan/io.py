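"""Readers and writers for the plain-text interchange formats.

Dosage matrices travel as TSV (rows = samples, first column ``sample_id``,
one column per SNP), phenotypes/covariates as TSV with a ``status`` column,
SNP metadata as TSV, and imputed genotypes as VCF with DS and/or GP FORMAT
fields (read through cyvcf2).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset, SnpRecord, compute_maf

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "snp1", "snp2", "model",
    "or_phase1", "ci_low_phase1", "ci_high_phase1", "p_phase1",
    "or_phase2", "ci_low_phase2", "ci_high_phase2", "p_phase2",
    "or_combined", "ci_low_combined", "ci_high_combined", "p_combined",
    "p_het", "k_studies", "selected", "bonferroni_significant",
]


def load_dosage_vcf(
    path: str | Path,
    count_allele_policy: str = "alt",
    study_id: str | None = None,
) -> GenotypeDataset:
    """Read genotypes from a VCF into a dosage matrix.

    Per record the dosage source is, in order of preference: the DS FORMAT
    field, the GP triple (DS = P(het) + 2 P(hom-alt)), then hard GT calls.
    Records with none of the three are skipped with a warning. With
    ``count_allele_policy="alt"`` the ALT allele is counted; with
    ``"minor"`` the dosage is flipped to 2 - d wherever the ALT allele
    frequency exceeds 0.5, so the count allele is the minor allele.
    """
    from cyvcf2 import VCF

    if count_allele_policy not in ("alt", "minor"):
        raise ValueError(f"unknown count_allele_policy {count_allele_policy!r}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    columns: list[np.ndarray] = []
    probs: list[np.ndarray | None] = []
    snps: list[SnpRecord] = []
    any_gp = False
    for var in vcf:
        ds = None
        gp = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        try:
            gp = var.format("GP")
        except KeyError:
            gp = None
        if gp is not None:
            gp = np.asarray(gp, dtype=float).reshape(n, 3)
            dose = gp[:, 1] + 2.0 * gp[:, 2]
            any_gp = True
        elif ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(n)
            gp = None
        else:
            gts = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
            if gts.size != n:
                logger.warning("%s: no DS/GP/GT data, skipped", var.ID)
                continue
            dose = np.where(gts == 0, 0.0,
                            np.where(gts == 1, 1.0,
                                     np.where(gts == 3, 2.0, np.nan)))
        ref, alt = var.REF, var.ALT[0]
        flipped = False
        if count_allele_policy == "minor":
            finite = dose[np.isfinite(dose)]
            if finite.size and finite.mean() / 2.0 > 0.5:
                dose = 2.0 - dose
                if gp is not None:
                    gp = gp[:, ::-1]
                ref, alt = alt, ref
                flipped = True
        rec = SnpRecord(
            snp_id=var.ID or f"{var.CHROM}:{var.POS}",
            chrom=str(var.CHROM),
            pos=int(var.POS),
            ref_allele=ref,
            count_allele=alt,
            maf=compute_maf(dose),
        )
        if flipped:
            logger.info("%s: counting minor allele %s", rec.snp_id, alt)
        snps.append(rec)
        columns.append(dose)
        probs.append(gp)

    dosages = np.column_stack(columns) if columns else np.empty((n, 0))
    gp_arr = None
    if any_gp:
        gp_arr = np.full((n, len(snps), 3), np.nan)
        for j, g in enumerate(probs):
            if g is not None:
                gp_arr[:, j, :] = g
    return GenotypeDataset(
        study_id=study_id or Path(path).stem,
        dosages=dosages,
        snps=snps,
        phenotype=np.zeros(n, dtype=int),
        sample_ids=samples,
        genotype_probs=gp_arr,
    )


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Dosage TSV -> DataFrame indexed by sample_id, one column per SNP."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                     float_precision="round_trip")
    return df.set_index(df.columns[0])


def write_dosage_tsv(path: str | Path, dosages: np.ndarray,
                     sample_ids: list[str], snp_ids: list[str]) -> None:
    df = pd.DataFrame(dosages, columns=snp_ids)
    df.insert(0, "sample_id", sample_ids)
    # repr-round-trip float formatting keeps read(write(x)) bit-exact
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate TSV -> DataFrame indexed by sample_id.

    Requires columns ``sample_id`` and ``status`` (1 = case, 0 = control);
    every remaining numeric column is a covariate.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ValueError(f"{path}: phenotype TSV needs sample_id and status columns")
    return df.set_index("sample_id")


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(SnpRecord(
            snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
            ref_allele=row.ref_allele, count_allele=row.count_allele,
            maf=float(getattr(row, "maf", np.nan)),
            imputation_r2=float(getattr(row, "imputation_r2", 1.0)),
            genotyped=bool(getattr(row, "genotyped", False)),
        ))
    return records


def write_snp_table(path: str | Path, snps: list[SnpRecord]) -> None:
    pd.DataFrame([{
        "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
        "ref_allele": s.ref_allele, "count_allele": s.count_allele,
        "maf": s.maf, "imputation_r2": s.imputation_r2,
        "genotyped": s.genotyped,
    } for s in snps]).to_csv(path, sep="\t", index=False)


def load_study(
    dosage_path: str | Path,
    phenotype_path: str | Path,
    snp_path: str | Path | None = None,
    study_id: str = "study",
    phase: str = "phase1",
) -> GenotypeDataset:
    """Assemble a study from dosage + phenotype (+ optional SNP metadata) TSVs.

    Samples are inner-joined on sample_id; covariates are every phenotype
    column other than ``status``.
    """
    dos = read_dosage_tsv(dosage_path)
    phe = read_phenotype_tsv(phenotype_path)
    shared = dos.index.intersection(phe.index)
    if len(shared) == 0:
        raise ValueError("no shared sample_ids between dosage and phenotype files")
    dos = dos.loc[shared]
    phe = phe.loc[shared]
    cov_cols = [c for c in phe.columns if c != "status"]
    if snp_path is not None:
        snps = read_snp_table(snp_path)
        by_id = {s.snp_id: s for s in snps}
        snps = [by_id[c] for c in dos.columns]
    else:
        snps = [
            SnpRecord(snp_id=c, chrom="0", pos=j + 1, ref_allele="A",
                      count_allele="B", maf=compute_maf(dos[c].to_numpy()))
            for j, c in enumerate(dos.columns)
        ]
    return GenotypeDataset(
        study_id=study_id,
        dosages=dos.to_numpy(dtype=float),
        snps=snps,
        phenotype=phe["status"].to_numpy(dtype=int),
        covariates=phe[cov_cols].to_numpy(dtype=float) if cov_cols else None,
        covariate_names=cov_cols,
        sample_ids=list(shared),
        phase=phase,
    )


def write_results_tsv(path: str | Path, rows: pd.DataFrame,
                      header_comments: list[str] | None = None) -> None:
    """Write a pair-result table with the fixed column order, prefixing
    ``#`` provenance comments (thresholds, manifest digest)."""
    cols = [c for c in RESULT_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        rows[cols].to_csv(fh, sep="\t", index=False)
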