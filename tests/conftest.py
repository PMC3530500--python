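import numpy as np
import pytest

from ardiscan.datamodel import GenotypeDataset, SnpRecord, compute_maf


def make_dataset(g1, g2, y, covariates=None, covariate_names=None,
                 study_id="t", phase="phase1", probs=None):
    """Assemble a two-SNP GenotypeDataset from raw arrays."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    snps = [
        SnpRecord("snp1", "1", 100, "A", "C", maf=compute_maf(g1)),
        SnpRecord("snp2", "2", 200, "G", "T", maf=compute_maf(g2)),
    ]
    return GenotypeDataset(
        study_id=study_id,
        dosages=np.column_stack([g1, g2]),
        snps=snps,
        phenotype=np.asarray(y, dtype=int),
        covariates=covariates,
        covariate_names=covariate_names or [],
        genotype_probs=probs,
        phase=phase,
    )


def expand_counts(cases, controls):
    """Genotype/phenotype vectors realizing a 3x3 case/control count grid."""
    g1, g2, y = [], [], []
    for a in range(3):
        for b in range(3):
            for status, n in ((1, int(cases[a][b])), (0, int(controls[a][b]))):
                g1.extend([a] * n)
                g2.extend([b] * n)
                y.extend([status] * n)
    return np.array(g1, float), np.array(g2, float), np.array(y, int)


# Two-locus genotype-combination counts (cases, controls) for a large
# case-control study; baseline cell (0,0), used for crude-OR arithmetic.
TWO_LOCUS_COUNTS = {
    "cases": [[3212, 1599, 229], [2896, 1355, 349], [691, 319, 250]],
    "controls": [[3968, 1783, 246], [3585, 1858, 316], [771, 493, 193]],
}


@pytest.fixture(scope="session")
def two_locus_table_data():
    g1, g2, y = expand_counts(TWO_LOCUS_COUNTS["cases"],
                              TWO_LOCUS_COUNTS["controls"])
    return make_dataset(g1, g2, y)


@pytest.fixture(scope="session")
def small_pair_dataset():
    """200-sample no-covariate two-SNP dataset for closed-form oracles."""
    rng = np.random.default_rng(7)
    g1 = rng.binomial(2, 0.3, 200).astype(float)
    g2 = rng.binomial(2, 0.25, 200).astype(float)
    eta = -0.5 + 0.3 * g1 + 0.2 * g2 - 0.4 * np.minimum(g1, 1) * np.minimum(g2, 1)
    y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(int)
    return make_dataset(g1, g2, y)
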