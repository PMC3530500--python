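"""The two published gene–gene search strategies.

1. Known-locus scan: for each susceptibility locus, test its interaction
   with every SNP passing the MAF / imputation-quality filters genome-wide;
   carry phase-1 hits below 1e-6 into replication, reporting one SNP per LD
   cluster.
2. Two-stage all-pairs scan: marginal screen (both fixed- and random-effect
   meta p below 1e-4), greedy LD pruning at r^2 > 0.8, then every pairwise
   interaction among the pruned SNPs with Bonferroni accounting over
   n(n-1)/2 tests.

Because the marginal screen and the interaction test's main effects share
the additive genetic coding, screening on marginal association is
independent of the interaction test, and only the second-stage tests need
multiple-testing adjustment.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset
from .interaction import MODEL_TESTS, test_marginal
from .meta import MetaResult, fixed_effect_meta, phase_meta, random_effect_meta

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Thresholds driving both search strategies (defaults as published)."""

    maf_min: float = 0.05
    r2_min: float = 0.3            # imputation quality
    marginal_p_max: float = 1e-4
    ld_r2_max: float = 0.8
    known_locus_select_p: float = 1e-6
    pairs_select_p: float = 5e-5
    alpha: float = 0.05
    het_p_min: float | None = None  # optional heterogeneity filter, off by default

    def __post_init__(self) -> None:
        for name in ("maf_min", "r2_min", "marginal_p_max", "ld_r2_max",
                     "known_locus_select_p", "pairs_select_p", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


#: The 14 colorectal-cancer susceptibility loci used for the known-locus scan.
KNOWN_CRC_LOCI: dict[str, str] = {
    "rs6687758": "1q41",
    "rs10936599": "3q26.2",
    "rs16892766": "8q23.3",
    "rs6983267": "8q24",
    "rs10795668": "10p14",
    "rs3802842": "11q23",
    "rs7136702": "12q13.13",
    "rs4444235": "14q22.2",
    "rs4779584": "15q13",
    "rs9929218": "16q22.1",
    "rs4939827": "18q21",
    "rs10411210": "19q13",
    "rs961253": "20p12.3",
    "rs4925386": "20q13.33",
}


@dataclass
class KnownLocusPanel:
    loci: dict[str, str] = field(default_factory=lambda: dict(KNOWN_CRC_LOCI))

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel rsIDs must be unique")

    @property
    def rsids(self) -> list[str]:
        return list(self.loci)


def select_marginal_candidates(
    marginal: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> list[str]:
    """Apply the stage-1 candidate filter.

    ``marginal`` has one row per SNP with columns ``snp_id``, ``maf``,
    ``mean_r2`` (average imputation quality across studies, genotyped
    counted as 1), ``p_fixed`` and ``p_random``. A SNP is kept iff it passes
    all four conditions: MAF above threshold, average imputation quality
    above threshold, and both fixed- and random-effect meta p-values below
    the marginal cutoff (requiring both avoids signals dominated by a few
    studies).
    """
    cfg = cfg or ScreenConfig()
    keep = (
        (marginal["maf"] > cfg.maf_min)
        & (marginal["mean_r2"] > cfg.r2_min)
        & (marginal["p_fixed"] < cfg.marginal_p_max)
        & (marginal["p_random"] < cfg.marginal_p_max)
    )
    return marginal.loc[keep, "snp_id"].tolist()


def marginal_meta_table(
    studies: list[GenotypeDataset],
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP marginal association meta-analysis across studies.

    Returns the DataFrame consumed by :func:`select_marginal_candidates`,
    including per-SNP MAF (pooled) and mean imputation quality.
    """
    snp_ids = snp_ids or studies[0].snp_ids
    rows = []
    for snp in snp_ids:
        ests = []
        mafs, r2s = [], []
        for st in studies:
            try:
                j = st.snp_index(snp)
            except KeyError:
                continue
            ests.append(test_marginal(st, snp))
            mafs.append(st.snps[j].maf)
            r2s.append(st.snps[j].effective_r2)
        usable = [e for e in ests if e.converged]
        if not usable:
            continue
        fixed = fixed_effect_meta(usable)
        random = random_effect_meta(usable)
        rows.append({
            "snp_id": snp,
            "maf": float(np.nanmean(mafs)),
            "mean_r2": float(np.mean(r2s)),
            "beta_fixed": fixed.beta,
            "p_fixed": fixed.p,
            "p_random": random.p,
            "p_het": fixed.p_het,
        })
    return pd.DataFrame(rows)


def ld_r2(d1: np.ndarray, d2: np.ndarray, min_n: int = 30) -> float:
    """Squared Pearson correlation of two dosage vectors over shared
    complete cases. Zero variance in either vector is undefined and is
    treated as 0 with a warning."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    mask = np.isfinite(d1) & np.isfinite(d2)
    if int(mask.sum()) < min_n:
        raise ValueError(f"need >= {min_n} joint non-missing samples")
    a, b = d1[mask], d2[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero dosage variance: LD r^2 undefined, treated as 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def control_dosage_matrix(studies: list[GenotypeDataset],
                          snp_ids: list[str]) -> np.ndarray:
    """Control dosages pooled across studies (samples x SNPs; NaN where a
    study lacks the SNP). LD is estimated in controls to avoid
    case-enrichment distortion."""
    blocks = []
    for st in studies:
        ctrl = st.phenotype == 0
        block = np.full((int(ctrl.sum()), len(snp_ids)), np.nan)
        for j, snp in enumerate(snp_ids):
            try:
                block[:, j] = st.dosage(snp)[ctrl]
            except KeyError:
                pass
        blocks.append(block)
    return np.vstack(blocks)


def pairwise_ld(studies: list[GenotypeDataset],
                snp_ids: list[str]) -> pd.DataFrame:
    """Pairwise LD r^2 matrix from pooled control dosages."""
    mat = control_dosage_matrix(studies, snp_ids)
    k = len(snp_ids)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = ld_r2(mat[:, i], mat[:, j])
    return pd.DataFrame(out, index=snp_ids, columns=snp_ids)


def ld_prune(ranked_snp_ids: list[str], r2: pd.DataFrame,
             cfg: ScreenConfig | None = None) -> list[str]:
    """Greedy LD pruning of a p-value-ranked SNP list.

    Starting with the strongest signal, every later SNP with r^2 above the
    threshold to the current SNP is removed; the sweep then moves to the
    next surviving SNP until the end of the list. Output preserves the rank
    order and is maximal: no surviving pair exceeds the threshold.
    """
    cfg = cfg or ScreenConfig()
    alive = list(ranked_snp_ids)
    kept: list[str] = []
    while alive:
        head = alive.pop(0)
        kept.append(head)
        alive = [s for s in alive if r2.loc[head, s] <= cfg.ld_r2_max]
    return kept


def rank_by_p(marginal: pd.DataFrame,
              snp_info: dict[str, tuple[str, int]] | None = None) -> list[str]:
    """Order SNPs by marginal p ascending; ties break by chromosome then
    position for a deterministic total order."""
    df = marginal.copy()
    if snp_info:
        df["chrom"] = [snp_info.get(s, ("", 0))[0] for s in df["snp_id"]]
        df["pos"] = [snp_info.get(s, ("", 0))[1] for s in df["snp_id"]]
    else:
        df["chrom"], df["pos"] = "", 0
    df = df.sort_values(["p_fixed", "chrom", "pos"], kind="mergesort")
    return df["snp_id"].tolist()


def bonferroni_pairs(n_snps: int, alpha: float = 0.05) -> tuple[int, float]:
    """Number of unordered pairs n(n-1)/2 and the Bonferroni threshold
    alpha over that count."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs to form pairs")
    n_tests = n_snps * (n_snps - 1) // 2
    return n_tests, alpha / n_tests


def _meta_row(snp1: str, snp2: str, model: str,
              metas: dict[str, MetaResult | None]) -> dict:
    row: dict = {"snp1": snp1, "snp2": snp2, "model": model}
    for phase in ("phase1", "phase2", "combined"):
        m = metas.get(phase)
        if m is None:
            row.update({f"or_{phase}": np.nan, f"ci_low_{phase}": np.nan,
                        f"ci_high_{phase}": np.nan, f"p_{phase}": np.nan})
        else:
            lo, hi = m.ci95
            row.update({f"or_{phase}": m.odds_ratio, f"ci_low_{phase}": lo,
                        f"ci_high_{phase}": hi, f"p_{phase}": m.p})
    comb = metas.get("combined")
    row["p_het"] = np.nan if comb is None or comb.p_het is None else comb.p_het
    row["k_studies"] = 0 if comb is None else comb.k
    return row


def test_pair_across_studies(studies: list[GenotypeDataset], snp1: str,
                             snp2: str, model: str = "ardi",
                             include_adenoma: bool = False):
    """Run one interaction model per study and meta-analyze by phase."""
    test = MODEL_TESTS[model]
    estimates = []
    for st in studies:
        try:
            estimates.append(test(st, snp1, snp2))
        except KeyError:
            continue
    usable = [e for e in estimates if e.converged]
    metas = (phase_meta(usable, include_adenoma=include_adenoma)
             if usable else {"phase1": None, "phase2": None,
                             "adenoma": None, "combined": None})
    return estimates, metas


def scan_pairs(studies: list[GenotypeDataset], snp_ids: list[str],
               cfg: ScreenConfig | None = None,
               model: str = "ardi") -> pd.DataFrame:
    """All-pairs interaction scan over a pruned SNP panel.

    One row per unordered pair (always C(n,2) rows); per-study tests are
    meta-analyzed by phase. ``selected`` flags phase-1 p below the
    replication cutoff; ``bonferroni_significant`` flags combined p below
    alpha / C(n,2). Fit failures leave a row with missing estimates.
    """
    cfg = cfg or ScreenConfig()
    n_tests, threshold = bonferroni_pairs(len(snp_ids), cfg.alpha)
    rows = []
    for snp1, snp2 in itertools.combinations(snp_ids, 2):
        _, metas = test_pair_across_studies(studies, snp1, snp2, model)
        row = _meta_row(snp1, snp2, model, metas)
        p1 = row["p_phase1"]
        pc = row["p_combined"]
        row["selected"] = bool(np.isfinite(p1) and p1 < cfg.pairs_select_p)
        row["bonferroni_significant"] = bool(np.isfinite(pc) and pc < threshold)
        # heterogeneity is reported, never filtered by default
        if cfg.het_p_min is not None and np.isfinite(row["p_het"]):
            row["selected"] &= bool(row["p_het"] > cfg.het_p_min)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_tests"] = n_tests
    df.attrs["bonferroni_threshold"] = threshold
    return df


def scan_known_loci(studies: list[GenotypeDataset], panel: KnownLocusPanel,
                    cfg: ScreenConfig | None = None,
                    model: str = "ardi") -> pd.DataFrame:
    """Known-locus scan: each panel locus against every filtered SNP.

    Partner SNPs must pass the MAF and average imputation-quality filters
    and must not be LD partners (r^2 above threshold, pooled controls) of
    the locus itself — testing interaction between two SNPs carrying the
    same signal is not meaningful. Rows with phase-1 p below the selection
    cutoff are flagged; among flagged partners in mutual LD only the most
    significant is reported (``reported`` column).
    """
    cfg = cfg or ScreenConfig()
    rows = []
    all_ids = studies[0].snp_ids
    for locus in panel.rsids:
        if locus not in all_ids:
            logger.warning("known locus %s absent from data: skipped", locus)
            continue
        partners = []
        for snp in all_ids:
            if snp == locus:
                continue
            recs = [st.snps[st.snp_index(snp)] for st in studies
                    if snp in st.snp_ids]
            maf = float(np.nanmean([r.maf for r in recs]))
            mean_r2 = float(np.mean([r.effective_r2 for r in recs]))
            if maf <= cfg.maf_min or mean_r2 <= cfg.r2_min:
                continue
            partners.append(snp)
        if not partners:
            continue
        ctrl = control_dosage_matrix(studies, [locus] + partners)
        locus_d = ctrl[:, 0]
        partners = [s for i, s in enumerate(partners)
                    if ld_r2(locus_d, ctrl[:, i + 1]) <= cfg.ld_r2_max]
        for snp in partners:
            _, metas = test_pair_across_studies(studies, locus, snp, model)
            row = _meta_row(locus, snp, model, metas)
            row["locus"] = locus
            p1 = row["p_phase1"]
            row["selected"] = bool(np.isfinite(p1)
                                   and p1 < cfg.known_locus_select_p)
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df.attrs["n_selected"] = 0
        return df
    # within LD clusters of selected partners, report the best-p representative
    df["reported"] = False
    for locus, group in df[df["selected"]].groupby("locus"):
        order = group.sort_values("p_phase1").index.tolist()
        chosen: list[str] = []
        ctrl = control_dosage_matrix(
            studies, df.loc[order, "snp2"].tolist())
        col = {s: i for i, s in enumerate(df.loc[order, "snp2"])}
        for idx in order:
            snp = df.loc[idx, "snp2"]
            if all(ld_r2(ctrl[:, col[snp]], ctrl[:, col[c]]) <= cfg.ld_r2_max
                   for c in chosen):
                chosen.append(snp)
                df.loc[idx, "reported"] = True
    df.attrs["n_selected"] = int(df["selected"].sum())
    return df
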