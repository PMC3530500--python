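"""Workflow orchestration: the two published search strategies end to end,
with a run manifest for reproducibility.

A config is a flat mapping (YAML file or dict): study file paths, screening
thresholds, seeds, and output directory. Deterministic stages are pure
functions of (inputs, config, seed), so reruns with an identical manifest
produce identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import GenotypeDataset
from .diagnostics import inflation_guard, record_recoding
from .io import load_study, write_results_tsv
from .screening import (
    KnownLocusPanel,
    ScreenConfig,
    bonferroni_pairs,
    ld_prune,
    marginal_meta_table,
    pairwise_ld,
    rank_by_p,
    scan_known_loci,
    scan_pairs,
    select_marginal_candidates,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_FIT_FAILURE = 4


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    stage_counts: dict[str, int] = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "inputs": self.input_digests,
             "seed": self.seed, "version": self.version},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({**asdict(self), "digest": self.digest()}, fh,
                      indent=2, default=str)


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def screen_config_from(config: dict) -> ScreenConfig:
    fields = ScreenConfig.__dataclass_fields__
    return ScreenConfig(**{k: v for k, v in config.items() if k in fields})


def load_studies_from_config(config: dict) -> tuple[list[GenotypeDataset], RunManifest]:
    manifest = RunManifest(config=dict(config), seed=config.get("seed"))
    studies = []
    for entry in config["studies"]:
        study = load_study(
            entry["dosages"], entry["phenotypes"], entry.get("snps"),
            study_id=entry.get("study_id", Path(entry["dosages"]).stem),
            phase=entry.get("phase", "phase1"),
        )
        studies.append(study)
        for key in ("dosages", "phenotypes", "snps"):
            if entry.get(key):
                manifest.input_digests[str(entry[key])] = _file_digest(entry[key])
    manifest.stage_counts["studies"] = len(studies)
    return studies, manifest


def _provenance(cfg: ScreenConfig, manifest: RunManifest) -> list[str]:
    lines = [f"ardiscan {__version__} manifest={manifest.digest()}"]
    lines += [f"{k}={v}" for k, v in asdict(cfg).items()]
    return lines


def run_known_locus_workflow(
    config: dict,
    studies: list[GenotypeDataset] | None = None,
) -> dict:
    """Known-locus scan -> inflation diagnostic -> guard rerun if needed ->
    phase-1 selection -> combined meta; writes a results TSV, a lambda
    report, and the manifest."""
    cfg = screen_config_from(config)
    if studies is None:
        studies, manifest = load_studies_from_config(config)
    else:
        manifest = RunManifest(config=dict(config), seed=config.get("seed"))
    panel = KnownLocusPanel(config["panel"]) if "panel" in config \
        else KnownLocusPanel()
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    result = scan_known_loci(studies, panel, cfg, model=config.get("model", "ardi"))
    reports = []
    if not result.empty:
        for locus, group in result.groupby("locus"):
            pvals = group["p_phase1"].dropna().to_numpy()
            if pvals.size == 0:
                continue
            report = inflation_guard(pvals, locus_id=locus,
                                     threshold=config.get("lambda_threshold", 1.05))
            if report.inflated:
                logger.info("locus %s inflated (lambda=%.3f): rerunning with "
                            "unrestricted main effects", locus, report.lam)
                rerun = scan_known_loci(
                    studies, KnownLocusPanel({locus: panel.loci.get(locus, "")}),
                    cfg, model="ardi_umain")
                record_recoding(report, rerun["p_phase1"].dropna().to_numpy())
                result = result[result["locus"] != locus]
                result = pd.concat([result, rerun], ignore_index=True)
            reports.append(report)
    manifest.stage_counts["scan_rows"] = len(result)
    manifest.stage_counts["selected"] = int(result["selected"].sum()) \
        if not result.empty else 0
    write_results_tsv(out_dir / "known_locus_results.tsv", result,
                      _provenance(cfg, manifest))
    lam_rows = pd.DataFrame([{
        "locus": r.locus_id, "lambda": r.lam, "n_tests": r.n_tests,
        "coding_used": r.coding_used,
        "lambda_after_recoding": r.lam_after_recoding,
    } for r in reports])
    lam_rows.to_csv(out_dir / "inflation_report.tsv", sep="\t", index=False)
    manifest.write(out_dir / "manifest.json")
    return {"results": result, "inflation": reports, "manifest": manifest}


def run_pair_scan_workflow(
    config: dict,
    studies: list[GenotypeDataset] | None = None,
) -> dict:
    """Marginal scan -> candidate selection -> LD pruning -> all-pairs
    interaction scan with Bonferroni accounting; writes result TSVs and the
    manifest."""
    cfg = screen_config_from(config)
    if studies is None:
        studies, manifest = load_studies_from_config(config)
    else:
        manifest = RunManifest(config=dict(config), seed=config.get("seed"))
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    marginal = marginal_meta_table(studies)
    manifest.stage_counts["snps_tested"] = len(marginal)
    candidates = select_marginal_candidates(marginal, cfg)
    manifest.stage_counts["candidates"] = len(candidates)
    if len(candidates) < 2:
        logger.warning("fewer than 2 candidate SNPs: no pairs to test")
        empty = pd.DataFrame()
        write_results_tsv(out_dir / "pair_scan_results.tsv", empty,
                          _provenance(cfg, manifest))
        manifest.write(out_dir / "manifest.json")
        return {"marginal": marginal, "pruned": candidates,
                "results": empty, "manifest": manifest}

    snp_info = {}
    for st in studies:
        for s in st.snps:
            snp_info.setdefault(s.snp_id, (s.chrom, s.pos))
    ranked = [s for s in rank_by_p(marginal, snp_info) if s in set(candidates)]
    r2 = pairwise_ld(studies, ranked)
    pruned = ld_prune(ranked, r2, cfg)
    manifest.stage_counts["pruned"] = len(pruned)
    n_tests, threshold = bonferroni_pairs(len(pruned), cfg.alpha)
    manifest.stage_counts["n_tests"] = n_tests

    result = scan_pairs(studies, pruned, cfg, model=config.get("model", "ardi"))
    manifest.stage_counts["selected"] = int(result["selected"].sum())
    extra = [f"pruned_snps={len(pruned)}", f"n_tests={n_tests}",
             f"bonferroni_threshold={threshold:.6g}"]
    write_results_tsv(out_dir / "pair_scan_results.tsv", result,
                      _provenance(cfg, manifest) + extra)
    marginal.to_csv(out_dir / "marginal_results.tsv", sep="\t", index=False)
    manifest.write(out_dir / "manifest.json")
    return {"marginal": marginal, "pruned": pruned, "results": result,
            "n_tests": n_tests, "bonferroni_threshold": threshold,
            "manifest": manifest}
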