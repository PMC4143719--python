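"""End-to-end pipeline: phenotypes -> QC -> PCA -> scan -> blocks -> tests.

Two modes mirror the two analyses the package supports:

* ``candidate`` — haplotype blocks are the LD blocks containing the SNPs
  that pass the per-SNP scan at the nominal threshold (gene-based mode);
* ``chromosome`` — every block found chromosome-wide (100-kb pairwise LD
  window) is tested, with a Bonferroni family-wise threshold of
  0.05 / number of blocks.

The pipeline is a pure function of (inputs, config, seed); per-stage
artifacts are written as TSV/CSV into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocktests import (
    bonferroni_threshold,
    haplotype_specific_tests,
    omnibus_lrt,
    permutation_test,
)
from .containers import GenotypeMatrix
from .haplotypes import diplotype_posteriors, em_haplotype_frequencies, expected_dosage_design
from .io import read_exam_csv, read_ped, read_subject_csv, read_vcf, write_vcf
from .ld import (
    DEFAULT_WINDOW_BP,
    block_containing,
    blocks_to_bed,
    four_gamete_blocks,
    gabriel_blocks,
)
from .pca import ancestry_pcs
from .phenotype import build_covariates
from .qc import DEFAULT_THRESHOLDS, run_qc_pipeline
from .scan import CANDIDATE_ALPHA, select_candidates, snp_scan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str  # .vcf or .ped prefix
    exams: str
    subjects: str
    outdir: str
    mode: str = "candidate"  # candidate | chromosome
    hypertension_rule: str = "and"
    qc_thresholds: dict = field(default_factory=dict)
    pca_k: int = 1
    scan_alpha: float = CANDIDATE_ALPHA
    block_method: str = "gabriel"  # gabriel | four_gamete
    window_bp: int = DEFAULT_WINDOW_BP
    pool_below: float = 0.01
    test_alpha: float = 0.05
    permutations: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("candidate", "chromosome"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.block_method not in ("gabriel", "four_gamete"):
            raise ValueError(f"unknown block method {self.block_method!r}")
        if self.permutations > 0 and self.seed is None:
            raise ValueError("seed required when permutations enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_genotypes(path: str) -> GenotypeMatrix:
    p = Path(path)
    if p.suffix == ".vcf":
        return read_vcf(p)
    return read_ped(p.with_suffix(""))


def _find_blocks(G: GenotypeMatrix, cfg: PipelineConfig):
    if cfg.block_method == "gabriel":
        return gabriel_blocks(G, window_bp=cfg.window_bp)
    return four_gamete_blocks(G)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a report bundle and writes artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"haploblock {__version__} pipeline, mode={cfg.mode}, seed={cfg.seed}")

    # phenotypes
    exam_df = read_exam_csv(cfg.exams)
    subject_df = read_subject_csv(cfg.subjects)
    covariates = build_covariates(exam_df, subject_df, rule=cfg.hypertension_rule)
    log(
        f"phenotypes: {len(subject_df)} subjects in, {len(covariates)} with outcome "
        f"({int(covariates['Y'].sum())} cases / {int((1 - covariates['Y']).sum())} controls)"
    )

    # genotypes + QC
    G = _load_genotypes(cfg.genotypes)
    log(f"genotypes: {G.n_individuals} individuals x {G.n_snps} SNPs")
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.qc_thresholds}
    G, qc_report = run_qc_pipeline(G, thresholds)
    for row in qc_report.steps.itertuples(index=False):
        log(
            f"qc/{row.step}: removed {row.n_individuals_removed} individuals, "
            f"{row.n_snps_removed} SNPs -> {row.individuals_remaining} x {row.snps_remaining}"
        )
    qc_report.to_tsv(outdir / "qc_report.tsv")

    # intersect with phenotyped individuals, in genotype order
    have_pheno = set(covariates["individual_id"])
    keep = np.array([iid in have_pheno for iid in G.individuals])
    G = G.subset_individuals(keep)
    covariates = (
        covariates.set_index("individual_id").loc[G.individuals].reset_index()
    )
    log(f"analysis set: {G.n_individuals} individuals with genotypes and phenotypes")

    # ancestry PCs
    pcs = ancestry_pcs(G, k=cfg.pca_k)
    covariates["pc1"] = pcs.components[:, 0]
    covariates.to_csv(outdir / "covariates.csv", index=False)

    # per-SNP scan
    scan_df = snp_scan(G, covariates)
    scan_df.to_csv(outdir / "snp_scan.tsv", sep="\t", index=False)
    candidates = select_candidates(scan_df, alpha=cfg.scan_alpha)
    log(f"scan: {len(candidates)} candidate SNP(s) at p < {cfg.scan_alpha:g}")

    # blocks
    blocks = _find_blocks(G, cfg)
    blocks_to_bed(blocks, outdir / "blocks.bed")
    log(f"blocks: {len(blocks)} found by {cfg.block_method}")
    if cfg.mode == "candidate":
        snp_pos = {sid: k for k, sid in enumerate(G.snps["id"])}
        chosen, singletons = [], []
        for sid in candidates["snp_id"]:
            b = block_containing(blocks, snp_pos[sid])
            if b is None:
                singletons.append(sid)
            elif all(b is not c for c in chosen):
                chosen.append(b)
        if singletons:
            log(f"candidate SNP(s) outside all blocks (excluded): {singletons}")
        test_blocks = chosen
    else:
        test_blocks = blocks
    log(f"testing {len(test_blocks)} block(s)")

    # haplotype analysis
    omni_rows, effect_rows = [], []
    n_tests = max(len(test_blocks), 1)
    fw_threshold = (
        bonferroni_threshold(cfg.test_alpha, n_tests)
        if cfg.mode == "chromosome"
        else cfg.test_alpha
    )
    for bi, block in enumerate(test_blocks):
        geno = G.block_values(block.snp_indices)
        table = em_haplotype_frequencies(geno)
        dists = diplotype_posteriors(geno, table, G.individuals)
        design = expected_dosage_design(dists, table, pool_below=cfg.pool_below)
        omni = omnibus_lrt(design, covariates)
        row = {
            "block_id": bi,
            "chrom": block.chrom,
            "start": block.start_pos,
            "end": block.end_pos,
            "n_snps": block.n_snps,
            "lrt": omni.lrt_stat,
            "df": omni.df,
            "p_value": omni.p_value,
            "threshold": fw_threshold,
        }
        if cfg.permutations > 0:
            row["perm_p"] = permutation_test(
                design, covariates, B=cfg.permutations, seed=cfg.seed + bi
            )
        omni_rows.append(row)
        if omni.converged and omni.p_value < fw_threshold:
            effects, block_threshold = haplotype_specific_tests(
                design, covariates, alpha_family=cfg.test_alpha
            )
            for e in effects:
                effect_rows.append(
                    {
                        "block_id": bi,
                        "haplotype": e.haplotype,
                        "or_estimate": e.or_estimate,
                        "ci_low": e.ci95[0],
                        "ci_high": e.ci95[1],
                        "p_value": e.p_value,
                        "frequency": e.frequency,
                        "threshold": block_threshold,
                        "significant": e.p_value < block_threshold,
                    }
                )
    omnibus_df = pd.DataFrame(omni_rows)
    effects_df = pd.DataFrame(effect_rows)
    omnibus_df.to_csv(outdir / "omnibus.tsv", sep="\t", index=False)
    effects_df.to_csv(outdir / "haplotype_effects.tsv", sep="\t", index=False)
    write_vcf(G, outdir / "genotypes_qc.vcf")
    log(
        f"omnibus: {int((omnibus_df['p_value'] < fw_threshold).sum()) if len(omnibus_df) else 0}"
        f" significant block(s) at threshold {fw_threshold:g}"
    )

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_individuals": G.n_individuals,
        "n_snps": G.n_snps,
        "n_candidates": int(len(candidates)),
        "n_blocks": len(blocks),
        "n_blocks_tested": len(test_blocks),
        "threshold": fw_threshold,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "covariates": covariates,
        "qc_report": qc_report,
        "scan": scan_df,
        "candidates": candidates,
        "blocks": blocks,
        "blocks_tested": test_blocks,
        "omnibus": omnibus_df,
        "effects": effects_df,
        "summary": summary,
    }
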