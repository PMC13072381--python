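"""File-based pipeline orchestration.

Each stage reads its inputs from, and writes its outputs to, a working
directory in plain-text formats (VCF/GFF3/FASTA/TSV/JSON), so every stage
is independently runnable and testable.  ``run_pipeline`` chains the
stages, logs progress, and writes a manifest with parameter values and
SHA-256 hashes of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import assoc as smassoc
from . import expression as smexpr
from . import io as smio
from . import popgen as smpop
from . import qtl_integrate as smqtl
from . import segregation as smseg
from . import synthgen as smgen
from .errors import DependencyError, StageError

logger = logging.getLogger("specklemap.pipeline")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = Field(default=0, ge=0, lt=2**31)
    simulate: bool = True

    # synthetic panel
    n_ind: int = Field(default=120, ge=4)
    k_true: int = Field(default=2, ge=1)
    fst: float = Field(default=0.2, ge=0.0, lt=1.0)
    n_loci: int = Field(default=800, ge=10)
    chrom_length: int = Field(default=500_000, ge=1000)
    n_chrom: int = Field(default=2, ge=1)
    ld_rho: float = Field(default=0.9, ge=0.0, lt=1.0)
    n_causal: int = Field(default=3, ge=0)
    h2_target: float = Field(default=0.5, ge=0.0, lt=1.0)
    missing_rate: float = Field(default=0.02, ge=0.0, lt=1.0)

    # synthetic F2 samples
    f2_n: int = Field(default=200, ge=10)
    f2_model: str = "2MG-EAD"
    f2_m: float = 10.0
    f2_d: float = 4.0
    f2_sigma_e2: float = 1.5

    # segregation
    segregation_top: int = Field(default=5, ge=1)
    em_restarts: int = Field(default=10, ge=0)

    # popgen
    maf_min: float = Field(default=0.05, ge=0.0, le=0.5)
    miss_max: float = Field(default=0.5, ge=0.0, le=1.0)
    k_min: int = Field(default=2, ge=1)
    k_max: int = Field(default=5, ge=1)
    cv_folds: int = Field(default=3, ge=2)
    max_dist_kb: float = Field(default=250.0, gt=0)
    bin_kb: float = Field(default=5.0, gt=0)

    # association
    assoc_models: List[str] = ["glm", "glmq", "mlmk", "mlmkq"]
    alpha: float = Field(default=0.05, gt=0, lt=1)

    # integration
    flank_bp: int = Field(default=250_000, ge=0)

    # expression
    calibrator: str = "2D"
    reference_gene: str = "GAPDH"
    ct_groups: List[str] = ["2D", "4D", "6D", "8D", "10D"]
    ct_effects: Dict[str, float] = {
        "2D": 0.0, "4D": -0.2, "6D": -1.0, "8D": -1.6, "10D": -2.4,
    }
    ct_n_bio: int = Field(default=3, ge=2)


def _path(cfg: PipelineConfig, name: str) -> str:
    return os.path.join(cfg.out_dir, name)


def _require(cfg: PipelineConfig, stage: str, name: str) -> str:
    p = _path(cfg, name)
    if not os.path.exists(p):
        raise DependencyError(stage, os.path.splitext(name)[0])
    return p


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> List[str]:
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = {str(i + 1): cfg.chrom_length for i in range(cfg.n_chrom)}
    causal_idx = sorted(
        rng.choice(cfg.n_loci, size=min(cfg.n_causal, cfg.n_loci), replace=False).tolist()
    )
    causal = [(int(i), float(rng.normal(1.0, 0.3)) * (1 if rng.random() < 0.7 else -1))
              for i in causal_idx]
    panel_spec = smgen.PanelSimSpec(
        n_ind=cfg.n_ind, K_true=cfg.k_true, fst=cfg.fst,
        chrom_lengths=chrom_lengths, n_loci=cfg.n_loci, ld_rho=cfg.ld_rho,
        causal=causal, h2_target=cfg.h2_target if causal else 0.0,
        missing_rate=cfg.missing_rate, seed=cfg.seed,
    )
    gm, pheno, truth = smgen.simulate_population(panel_spec)

    f2 = {}
    for group, seed_off in (("inbred", 1), ("hybrid", 2)):
        f2[group] = smgen.simulate_f2_phenotypes(
            smgen.F2SimSpec(
                model_code=cfg.f2_model, m=cfg.f2_m, effects={"d": cfg.f2_d},
                sigma_e2=cfg.f2_sigma_e2, n=cfg.f2_n, seed=cfg.seed + seed_off,
                group=group,
            )
        )
    ct = smgen.simulate_ct_table(
        cfg.ct_groups, cfg.ct_n_bio, cfg.ct_effects, seed=cfg.seed + 3,
        reference_gene=cfg.reference_gene,
    )
    paths = smgen.write_fixtures(
        cfg.out_dir, panel=gm, panel_pheno=pheno, truth=truth,
        f2_samples=f2, ct=ct, chrom_lengths=chrom_lengths,
        seed=cfg.seed, overwrite=True,
    )
    return sorted(paths.values())


def stage_segregate(cfg: PipelineConfig) -> List[str]:
    out = []
    for group in ("inbred", "hybrid"):
        path = _require(cfg, "segregate", f"pheno_{group}.tsv")
        pheno = smio.read_phenotypes(path)
        fits = smseg.fit_catalog(pheno, n_restarts=cfg.em_restarts, seed=cfg.seed)
        top = smseg.select_top_models(fits, cfg.segregation_top)
        rows = []
        for f in top:
            dec = smseg.decompose_variance(f, pheno) if f.converged else None
            rows.append({
                "model": f.code, "lnL": f.lnL, "aic": f.aic,
                "converged": f.converged,
                "h2_mg_pct": dec.h2_mg_pct if dec else np.nan,
                "sigma2_mg": dec.sigma2_mg if dec else np.nan,
                **{f"est_{k}": v for k, v in f.estimates.items()},
            })
        dest = _path(cfg, f"segregation_{group}.tsv")
        pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)
        out.append(dest)
    return out


def stage_filter(cfg: PipelineConfig) -> List[str]:
    vcf = _require(cfg, "filter", "panel.vcf")
    gm = smio.read_vcf(vcf)
    kept, report = smpop.filter_variants(gm, cfg.maf_min, cfg.miss_max)
    dest = _path(cfg, "panel_filtered.vcf")
    smio.write_vcf(kept, dest)
    rep = _path(cfg, "filter_report.tsv")
    report.removed.to_csv(rep, sep="\t", index=False)
    return [dest, rep]


def stage_popgen(cfg: PipelineConfig) -> List[str]:
    vcf = _require(cfg, "popgen", "panel_filtered.vcf")
    gm = smio.read_vcf(vcf)
    ids = gm.individuals["id"].tolist()
    out = []

    K = smpop.kinship_vanraden(gm)
    kpath = _path(cfg, "kinship.tsv")
    smio.write_matrix_tsv(K, kpath, labels=ids)
    out.append(kpath)

    adm = smpop.fit_admixture_cv(
        gm, K_range=range(cfg.k_min, cfg.k_max + 1),
        folds=cfg.cv_folds, seed=cfg.seed,
    )
    qpath = _path(cfg, "q_matrix.tsv")
    pd.DataFrame(adm.Q, index=ids).to_csv(qpath, sep="\t")
    cvpath = _path(cfg, "cv_errors.tsv")
    pd.DataFrame(
        {"K": list(adm.cv_errors), "cv_error": list(adm.cv_errors.values())}
    ).to_csv(cvpath, sep="\t", index=False)
    out += [qpath, cvpath]

    tree = smpop.pdistance_nj(gm)
    tpath = _path(cfg, "tree.nwk")
    with open(tpath, "w") as fh:
        fh.write(tree + "\n")
    out.append(tpath)

    ld = smpop.ld_decay(gm, max_dist_kb=cfg.max_dist_kb, bin_kb=cfg.bin_kb)
    ldpath = _path(cfg, "ld_decay.tsv")
    ld.decay_curve.to_csv(ldpath, sep="\t", index=False)
    out.append(ldpath)
    return out


def stage_assoc(cfg: PipelineConfig) -> List[str]:
    vcf = _require(cfg, "assoc", "panel_filtered.vcf")
    gm = smio.read_vcf(vcf)
    pheno_path = _require(cfg, "assoc", "panel_pheno.tsv")
    df = pd.read_csv(pheno_path, sep="\t")
    y = df.set_index("id").loc[gm.individuals["id"], "speckle_count"].to_numpy()
    from .containers import PhenotypeVector

    pv = PhenotypeVector(values=y, group="panel")
    Q = K = None
    if any(m in cfg.assoc_models for m in ("glmq", "mlmkq")):
        Q = pd.read_csv(_require(cfg, "assoc", "q_matrix.tsv"), sep="\t", index_col=0).to_numpy()
    if any(m in cfg.assoc_models for m in ("mlmk", "mlmkq")):
        K = smio.read_matrix_tsv(_require(cfg, "assoc", "kinship.tsv"))
    out = []
    for tag in cfg.assoc_models:
        scan = smassoc.run_association(gm, pv, tag, Q=Q, K=K)
        dest = _path(cfg, f"scan_{tag}.tsv")
        scan.table.to_csv(dest, sep="\t", index=False)
        out.append(dest)
        qq = smassoc.qq_and_lambda(scan)
        qq_dest = _path(cfg, f"qq_{tag}.png")
        smassoc.plot_qq(qq, qq_dest, title=f"{tag}: lambda={qq.lam:.3f}")
        out.append(qq_dest)
    return out


def stage_joint(cfg: PipelineConfig) -> List[str]:
    scans = []
    for tag in cfg.assoc_models:
        path = _require(cfg, "joint", f"scan_{tag}.tsv")
        table = pd.read_csv(path, sep="\t")
        scans.append(smassoc.AssociationScan(model_tag=tag, table=table))
    jd = smassoc.joint_detection(scans, alpha=cfg.alpha)
    dest = _path(cfg, "joint_detection.json")
    with open(dest, "w") as fh:
        json.dump(
            {
                "significant_counts": {t: len(s) for t, s in jd.sig_sets.items()},
                "joint_counts": jd.joint_counts,
                "exclusive": {
                    "+".join(sorted(k)): sorted(v) for k, v in jd.exclusive.items() if v
                },
                "thresholds": jd.thresholds,
            },
            fh,
            indent=1,
        )
    return [dest]


def stage_qtl(cfg: PipelineConfig) -> List[str]:
    vcf = _require(cfg, "qtl", "panel_filtered.vcf")
    gm = smio.read_vcf(vcf)
    pheno_path = _require(cfg, "qtl", "panel_pheno.tsv")
    df = pd.read_csv(pheno_path, sep="\t")
    from .containers import PhenotypeVector

    y = PhenotypeVector(
        values=df.set_index("id").loc[gm.individuals["id"], "speckle_count"].to_numpy(),
        group="panel",
    )
    scan_path = _require(cfg, "qtl", "scan_glm.tsv")
    scan = smassoc.AssociationScan(model_tag="glm", table=pd.read_csv(scan_path, sep="\t"))
    qtls = smqtl.map_qtl_intervals(gm, y, method="lod", scan=scan)
    out = []
    qtl_path = _path(cfg, "qtl_intervals.tsv")
    pd.DataFrame(
        [
            {"name": q.name, "chrom": q.chrom, "left": q.left, "right": q.right,
             "peak_score": q.peak_score, "pve_pct": q.pve_pct, "method": q.method}
            for q in qtls
        ]
    ).to_csv(qtl_path, sep="\t", index=False)
    out.append(qtl_path)

    sig, _ = smassoc.significant_set(scan, alpha=cfg.alpha)
    qtns = pd.DataFrame(
        {
            "id": [f"qtn{i}" for i in sorted(sig)],
            "chrom": scan.table["chrom"].iloc[sorted(sig)].astype(str).to_numpy(),
            "pos": scan.table["pos"].iloc[sorted(sig)].to_numpy(),
        }
    )
    overlap = smqtl.overlap_qtn_qtl(qtns, qtls)
    ov_path = _path(cfg, "qtn_qtl_overlap.tsv")
    overlap.to_csv(ov_path, sep="\t", index=False)
    out.append(ov_path)

    genes = smqtl.GeneModelSet.from_gff3(_require(cfg, "qtl", "genes.gff3"))
    windows = smqtl.candidate_genes_in_windows(qtns, genes, flank=cfg.flank_bp)
    win_path = _path(cfg, "candidate_windows.tsv")
    pd.DataFrame(
        [
            {"qtn": w.qtn, "chrom": w.chrom, "left": w.left, "right": w.right,
             "n_genes": len(w.gene_ids), "genes": ",".join(w.gene_ids)}
            for w in windows
        ]
    ).to_csv(win_path, sep="\t", index=False)
    out.append(win_path)

    genome = smio.read_fasta(_require(cfg, "qtl", "genome.fa"))
    gm_all = smio.read_vcf(_require(cfg, "qtl", "panel.vcf"))
    annotated, counts = smqtl.annotate_variants(gm_all.loci, genes, genome)
    ann_path = _path(cfg, "variant_annotation.tsv")
    annotated.to_csv(ann_path, sep="\t", index=False)
    counts_path = _path(cfg, "variant_category_counts.json")
    with open(counts_path, "w") as fh:
        json.dump(counts, fh, indent=1)
    out += [ann_path, counts_path]
    return out


def stage_expression(cfg: PipelineConfig) -> List[str]:
    ct_path = _require(cfg, "expression", "ct.tsv")
    ct = smio.read_ct_table(ct_path, reference_gene=cfg.reference_gene)
    rel = smexpr.relative_expression(ct, calibrator_group=cfg.calibrator)
    out = []
    rq_path = _path(cfg, "relative_expression.tsv")
    rel.per_sample.to_csv(rq_path, sep="\t", index=False)
    out.append(rq_path)
    group_path = _path(cfg, "relative_expression_groups.tsv")
    rel.per_group.to_csv(group_path, sep="\t", index=False)
    out.append(group_path)

    rows = []
    for gene in sorted(rel.per_sample["gene"].unique()):
        sub = rel.per_sample[rel.per_sample["gene"] == gene]
        by_group = {g: s["rq"].to_numpy() for g, s in sub.groupby("group")}
        letters = smexpr.anova_letters(by_group, alpha=cfg.alpha)
        for g, letter in letters.letters.items():
            rows.append({"gene": gene, "group": g, "letters": letter,
                         "anova_p": letters.p_value})
    let_path = _path(cfg, "expression_letters.tsv")
    pd.DataFrame(rows).to_csv(let_path, sep="\t", index=False)
    out.append(let_path)
    return out


STAGES = {
    "simulate": stage_simulate,
    "segregate": stage_segregate,
    "filter": stage_filter,
    "popgen": stage_popgen,
    "assoc": stage_assoc,
    "joint": stage_joint,
    "qtl": stage_qtl,
    "expression": stage_expression,
}


def run_pipeline(
    config: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> Dict:
    """Execute the configured stages in order and write a run manifest."""
    from . import __version__

    os.makedirs(config.out_dir, exist_ok=True)
    selected = list(STAGES) if stages is None else list(stages)
    if not config.simulate and "simulate" in selected and stages is None:
        selected.remove("simulate")
    unknown = [s for s in selected if s not in STAGES]
    if unknown:
        raise StageError(unknown[0], "unknown stage name")

    handler = logging.FileHandler(os.path.join(config.out_dir, "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    outputs: Dict[str, List[str]] = {}
    try:
        for name in STAGES:
            if name not in selected:
                continue
            logger.info("stage %s: start", name)
            try:
                files = STAGES[name](config)
            except DependencyError:
                raise
            except Exception as exc:  # halt with a stage-named error
                raise StageError(name, str(exc)) from exc
            outputs[name] = files
            logger.info("stage %s: wrote %d files", name, len(files))
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "package_version": __version__,
        "parameters": config.model_dump(),
        "stages": {
            name: [
                {"path": os.path.relpath(p, config.out_dir), "sha256": _sha256(p)}
                for p in files
            ]
            for name, files in outputs.items()
        },
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
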