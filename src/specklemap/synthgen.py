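"""Synthetic inputs for every pipeline stage.

Three generators:

* F2 phenotype samples drawn from any catalog genetic model — a major-
  genotype class is sampled from the model's Mendelian weights, Gaussian
  polygenic + environmental noise is added, and the result is rounded and
  clipped at zero to mimic a speckle count.
* A structured SNP panel: K latent subpopulations with Balding–Nichols
  differentiated allele frequencies, first-order chain LD decaying per kb,
  a handful of causal loci driving a count trait at a target heritability,
  and optional missingness.
* Triplicate qPCR Ct tables for target genes plus a reference gene across
  phenotype groups, with per-group ΔCt shifts.

``write_fixtures`` serializes a bundle to the plain-text formats the rest
of the pipeline reads (VCF v4.2, GFF3, FASTA, TSV, truth JSON).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .containers import CtTable, GenotypeMatrix, PhenotypeVector
from .errors import ContractError
from .segregation import get_model

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class F2SimSpec:
    """Specification of one simulated F2 phenotype sample."""

    model_code: str
    m: float
    effects: Mapping[str, float] = field(default_factory=dict)
    sigma_e2: float = 1.0
    sigma_pg2: float = 0.0
    n: int = 200
    seed: int = 0
    group: str = "F2"

    def validate(self):
        if self.n < 1:
            raise ContractError("n must be >= 1")
        if self.sigma_e2 <= 0:
            raise ContractError("sigma_e2 must be > 0")
        if self.sigma_pg2 < 0:
            raise ContractError("sigma_pg2 must be >= 0")
        get_model(self.model_code)  # raises CatalogError if unknown


@dataclass
class PanelSimSpec:
    """Specification of one structured SNP panel with a causal count trait.

    Defaults mirror the study design this generator emulates: 120
    individuals in 8 phenotype groups of 15.
    """

    n_ind: int = 120
    K_true: int = 2
    fst: float = 0.1
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 500_000, "2": 500_000}
    )
    n_loci: int = 1000
    ld_rho: float = 0.9
    causal: Sequence[Tuple[int, float]] = field(default_factory=list)
    h2_target: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    base_count: float = 5.0
    group_labels: Sequence[str] = ("2D", "3D", "4D", "5D", "6D", "8D", "10D", "MD")

    def validate(self):
        if self.n_ind < 2:
            raise ContractError("n_ind must be >= 2")
        if not (0 <= self.fst < 1):
            raise ContractError("fst must be in [0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise ContractError("ld_rho must be in [0, 1)")
        if not (0 <= self.h2_target < 1):
            raise ContractError("h2_target must be in [0, 1)")
        if self.h2_target == 0 and len(self.causal) > 0:
            raise ContractError("h2_target=0 is inconsistent with causal loci")
        if not (0 <= self.missing_rate < 1):
            raise ContractError("missing_rate must be in [0, 1)")
        for idx, _ in self.causal:
            if not (0 <= idx < self.n_loci):
                raise ContractError(f"causal index {idx} out of range")


@dataclass
class PanelTruth:
    """Ground truth retained from a panel simulation."""

    Q: np.ndarray
    subpop_freqs: np.ndarray  # K x n_loci
    causal: List[Tuple[int, float]]
    h2_realized: float
    genetic_values: np.ndarray


# ---------------------------------------------------------------------------
# F2 phenotypes
# ---------------------------------------------------------------------------


def simulate_f2_phenotypes(spec: F2SimSpec) -> PhenotypeVector:
    """Draw speckle counts from a named major-gene model.

    Each individual's genotype class is multinomial over the model's F2
    weights; its count is the class mean plus Gaussian polygenic and
    environmental noise, rounded to the nearest integer and clipped at 0.
    """
    spec.validate()
    model = get_model(spec.model_code)
    params = [spec.m] + [spec.effects.get(name, 0.0) for name in model.param_names[1:]]
    means = model.component_means(params)
    rng = np.random.default_rng(spec.seed)
    classes = rng.choice(model.n_components, size=spec.n, p=model.weights)
    sd = np.sqrt(spec.sigma_e2 + spec.sigma_pg2)
    raw = means[classes] + rng.normal(0.0, sd, size=spec.n)
    counts = np.clip(np.round(raw), 0, None).astype(int)
    sexes = np.where(rng.random(spec.n) < 0.5, "M", "F")
    return PhenotypeVector(values=counts, group=spec.group, generation="F2", sex=sexes)


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------


def _positions(chrom_lengths: Mapping[str, int], n_loci: int, rng) -> pd.DataFrame:
    """Allocate loci to chromosomes proportionally to length; sorted positions."""
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], float)
    counts = np.floor(n_loci * lengths / lengths.sum()).astype(int)
    while counts.sum() < n_loci:
        counts[int(np.argmax(lengths - counts))] += 1
    rows = []
    for c, k in zip(chroms, counts):
        L = chrom_lengths[c]
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(k, L), replace=False))
        for p in pos:
            rows.append((c, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=len(df))
    alt = (ref + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = bases[ref]
    df["alt"] = bases[alt]
    return df


def simulate_population(
    spec: PanelSimSpec,
) -> Tuple[GenotypeMatrix, PhenotypeVector, PanelTruth]:
    """Simulate a structured SNP panel and a causal count trait.

    Subpopulation allele frequencies follow the Balding–Nichols model at
    differentiation level ``fst`` around a uniform ancestral frequency.
    Haplotypes are generated with a Gaussian-copula chain along each
    chromosome so that allele correlation between adjacent loci decays as
    ``ld_rho ** distance_kb``.  Each individual draws its two haplotype
    ancestries from a subpopulation assignment (hard Q).  The trait is the
    causal dosage sum plus Gaussian noise scaled so the realized
    heritability matches ``h2_target``, shifted to a non-negative count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    loci = _positions(spec.chrom_lengths, spec.n_loci, rng)
    M = len(loci)
    K = spec.K_true

    p_anc = rng.uniform(0.1, 0.9, size=M)
    if spec.fst > 0:
        a = p_anc * (1 - spec.fst) / spec.fst
        b = (1 - p_anc) * (1 - spec.fst) / spec.fst
        freqs = np.clip(rng.beta(a, b, size=(K, M)), 0.01, 0.99)
    else:
        freqs = np.tile(p_anc, (K, 1))

    # balanced hard subpopulation assignment
    pop = np.repeat(np.arange(K), int(np.ceil(spec.n_ind / K)))[: spec.n_ind]
    Q = np.zeros((spec.n_ind, K))
    Q[np.arange(spec.n_ind), pop] = 1.0

    # Gaussian copula chain per chromosome and haplotype
    geno = np.zeros((spec.n_ind, M))
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy(float)
    thresh = _norm.ppf(freqs[pop])  # n_ind x M threshold per individual
    for _hap in range(2):
        z = np.empty((spec.n_ind, M))
        for c in pd.unique(chrom_arr):
            idx = np.where(chrom_arr == c)[0]
            zc = np.empty((spec.n_ind, idx.size))
            zc[:, 0] = rng.normal(size=spec.n_ind)
            d_kb = np.diff(pos_arr[idx]) / 1000.0
            rhos = spec.ld_rho ** d_kb if spec.ld_rho > 0 else np.zeros(idx.size - 1)
            for j in range(1, idx.size):
                r = rhos[j - 1]
                zc[:, j] = r * zc[:, j - 1] + np.sqrt(1 - r * r) * rng.normal(
                    size=spec.n_ind
                )
            z[:, idx] = zc
        geno += (z < thresh).astype(float)

    # trait
    gvals = np.zeros(spec.n_ind)
    for idx, beta in spec.causal:
        gvals += beta * geno[:, idx]
    if spec.causal and spec.h2_target > 0:
        var_g = float(np.var(gvals))
        if var_g == 0:
            raise ContractError("causal loci are monomorphic; trait undefined")
        sigma2_env = var_g * (1 - spec.h2_target) / spec.h2_target
    else:
        sigma2_env = 1.0
    noise = rng.normal(0.0, np.sqrt(sigma2_env), size=spec.n_ind)
    raw = spec.base_count + gvals - gvals.mean() + noise
    counts = np.clip(np.round(raw), 0, None).astype(int)
    var_tot = float(np.var(gvals + noise))
    h2_real = float(np.var(gvals) / var_tot) if var_tot > 0 else 0.0

    # missingness
    if spec.missing_rate > 0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno[mask] = np.nan

    # phenotype-group labels: rank the count into len(group_labels) bins
    labels = list(spec.group_labels)
    order = np.argsort(np.argsort(counts, kind="stable"), kind="stable")
    bins = (order * len(labels)) // spec.n_ind
    groups = np.array([labels[b] for b in bins])

    individuals = pd.DataFrame(
        {"id": [f"ind{i+1:03d}" for i in range(spec.n_ind)], "group": groups}
    )
    gm = GenotypeMatrix(genotypes=geno, loci=loci, individuals=individuals)
    pheno = PhenotypeVector(
        values=counts,
        group="panel",
        generation="NA",
        ids=individuals["id"].to_numpy(),
    )
    truth = PanelTruth(
        Q=Q,
        subpop_freqs=freqs,
        causal=list(spec.causal),
        h2_realized=h2_real,
        genetic_values=gvals,
    )
    return gm, pheno, truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    groups: Sequence[str],
    n_bio: int,
    effects: Mapping[str, float],
    seed: int,
    *,
    targets: Sequence[str] = ("GH1", "TRXR1", "LAC2"),
    reference_gene: str = "GAPDH",
    n_tech: int = 3,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    bio_sd: float = 0.15,
    tech_sd: float = 0.05,
) -> CtTable:
    """Simulate triplicate technical Ct values per biological sample.

    ``effects`` maps group → ΔCt shift applied to the target genes only
    (a negative shift means higher expression).  The reference gene is
    always produced for every sample.
    """
    if n_bio < 2:
        import warnings

        warnings.warn("n_bio < 2: downstream ANOVA will be impossible", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        shift = float(effects.get(g, 0.0))
        for b in range(n_bio):
            sample = f"{g}_b{b+1}"
            ref_level = base_ct_reference + rng.normal(0, bio_sd)
            for gene in list(targets) + [reference_gene]:
                if gene == reference_gene:
                    true_ct = ref_level
                else:
                    true_ct = base_ct_target + shift + rng.normal(0, bio_sd)
                    # keep ΔCt anchored to the sample's reference level
                    true_ct += ref_level - base_ct_reference
                for rep in range(1, n_tech + 1):
                    ct = true_ct + rng.normal(0, tech_sd)
                    rows.append((sample, g, gene, rep, round(float(ct), 4)))
    df = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    return CtTable(records=df, reference_gene=reference_gene)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def _synthesize_genome(
    chrom_lengths: Mapping[str, int], loci: pd.DataFrame, seed: int
) -> Dict[str, str]:
    """Random chromosome sequences whose bases agree with the VCF ref alleles."""
    rng = np.random.default_rng(seed)
    genome = {}
    for c, L in chrom_lengths.items():
        seq = rng.choice(list("ACGT"), size=L)
        sub = loci[loci["chrom"] == c]
        seq[sub["pos"].to_numpy() - 1] = sub["ref"].to_numpy()
        genome[str(c)] = "".join(seq)
    return genome


def make_gene_models(
    chrom_lengths: Mapping[str, int],
    *,
    coverage: float = 0.4,
    gene_length: int = 3000,
    n_exons: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile synthetic gene models over each chromosome.

    Genes of fixed length with ``n_exons`` exons are placed so that they
    cover roughly ``coverage`` of each chromosome; strands alternate and
    each gene's CDS length is a multiple of 3.
    """
    rows = []
    gid = 0
    for c, L in chrom_lengths.items():
        n_genes = max(1, int(coverage * L / gene_length))
        spacing = L // (n_genes + 1)
        for k in range(n_genes):
            start = spacing * (k + 1) - gene_length // 2
            start = max(1, start)
            end = min(L, start + gene_length - 1)
            if end - start + 1 < 300:
                continue
            gid += 1
            strand = "+" if gid % 2 else "-"
            name = f"gene{gid:04d}"
            rows.append((c, "synth", "gene", start, end, ".", strand, ".", f"ID={name}"))
            span = end - start + 1
            exon_len = span // (2 * n_exons - 1)
            cds_len = 3 * max(1, (exon_len - 20) // 3)
            for e in range(n_exons):
                es = start + 2 * e * exon_len
                ee = min(end, es + exon_len - 1)
                rows.append(
                    (c, "synth", "exon", es, ee, ".", strand, ".",
                     f"ID={name}.e{e+1};Parent={name}")
                )
                cs = es + 10
                ce = min(ee, cs + cds_len - 1)
                if ce >= cs:
                    rows.append(
                        (c, "synth", "CDS", cs, ce, ".", strand, "0",
                         f"ID={name}.c{e+1};Parent={name}")
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes",
        ],
    )


def write_fixtures(
    out_dir: str,
    *,
    panel: Optional[GenotypeMatrix] = None,
    panel_pheno: Optional[PhenotypeVector] = None,
    truth: Optional[PanelTruth] = None,
    f2_samples: Optional[Mapping[str, PhenotypeVector]] = None,
    ct: Optional[CtTable] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    gene_coverage: float = 0.4,
    seed: int = 0,
    overwrite: bool = False,
) -> Dict[str, str]:
    """Write a complete plain-text fixture bundle; returns path map.

    Emits (as applicable): ``panel.vcf`` (GT-only VCF v4.2),
    ``panel_pheno.tsv``, ``pheno_<group>.tsv``, ``genes.gff3``,
    ``genome.fa``, ``ct.tsv`` and ``truth.json``.
    """
    from . import io as smio

    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    def target(name: str) -> str:
        p = os.path.join(out_dir, name)
        if os.path.exists(p) and not overwrite:
            raise ContractError(f"fixture {p} exists (pass overwrite=True)")
        return p

    if panel is not None:
        if chrom_lengths is None:
            chrom_lengths = {
                str(c): int(panel.loci.loc[panel.loci["chrom"] == c, "pos"].max() + 10_000)
                for c in pd.unique(panel.loci["chrom"])
            }
        paths["vcf"] = target("panel.vcf")
        smio.write_vcf(panel, paths["vcf"], chrom_lengths=chrom_lengths)
        genome = _synthesize_genome(chrom_lengths, panel.loci, seed)
        paths["fasta"] = target("genome.fa")
        smio.write_fasta(genome, paths["fasta"])
        gff = make_gene_models(chrom_lengths, coverage=gene_coverage, seed=seed)
        paths["gff3"] = target("genes.gff3")
        smio.write_gff3(gff, paths["gff3"])
    if panel_pheno is not None and panel is not None:
        df = panel_pheno.to_frame()
        df["id"] = panel.individuals["id"].to_numpy()
        df["group"] = panel.individuals["group"].to_numpy()
        paths["panel_pheno"] = target("panel_pheno.tsv")
        df.to_csv(paths["panel_pheno"], sep="\t", index=False)
    for name, pv in (f2_samples or {}).items():
        key = f"pheno_{name}"
        paths[key] = target(f"{key}.tsv")
        pv.to_frame().to_csv(paths[key], sep="\t", index=False)
    if ct is not None:
        paths["ct"] = target("ct.tsv")
        ct.records.to_csv(paths["ct"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = target("truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "causal": [[int(i), float(b)] for i, b in truth.causal],
                    "h2_realized": truth.h2_realized,
                    "Q": truth.Q.tolist(),
                },
                fh,
                indent=1,
            )
    return paths
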