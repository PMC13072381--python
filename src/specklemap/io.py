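"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF is read with ``cyvcf2`` and written as minimal GT-only VCF v4.2;
FASTA goes through Biopython; GFF3 is tab-separated text (read into a tidy
DataFrame, parsed into gene models by :mod:`specklemap.qtl_integrate`).
"""

from __future__ import annotations

import os
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .containers import CtTable, GenotypeMatrix, PhenotypeVector
from .errors import ContractError

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    gm: GenotypeMatrix, path: str, chrom_lengths: Optional[Mapping[str, int]] = None
) -> None:
    """Write a minimal VCF v4.2 with GT as the only FORMAT field."""
    ids = gm.individuals["id"].astype(str).tolist()
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(gm.loci.loc[gm.loci["chrom"] == c, "pos"].max())
            for c in pd.unique(gm.loci["chrom"])
        }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=specklemap\n")
        for c, L in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={int(L)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        loci = gm.loci
        ref = loci["ref"] if "ref" in loci else pd.Series(["A"] * len(loci))
        alt = loci["alt"] if "alt" in loci else pd.Series(["T"] * len(loci))
        for j in range(gm.n_loci):
            gts = [
                _GT_STRINGS.get(g, "./.") if np.isfinite(g) else "./."
                for g in gm.genotypes[:, j]
            ]
            fh.write(
                f"{loci['chrom'].iloc[j]}\t{int(loci['pos'].iloc[j])}\t"
                f"snp{j+1}\t{ref.iloc[j]}\t{alt.iloc[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix (alt-allele count, NaN missing)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(dos)
    vcf.close()
    if not rows:
        raise ContractError(f"no biallelic variants in {path}")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = np.array(dosages).T
    individuals = pd.DataFrame({"id": samples, "group": ["NA"] * len(samples)})
    return GenotypeMatrix(genotypes=genotypes, loci=loci, individuals=individuals)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=str(name), description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS, dtype={"seqid": str}
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# phenotype / Ct TSV
# ---------------------------------------------------------------------------


def write_phenotypes(pv: PhenotypeVector, path: str) -> None:
    pv.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str, group: Optional[str] = None) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise ContractError(f"no rows with group={group!r} in {path}")
    label = group if group is not None else (
        df["group"].iloc[0] if df["group"].nunique() == 1 else "pooled"
    )
    return PhenotypeVector(
        values=df["speckle_count"].to_numpy(int),
        group=str(label),
        generation=str(df["generation"].iloc[0]) if "generation" in df else "",
        sex=df["sex"].to_numpy() if "sex" in df else None,
        ids=df["id"].astype(str).to_numpy() if "id" in df else None,
    )


def read_ct_table(path: str, reference_gene: str = "GAPDH") -> CtTable:
    df = pd.read_csv(path, sep="\t")
    return CtTable(records=df, reference_gene=reference_gene)


def write_matrix_tsv(mat: np.ndarray, path: str, labels=None) -> None:
    df = pd.DataFrame(mat, index=labels, columns=labels)
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(float)
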