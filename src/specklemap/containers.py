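"""Core in-memory containers shared across the analysis stages.

The containers are deliberately thin: a phenotype sample is a labelled
integer vector, a genotype panel is an individuals × loci dosage matrix
with per-locus metadata, and a qPCR table is a tidy DataFrame.  Heavier
behaviour (filtering, kinship, likelihoods) lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError

#: sentinel for a missing dosage — containers store dosages as float with NaN
MISSING = np.nan


@dataclass
class PhenotypeVector:
    """Individual speckle counts with generation/group/sex labels.

    Parameters
    ----------
    values
        Non-negative integer counts, one per individual.
    group
        Population label, e.g. ``"inbred"``, ``"hybrid"`` or a phenotype
        class such as ``"2D"``.
    generation
        Cross generation label, e.g. ``"F2"``.
    sex
        Optional per-individual sex labels (``"M"``/``"F"``).
    ids
        Optional per-individual identifiers.
    """

    values: np.ndarray
    group: str = ""
    generation: str = ""
    sex: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ContractError("phenotype values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values.astype(float))):
            raise ContractError("phenotype values must be finite")
        if self.values.size and np.any(self.values < 0):
            raise ContractError("speckle counts must be non-negative")
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
            if self.sex.shape != self.values.shape:
                raise ContractError("sex labels must match values in length")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape != self.values.shape:
                raise ContractError("ids must match values in length")

    def __len__(self) -> int:
        return int(self.values.size)

    def subset(self, mask: np.ndarray) -> "PhenotypeVector":
        return PhenotypeVector(
            values=self.values[mask],
            group=self.group,
            generation=self.generation,
            sex=None if self.sex is None else self.sex[mask],
            ids=None if self.ids is None else self.ids[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "id": self.ids if self.ids is not None else [f"ind{i+1}" for i in range(n)],
                "group": [self.group] * n,
                "sex": self.sex if self.sex is not None else ["NA"] * n,
                "generation": [self.generation or "NA"] * n,
                "speckle_count": self.values,
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic loci, coded as alt-allele dosage 0/1/2.

    ``genotypes`` is float with NaN for missing calls.  ``loci`` carries
    chromosome, 1-based position, ref and alt alleles; ``individuals``
    carries sample IDs and phenotype-group labels.
    """

    genotypes: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ContractError("genotypes must be 2-D (individuals x loci)")
        if len(self.loci) != self.genotypes.shape[1]:
            raise ContractError("loci table length must equal locus count")
        if len(self.individuals) != self.genotypes.shape[0]:
            raise ContractError("individuals table length must equal row count")
        for col in ("chrom", "pos"):
            if col not in self.loci.columns:
                raise ContractError(f"loci table missing column '{col}'")
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
            raise ContractError("dosages must be 0, 1, 2 or missing")
        # positions strictly increasing within each chromosome
        pos = self.loci["pos"].to_numpy()
        chrom = self.loci["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ContractError(f"positions not strictly increasing on {c}")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return np.mean(~np.isfinite(self.genotypes), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-locus mean."""
        g = self.genotypes.copy()
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(g, axis=0)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        idx = np.where(~np.isfinite(g))
        g[idx] = mu[idx[1]]
        return g

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[:, mask],
            loci=self.loci.loc[mask].reset_index(drop=True),
            individuals=self.individuals.copy(),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[mask, :],
            loci=self.loci.copy(),
            individuals=self.individuals.loc[mask].reset_index(drop=True),
        )


@dataclass
class CtTable:
    """Tidy qRT-PCR cycle-threshold table.

    Columns: ``sample``, ``group``, ``gene``, ``replicate``, ``ct``.
    """

    records: pd.DataFrame
    reference_gene: str = "GAPDH"

    REQUIRED = ("sample", "group", "gene", "replicate", "ct")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ContractError(f"Ct table missing column '{col}'")
        if (self.records["ct"] <= 0).any():
            raise ContractError("Ct values must be positive")
        samples = set(self.records["sample"])
        with_ref = set(self.records.loc[self.records["gene"] == self.reference_gene, "sample"])
        self.samples_without_reference = sorted(samples - with_ref)

    @property
    def genes(self) -> list:
        return sorted(self.records["gene"].unique())

    @property
    def target_genes(self) -> list:
        return [g for g in self.genes if g != self.reference_gene]


def concat_phenotypes(vectors: Sequence[PhenotypeVector], group: str = "pooled") -> PhenotypeVector:
    """Pool several phenotype samples into one labelled vector."""
    values = np.concatenate([v.values for v in vectors])
    sexes = None
    if all(v.sex is not None for v in vectors):
        sexes = np.concatenate([v.sex for v in vectors])
    return PhenotypeVector(values=values, group=group, generation="F2", sex=sexes)
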