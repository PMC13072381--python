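"""QTL interval mapping, QTN/QTL overlap, candidate windows and annotation.

The "linkage-style" QTL mapping here is a marker-scan reconstruction: a
single-marker score profile (−log10 p) is thresholded, each peak becomes a
QTL, and the interval is the contiguous run of markers within 1.5 score
units of the peak (the classical support-interval convention).  The
alternative "ranking" method takes the top quantile of markers and groups
adjacent ones.  QTL names follow the Q-<prefix>-<chromosome>-<serial>
convention with serials assigned in genomic order per chromosome.

Candidate windows extend ±flank bp (default 250 kb) around each
significant SNP; a gene belongs to a window if its span intersects it
(closed 1-based intervals, any overlap counts).

Variant functional annotation assigns exactly one primary category per
variant by priority exon > splice-site (2 bp at each intron end) > intron
> upstream-2kb > downstream-2kb > intergenic, strand aware, and calls
codon-level effects for CDS variants under the standard genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .assoc import AssociationScan, run_association
from .containers import GenotypeMatrix, PhenotypeVector
from .errors import ContractError

# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ContractError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons + self.cds:
            if not (self.start <= s <= e <= self.end):
                raise ContractError(f"gene {self.gene_id}: child outside gene span")

    @property
    def introns(self) -> List[Tuple[int, int]]:
        ex = sorted(self.exons)
        return [
            (ex[i][1] + 1, ex[i + 1][0] - 1)
            for i in range(len(ex) - 1)
            if ex[i + 1][0] - ex[i][1] > 1
        ]


@dataclass
class GeneModelSet:
    genes: List[Gene]

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModelSet":
        """Load gene/exon/CDS features from a GFF3 file via gffutils."""
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for gf in db.features_of_type("gene"):
            exons = [(f.start, f.end) for f in db.children(gf, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(gf, featuretype="CDS")]
            genes.append(
                Gene(
                    gene_id=gf.id,
                    chrom=str(gf.seqid),
                    strand=gf.strand,
                    start=gf.start,
                    end=gf.end,
                    exons=sorted(exons),
                    cds=sorted(cds),
                )
            )
        return cls(genes=genes)

    def by_chrom(self) -> Dict[str, List[Gene]]:
        out: Dict[str, List[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


# ---------------------------------------------------------------------------
# QTL mapping
# ---------------------------------------------------------------------------

QTL_NAME_RE = re.compile(r"^Q-[A-Za-z]+-\d+-\d+$")


@dataclass
class QTLInterval:
    name: str
    trait: str
    chrom: str
    left: int
    right: int
    peak_score: float
    pve_pct: float
    method: str = "lod"

    def __post_init__(self):
        if self.left > self.right:
            raise ContractError("QTL interval left must be <= right")


def _chrom_number(chrom: str) -> str:
    digits = re.sub(r"\D", "", str(chrom))
    return digits if digits else "0"


def map_qtl_intervals(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    method: str = "lod",
    scan: Optional[AssociationScan] = None,
    threshold: Optional[float] = None,
    support_drop: float = 1.5,
    top_quantile: float = 0.99,
    prefix: str = "Rf",
    trait: str = "speckle",
) -> List[QTLInterval]:
    """Marker-scan QTL intervals from a score profile.

    ``lod``: peaks of the −log10 p profile above the threshold (default
    Bonferroni) become QTL; the interval extends over the contiguous
    markers within ``support_drop`` score units of the peak.

    ``ranking``: markers in the top ``top_quantile`` of scores, grouped by
    adjacency into intervals.
    """
    if scan is None:
        scan = run_association(g, y, "glm")
    tab = scan.table
    scores = tab["score"].to_numpy()
    M = len(tab)
    if threshold is None:
        threshold = -np.log10(0.05 / M)  # Bonferroni on the score scale

    intervals: List[Tuple[str, int, int, float, float]] = []
    chrom_arr = tab["chrom"].astype(str).to_numpy()
    pos_arr = tab["pos"].to_numpy()
    for c in pd.unique(chrom_arr):
        idx = np.where(chrom_arr == c)[0]
        s = scores[idx]
        if method == "lod":
            above = s >= threshold
            if not above.any():
                continue
            used = np.zeros(len(idx), dtype=bool)
            order = np.argsort(s)[::-1]
            for k in order:
                if not above[k] or used[k]:
                    continue
                peak = s[k]
                lo = k
                while lo > 0 and s[lo - 1] >= peak - support_drop:
                    lo -= 1
                hi = k
                while hi < len(idx) - 1 and s[hi + 1] >= peak - support_drop:
                    hi += 1
                used[lo: hi + 1] = True
                pve = float(tab["pve_pct"].to_numpy()[idx[k]])
                intervals.append((c, int(pos_arr[idx[lo]]), int(pos_arr[idx[hi]]), float(peak), pve))
        elif method == "ranking":
            cutoff = np.quantile(scores, top_quantile)
            hits = np.where(s >= cutoff)[0]
            if hits.size == 0:
                continue
            run_start = hits[0]
            prev = hits[0]
            for h in list(hits[1:]) + [None]:
                if h is not None and h == prev + 1:
                    prev = h
                    continue
                seg = np.arange(run_start, prev + 1)
                k = seg[np.argmax(s[seg])]
                intervals.append(
                    (c, int(pos_arr[idx[run_start]]), int(pos_arr[idx[prev]]),
                     float(s[k]), float(tab["pve_pct"].to_numpy()[idx[k]]))
                )
                if h is not None:
                    run_start = prev = h
        else:
            raise ContractError(f"unknown QTL mapping method {method!r}")

    # name in genomic order, serial per chromosome
    intervals.sort(key=lambda t: (t[0], t[1]))
    serial: Dict[str, int] = {}
    out = []
    for c, left, right, peak, pve in intervals:
        serial[c] = serial.get(c, 0) + 1
        name = f"Q-{prefix}-{_chrom_number(c)}-{serial[c]}"
        out.append(
            QTLInterval(
                name=name, trait=trait, chrom=c, left=left, right=right,
                peak_score=peak, pve_pct=pve, method=method,
            )
        )
    return out


# ---------------------------------------------------------------------------
# QTN / QTL overlap
# ---------------------------------------------------------------------------


def overlap_qtn_qtl(
    qtns: pd.DataFrame, qtls: Sequence[QTLInterval]
) -> pd.DataFrame:
    """Match each significant SNP to the QTL intervals that contain it.

    ``qtns`` needs columns ``id``, ``chrom``, ``pos``.  A QTN matches a QTL
    iff it lies on the same chromosome and left ≤ pos ≤ right (closed,
    1-based).  The result lists every (QTN, QTL) pair plus unmatched QTNs
    with a null QTL name.
    """
    rows = []
    for _, q in qtns.iterrows():
        matched = False
        for itv in qtls:
            if str(q["chrom"]) == str(itv.chrom) and itv.left <= int(q["pos"]) <= itv.right:
                rows.append((q["id"], q["chrom"], int(q["pos"]), itv.name, itv.left, itv.right))
                matched = True
        if not matched:
            rows.append((q["id"], q["chrom"], int(q["pos"]), None, None, None))
    return pd.DataFrame(
        rows, columns=["qtn", "chrom", "pos", "qtl", "qtl_left", "qtl_right"]
    )


# ---------------------------------------------------------------------------
# candidate windows
# ---------------------------------------------------------------------------


@dataclass
class CandidateWindow:
    qtn: str
    chrom: str
    left: int
    right: int
    gene_ids: List[str]


def candidate_genes_in_windows(
    qtns: pd.DataFrame,
    genes: GeneModelSet,
    flank: int = 250_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> List[CandidateWindow]:
    """Genes whose span intersects ±``flank`` bp around each QTN.

    The window is clipped at 1 and at the chromosome length when known.
    Intervals are closed, so a gene starting exactly at ``pos + flank``
    is included.
    """
    if flank < 0:
        raise ContractError("flank must be >= 0")
    by_chrom = genes.by_chrom()
    known_chroms = set(by_chrom) | set(chrom_lengths or {})
    out = []
    for _, q in qtns.iterrows():
        c = str(q["chrom"])
        if known_chroms and c not in known_chroms:
            raise ContractError(f"unknown chromosome {c!r} for QTN {q['id']!r}")
        pos = int(q["pos"])
        left = max(1, pos - flank)
        right = pos + flank
        if chrom_lengths and c in chrom_lengths:
            right = min(right, int(chrom_lengths[c]))
        hits = [
            gene.gene_id
            for gene in by_chrom.get(c, [])
            if gene.start <= right and gene.end >= left
        ]
        out.append(CandidateWindow(qtn=str(q["id"]), chrom=c, left=left, right=right, gene_ids=hits))
    return out


# ---------------------------------------------------------------------------
# variant functional annotation
# ---------------------------------------------------------------------------

SPLICE_BP = 2  # splice-site width at each intron end

PRIMARY_CATEGORIES = (
    "exon", "splice_site", "intron", "upstream_2kb", "downstream_2kb", "intergenic",
)


def _category_for_gene(pos: int, gene: Gene, reg_bp: int = 2000) -> Optional[str]:
    if gene.start <= pos <= gene.end:
        for s, e in gene.exons:
            if s <= pos <= e:
                return "exon"
        for s, e in gene.introns:
            if s <= pos <= min(e, s + SPLICE_BP - 1) or max(s, e - SPLICE_BP + 1) <= pos <= e:
                return "splice_site"
        for s, e in gene.introns:
            if s <= pos <= e:
                return "intron"
        return "exon" if not gene.exons else "intron"
    # strand-aware flanks
    if gene.strand == "+":
        if gene.start - reg_bp <= pos < gene.start:
            return "upstream_2kb"
        if gene.end < pos <= gene.end + reg_bp:
            return "downstream_2kb"
    else:
        if gene.end < pos <= gene.end + reg_bp:
            return "upstream_2kb"
        if gene.start - reg_bp <= pos < gene.start:
            return "downstream_2kb"
    return None


def _cds_effect(pos, ref, alt, gene: Gene, genome: Mapping[str, str]) -> Optional[str]:
    """Codon-level effect of a SNP inside a CDS; None if not in any CDS."""
    seq = genome[gene.chrom]
    cds = sorted(gene.cds)
    # CDS-relative offset of pos in transcription order
    inside = any(s <= pos <= e for s, e in cds)
    if not inside:
        return None
    cds_seq = "".join(seq[s - 1: e] for s, e in cds)
    offset = 0
    for s, e in cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    alt_seq = cds_seq[:offset] + alt + cds_seq[offset + 1:]
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_seq = str(Seq(alt_seq).reverse_complement())
        offset = len(cds_seq) - offset - 1
    codon_i = offset // 3
    ref_codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
    alt_codon = alt_seq[3 * codon_i: 3 * codon_i + 3]
    if len(ref_codon) < 3:
        return "unknown"
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "nonsynonymous"


def annotate_variants(
    variants: pd.DataFrame,
    genes: GeneModelSet,
    genome: Mapping[str, str],
    reg_bp: int = 2000,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Primary category + coding effect for each variant.

    ``variants`` needs columns ``chrom``, ``pos``, ``ref``, ``alt``.
    Every variant gets exactly one primary category (highest-priority
    category over all overlapping gene models).  SNPs in a CDS get a codon
    effect; indels in a CDS are frameshift iff the length difference is not
    a multiple of 3.  Variants whose ref allele disagrees with the genome
    are flagged and excluded from effect calls.
    """
    prio = {c: i for i, c in enumerate(PRIMARY_CATEGORIES)}
    by_chrom = genes.by_chrom()
    cats, effects, flags = [], [], []
    for _, v in variants.iterrows():
        c, pos = str(v["chrom"]), int(v["pos"])
        ref, alt = str(v["ref"]), str(v["alt"])
        if c not in genome:
            raise ContractError(f"genome sequence missing chromosome {c!r}")
        seq = genome[c]
        if pos < 1 or pos + len(ref) - 1 > len(seq):
            raise ContractError(f"variant at {c}:{pos} outside genome sequence")
        ref_ok = seq[pos - 1: pos - 1 + len(ref)].upper() == ref.upper()
        best = "intergenic"
        best_gene: Optional[Gene] = None
        for gene in by_chrom.get(c, []):
            cat = _category_for_gene(pos, gene, reg_bp)
            if cat is not None and prio[cat] < prio[best]:
                best = cat
                best_gene = gene
        effect = None
        if not ref_ok:
            effect = "ref_mismatch"
        elif best == "exon" and best_gene is not None:
            if len(ref) == 1 and len(alt) == 1:
                effect = _cds_effect(pos, ref, alt, best_gene, genome)
            else:
                in_cds = any(s <= pos <= e for s, e in best_gene.cds)
                if in_cds:
                    shift = abs(len(ref) - len(alt)) % 3
                    effect = "frameshift" if shift != 0 else "non_frameshift"
        cats.append(best)
        effects.append(effect)
        flags.append(not ref_ok)
    out = variants.copy()
    out["category"] = cats
    out["effect"] = effects
    out["ref_mismatch"] = flags
    counts = out["category"].value_counts().to_dict()
    for c in PRIMARY_CATEGORIES:
        counts.setdefault(c, 0)
    return out, counts
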