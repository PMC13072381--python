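"""QTL intervals, QTN overlap, candidate windows and variant annotation."""

import numpy as np
import pandas as pd
import pytest

from specklemap import assoc, synthgen as gen
from specklemap import qtl_integrate as qi
from specklemap.containers import PhenotypeVector
from specklemap.errors import ContractError


# ---------------------------------------------------------------------------
# QTL mapping
# ---------------------------------------------------------------------------


def test_flat_phenotype_yields_no_qtl():
    empties = 0
    for s in range(20):
        spec = gen.PanelSimSpec(n_ind=80, K_true=1, fst=0.0, n_loci=300,
                                chrom_lengths={"1": 600_000}, ld_rho=0.0, seed=600 + s)
        gm, _, _ = gen.simulate_population(spec)
        rng = np.random.default_rng(1000 + s)
        y = PhenotypeVector(values=rng.integers(2, 12, 80))
        qtls = qi.map_qtl_intervals(gm, y, method="lod")
        empties += len(qtls) == 0
    assert empties >= 18


def test_causal_marker_inside_mapped_interval():
    spec = gen.PanelSimSpec(n_ind=150, K_true=1, fst=0.0, n_loci=400,
                            chrom_lengths={"1": 400_000}, ld_rho=0.9,
                            causal=[(200, 2.0)], h2_target=0.4, seed=77)
    gm, pheno, _ = gen.simulate_population(spec)
    qtls = qi.map_qtl_intervals(gm, pheno, method="lod")
    assert qtls, "no QTL mapped over a strong causal locus"
    causal_pos = gm.loci["pos"].iloc[200]
    assert any(q.left <= causal_pos <= q.right for q in qtls)
    for q in qtls:
        assert qi.QTL_NAME_RE.match(q.name)


def test_ranking_method_returns_top_quantile_runs():
    spec = gen.PanelSimSpec(n_ind=100, K_true=1, fst=0.0, n_loci=200,
                            chrom_lengths={"1": 200_000}, ld_rho=0.5,
                            causal=[(100, 1.5)], h2_target=0.4, seed=8)
    gm, pheno, _ = gen.simulate_population(spec)
    qtls = qi.map_qtl_intervals(gm, pheno, method="ranking", top_quantile=0.98)
    assert qtls
    assert all(q.method == "ranking" for q in qtls)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def _qtl(chrom, left, right, serial=1):
    return qi.QTLInterval(name=f"Q-Rf-{chrom}-{serial}", trait="t", chrom=str(chrom),
                          left=left, right=right, peak_score=5.0, pve_pct=5.0)


def test_overlap_boundaries_inclusive():
    qtls = [_qtl(1, 100, 200)]
    qtns = pd.DataFrame({"id": ["a", "b", "c"], "chrom": ["1", "1", "1"],
                         "pos": [100, 200, 201]})
    out = qi.overlap_qtn_qtl(qtns, qtls)
    assert out.loc[out["qtn"] == "a", "qtl"].iloc[0] == "Q-Rf-1-1"
    assert out.loc[out["qtn"] == "b", "qtl"].iloc[0] == "Q-Rf-1-1"
    assert out.loc[out["qtn"] == "c", "qtl"].isna().all()


def test_overlap_matches_brute_force():
    rng = np.random.default_rng(12)
    qtls = []
    for k in range(5):
        left = int(rng.integers(1, 90_000))
        qtls.append(_qtl(rng.integers(1, 3), left, left + int(rng.integers(100, 20_000)), k))
    qtns = pd.DataFrame({
        "id": [f"q{i}" for i in range(10)],
        "chrom": rng.integers(1, 3, 10).astype(str),
        "pos": rng.integers(1, 110_000, 10),
    })
    out = qi.overlap_qtn_qtl(qtns, qtls)
    matched = set(zip(out.dropna(subset=["qtl"])["qtn"], out.dropna(subset=["qtl"])["qtl"]))
    brute = set()
    for _, q in qtns.iterrows():
        for itv in qtls:
            if str(q["chrom"]) == itv.chrom and itv.left <= q["pos"] <= itv.right:
                brute.add((q["id"], itv.name))
    assert matched == brute


# ---------------------------------------------------------------------------
# candidate windows
# ---------------------------------------------------------------------------


def toy_genes():
    mk = lambda gid, c, s, e, strand="+": qi.Gene(
        gene_id=gid, chrom=c, strand=strand, start=s, end=e,
        exons=[(s, e)], cds=[(s, s + 29)],
    )
    return qi.GeneModelSet(genes=[
        mk("g1", "1", 1_000, 2_000),
        mk("g2", "1", 260_000, 262_000),
        mk("g3", "1", 260_001 + 250_000, 260_100 + 250_000),
        mk("g4", "1", 600_000, 601_000, "-"),
        mk("g5", "2", 5_000, 6_000),
        mk("g6", "2", 240_000, 241_000),
    ])


def test_window_boundary_rules():
    genes = toy_genes()
    qtns = pd.DataFrame({"id": ["q"], "chrom": ["1"], "pos": [10_000]})
    wins = qi.candidate_genes_in_windows(qtns, genes, flank=250_000)
    # window [1, 260000]: g2 starts exactly at pos+flank -> included
    assert wins[0].gene_ids == ["g1", "g2"]
    # g3 starts at pos+flank+1 (given pos 10001 shifted) -> excluded
    qtns2 = pd.DataFrame({"id": ["q"], "chrom": ["1"], "pos": [10_000]})
    wins2 = qi.candidate_genes_in_windows(qtns2, genes, flank=250_000)
    assert "g3" not in wins2[0].gene_ids


def test_windows_match_manual_arithmetic():
    genes = toy_genes()
    qtns = pd.DataFrame({"id": ["a", "b"], "chrom": ["1", "2"], "pos": [400_000, 100]})
    wins = qi.candidate_genes_in_windows(qtns, genes, flank=250_000)
    # a: [150000, 650000] -> g2, g3, g4 ; b: [1, 250100] -> g5, g6
    assert wins[0].gene_ids == ["g2", "g3", "g4"]
    assert wins[1].gene_ids == ["g5", "g6"]


def test_windows_monotone_in_flank():
    genes = toy_genes()
    qtns = pd.DataFrame({"id": ["a"], "chrom": ["1"], "pos": [300_000]})
    prev = set()
    for flank in (1_000, 50_000, 300_000, 700_000):
        wins = qi.candidate_genes_in_windows(qtns, genes, flank=flank)
        cur = set(wins[0].gene_ids)
        assert prev <= cur
        prev = cur


def test_unknown_chromosome_rejected():
    qtns = pd.DataFrame({"id": ["a"], "chrom": ["99"], "pos": [5]})
    with pytest.raises(ContractError):
        qi.candidate_genes_in_windows(qtns, toy_genes(), flank=10)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotation_fixture():
    """Hand-built genome + two genes with known codon content."""
    # plus-strand gene: CDS 101..130, codons AAA TAC GGG ... (10 codons)
    cds_plus = "AAATACGGGCTTACCGATTGGCATCGAGTT"
    seq = ["A"] * 3000
    seq[100:130] = list(cds_plus)
    # minus-strand gene 201..260 with CDS 201..230; genome holds the reverse
    # complement of coding sequence ATGGCC... (arbitrary)
    coding_minus = "ATGGCCAAATTTCCCGGGTACTAGACCGTT"[:30]
    from Bio.Seq import Seq as BSeq

    seq[200:230] = list(str(BSeq(coding_minus).reverse_complement()))
    genome = {"1": "".join(seq)}
    genes = qi.GeneModelSet(genes=[
        qi.Gene("gp", "1", "+", 91, 160, exons=[(91, 120), (141, 160)],
                cds=[(101, 120), (141, 150)]),
        qi.Gene("gm", "1", "-", 195, 270, exons=[(195, 270)], cds=[(201, 230)]),
    ])
    return genome, genes, cds_plus, coding_minus


def test_primary_categories_and_counts_partition():
    genome, genes, _, _ = annotation_fixture()
    variants = pd.DataFrame({
        "chrom": ["1"] * 6,
        "pos": [95, 121, 130, 89, 165, 2900],
        "ref": [genome["1"][p - 1] for p in [95, 121, 130, 89, 165, 2900]],
        "alt": ["C"] * 6,
    })
    out, counts = qi.annotate_variants(variants, genes, genome)
    assert out["category"].tolist() == [
        "exon",            # 95 inside first exon
        "splice_site",     # 121 = first intron base
        "intron",          # 130 mid-intron
        "upstream_2kb",    # 89 just before plus-strand gene start
        "downstream_2kb",  # 165: downstream of gp (+) and of gm (-)
        "intergenic",      # 2900: >2 kb from every gene
    ]
    assert sum(counts.values()) == len(variants)


def test_upstream_1500bp_plus_strand():
    genome = {"1": "A" * 5000}
    genes = qi.GeneModelSet(genes=[
        qi.Gene("g", "1", "+", 3000, 4000, exons=[(3000, 4000)], cds=[])
    ])
    v = pd.DataFrame({"chrom": ["1"], "pos": [1500], "ref": ["A"], "alt": ["T"]})
    out, _ = qi.annotate_variants(v, genes, genome)
    assert out["category"].iloc[0] == "upstream_2kb"


def test_codon_effects_against_codon_table():
    genome, genes, cds_plus, _ = annotation_fixture()
    # codon 1 AAA (Lys): position 103 third base A->G => AAG still Lys
    # codon 2 TAC (Tyr): position 106 third base C->A => TAA stop
    variants = pd.DataFrame({
        "chrom": ["1", "1"],
        "pos": [103, 106],
        "ref": ["A", "C"],
        "alt": ["G", "A"],
    })
    out, _ = qi.annotate_variants(variants, genes, genome)
    assert out["effect"].tolist() == ["synonymous", "stop_gain"]


def test_indel_frameshift_rule():
    genome, genes, _, _ = annotation_fixture()
    variants = pd.DataFrame({
        "chrom": ["1", "1"],
        "pos": [103, 110],
        "ref": [genome["1"][102:104], genome["1"][109:113]],  # len 2 and len 4
        "alt": [genome["1"][102], genome["1"][109]],          # deletions of 1 and 3
    })
    out, _ = qi.annotate_variants(variants, genes, genome)
    assert out["effect"].tolist() == ["frameshift", "non_frameshift"]


def test_ref_mismatch_flagged_and_excluded_from_effects():
    genome, genes, _, _ = annotation_fixture()
    wrong = "C" if genome["1"][102] != "C" else "G"
    v = pd.DataFrame({"chrom": ["1"], "pos": [103], "ref": [wrong], "alt": ["T"]})
    out, _ = qi.annotate_variants(v, genes, genome)
    assert out["ref_mismatch"].iloc[0]
    assert out["effect"].iloc[0] == "ref_mismatch"


def test_minus_strand_synonymous_call():
    genome, genes, _, coding_minus = annotation_fixture()
    # first codon of the minus-strand gene is ATG at genomic 228..230
    # (reverse complement); mutate genomic base 201 which is the last base
    # of the coding sequence's final codon (GTT -> Val); change to C so the
    # codon becomes GTG, still Val -> synonymous
    pos = 201
    ref = genome["1"][pos - 1]
    # genomic base at 201 is complement of coding base 30 ('T' -> 'A')
    v = pd.DataFrame({"chrom": ["1"], "pos": [pos], "ref": [ref], "alt": ["C"]})
    out, _ = qi.annotate_variants(v, genes, genome)
    assert out["effect"].iloc[0] == "synonymous"
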