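"""qRT-PCR relative expression (2^−ΔΔCt) and group comparison.

Technical replicates are averaged to one Ct per (sample, gene);
ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator
group's mean ΔCt; relative quantity rq = 2^−ΔΔCt (amplification efficiency
fixed at 2).  Group differences are assessed by one-way ANOVA with Tukey
HSD pairwise tests summarized as a compact-letter display: groups sharing
a letter are not significantly different at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtTable
from .errors import ContractError


@dataclass
class RelativeExpression:
    per_sample: pd.DataFrame  # sample, group, gene, dct, ddct, rq
    per_group: pd.DataFrame   # group, gene, mean_rq, sd_rq, n
    calibrator_group: str
    excluded_samples: List[str]


def relative_expression(ct: CtTable, calibrator_group: str) -> RelativeExpression:
    """2^−ΔΔCt relative expression against a reference gene and calibrator group."""
    df = ct.records
    if calibrator_group not in set(df["group"]):
        raise ContractError(f"calibrator group {calibrator_group!r} not in Ct table")
    if ct.samples_without_reference:
        warnings.warn(
            f"samples without reference gene excluded: {ct.samples_without_reference}",
            stacklevel=2,
        )
    df = df[~df["sample"].isin(ct.samples_without_reference)]

    rep_counts = df.groupby(["sample", "gene"])["ct"].count()
    if (rep_counts < 2).any():
        warnings.warn("fewer than 2 technical replicates for some (sample, gene)",
                      stacklevel=2)

    mean_ct = (
        df.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    )
    ref = mean_ct[mean_ct["gene"] == ct.reference_gene][["sample", "ct"]].rename(
        columns={"ct": "ct_ref"}
    )
    tgt = mean_ct[mean_ct["gene"] != ct.reference_gene].merge(ref, on="sample")
    tgt["dct"] = tgt["ct"] - tgt["ct_ref"]
    cal_mean = (
        tgt[tgt["group"] == calibrator_group].groupby("gene")["dct"].mean()
    )
    tgt["ddct"] = tgt["dct"] - tgt["gene"].map(cal_mean)
    tgt["rq"] = np.power(2.0, -tgt["ddct"])
    per_sample = tgt[["sample", "group", "gene", "dct", "ddct", "rq"]].reset_index(drop=True)
    per_group = (
        per_sample.groupby(["group", "gene"], as_index=False)
        .agg(mean_rq=("rq", "mean"), sd_rq=("rq", "std"), n=("rq", "count"))
    )
    return RelativeExpression(
        per_sample=per_sample,
        per_group=per_group,
        calibrator_group=calibrator_group,
        excluded_samples=list(ct.samples_without_reference),
    )


@dataclass
class AnovaLetters:
    f_stat: float
    p_value: float
    letters: Dict[str, str]
    tukey: pd.DataFrame  # group1, group2, p_adj
    degenerate: bool = False


def anova_letters(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaLetters:
    """One-way ANOVA + Tukey HSD + compact-letter display.

    Letters are assigned from the maximal cliques of the "not significantly
    different" graph, ordered by descending group mean, so two groups share
    a letter iff their Tukey-adjusted p-value is ≥ alpha.
    """
    import networkx as nx

    groups = list(values_by_group)
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ContractError("need at least 2 values per group")
    degenerate = all(np.var(a) == 0 for a in arrays)
    if degenerate:
        same = len({float(a[0]) for a in arrays}) == 1
        letters = {g: "a" for g in groups} if same else {
            g: chr(ord("a") + i) for i, g in enumerate(groups)
        }
        return AnovaLetters(
            f_stat=float("nan"), p_value=float("nan"),
            letters=letters, tukey=pd.DataFrame(), degenerate=True,
        )

    f_stat, p_value = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    G = nx.Graph()
    G.add_nodes_from(groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(res.pvalue[i, j])
            rows.append((groups[i], groups[j], p_adj))
            if p_adj >= alpha:
                G.add_edge(groups[i], groups[j])
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "p_adj"])

    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    cliques = list(nx.find_cliques(G))
    cliques.sort(key=lambda c: (-max(means[g] for g in c), sorted(c)))
    letters: Dict[str, List[str]] = {g: [] for g in groups}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k) if k < 26 else f"z{k}"
        for g in clique:
            letters[g].append(letter)
    display = {g: "".join(sorted(ls)) for g, ls in letters.items()}
    return AnovaLetters(
        f_stat=float(f_stat), p_value=float(p_value),
        letters=display, tukey=tukey, degenerate=False,
    )
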