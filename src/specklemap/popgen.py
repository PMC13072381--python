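"""SNP-panel population genetics.

Locus filtering (MAF / missingness), the VanRaden centered genomic
relationship matrix, likelihood-based admixture inference with a
cross-validated choice of the number of ancestral clusters K, p-distance
neighbor joining, and linkage-disequilibrium r² decay with stable-distance
detection.

The admixture and neighbor-joining routines are deliberate desk-scale
reimplementations of the classical algorithms (block-relaxation binomial
likelihood; Saitou–Nei agglomeration) so the whole pipeline stays
self-contained and unit-testable.

Missing-data policy: pairwise deletion for distances and LD, per-locus
mean imputation for kinship and admixture fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ContractError

# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removed: pd.DataFrame  # columns: index, chrom, pos, reason, maf, missing

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_variants(
    g: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.5
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with MAF < ``maf_min`` or missing fraction > ``miss_max``.

    Both comparisons are strict, so boundary loci (MAF exactly at the cutoff,
    missingness exactly at the cap) are retained.  A locus with every call
    missing is removed for missingness.
    """
    maf = g.maf()
    miss = g.missing_fraction()
    low_maf = np.where(np.isfinite(maf), maf < maf_min, False)
    high_miss = miss > miss_max
    # an all-missing locus has undefined MAF; it is always uninformative
    all_missing = ~np.isfinite(maf)
    drop = low_maf | high_miss | all_missing
    reasons = np.where(
        high_miss | all_missing,
        np.where(low_maf, "maf+missing", "missing"),
        "maf",
    )
    removed = pd.DataFrame(
        {
            "index": np.where(drop)[0],
            "chrom": g.loci["chrom"].to_numpy()[drop],
            "pos": g.loci["pos"].to_numpy()[drop],
            "reason": reasons[drop],
            "maf": maf[drop],
            "missing": miss[drop],
        }
    )
    kept = g.subset_loci(~drop)
    if kept.n_loci == 0:
        warnings.warn("all loci removed by filtering", stacklevel=2)
    return kept, FilterReport(n_input=g.n_loci, n_kept=kept.n_loci, removed=removed)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_vanraden(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden centered genomic relationship matrix.

    K = ZZᵀ / (2·Σ pⱼ(1−pⱼ)) with Z the per-locus mean-imputed dosage minus
    2p.  Symmetric and positive semi-definite up to numerical tolerance.
    """
    if g.n_ind < 2:
        raise ContractError("kinship requires at least 2 individuals")
    M = g.imputed()
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ContractError("no polymorphic loci; kinship undefined")
    Z = M - 2.0 * p
    K = (Z @ Z.T) / denom
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureResult:
    Q: np.ndarray
    F: np.ndarray
    cv_errors: Dict[int, float]
    best_K: int
    loglik: float
    converged: bool
    Q_by_K: Dict[int, np.ndarray] = field(default_factory=dict)


def _admixture_em(
    D: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray, float, bool]:
    """Block-relaxation EM for the binomial admixture likelihood.

    ``D`` is the n × M dosage matrix (0/1/2); ``obs`` a boolean mask of
    observed entries (missing entries contribute nothing).
    """
    n, M = D.shape
    Dm = np.where(obs, D, 0.0)
    twos = np.where(obs, 2.0 - D, 0.0)
    denom_q = 2.0 * obs.sum(axis=1)[:, None]  # per-individual observed alleles
    if K == 1:
        F = (Dm.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1e-12))[None, :]
        Q = np.ones((n, 1))
        P = np.clip(Q @ F, 1e-9, 1 - 1e-9)
        ll = float(np.sum(np.where(obs, Dm * np.log(P) + twos * np.log1p(-P), 0.0)))
        return Q, F, ll, True

    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(
        (Dm.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1e-12))[None, :]
        + rng.normal(0, 0.05, size=(K, M)),
        0.01,
        0.99,
    )
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, 1e-9, 1 - 1e-9)
        ll = float(np.sum(Dm * np.log(P) + twos * np.log1p(-P)))
        if np.isfinite(prev) and abs(ll - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = ll
        # E-step expected ancestry counts
        A = Dm / P          # n x M
        B = twos / (1.0 - P)
        # Q update: q_ik ∝ Σ_j q_ik f_kj a_ij + q_ik (1-f_kj) b_ij
        num_q = Q * (A @ F.T) + Q * (B @ (1.0 - F).T)
        Q = num_q / np.maximum(denom_q, 1e-12)
        Q = np.clip(Q, 1e-9, None)
        Q /= Q.sum(axis=1, keepdims=True)
        # F update
        num_f = (Q.T @ A) * F           # K x M: Σ_i a_ij q_ik f_kj
        den_f = num_f + (Q.T @ B) * (1.0 - F)
        F = np.clip(num_f / np.maximum(den_f, 1e-12), 1e-4, 1 - 1e-4)
    P = np.clip(Q @ F, 1e-9, 1 - 1e-9)
    ll = float(np.sum(Dm * np.log(P) + twos * np.log1p(-P)))
    return Q, F, ll, converged


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    _masked: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit ancestry proportions Q and ancestral frequencies F at fixed K."""
    D = g.genotypes
    obs = np.isfinite(D)
    if _masked is not None:
        obs = obs & ~_masked
    D = np.where(obs, D, 0.0)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        out = _admixture_em(D, obs, K, rng, max_iter=max_iter, tol=tol)
        if best is None or out[2] > best[2]:
            best = out
    return best


def fit_admixture_cv(
    g: GenotypeMatrix,
    K_range: Sequence[int] = tuple(range(2, 10)),
    folds: int = 5,
    seed: int = 0,
    n_init: int = 2,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> AdmixtureResult:
    """Choose K by cross-validation on held-out genotype entries.

    Observed entries are split into ``folds`` random folds; for each fold
    the model is refit with the fold masked and the CV error is the mean
    squared deviation between held-out dosage/2 and the predicted allele
    probability.  ``best_K`` minimizes the mean CV error.
    """
    if g.n_loci < 50:
        warnings.warn("fewer than 50 loci: admixture inference is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(np.isfinite(g.genotypes))
    perm = rng.permutation(len(obs_idx))
    cv_errors: Dict[int, float] = {}
    Q_by_K: Dict[int, np.ndarray] = {}
    converged_all = True
    for K in K_range:
        errs = []
        for f in range(folds):
            hold = obs_idx[perm[f::folds]]
            mask = np.zeros(g.genotypes.shape, dtype=bool)
            mask[hold[:, 0], hold[:, 1]] = True
            Q, F, _, conv = fit_admixture(
                g, K, seed=seed + 1000 * K + f, n_init=n_init,
                max_iter=max_iter, tol=tol, _masked=mask,
            )
            converged_all &= conv
            P = Q @ F
            d = g.genotypes[hold[:, 0], hold[:, 1]] / 2.0
            errs.append(float(np.mean((d - P[hold[:, 0], hold[:, 1]]) ** 2)))
        cv_errors[int(K)] = float(np.mean(errs))
    best_K = min(cv_errors, key=lambda k: (cv_errors[k], k))
    # final fits on the full data (store Q for every K for reporting)
    for K in K_range:
        Qk, Fk, llk, convk = fit_admixture(
            g, K, seed=seed + 7 * K, n_init=max(n_init, 3), max_iter=2 * max_iter, tol=tol
        )
        Q_by_K[int(K)] = Qk
        if K == best_K:
            Q, F, ll, conv = Qk, Fk, llk, convk
            converged_all &= convk
    return AdmixtureResult(
        Q=Q, F=F, cv_errors=cv_errors, best_K=int(best_K),
        loglik=ll, converged=converged_all, Q_by_K=Q_by_K,
    )


# ---------------------------------------------------------------------------
# p-distance + neighbor joining
# ---------------------------------------------------------------------------


def p_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise fraction of mutually non-missing loci with differing dosage."""
    G = g.genotypes
    n = g.n_ind
    D = np.zeros((n, n))
    obs = np.isfinite(G)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                raise ContractError(
                    f"individuals {i} and {j} share no non-missing loci"
                )
            D[i, j] = D[j, i] = float(np.sum(G[i, both] != G[j, both])) / m
    return D


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Negative branch lengths are clamped to zero with the remainder carried
    by the sibling edge so the pairwise path length is preserved.
    """
    n = len(labels)
    if n < 3:
        raise ContractError("neighbor joining needs at least 3 taxa")
    D = np.asarray(D, float).copy()
    nodes = [str(l) for l in labels]  # newick fragment per active node
    active = list(range(n))

    def clamp(li, lj, dij):
        li_c = max(li, 0.0)
        lj_c = max(dij - li_c, 0.0)
        return li_c, lj_c

    while len(active) > 3:
        N = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (N - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        a, b = np.unravel_index(np.argmin(Qm), Qm.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (N - 2))
        li, lj = clamp(li, dij - li, dij)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to the others
        dnew = np.zeros(D.shape[0] + 1)
        for c_pos, k in enumerate(active):
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew[:-1]
        D[:-1, -1] = dnew[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"


def pdistance_nj(g: GenotypeMatrix) -> str:
    """p-distance matrix + neighbor joining over the panel individuals."""
    if g.n_ind < 3:
        raise ContractError("need at least 3 individuals for a tree")
    D = p_distance_matrix(g)
    return neighbor_joining(D, g.individuals["id"].astype(str).tolist())


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    pairs: pd.DataFrame        # columns: chrom, dist_bp, r2
    decay_curve: pd.DataFrame  # columns: bin_left_kb, bin_right_kb, mean_r2, n_pairs
    stable_distance_kb: Optional[float]
    n_skipped_monomorphic: int


def _pairwise_r2(G: np.ndarray, i: int, j: int) -> Optional[float]:
    """Composite (Rogers–Huff style) r²: squared dosage correlation."""
    a, b = G[:, i], G[:, j]
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 3:
        return None
    x, y = a[both], b[both]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_decay(
    g: GenotypeMatrix,
    max_dist_kb: float = 500.0,
    bin_kb: float = 5.0,
    stability_window_kb: float = 50.0,
    stability_tol: float = 0.05,
) -> LDResult:
    """Intra-chromosome LD r² against physical distance.

    r² is the squared Pearson correlation of unphased dosage vectors
    (composite LD), pairs with a missing member dropped pairwise.  The
    decay curve is the binned mean; the stable distance is the left edge
    of the first bin from which the relative change of the (3-bin rolling
    mean) smoothed curve stays below ``stability_tol`` across
    ``stability_window_kb``.
    """
    G = g.genotypes
    chrom = g.loci["chrom"].to_numpy()
    pos = g.loci["pos"].to_numpy(float)
    max_bp = max_dist_kb * 1000.0
    recs = []
    skipped = 0
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        p = pos[idx]
        for a_pos in range(len(idx)):
            upper = np.searchsorted(p, p[a_pos] + max_bp, side="right")
            for b_pos in range(a_pos + 1, upper):
                r2 = _pairwise_r2(G, idx[a_pos], idx[b_pos])
                if r2 is None:
                    skipped += 1
                    continue
                recs.append((c, p[b_pos] - p[a_pos], r2))
    pairs = pd.DataFrame(recs, columns=["chrom", "dist_bp", "r2"])
    if pairs.empty:
        return LDResult(pairs, pd.DataFrame(), None, skipped)

    edges = np.arange(0.0, max_dist_kb + bin_kb, bin_kb)
    dist_kb = pairs["dist_bp"].to_numpy() / 1000.0
    which = np.clip(np.digitize(dist_kb, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            rows.append((edges[b], edges[b + 1], float(pairs["r2"].to_numpy()[sel].mean()), int(sel.sum())))
    curve = pd.DataFrame(rows, columns=["bin_left_kb", "bin_right_kb", "mean_r2", "n_pairs"])

    stable = _stable_distance(curve, stability_window_kb, stability_tol, bin_kb)
    return LDResult(pairs, curve, stable, skipped)


def _stable_distance(curve, window_kb, tol, bin_kb) -> Optional[float]:
    if len(curve) < 3:
        return None
    smooth = curve["mean_r2"].rolling(3, center=True, min_periods=1).mean().to_numpy()
    left = curve["bin_left_kb"].to_numpy()
    need = max(1, int(round(window_kb / bin_kb)))
    rel = np.abs(np.diff(smooth)) / np.maximum(np.abs(smooth[:-1]), 1e-12)
    ok = rel < tol
    for start in range(len(ok) - need + 1):
        if ok[start: start + need].all():
            return float(left[start])
    return None
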