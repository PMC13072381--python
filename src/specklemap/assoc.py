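"""Four-model genome-wide association scanning.

* ``glm``   — per-locus ordinary least squares, y ~ 1 + dosage.
* ``glmq``  — OLS with ancestry-proportion covariates (Q matrix, one
  column dropped against the intercept).
* ``mlmk``  — mixed linear model y = Xβ + g·β_snp + u + ε with
  Var(u) = σ_g² K, exact per-marker REML via a one-time spectral
  decomposition of the kinship matrix (EMMA).
* ``mlmkq`` — the mixed model with Q covariates as well.

Each scan records the marker effect, standard error, Wald p-value,
−log10 p score and the percent of phenotypic variance explained (squared
partial correlation of the marker given the covariates).  Scans are
compared by genomic-inflation λ and intersected for joint detection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, PhenotypeVector
from .errors import ContractError

MODEL_TAGS = ("glm", "glmq", "mlmk", "mlmkq")


@dataclass
class AssociationScan:
    model_tag: str
    table: pd.DataFrame  # chrom, pos, beta, se, p, score, pve_pct, n_used, flag
    threshold: Optional[float] = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()


def _covariates(n: int, Q: Optional[np.ndarray], with_q: bool) -> np.ndarray:
    C = np.ones((n, 1))
    if with_q:
        if Q is None:
            raise ContractError("this model requires a Q matrix")
        Q = np.asarray(Q, float)
        if Q.shape[0] != n:
            raise ContractError("Q matrix row count must match individuals")
        # drop one ancestry column: proportions sum to 1 (collinear with intercept)
        C = np.hstack([C, Q[:, :-1]])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ContractError("singular covariate matrix (column 'Q')")
    return C


def _ols_scan(y, X, C):
    """Vectorized per-locus OLS after residualizing on the covariates."""
    n, M = X.shape
    # projector onto the orthogonal complement of C
    Ct = np.linalg.pinv(C.T @ C) @ C.T
    y_r = y - C @ (Ct @ y)
    X_r = X - C @ (Ct @ X)
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    resid = y_r[:, None] - X_r * beta[None, :]
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ContractError("not enough residual degrees of freedom")
    s2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(s2 / sxx_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    syy = float(y_r @ y_r)
    pve = np.where(syy > 0, (sxy**2) / (sxx_safe * syy), 0.0) * 100.0
    beta[mono] = 0.0
    se[mono] = np.nan
    p[mono] = 1.0
    pve[mono] = 0.0
    return beta, se, p, pve, mono


def _reml_neg_ll(log_delta, ys, Ws, lam, n, q, logdet_WtW):
    delta = np.exp(log_delta)
    dv = lam + delta
    Wd = Ws / dv[:, None]
    A = Ws.T @ Wd
    b = Wd.T @ ys
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    r = ys - Ws @ beta
    rss = float(r @ (r / dv))
    if rss <= 0:
        return np.inf
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    nq = n - q
    ll = 0.5 * (
        nq * np.log(nq / (2.0 * np.pi))
        - nq
        - nq * np.log(rss)
        - float(np.sum(np.log(dv)))
        + logdet_WtW
        - logdet_A
    )
    return -ll


def _emma_fit(ys, Ws, lam, logdet_WtW):
    """Exact REML over the variance ratio δ = σ_e²/σ_g²; returns GLS pieces."""
    n, q = Ws.shape
    grid = np.linspace(np.log(1e-5), np.log(1e5), 25)
    vals = [_reml_neg_ll(g, ys, Ws, lam, n, q, logdet_WtW) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_ll, bounds=(lo, hi), method="bounded",
        args=(ys, Ws, lam, n, q, logdet_WtW),
    )
    delta = float(np.exp(res.x))
    dv = lam + delta
    Wd = Ws / dv[:, None]
    A = Ws.T @ Wd
    beta = np.linalg.solve(A, Wd.T @ ys)
    r = ys - Ws @ beta
    rss = float(r @ (r / dv))
    sigma_g2 = rss / (n - q)
    cov = sigma_g2 * np.linalg.inv(A)
    return beta, cov, delta, sigma_g2, dv


def run_association(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    model_tag: str,
    Q: Optional[np.ndarray] = None,
    K: Optional[np.ndarray] = None,
) -> AssociationScan:
    """Scan every locus under one of the four association models."""
    if model_tag not in MODEL_TAGS:
        raise ContractError(f"unknown model tag {model_tag!r}")
    yv = np.asarray(y.values, float)
    if yv.size != g.n_ind:
        raise ContractError("phenotype and genotype individual counts differ")
    X = g.imputed()
    n = g.n_ind
    with_q = model_tag in ("glmq", "mlmkq")
    mixed = model_tag in ("mlmk", "mlmkq")
    C = _covariates(n, Q, with_q)

    if not mixed:
        beta, se, p, pve, mono = _ols_scan(yv, X, C)
    else:
        if K is None:
            raise ContractError("mixed models require a kinship matrix K")
        K = np.asarray(K, float)
        if K.shape != (n, n):
            raise ContractError("kinship matrix shape must match individuals")
        lam, U = np.linalg.eigh((K + K.T) / 2.0)
        lam = np.maximum(lam, 0.0)
        ys = U.T @ yv
        Cs = U.T @ C
        Xs = U.T @ X
        M = g.n_loci
        beta = np.zeros(M)
        se = np.full(M, np.nan)
        p = np.ones(M)
        pve = np.zeros(M)
        mono = np.zeros(M, dtype=bool)
        for j in range(M):
            xj = X[:, j]
            if np.std(xj) <= 1e-12:
                mono[j] = True
                continue
            Ws = np.hstack([Cs, Xs[:, j: j + 1]])
            W = np.hstack([C, xj[:, None]])
            sign, logdet_WtW = np.linalg.slogdet(W.T @ W)
            if sign <= 0:
                mono[j] = True
                continue
            b, cov, delta, sg2, dv = _emma_fit(ys, Ws, lam, logdet_WtW)
            q_cov = Ws.shape[1]
            bj = float(b[-1])
            sej = float(np.sqrt(max(cov[-1, -1], 0.0)))
            if sej == 0:
                mono[j] = True
                continue
            tj = bj / sej
            pj = float(2.0 * stats.t.sf(abs(tj), n - q_cov))
            beta[j], se[j], p[j] = bj, sej, max(pj, 1e-300)
            # squared partial correlation on the whitened scale
            wt = 1.0 / np.sqrt(dv)
            yw = ys * wt
            Cw = Cs * wt[:, None]
            xw = Xs[:, j] * wt
            Pc = np.linalg.pinv(Cw.T @ Cw) @ Cw.T
            y_r = yw - Cw @ (Pc @ yw)
            x_r = xw - Cw @ (Pc @ xw)
            den = float((x_r @ x_r) * (y_r @ y_r))
            pve[j] = 100.0 * (float(x_r @ y_r) ** 2 / den) if den > 0 else 0.0

    p = np.clip(p, 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "chrom": g.loci["chrom"],
            "pos": g.loci["pos"],
            "beta": beta,
            "se": se,
            "p": p,
            "score": -np.log10(p),
            "pve_pct": pve,
            "n_used": np.sum(np.isfinite(g.genotypes), axis=0),
            "monomorphic": mono,
        }
    )
    return AssociationScan(model_tag=model_tag, table=table)


# ---------------------------------------------------------------------------
# QQ / lambda
# ---------------------------------------------------------------------------

_CHI2_MEDIAN = 0.45494  # median of chi-square with 1 df


@dataclass
class QQData:
    expected: np.ndarray  # -log10 expected quantiles
    observed: np.ndarray  # sorted -log10 p
    lam: float


def qq_and_lambda(scan) -> QQData:
    """QQ coordinates and the genomic inflation factor λ.

    λ is the median of the χ²(1) quantiles of the p-values divided by the
    null χ²(1) median; λ ≈ 1 indicates a calibrated scan.
    """
    p = scan.p if hasattr(scan, "p") else np.asarray(scan, float)
    p = np.asarray(p, float)
    if p.size < 10:
        raise ContractError("need at least 10 p-values for a QQ summary")
    p = np.clip(np.sort(p), 1e-300, 1.0)
    M = p.size
    expected = -np.log10((np.arange(1, M + 1) - 0.5) / M)  # descending
    observed = -np.log10(p)  # p ascending -> score descending, aligned
    lam = float(np.median(stats.chi2.isf(p, df=1)) / _CHI2_MEDIAN)
    return QQData(expected=expected, observed=observed, lam=lam)


def plot_qq(qq: QQData, path: str, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq.expected, qq.observed, s=6, color="black")
    lim = max(qq.expected.max(), qq.observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(title or f"$\\lambda$ = {qq.lam:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# joint detection
# ---------------------------------------------------------------------------


@dataclass
class JointDetection:
    sig_sets: Dict[str, Set[int]]
    exclusive: Dict[FrozenSet[str], Set[int]]
    joint_counts: Dict[int, int]  # order -> number of loci significant in >= order models
    thresholds: Dict[str, float]

    def exclusive_counts(self) -> Dict[Tuple[str, ...], int]:
        return {tuple(sorted(k)): len(v) for k, v in self.exclusive.items()}


def significant_set(scan: AssociationScan, threshold_rule="bonferroni", alpha=0.05,
                    score_min: Optional[float] = None) -> Tuple[Set[int], float]:
    M = len(scan)
    if score_min is not None:
        thr_p = 10.0 ** (-score_min)
    elif threshold_rule == "bonferroni":
        thr_p = alpha / M
    else:
        raise ContractError(f"unknown threshold rule {threshold_rule!r}")
    sig = set(np.where(scan.p < thr_p)[0].tolist())
    return sig, thr_p


def joint_detection(
    scans: Sequence[AssociationScan],
    threshold_rule: str = "bonferroni",
    alpha: float = 0.05,
    score_min: Optional[float] = None,
) -> JointDetection:
    """Venn accounting of significant loci across model tags.

    ``exclusive`` maps each non-empty subset of model tags to the loci
    significant in exactly that subset; ``joint_counts[k]`` is the number
    of loci significant under at least k models.
    """
    if len({len(s) for s in scans}) != 1:
        raise ContractError("scans do not share a common locus index")
    for s in scans:
        if not s.table[["chrom", "pos"]].equals(scans[0].table[["chrom", "pos"]]):
            raise ContractError("scans do not share a common locus index")
    sig_sets: Dict[str, Set[int]] = {}
    thresholds: Dict[str, float] = {}
    for s in scans:
        sig, thr = significant_set(s, threshold_rule, alpha, score_min)
        sig_sets[s.model_tag] = sig
        thresholds[s.model_tag] = thr
    tags = list(sig_sets)
    universe = set().union(*sig_sets.values()) if sig_sets else set()
    exclusive: Dict[FrozenSet[str], Set[int]] = {}
    for r in range(1, len(tags) + 1):
        for combo in itertools.combinations(tags, r):
            inside = set(universe)
            for t in combo:
                inside &= sig_sets[t]
            for t in tags:
                if t not in combo:
                    inside -= sig_sets[t]
            exclusive[frozenset(combo)] = inside
    joint_counts = {}
    for k in range(1, len(tags) + 1):
        joint_counts[k] = sum(
            1 for locus in universe
            if sum(locus in sig_sets[t] for t in tags) >= k
        )
    return JointDetection(
        sig_sets=sig_sets, exclusive=exclusive,
        joint_counts=joint_counts, thresholds=thresholds,
    )
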