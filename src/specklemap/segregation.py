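"""Mixed major-gene + polygene inheritance analysis of F2 phenotypes.

A quantitative trait segregating in an F2 family is modelled as a finite
normal mixture whose mixing proportions are fixed Mendelian ratios and whose
component means are linear functions of a small set of genetic effects:
the population base value *m*, additive effects *d* (one per major locus)
and dominance effects *h*.  A model is a named set of linear constraints on
those effects; fitting maximizes the mixture likelihood over the free
effects plus one pooled within-component variance σ², and models compete
by AIC.  Polygenic background is absorbed into σ² (it is not separable from
environmental noise with F2 data alone); when an external environmental
variance is supplied the polygenic share is recovered by subtraction.

Model codes follow the conventional suffix grammar:

* ``-A``  — additive only (h = 0)
* ``-AD`` — additive + dominance, all free
* ``-EA`` — equal additive effects across loci, no dominance
* ``-EAD``— equal additive and dominance effects (d_a = d_b = h_a = h_b)
* ``-CD`` — complete dominance (h = d per locus)
* ``-NCD``— negative complete dominance (h = −d)
* ``MX2-X-AD`` — two major genes under constraint X plus an
  additive-dominance polygene background.

For one major gene the F2 genotype classes AA:Aa:aa arrive with weights
(¼, ½, ¼) and means m+d, m+h, m−d.  For two independent major genes the
nine two-locus classes have weights (1,2,1,2,4,2,1,2,1)/16 and means
m + x_a·d_a + z_a·h_a + x_b·d_b + z_b·h_b with x ∈ {1,0,−1} (homozygote
dose) and z ∈ {0,1} (heterozygote indicator); constrained designs collapse
classes with equal means, e.g. 2MG-EAD collapses to three components with
weights (9, 6, 1)/16 and means m+2d, m, m−2d.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .containers import PhenotypeVector
from .errors import CatalogError, ContractError

# ---------------------------------------------------------------------------
# model catalog
# ---------------------------------------------------------------------------

#: AIC parameter counts of the classical segregation-analysis software, as
#: back-computed from its published lnL/AIC pairs.  This convention counts
#: parameters inconsistently across model families (e.g. the fully free
#: two-locus mixture is charged only one parameter more than its
#: equal-effects special case), which makes model selection between nested
#: models nearly coin-flip; it is therefore NOT the default — the default
#: ``minimal`` convention charges each free mean parameter plus the common
#: variance.  Pass ``k_convention="printed"`` to reproduce the classical
#: ranking values.
K_AIC_PRINTED: Dict[str, int] = {
    "1MG-AD": 6,
    "1MG-EAD": 5,
    "1MG-NCD": 5,
    "2MG-EA": 4,
    "2MG-EAD": 4,
    "2MG-CD": 5,
    "MX2-EA-AD": 2,
    "MX2-A-AD": 3,
    "MX2-AD-AD": 5,
    "PG": 2,
    # extended catalog entries use minimal free parameters + 1
    "1MG-A": 3,
    "2MG-AD": 6,
}


@dataclass(frozen=True)
class GeneticModelSpec:
    """One named mixture model: fixed F2 weights + linear mean constraints.

    ``mean_design`` is a (components × parameters) matrix mapping the free
    mean parameters (first column is always the intercept *m*) to the
    component means.
    """

    code: str
    weights: np.ndarray
    mean_design: np.ndarray
    param_names: Tuple[str, ...]
    k_aic: int
    has_polygene: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if not np.isclose(w.sum(), 1.0):
            raise ContractError(f"{self.code}: weights must sum to 1")
        if np.linalg.matrix_rank(self.mean_design) < self.mean_design.shape[1]:
            raise ContractError(f"{self.code}: mean design not full column rank")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return self.mean_design.shape[1]

    def component_means(self, params: Sequence[float]) -> np.ndarray:
        return self.mean_design @ np.asarray(params, float)


# genotype-class enumeration ------------------------------------------------

_ONE_LOCUS = [(1, 0, 0.25), (0, 1, 0.50), (-1, 0, 0.25)]  # (x, z, weight)


def _collapse(rows: np.ndarray, weights: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge genotype classes whose design rows coincide, summing weights."""
    seen: Dict[tuple, int] = {}
    out_rows: List[np.ndarray] = []
    out_w: List[float] = []
    for row, w in zip(rows, weights):
        key = tuple(np.round(row, 12))
        if key in seen:
            out_w[seen[key]] += w
        else:
            seen[key] = len(out_rows)
            out_rows.append(row)
            out_w.append(w)
    return np.array(out_rows, float), np.array(out_w, float)


def _one_locus_design(d_col, h_col, n_params):
    rows, ws = [], []
    for x, z, w in _ONE_LOCUS:
        row = np.zeros(n_params)
        row[0] = 1.0
        row += x * d_col + z * h_col
        rows.append(row)
        ws.append(w)
    return _collapse(np.array(rows), np.array(ws))


def _two_locus_design(da_col, ha_col, db_col, hb_col, n_params):
    rows, ws = [], []
    for (xa, za, wa), (xb, zb, wb) in itertools.product(_ONE_LOCUS, _ONE_LOCUS):
        row = np.zeros(n_params)
        row[0] = 1.0
        row += xa * da_col + za * ha_col + xb * db_col + zb * hb_col
        rows.append(row)
        ws.append(wa * wb)
    return _collapse(np.array(rows), np.array(ws))


def _e(n, i):
    v = np.zeros(n)
    if i is not None:
        v[i] = 1.0
    return v


def _make_model(
    code: str, has_polygene: bool = False, k_convention: str = "minimal"
) -> GeneticModelSpec:
    if code.startswith("MX2-"):
        # MX2-<major constraint>-<polygene kind>: the mixture structure is
        # that of the corresponding two-major-gene model
        major = code[4:].rsplit("-", 1)[0]
        base = f"2MG-{major}"
    else:
        base = code
    if code == "PG":
        design, w = np.array([[1.0]]), np.array([1.0])
        names: Tuple[str, ...] = ("m",)
    elif base.startswith("1MG-"):
        suffix = base[4:]
        if suffix == "AD":
            names = ("m", "d", "h")
            design, w = _one_locus_design(_e(3, 1), _e(3, 2), 3)
        elif suffix == "A":
            names = ("m", "d")
            design, w = _one_locus_design(_e(2, 1), _e(2, None), 2)
        elif suffix == "EAD":  # h = d
            names = ("m", "d")
            design, w = _one_locus_design(_e(2, 1), _e(2, 1), 2)
        elif suffix == "NCD":  # h = -d
            names = ("m", "d")
            design, w = _one_locus_design(_e(2, 1), -_e(2, 1), 2)
        elif suffix == "CD":  # h = d
            names = ("m", "d")
            design, w = _one_locus_design(_e(2, 1), _e(2, 1), 2)
        else:
            raise CatalogError(code)
    else:  # two-locus constraints (used by 2MG-* and MX2-*-AD majors)
        suffix = base[4:] if base.startswith("2MG-") else base
        if suffix == "AD":
            names = ("m", "d_a", "h_a", "d_b", "h_b")
            design, w = _two_locus_design(_e(5, 1), _e(5, 2), _e(5, 3), _e(5, 4), 5)
        elif suffix == "A":
            names = ("m", "d_a", "d_b")
            design, w = _two_locus_design(_e(3, 1), _e(3, None), _e(3, 2), _e(3, None), 3)
        elif suffix == "EA":  # d_a = d_b, no dominance
            names = ("m", "d")
            design, w = _two_locus_design(_e(2, 1), _e(2, None), _e(2, 1), _e(2, None), 2)
        elif suffix == "EAD":  # d_a = d_b = h_a = h_b
            names = ("m", "d")
            design, w = _two_locus_design(_e(2, 1), _e(2, 1), _e(2, 1), _e(2, 1), 2)
        elif suffix == "CD":  # h = d per locus
            names = ("m", "d_a", "d_b")
            design, w = _two_locus_design(_e(3, 1), _e(3, 1), _e(3, 2), _e(3, 2), 3)
        else:
            raise CatalogError(code)
    if k_convention == "printed":
        k = K_AIC_PRINTED.get(code, len(names) + 1)
    elif k_convention == "minimal":
        k = len(names) + 1  # free mean parameters + common variance
    else:
        raise ContractError(f"unknown k_convention {k_convention!r}")
    return GeneticModelSpec(
        code=code,
        weights=w,
        mean_design=design,
        param_names=names,
        k_aic=k,
        has_polygene=has_polygene,
    )


_DEFAULT_CODES = [
    "1MG-AD",
    "1MG-EAD",
    "1MG-NCD",
    "2MG-EA",
    "2MG-EAD",
    "2MG-CD",
    "MX2-EA-AD",
    "MX2-A-AD",
    "MX2-AD-AD",
    "PG",
]

_EXTENDED_CODES = ["1MG-A", "2MG-AD"]

#: user hook for registering additional model codes (e.g. three-gene classes)
_EXTRA_MODELS: Dict[str, GeneticModelSpec] = {}


def register_model(model: GeneticModelSpec) -> None:
    """Register an extra model so ``build_model_catalog``/``get_model`` see it."""
    _EXTRA_MODELS[model.code] = model


def build_model_catalog(
    enable_extended: bool = False, k_convention: str = "minimal"
) -> List[GeneticModelSpec]:
    """Return the default genetic-model catalog.

    The default list covers one- and two-major-gene constrained models, the
    mixed major-gene + polygene variants and a pure-polygene (single
    component) model.  ``enable_extended`` adds the unconstrained extras.
    ``k_convention`` selects the AIC parameter-count convention:
    ``"minimal"`` (free mean parameters + σ²) or ``"printed"``
    (:data:`K_AIC_PRINTED`, the classical software's counts).
    """
    codes = list(_DEFAULT_CODES)
    if enable_extended:
        codes += _EXTENDED_CODES
    models = [
        _make_model(c, has_polygene=c.startswith("MX2") or c == "PG",
                    k_convention=k_convention)
        for c in codes
    ]
    models.extend(_EXTRA_MODELS.values())
    return models


def get_model(code: str, k_convention: str = "minimal") -> GeneticModelSpec:
    """Look up one model by code; raises :class:`CatalogError` if unknown."""
    if code in _EXTRA_MODELS:
        return _EXTRA_MODELS[code]
    if code in _DEFAULT_CODES or code in _EXTENDED_CODES:
        return _make_model(code, has_polygene=code.startswith("MX2") or code == "PG",
                           k_convention=k_convention)
    raise CatalogError(f"unknown genetic model code: {code!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class SegregationFit:
    code: str
    estimates: Dict[str, float]
    component_means: np.ndarray
    weights: np.ndarray
    lnL: float
    aic: float
    converged: bool
    n_restarts_used: int
    monotone: bool = True
    variance_floored: bool = False
    model: Optional[GeneticModelSpec] = None

    @property
    def sigma2(self) -> float:
        return self.estimates["sigma2"]


def compute_aic(lnL: float, k: int) -> float:
    """Akaike information criterion, −2·lnL + 2·k (smaller is better)."""
    if k < 0:
        raise ContractError("parameter count k must be non-negative")
    return -2.0 * lnL + 2.0 * k


def _mixture_loglik_terms(y, means, sigma2, logw):
    z = (y[:, None] - means[None, :]) ** 2
    ll = -0.5 * np.log(2.0 * np.pi * sigma2) - z / (2.0 * sigma2) + logw[None, :]
    m = ll.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))
    return ll, lse


def mixture_loglik(y: np.ndarray, model: GeneticModelSpec, params, sigma2: float) -> float:
    """Log-likelihood of ``y`` under the model's normal mixture."""
    means = model.component_means(params)
    _, lse = _mixture_loglik_terms(
        np.asarray(y, float), means, sigma2, np.log(model.weights)
    )
    return float(lse.sum())


def _em_run(y, X, w, beta, sigma2, max_iter, tol, var_floor):
    """One EM run; returns (beta, sigma2, lnL, converged, monotone, floored)."""
    n = y.size
    logw = np.log(w)
    prev = -np.inf
    monotone = True
    floored = False
    converged = False
    for _ in range(max_iter):
        means = X @ beta
        ll, lse = _mixture_loglik_terms(y, means, sigma2, logw)
        lnL = lse.sum()
        if lnL < prev - 1e-9 * max(1.0, abs(prev)):
            monotone = False
        if np.isfinite(prev) and abs(lnL - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = lnL
        r = np.exp(ll - lse[:, None])  # responsibilities, n x J
        nj = r.sum(axis=0)
        sy = r.T @ y
        # weighted least squares M-step for the constrained means
        A = X.T @ (X * nj[:, None])
        try:
            beta = np.linalg.solve(A, X.T @ sy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, X.T @ sy, rcond=None)[0]
        means = X @ beta
        sigma2 = float((r * (y[:, None] - means[None, :]) ** 2).sum() / n)
        if sigma2 < var_floor:
            sigma2 = var_floor
            floored = True
    means = X @ beta
    _, lse = _mixture_loglik_terms(y, means, sigma2, logw)
    return beta, sigma2, float(lse.sum()), converged, monotone, floored


def _quantile_init(y, model):
    """Model-implied quantile split: match sorted data segments to components."""
    n = y.size
    ys = np.sort(y)[::-1]  # descending; catalog lists high-effect class first
    edges = np.concatenate([[0], np.round(np.cumsum(model.weights) * n).astype(int)])
    edges[-1] = n
    ybar = np.empty(model.n_components)
    for j in range(model.n_components):
        seg = ys[edges[j]: max(edges[j + 1], edges[j] + 1)]
        ybar[j] = seg.mean() if seg.size else ys.mean()
    X, w = model.mean_design, model.weights
    A = X.T @ (X * w[:, None])
    beta = np.linalg.solve(A, X.T @ (w * ybar))
    resid = y.var() if y.var() > 0 else 1.0
    return beta, resid


def fit_segregation(
    pheno: PhenotypeVector,
    model: GeneticModelSpec,
    *,
    sigma_e2: Optional[float] = None,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
) -> SegregationFit:
    """Maximum-likelihood fit of one constrained mixture model via EM.

    The E-step computes component responsibilities under fixed Mendelian
    weights; the M-step solves a weighted least-squares problem for the free
    mean parameters and pools a common within-component variance.
    Initialization is a model-implied quantile split plus seeded random
    restarts; the best restart by final log-likelihood wins.

    ``sigma_e2`` (environmental variance from parental/F1 samples) lets the
    mixed-inheritance (MX) models report a polygenic variance component
    σ²_pg = max(0, σ²_within − σ²_e).
    """
    y = np.asarray(pheno.values, float)
    if y.size <= model.n_params:
        raise ContractError(
            f"{model.code}: need more observations ({y.size}) than free parameters"
        )
    var_floor = 1e-6 * max(float(np.var(y)), 1e-12)
    rng = np.random.default_rng(seed)

    inits = [_quantile_init(y, model)]
    sd = float(np.std(y)) or 1.0
    for _ in range(n_restarts):
        beta = np.zeros(model.n_params)
        beta[0] = float(np.mean(y)) + rng.normal(0, 0.5 * sd)
        beta[1:] = rng.normal(0, sd, size=model.n_params - 1)
        inits.append((beta, float(np.var(y)) * rng.uniform(0.05, 1.0) + var_floor))

    best = None
    monotone_all = True
    for beta0, s20 in inits:
        out = _em_run(y, model.mean_design, model.weights, beta0, s20, max_iter, tol, var_floor)
        monotone_all &= out[4]
        if best is None or out[2] > best[2]:
            best = out
    beta, sigma2, lnL, converged, _, floored = best

    estimates = {name: float(b) for name, b in zip(model.param_names, beta)}
    estimates["sigma2"] = float(sigma2)
    if model.has_polygene:
        if sigma_e2 is not None:
            estimates["sigma2_pg"] = max(0.0, sigma2 - float(sigma_e2))
            estimates["sigma2_e"] = float(sigma_e2)
        else:
            estimates["sigma2_pg"] = float("nan")  # not separable from F2 alone
    return SegregationFit(
        code=model.code,
        estimates=estimates,
        component_means=model.component_means(beta),
        weights=model.weights.copy(),
        lnL=lnL,
        aic=compute_aic(lnL, model.k_aic),
        converged=converged,
        n_restarts_used=n_restarts,
        monotone=monotone_all,
        variance_floored=floored,
        model=model,
    )


def fit_catalog(
    pheno: PhenotypeVector,
    models: Optional[Sequence[GeneticModelSpec]] = None,
    **kwargs,
) -> List[SegregationFit]:
    """Fit every model in the catalog to one phenotype sample."""
    if models is None:
        models = build_model_catalog()
    return [fit_segregation(pheno, m, **kwargs) for m in models]


def select_top_models(fits: Sequence[SegregationFit], n: int = 5) -> List[SegregationFit]:
    """Rank fits by ascending AIC; ties by smaller k then lexicographic code."""
    if not fits:
        raise ContractError("no fits to rank")

    def key(f: SegregationFit):
        k = f.model.k_aic if f.model is not None else 0
        return (f.aic, k, f.code)

    return sorted(fits, key=key)[: max(0, min(n, len(fits)))]


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class FitDiagnostics:
    u1_sq: float
    u2_sq: float
    u3_sq: float
    p_u1: float
    p_u2: float
    p_u3: float
    nW_sq: float
    p_nW: float
    Dn: float
    p_Dn: float
    small_sample: bool = False


def uniformity_statistics(u: np.ndarray) -> Dict[str, float]:
    """U₁², U₂², U₃² uniformity statistics of PIT values on [0, 1].

    Each statistic is (Σᵢ πⱼ(uᵢ))²/n for the j-th orthonormal shifted
    Legendre polynomial and is χ²(1)-distributed under uniformity.
    In particular U₁² = 12·n·(ū − ½)².
    """
    u = np.asarray(u, float)
    n = u.size
    p1 = np.sqrt(3.0) * (2 * u - 1)
    p2 = np.sqrt(5.0) * (6 * u**2 - 6 * u + 1)
    p3 = np.sqrt(7.0) * (20 * u**3 - 30 * u**2 + 12 * u - 1)
    out = {}
    for name, p in (("u1_sq", p1), ("u2_sq", p2), ("u3_sq", p3)):
        s = float(p.sum() ** 2 / n)
        out[name] = s
        out["p_" + name[:2]] = float(stats.chi2.sf(s, df=1))
    return out


def mixture_cdf(x: np.ndarray, fit: SegregationFit) -> np.ndarray:
    sd = np.sqrt(fit.sigma2)
    x = np.asarray(x, float)
    z = (x[:, None] - fit.component_means[None, :]) / sd
    return stats.norm.cdf(z) @ fit.weights


def goodness_of_fit(
    fit: SegregationFit, pheno: PhenotypeVector, seed: int = 0
) -> FitDiagnostics:
    """Uniformity diagnostics of the probability integral transform.

    Under a correct model the fitted-CDF values of the data are uniform on
    [0,1].  U₁², U₂², U₃² project the PIT values on the first three
    normalized Legendre polynomials (each squared sum / n is χ²(1) under
    uniformity); nW² is the Cramér–von Mises statistic and Dn the
    Kolmogorov statistic, both against the uniform law.

    Counts are rounded observations of a continuous variable, so the plain
    PIT is discrete and would mechanically inflate every statistic.  A
    count x is therefore transformed with the randomized PIT
    u = F̂(x−½) + V·(F̂(x+½) − F̂(x−½)), V ~ U(0,1), which is exactly
    uniform when the fitted mixture is correct; ``seed`` makes the
    randomization reproducible.
    """
    if not fit.converged:
        raise ContractError("goodness_of_fit requires a converged fit")
    y = np.asarray(pheno.values, float)
    n = y.size
    if np.allclose(y, np.round(y)):
        lo = mixture_cdf(y - 0.5, fit)
        hi = mixture_cdf(y + 0.5, fit)
        v = np.random.default_rng([seed, 0x9E3779B9]).random(n)
        u = lo + v * (hi - lo)
    else:
        u = mixture_cdf(y, fit)
    u = np.clip(u, 1e-12, 1 - 1e-12)

    us = uniformity_statistics(u)
    cvm = stats.cramervonmises(u, "uniform")
    ks = stats.kstest(u, "uniform")
    return FitDiagnostics(
        u1_sq=us["u1_sq"],
        u2_sq=us["u2_sq"],
        u3_sq=us["u3_sq"],
        p_u1=us["p_u1"],
        p_u2=us["p_u2"],
        p_u3=us["p_u3"],
        nW_sq=float(cvm.statistic),
        p_nW=float(min(1.0, cvm.pvalue)),
        Dn=float(ks.statistic),
        p_Dn=float(ks.pvalue),
        small_sample=n < 8,
    )


# ---------------------------------------------------------------------------
# variance decomposition & sex comparison
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    sigma2_mg: float
    sigma2_P: float
    h2_mg_pct: float
    sigma2_pg: float = 0.0


def decompose_variance(fit: SegregationFit, pheno: PhenotypeVector) -> VarianceDecomposition:
    """Major-gene variance = between-component variance of the fitted mixture.

    Heritability of the major genes is that variance over the sample
    phenotypic variance, reported in percent and capped to [0, 100].
    """
    if not fit.converged:
        raise ContractError("decompose_variance requires a converged fit")
    y = np.asarray(pheno.values, float)
    sigma2_P = float(np.var(y, ddof=1))
    if sigma2_P == 0:
        raise ContractError("phenotypic variance is zero; heritability undefined")
    mu_bar = float(fit.weights @ fit.component_means)
    sigma2_mg = float(fit.weights @ (fit.component_means - mu_bar) ** 2)
    h2 = float(np.clip(100.0 * sigma2_mg / sigma2_P, 0.0, 100.0))
    sigma2_pg = fit.estimates.get("sigma2_pg", 0.0)
    if not np.isfinite(sigma2_pg):
        sigma2_pg = 0.0
    return VarianceDecomposition(
        sigma2_mg=sigma2_mg, sigma2_P=sigma2_P, h2_mg_pct=h2, sigma2_pg=sigma2_pg
    )


def compare_sexes(male: PhenotypeVector, female: PhenotypeVector) -> Dict[str, float]:
    """Welch t-test on raw counts + Pearson r of per-count frequency spectra.

    The correlation is computed between the two sexes' relative-frequency
    vectors over the union of observed count values, summarizing whether the
    two distributions follow the same shape.
    """
    a = np.asarray(male.values, float)
    b = np.asarray(female.values, float)
    if a.size < 2 or b.size < 2:
        raise ContractError("need at least 2 observations per sex")
    degenerate = np.var(a) == 0 and np.var(b) == 0
    if degenerate and np.mean(a) == np.mean(b):
        t, p = (0.0, 1.0)
    elif degenerate:
        t, p = (float("nan"), float("nan"))
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)

    support = np.arange(int(min(a.min(), b.min())), int(max(a.max(), b.max())) + 1)
    fa = np.array([(a == v).mean() for v in support])
    fb = np.array([(b == v).mean() for v in support])
    if np.std(fa) == 0 or np.std(fb) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(fa, fb)[0, 1])
    return {"t": t, "p": p, "pearson_r": r, "degenerate": float(degenerate)}
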