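"""Segregation analysis: model catalog, EM fitting, AIC ranking, diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from specklemap import synthgen as gen
from specklemap.containers import PhenotypeVector
from specklemap.errors import CatalogError, ContractError
from specklemap.segregation import (
    SegregationFit,
    build_model_catalog,
    compare_sexes,
    compute_aic,
    decompose_variance,
    fit_segregation,
    get_model,
    goodness_of_fit,
    mixture_loglik,
    select_top_models,
    uniformity_statistics,
)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def enumerate_two_locus(d_a, h_a, d_b, h_b, m=0.0):
    """Brute-force oracle: the 9 two-locus F2 classes collapsed by mean."""
    one = [(1, 0, 0.25), (0, 1, 0.5), (-1, 0, 0.25)]
    acc = {}
    for (xa, za, wa), (xb, zb, wb) in itertools.product(one, one):
        mu = round(m + xa * d_a + za * h_a + xb * d_b + zb * h_b, 9)
        acc[mu] = acc.get(mu, 0.0) + wa * wb
    return acc


def test_catalog_weights_sum_to_one():
    for model in build_model_catalog(enable_extended=True):
        assert np.isclose(model.weights.sum(), 1.0)


def test_2mg_ead_collapses_to_three_components():
    model = get_model("2MG-EAD")
    m, d = 10.0, 4.0
    oracle = enumerate_two_locus(d, d, d, d, m)
    assert oracle == {18.0: 9 / 16, 10.0: 6 / 16, 2.0: 1 / 16}
    means = model.component_means([m, d])
    got = dict(zip(np.round(means, 9), model.weights))
    assert got == pytest.approx(oracle)


def test_2mg_cd_collapses_to_four_components():
    model = get_model("2MG-CD")
    d_a, d_b = 4.0, 2.0
    oracle = enumerate_two_locus(d_a, d_a, d_b, d_b)  # h = d per locus
    means = model.component_means([0.0, d_a, d_b])
    got = dict(zip(np.round(means, 9), model.weights))
    assert got == pytest.approx(oracle)
    assert sorted(np.round(model.weights * 16).astype(int)) == [1, 3, 3, 9]


def test_unknown_model_code_raises():
    with pytest.raises(CatalogError):
        get_model("4MG-XYZ")


# ---------------------------------------------------------------------------
# AIC
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lnl,k,expected,tol",
    [
        (-114.9168, 4, 237.8336, 1e-9),   # worked example (printed 237.8335)
        (-135.6873, 5, 281.3746, 1e-9),
        (0.0, 0, 0.0, 0.0),
    ],
)
def test_compute_aic(lnl, k, expected, tol):
    assert compute_aic(lnl, k) == pytest.approx(expected, abs=max(tol, 1e-12))


def test_aic_identity_holds_for_fits():
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("1MG-AD", m=8, effects={"d": 3, "h": 1}, sigma_e2=1, n=120, seed=3)
    )
    for model in build_model_catalog():
        fit = fit_segregation(pheno, model, n_restarts=2, seed=0)
        assert fit.aic == -2.0 * fit.lnL + 2.0 * model.k_aic


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_single_component_fit_is_closed_form():
    rng = np.random.default_rng(0)
    y = np.round(rng.normal(12, 3, 300)).clip(0).astype(int)
    pheno = PhenotypeVector(values=y)
    fit = fit_segregation(pheno, get_model("PG"), n_restarts=2, seed=0)
    assert fit.estimates["m"] == pytest.approx(float(np.mean(y)), abs=1e-6)
    assert fit.estimates["sigma2"] == pytest.approx(float(np.var(y)), rel=1e-6)


def grid_refine_oracle(y, model, bounds, rounds=6, pts=7):
    """Iterative grid refinement over the free mean params and sigma2."""
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    best, best_ll = None, -np.inf
    for _ in range(rounds):
        axes = [np.linspace(l, h, pts) for l, h in zip(lo, hi)]
        for combo in itertools.product(*axes):
            params, s2 = np.array(combo[:-1]), combo[-1]
            if s2 <= 0:
                continue
            ll = mixture_loglik(y, model, params, s2)
            if ll > best_ll:
                best_ll, best = ll, np.array(combo)
        span = (hi - lo) / (pts - 1)
        lo = best - span
        hi = best + span
    return best, best_ll


def test_2mg_cd_fit_matches_truth_and_grid_oracle():
    true = dict(m=10.0, d_a=4.0, d_b=2.0, s2=1.0)
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("2MG-CD", m=true["m"], effects={"d_a": true["d_a"], "d_b": true["d_b"]},
                      sigma_e2=true["s2"], n=800, seed=1)
    )
    model = get_model("2MG-CD")
    fit = fit_segregation(pheno, model, n_restarts=6, seed=0)
    # the model is exchangeable in (d_a, d_b): compare the sorted pair
    d_hat = sorted([fit.estimates["d_a"], fit.estimates["d_b"]], reverse=True)
    d_true = sorted([true["d_a"], true["d_b"]], reverse=True)
    # rough asymptotic SEs: means ~ sigma/sqrt(n_class); use generous 3-SE bands
    se = np.sqrt(fit.sigma2 / (len(pheno) * np.array([1.0, 0.25, 0.25])))
    assert abs(fit.estimates["m"] - true["m"]) < 3 * se[0] + 0.2
    assert abs(d_hat[0] - d_true[0]) < 3 * se[1] + 0.2
    assert abs(d_hat[1] - d_true[1]) < 3 * se[2] + 0.2
    y = pheno.values.astype(float)
    start = [
        (fit.estimates["m"] - 1, fit.estimates["m"] + 1),
        (fit.estimates["d_a"] - 1, fit.estimates["d_a"] + 1),
        (fit.estimates["d_b"] - 1, fit.estimates["d_b"] + 1),
        (max(fit.sigma2 / 2, 0.05), fit.sigma2 * 2),
    ]
    oracle, oracle_ll = grid_refine_oracle(y, model, start)
    assert abs(fit.estimates["m"] - oracle[0]) < 1e-3
    assert abs(fit.estimates["d_a"] - oracle[1]) < 1e-3
    assert abs(fit.estimates["d_b"] - oracle[2]) < 1e-3
    assert fit.lnL >= oracle_ll - 1e-6


def test_true_model_beats_pure_polygene():
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("2MG-EAD", m=10, effects={"d": 4}, sigma_e2=1, n=500, seed=2)
    )
    fit_true = fit_segregation(pheno, get_model("2MG-EAD"), n_restarts=4, seed=0)
    fit_pg = fit_segregation(pheno, get_model("PG"), n_restarts=2, seed=0)
    assert fit_true.lnL >= fit_pg.lnL


def test_em_monotone_over_100_random_starts():
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("2MG-EAD", m=10, effects={"d": 4}, sigma_e2=1, n=200, seed=5)
    )
    fit = fit_segregation(pheno, get_model("2MG-EAD"), n_restarts=100, seed=1)
    assert fit.monotone  # lnL never decreased in any restart
    assert fit.converged


def test_em_matches_grid_oracle_1mg_ad_small_n():
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("1MG-AD", m=10, effects={"d": 4, "h": 2}, sigma_e2=1, n=50, seed=9)
    )
    model = get_model("1MG-AD")
    fit = fit_segregation(pheno, model, n_restarts=10, seed=0)
    bounds = [(6, 16), (0, 8), (-4, 6), (0.2, 6)]
    _, oracle_ll = grid_refine_oracle(pheno.values.astype(float), model, bounds)
    assert fit.lnL >= oracle_ll - 1e-6


def test_too_few_observations_rejected():
    pheno = PhenotypeVector(values=np.array([3, 4]))
    with pytest.raises(ContractError):
        fit_segregation(pheno, get_model("1MG-AD"))


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _stub(code, lnl, k):
    model = get_model(code) if code != "X" else None
    return SegregationFit(
        code=code, estimates={"sigma2": 1.0}, component_means=np.array([0.0]),
        weights=np.array([1.0]), lnL=lnl, aic=compute_aic(lnl, k),
        converged=True, n_restarts_used=0, model=model,
    )


def test_printed_inbred_block_ranks_2mg_ead_first():
    block = [
        ("2MG-EAD", -114.9168, 4),
        ("1MG-NCD", -119.9981, 5),
        ("1MG-EAD", -120.0112, 5),
        ("2MG-EA", -121.671, 4),
        ("1MG-AD", -119.9806, 6),
    ]
    fits = [_stub(c, l, k) for c, l, k in block]
    ranked = select_top_models(fits, 5)
    assert ranked[0].code == "2MG-EAD"
    aics = [f.aic for f in ranked]
    assert aics == sorted(aics)
    assert aics == pytest.approx([237.8336, 249.9963, 250.0225, 251.3421, 251.9612], abs=2e-4)


def test_select_top_models_tie_and_truncation_rules():
    a = _stub("2MG-EA", -10.0, 4)     # aic 28
    b = _stub("2MG-CD", -9.0, 5)      # aic 28 with larger k
    ranked = select_top_models([b, a], 5)
    assert [f.code for f in ranked] == ["2MG-EA", "2MG-CD"]
    assert len(select_top_models([a, b], 1)) == 1


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def test_u1_vanishes_on_exact_uniform_grid():
    n = 64
    u = (np.arange(1, n + 1) - 0.5) / n
    out = uniformity_statistics(u)
    assert out["u1_sq"] == pytest.approx(0.0, abs=1e-20)


def test_u1_identity_12n_mean_half_squared():
    rng = np.random.default_rng(7)
    for _ in range(5):
        u = rng.random(137)
        out = uniformity_statistics(u)
        n = u.size
        assert out["u1_sq"] == pytest.approx(12 * n * (u.mean() - 0.5) ** 2, rel=1e-10)


def test_gof_calibrated_on_model_truth():
    """Data simulated from the fitted model: each test rejects rarely."""
    rejections = np.zeros(5)
    n_seeds = 20
    for s in range(n_seeds):
        pheno = gen.simulate_f2_phenotypes(
            gen.F2SimSpec("2MG-EAD", m=10, effects={"d": 4}, sigma_e2=1, n=500, seed=100 + s)
        )
        fit = fit_segregation(pheno, get_model("2MG-EAD"), n_restarts=3, seed=s)
        d = goodness_of_fit(fit, pheno, seed=s)
        rejections += np.array(
            [d.p_u1 < 0.05, d.p_u2 < 0.05, d.p_u3 < 0.05, d.p_nW < 0.05, d.p_Dn < 0.05]
        )
    assert (rejections <= 3).all(), rejections


def test_gof_small_sample_flag():
    pheno = PhenotypeVector(values=np.array([4, 5, 6, 5, 4, 6]))
    fit = fit_segregation(pheno, get_model("PG"), n_restarts=1, seed=0)
    assert goodness_of_fit(fit, pheno).small_sample


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------


def test_equal_component_means_give_zero_h2():
    pheno = PhenotypeVector(values=np.array([3, 5, 4, 6, 5, 4, 3, 5]))
    fit = fit_segregation(pheno, get_model("PG"), n_restarts=1, seed=0)
    dec = decompose_variance(fit, pheno)
    assert dec.sigma2_mg == pytest.approx(0.0, abs=1e-12)
    assert dec.h2_mg_pct == 0.0


def test_h2_invariant_under_affine_rescaling():
    pheno = gen.simulate_f2_phenotypes(
        gen.F2SimSpec("2MG-EAD", m=10, effects={"d": 4}, sigma_e2=1, n=600, seed=4)
    )
    model = get_model("2MG-EAD")
    fit = fit_segregation(pheno, model, n_restarts=4, seed=0)
    dec = decompose_variance(fit, pheno)
    # rescale data and estimates consistently: y' = a*y + b
    a, b = 2.5, 7.0
    y2 = a * pheno.values.astype(float) + b
    fit2 = SegregationFit(
        code=fit.code, estimates=dict(fit.estimates),
        component_means=a * fit.component_means + b, weights=fit.weights,
        lnL=fit.lnL, aic=fit.aic, converged=True, n_restarts_used=0, model=model,
    )
    pheno2 = PhenotypeVector(values=y2)
    dec2 = decompose_variance(fit2, pheno2)
    assert dec2.h2_mg_pct == pytest.approx(dec.h2_mg_pct, abs=1e-9)


def test_zero_variance_phenotype_rejected():
    pheno = PhenotypeVector(values=np.full(20, 5))
    fit = _stub("PG", -1.0, 2)
    with pytest.raises(ContractError):
        decompose_variance(fit, pheno)


# ---------------------------------------------------------------------------
# sex comparison
# ---------------------------------------------------------------------------


def test_identical_sexes_agree_perfectly():
    v = PhenotypeVector(values=np.array([2, 3, 3, 5, 8, 2]))
    out = compare_sexes(v, v)
    assert out["t"] == pytest.approx(0.0, abs=1e-12)
    assert out["p"] == pytest.approx(1.0)
    assert out["pearson_r"] == pytest.approx(1.0)


def test_welch_p_matches_direct_formula():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([10.0, 20.0, 30.0])
    out = compare_sexes(PhenotypeVector(values=a), PhenotypeVector(values=b))
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    p = 2 * stats.t.sf(abs(t), df)
    assert out["t"] == pytest.approx(t, abs=1e-12)
    assert out["p"] == pytest.approx(p, abs=1e-12)


def test_disjoint_supports_anticorrelated_frequencies():
    a = PhenotypeVector(values=np.array([1, 1, 2, 2]))
    b = PhenotypeVector(values=np.array([9, 9, 10, 10]))
    out = compare_sexes(a, b)
    assert out["pearson_r"] <= 0


def test_degenerate_equal_constants_flagged():
    a = PhenotypeVector(values=np.full(5, 4))
    out = compare_sexes(a, PhenotypeVector(values=np.full(5, 7)))
    assert np.isnan(out["t"]) and out["degenerate"] == 1.0
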