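import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from protolex.ordinal import (ConvergenceError, bootstrap_ci, fit_clm,
                              fit_clmm, lr_test, marginal_contrast,
                              parse_formula, select_model)

from conftest import simulate_ordinal


def test_formula_parsing():
    resp, fixed, random = parse_formula(
        "rating ~ score + accent + wordhood:bin + (1|participant) + (1+score|item)")
    assert resp == "rating"
    assert fixed == ["score", "accent", "wordhood:bin"]
    assert [(r.group, r.slope) for r in random] == [
        ("participant", None), ("item", None), ("item", "score")]
    _, fixed2, _ = parse_formula("y ~ a*b")
    assert fixed2 == ["a", "b", "a:b"]


def test_group_symmetry_gives_zero_coefficient():
    # data invariant under swapping the group labels → coefficient exactly 0
    rows = []
    for k in range(1, 6):
        for g in (0.0, 1.0):
            rows += [{"rating": k, "g": g}] * (10 + 3 * k)
    fit = fit_clm(pd.DataFrame(rows), "rating ~ g")
    assert abs(fit.coef["g"]) < 1e-8


def test_saturated_fit_reproduces_empirical_cumulative_logits():
    # weighted data constructed to satisfy proportional odds exactly
    theta = np.array([-1.0, 0.0, 0.8, 1.7])
    beta = 0.9
    rows = []
    for g in (0.0, 1.0):
        cum = 1 / (1 + np.exp(-(theta - beta * g)))
        p = np.diff(np.concatenate(([0.0], cum, [1.0])))
        for k, w in enumerate(p, start=1):
            rows.append({"rating": k, "g": g, "w": 1000 * w})
    fit = fit_clm(pd.DataFrame(rows), "rating ~ g", weights="w")
    assert fit.thresholds == pytest.approx(theta, abs=1e-6)
    assert fit.coef["g"] == pytest.approx(beta, abs=1e-6)


def test_aic_identity():
    df = simulate_ordinal(300, seed=1)
    fit = fit_clm(df, "rating ~ x + g")
    assert fit.aic == pytest.approx(2 * fit.nparams - 2 * fit.loglike, abs=1e-10)
    assert fit.nparams == 4 + 2


def test_matches_independent_optimizer_loglike():
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    for seed in range(10):
        df = simulate_ordinal(150 + 20 * seed, seed=seed)
        fit = fit_clm(df, "rating ~ x + g")
        om = OrderedModel(df.rating, df[["x", "g"]], distr="logit").fit(
            method="bfgs", disp=0)
        assert fit.loglike == pytest.approx(om.llf, abs=1e-6)
        assert fit.coef["x"] == pytest.approx(om.params["x"], abs=1e-4)


def test_thresholds_strictly_increasing():
    df = simulate_ordinal(400, seed=3)
    fit = fit_clm(df, "rating ~ x + g")
    assert np.all(np.diff(fit.thresholds) > 0)


def test_likelihood_at_optimum_beats_truth():
    beta_x, beta_g, theta = 1.2, 0.7, (-2.0, -0.5, 0.5, 2.0)
    df = simulate_ordinal(500, beta_x, beta_g, theta, seed=4)
    fit = fit_clm(df, "rating ~ x + g")
    eta = beta_x * df.x + beta_g * df.g
    th = np.asarray(theta)
    cum = 1 / (1 + np.exp(-(th[None, :] - eta.to_numpy()[:, None])))
    probs = np.diff(np.concatenate(
        (np.zeros((len(df), 1)), cum, np.ones((len(df), 1))), axis=1))
    ll_truth = np.log(probs[np.arange(len(df)), df.rating - 1]).sum()
    assert fit.loglike >= ll_truth - 1e-9


def test_rank_deficiency_rejected():
    df = simulate_ordinal(100, seed=5)
    df["x2"] = df["x"]
    with pytest.raises(ValueError, match="rank"):
        fit_clm(df, "rating ~ x + x2")


def test_single_rating_level_rejected():
    df = pd.DataFrame({"rating": [3] * 20, "x": np.arange(20.0)})
    with pytest.raises(ValueError, match="rating levels"):
        fit_clm(df, "rating ~ x")


# ---------------------------------------------------------------------------
# mixed fits

def _mixed_data(n_p=15, n_i=40, sd_p=0.8, sd_i=0.0, beta=1.2, seed=0):
    r = np.random.default_rng(seed)
    x_i = r.normal(size=n_i)
    u = r.normal(0, sd_p, n_p) if sd_p else np.zeros(n_p)
    v = r.normal(0, sd_i, n_i) if sd_i else np.zeros(n_i)
    rows = []
    th = np.array([-2.0, -0.5, 0.5, 2.0])
    for p in range(n_p):
        for i in range(n_i):
            eta = beta * x_i[i] + u[p] + v[i]
            cum = 1 / (1 + np.exp(-(th - eta)))
            y = 1 + int((r.random() > cum).sum())
            rows.append({"rating": y, "x": x_i[i], "participant": p, "item": i})
    return pd.DataFrame(rows)


def test_clmm_reduces_to_clm_when_variance_zero():
    df = _mixed_data(sd_p=0.0, sd_i=0.0, seed=6)
    fixed = fit_clm(df, "rating ~ x")
    mixed = fit_clmm(df, "rating ~ x + (1|participant) + (1|item)")
    assert mixed.coef["x"] == pytest.approx(fixed.coef["x"], abs=1e-3)
    assert mixed.thresholds == pytest.approx(fixed.thresholds, abs=1e-3)
    assert mixed.singular  # variances at the boundary are flagged


def test_clmm_recovers_participant_variance():
    df = _mixed_data(n_p=40, n_i=60, sd_p=1.0, seed=7)
    fit = fit_clmm(df, "rating ~ x + (1|participant)")
    assert 0.6 < fit.re_sd["(1|participant)"] < 1.4
    assert fit.coef["x"] == pytest.approx(1.2, abs=0.35)


def test_clmm_single_group_rejected():
    df = _mixed_data(n_p=1, seed=8)
    with pytest.raises(ValueError, match="2 levels"):
        fit_clmm(df, "rating ~ x + (1|participant)")


def test_clmm_marginal_likelihood_below_fixed_upper_bound():
    df = _mixed_data(n_p=10, n_i=30, sd_p=0.6, seed=9)
    mixed = fit_clmm(df, "rating ~ x + (1|participant)")
    assert np.isfinite(mixed.loglike)
    assert mixed.aic == pytest.approx(2 * mixed.nparams - 2 * mixed.loglike)


# ---------------------------------------------------------------------------
# contrasts, bootstrap, model selection

def test_contrast_without_interaction_equals_coefficient():
    df = simulate_ordinal(500, seed=10)
    fit = fit_clm(df, "rating ~ x + g")
    est, z, (lo, hi) = marginal_contrast(fit, "g")
    assert est == pytest.approx(fit.coef["g"])
    se = (hi - lo) / (2 * norm.ppf(0.975))
    assert se == pytest.approx(fit.se["g"], rel=1e-6)
    assert lo < est < hi


def test_contrast_delta_se_matches_numerical_jacobian():
    df = simulate_ordinal(400, seed=11)
    df["xg"] = df.x * df.g
    fit = fit_clm(df, "rating ~ x + g + x:g")

    def contrast_fn(beta_vec):
        c = pd.Series(beta_vec, index=fit.coef.index)
        return c["g"] + c["x:g"] * fit.col_means["x"]

    eps = 1e-6
    b0 = fit.coef.to_numpy()
    jac = np.array([
        (contrast_fn(b0 + eps * np.eye(len(b0))[j])
         - contrast_fn(b0 - eps * np.eye(len(b0))[j])) / (2 * eps)
        for j in range(len(b0))])
    cov = fit.cov.loc[fit.coef.index, fit.coef.index].to_numpy()
    se_num = np.sqrt(jac @ cov @ jac)
    est, z, (lo, hi) = marginal_contrast(fit, "g")
    se_delta = (hi - lo) / (2 * norm.ppf(0.975))
    assert se_delta == pytest.approx(se_num, rel=0.05)


def test_contrast_at_interacting_level():
    df = simulate_ordinal(400, seed=12)
    fit = fit_clm(df, "rating ~ x + g + x:g")
    est, _, _ = marginal_contrast(fit, "g", at={"x": 2.0})
    assert est == pytest.approx(fit.coef["g"] + 2.0 * fit.coef["x:g"])


def test_contrast_unknown_factor_or_level_rejected():
    df = simulate_ordinal(200, seed=13)
    fit = fit_clm(df, "rating ~ x + g")
    with pytest.raises(KeyError):
        marginal_contrast(fit, "absent")
    with pytest.raises(KeyError):
        marginal_contrast(fit, "g", at={"bin[high]": 1.0})


def test_bootstrap_constant_vector_zero_width():
    lo, hi = bootstrap_ci([2.5] * 10, B=200, seed=0)
    assert lo == hi == 2.5


def test_bootstrap_single_value_rejected():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0])


def test_bootstrap_coverage_near_nominal():
    rng = np.random.default_rng(14)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.normal(size=100)
        lo, hi = bootstrap_ci(x, B=300, seed=int(rng.integers(2**31)))
        hits += lo <= 0 <= hi
    assert 0.89 <= hits / n_rep <= 0.99


def test_backward_elimination_drops_null_interaction():
    df = simulate_ordinal(800, seed=15)
    fit = select_model(df, "rating ~ x + g + x:g", alpha=0.05)
    assert "x:g" not in fit.coef.index  # no interaction in the truth
    assert {"x", "g"} <= set(fit.coef.index)


def test_lr_test_nested_order_enforced():
    df = simulate_ordinal(300, seed=16)
    full = fit_clm(df, "rating ~ x + g")
    red = fit_clm(df, "rating ~ x")
    p = lr_test(full, red)
    assert 0 <= p <= 1
    with pytest.raises(ValueError):
        lr_test(red, full)
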