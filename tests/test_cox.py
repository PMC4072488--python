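"""Cox engine: hand-checked likelihood values, oracle equivalence, inference."""

import numpy as np
import pytest
from scipy import stats

from cutscan.cox import (
    CoxPH,
    SurvivalData,
    breslow_baseline,
    partial_loglik,
    score_test,
)
from cutscan.exceptions import ConvergenceError, DegenerateDesignError, SchemaError

from conftest import random_survival_data, small_survival_fixtures


def grid_argmax_loglik(model, lo=-5.0, hi=5.0, fine_step=1e-4):
    """Two-stage grid-search maximizer of the partial likelihood (oracle)."""
    coarse = np.arange(lo, hi, 1e-2)
    ll = np.array([model.loglik([b]) for b in coarse])
    b0 = coarse[int(np.argmax(ll))]
    fine = np.arange(b0 - 2e-2, b0 + 2e-2, fine_step)
    ll = np.array([model.loglik([b]) for b in fine])
    return fine[int(np.argmax(ll))]


@pytest.mark.parametrize(
    "time,event,x,beta,ties,expected",
    [
        ([1, 2], [1, 1], [1, 0], 0.0, "breslow", np.log(0.5)),
        ([1, 2], [1, 1], [1, 0], 0.0, "efron", np.log(0.5)),
        ([1, 2], [1, 1], [1, 0], 1.0, "breslow", np.log(np.e / (np.e + 1))),
        ([1, 1], [1, 1], [1, 0], 0.0, "breslow", 2 * np.log(0.5)),
    ],
)
def test_partial_loglik_hand_values(time, event, x, beta, ties, expected):
    data = SurvivalData(time, event, x)
    assert partial_loglik(data, [beta], ties=ties) == pytest.approx(expected, abs=1e-12)


def test_partial_loglik_rejects_nonfinite_beta():
    data = SurvivalData([1, 2], [1, 1], [1, 0])
    with pytest.raises(ValueError):
        partial_loglik(data, [np.nan])


@pytest.mark.parametrize("fixture", small_survival_fixtures())
@pytest.mark.parametrize("ties", ["breslow", "efron"])
def test_fit_matches_grid_search(fixture, ties):
    """On every small single-covariate dataset the Newton fit lands on the
    grid-search maximizer of the partial likelihood."""
    time, event, x = fixture
    model = CoxPH(time, event, np.asarray(x, float).reshape(-1, 1), ties=ties)
    res = model.fit()
    assert res.converged
    assert res.params[0] == pytest.approx(grid_argmax_loglik(model), abs=1e-3)


def test_symmetric_tied_pair_gives_beta_zero():
    res = CoxPH([1, 1], [1, 1], [[1], [0]]).fit()
    assert res.converged
    assert res.params[0] == pytest.approx(0.0, abs=1e-12)


def test_row_order_invariance():
    time, event, x = [3, 1, 4, 1, 5, 9, 2, 6], [1, 0, 1, 1, 0, 1, 1, 1], [1, 1, 0, 0, 1, 0, 1, 0]
    res = CoxPH(time, event, x).fit()
    perm = [4, 2, 0, 7, 5, 1, 6, 3]
    res_p = CoxPH(np.array(time)[perm], np.array(event)[perm], np.array(x, float)[perm]).fit()
    assert res.params[0] == pytest.approx(res_p.params[0], abs=1e-12)
    assert res.llf == pytest.approx(res_p.llf, abs=1e-12)


def test_breslow_equals_efron_without_ties():
    rng = np.random.default_rng(3)
    time, event, x = random_survival_data(rng, n=80, p=2)
    rb = CoxPH(time, event, x, ties="breslow").fit()
    re = CoxPH(time, event, x, ties="efron").fit()
    assert np.allclose(rb.params, re.params, atol=1e-10)
    assert rb.llf == pytest.approx(re.llf, abs=1e-10)


@pytest.mark.parametrize("tied", [False, True])
def test_matches_lifelines(tied):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    rng = np.random.default_rng(11)
    time, event, x = random_survival_data(rng, n=150, p=2, tied=tied)
    df = pd.DataFrame({"time": time, "event": event, "a": x[:, 0], "b": x[:, 1]})
    cf = lifelines.CoxPHFitter().fit(df, "time", "event")
    res = CoxPH.from_dataframe(df, ["a", "b"]).fit()
    assert np.allclose(res.params, cf.params_.to_numpy(), atol=1e-6)
    assert np.allclose(res.bse, cf.standard_errors_.to_numpy(), atol=1e-6)


def test_likelihood_ascent_path():
    """With step-halving the partial log-likelihood never decreases."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        time, event, x = random_survival_data(rng, n=40, p=2)
        res = CoxPH(time, event, x).fit()
        assert np.all(np.diff(res.ll_path) >= -1e-12)
        assert res.llf >= res.llnull - 1e-8


def test_wald_interval_arithmetic():
    res = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [[1], [0], [1], [0]]).fit()
    # hand-built results: check the exp(beta -/+ z se) construction
    res.params = np.array([np.log(2.0)])
    res.cov = np.array([[0.01]])
    hr, lo, hi = res.wald_interval(0, alpha=0.05)
    z = stats.norm.ppf(0.975)
    assert hr == pytest.approx(2.0)
    assert lo == pytest.approx(np.exp(np.log(2) - z * 0.1))
    assert hi == pytest.approx(np.exp(np.log(2) + z * 0.1))
    # beta = 0: interval symmetric about 1 on the log scale
    res.params = np.array([0.0])
    hr, lo, hi = res.wald_interval(0)
    assert hr == 1.0 and lo * hi == pytest.approx(1.0)
    # Bonferroni alpha/31 is wider than plain alpha
    _, lo_b, hi_b = res.wald_interval(0, alpha=0.05 / 31)
    assert lo_b < lo and hi_b > hi


def test_wald_interval_requires_convergence():
    res = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [[1], [0], [1], [0]]).fit()
    res.converged = False
    with pytest.raises(ConvergenceError):
        res.wald_interval(0)


def test_score_test_hand_example():
    """Two subjects, times (1,2), both events, x=(1,0): U=1/2, I=1/4, chi2=1."""
    data = SurvivalData([1, 2], [1, 1], [1, 0])
    assert score_test(data) == pytest.approx(1.0, abs=1e-12)


def test_score_test_mirrored_groups_is_zero():
    # two identical groups: mirrored times and events
    time = [1, 2, 3, 1, 2, 3]
    event = [1, 1, 0, 1, 1, 0]
    x = [0, 0, 0, 1, 1, 1]
    assert score_test(SurvivalData(time, event, x)) == pytest.approx(0.0, abs=1e-12)


def test_breslow_baseline_reduces_to_nelson_aalen():
    res = CoxPH([1, 2, 3], [1, 1, 1], [[0.1], [-0.1], [0.0]]).fit()
    res.params = np.array([0.0])  # force the null model
    base = breslow_baseline(res)
    assert np.allclose(base["jump"], [1 / 3, 1 / 2, 1.0])
    assert np.allclose(base["cumhazard"], np.cumsum([1 / 3, 1 / 2, 1.0]))


def test_breslow_baseline_single_event_jump():
    res = CoxPH([1, 2, 3, 4, 5], [0, 0, 1, 0, 0], [[1], [0], [0.5], [0], [1]]).fit()
    res.params = np.array([0.0])
    base = breslow_baseline(res)
    assert base["jump"].to_numpy() == pytest.approx([1 / 3])  # 3 subjects still at risk


def test_predicted_survival_is_valid_curve():
    rng = np.random.default_rng(21)
    for _ in range(5):
        time, event, x = random_survival_data(rng, n=50, p=2)
        res = CoxPH(time, event, x).fit()
        _, S = res.predict_survival(x[:10])
        assert np.all((S >= 0) & (S <= 1))
        assert np.all(np.diff(S, axis=1) <= 1e-12)


def test_score_residuals_sum_to_score():
    rng = np.random.default_rng(4)
    time, event, x = random_survival_data(rng, n=100, p=2)
    res = CoxPH(time, event, x, ties="breslow").fit()
    assert np.allclose(res.score_residuals().sum(axis=0), 0.0, atol=1e-7)


def test_parameter_recovery_mean_over_seeds():
    """Single covariate, true log-HR 0.5, n=2000: mean estimate over 200
    seeds within +/-0.05 of the truth."""
    rng = np.random.default_rng(2024)
    est = []
    for _ in range(200):
        x = rng.normal(size=(2000, 1))
        t = rng.exponential(1.0 / np.exp(0.5 * x[:, 0]))
        c = rng.exponential(2.0, 2000)
        res = CoxPH(np.minimum(t, c), (t <= c).astype(int), x).fit()
        est.append(res.params[0])
    assert np.mean(est) == pytest.approx(0.5, abs=0.05)


def test_constant_covariate_raises():
    with pytest.raises(DegenerateDesignError):
        CoxPH([1, 2, 3], [1, 1, 1], [[1], [1], [1]])


def test_monotone_likelihood_reported_not_raised():
    # complete separation: all events in the x=1 group, all before censoring
    time = [1, 2, 3, 10, 11, 12]
    event = [1, 1, 1, 0, 0, 0]
    x = [[1], [1], [1], [0], [0], [0]]
    res = CoxPH(time, event, x).fit()
    assert not res.converged
    assert "monotone" in res.message


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(time=[0, 1], event=[1, 1], X=[[1], [0]]), "time"),
        (dict(time=[1, 2], event=[1, 2], X=[[1], [0]]), "event"),
        (dict(time=[1, 2], event=[0, 0], X=[[1], [0]]), "event"),
        (dict(time=[1, 2], event=[1, 1], X=[[np.nan], [0]]), "missing"),
    ],
)
def test_survival_data_validation(kwargs, msg):
    with pytest.raises(SchemaError, match=msg):
        SurvivalData(**kwargs)
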