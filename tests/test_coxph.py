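"""Cox partial-likelihood engine: hand enumeration, finite differences,
an independent root-finder, and an established implementation."""

import numpy as np
import pytest
from scipy import optimize

from rsscox import (
    CoxPH,
    GeneratorParams,
    NoEventsError,
    NotConvergedError,
    SingularInformationError,
    SurvivalDataset,
    draw_units,
    fit_coxph,
    log_partial_likelihood,
    observed_information,
    parametric_loglik,
    score,
    wald,
)

from conftest import random_survival_dataset


def brute_log_partial_likelihood(data, beta):
    """Direct enumeration of the event-wise conditional probabilities."""
    beta = np.asarray(beta, dtype=float)
    ll = 0.0
    for i in range(data.n):
        if data.status[i] != 1:
            continue  # censored terms contribute probability 1
        num = np.exp(data.covariates[i] @ beta)
        den = sum(
            np.exp(data.covariates[h] @ beta)
            for h in range(data.n)
            if data.time[h] >= data.time[i]
        )
        ll += np.log(num / den)
    return ll


# ---------------------------------------------------------------------------
# dataset container


def test_dataset_validation():
    with pytest.raises(ValueError):
        SurvivalDataset(time=[0.0, 1.0], status=[1, 1], covariates=[[1.0], [0.0]],
                        names=("x",))
    with pytest.raises(ValueError):
        SurvivalDataset(time=[1.0, 2.0], status=[1, 2], covariates=[[1.0], [0.0]],
                        names=("x",))
    with pytest.raises(ValueError):
        SurvivalDataset(time=[1.0, 2.0], status=[1, 1], covariates=[[1.0], [0.0]],
                        names=("x", "y"))


# ---------------------------------------------------------------------------
# hand-enumerated three-record example


def test_loglik_hand_example(three_record_data):
    # risk sets {1,2,3}, {2,3}, {3} with x = (1, 0, 1), beta = ln 2:
    # ln(2/5) + ln(1/3) + ln(1) = ln(2/15)
    assert log_partial_likelihood(three_record_data, [np.log(2.0)]) == pytest.approx(
        np.log(2.0 / 15.0), abs=1e-12
    )


def test_loglik_at_zero_counts_risk_sets(three_record_data):
    assert log_partial_likelihood(three_record_data, [0.0]) == pytest.approx(
        -(np.log(3) + np.log(2) + np.log(1))
    )


def test_single_event_loglik_is_zero():
    data = SurvivalDataset(time=[1.0], status=[1], covariates=[[2.0]], names=("x",))
    for b in (-1.0, 0.0, 3.0):
        assert log_partial_likelihood(data, [b]) == pytest.approx(0.0)


def test_score_hand_example(three_record_data):
    # (1 - 2/3) + (0 - 1/2) + (1 - 1) = -1/6
    assert score(three_record_data, [0.0])[0] == pytest.approx(-1.0 / 6.0)


def test_information_hand_example(three_record_data):
    # weighted variances 2/9 + 1/4 + 0 = 17/36
    info = observed_information(three_record_data, [0.0])
    assert info[0, 0] == pytest.approx(17.0 / 36.0)


def test_fit_matches_bisection_root(three_record_data):
    root = optimize.bisect(
        lambda b: score(three_record_data, [b])[0], -5.0, 5.0, xtol=1e-12
    )
    fit = fit_coxph(three_record_data)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(root, abs=1e-6)
    assert abs(score(three_record_data, fit.beta)[0]) < 1e-8


# ---------------------------------------------------------------------------
# oracle equivalence and differential checks on random datasets


def test_brute_force_enumeration_all_censoring_patterns(rng):
    """Direct product of conditional probabilities equals the cumulative
    implementation for every censoring pattern at n <= 6."""
    for n in (2, 4, 6):
        t = rng.exponential(1.0, n)
        X = rng.standard_normal((n, 2))
        beta = rng.normal(size=2)
        for mask in range(1, 2**n):  # at least one event
            status = np.array([(mask >> i) & 1 for i in range(n)])
            data = SurvivalDataset(time=t, status=status, covariates=X,
                                   names=("a", "b"))
            assert log_partial_likelihood(data, beta) == pytest.approx(
                brute_log_partial_likelihood(data, beta), abs=1e-10
            )


def test_score_matches_finite_differences(rng):
    h = 1e-5
    for _ in range(20):
        data = random_survival_dataset(rng)
        beta = rng.normal(scale=0.5, size=2)
        sc = score(data, beta)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (
                log_partial_likelihood(data, beta + e)
                - log_partial_likelihood(data, beta - e)
            ) / (2 * h)
            assert sc[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_information_matches_finite_difference_hessian(rng):
    h = 1e-4
    for _ in range(10):
        data = random_survival_dataset(rng)
        beta = rng.normal(scale=0.5, size=2)
        info = observed_information(data, beta)
        for j in range(2):
            for k in range(2):
                ej, ek = np.zeros(2), np.zeros(2)
                ej[j], ek[k] = h, h
                fd = -(
                    log_partial_likelihood(data, beta + ej + ek)
                    - log_partial_likelihood(data, beta + ej - ek)
                    - log_partial_likelihood(data, beta - ej + ek)
                    + log_partial_likelihood(data, beta - ej - ek)
                ) / (4 * h * h)
                assert info[j, k] == pytest.approx(fd, rel=1e-5, abs=1e-6)


def test_information_symmetric_psd(rng):
    for _ in range(10):
        data = random_survival_dataset(rng, n=40, p=3)
        beta = rng.normal(scale=1.0, size=3)
        info = observed_information(data, beta)
        assert np.allclose(info, info.T)
        assert np.linalg.eigvalsh(info).min() >= -1e-10


def test_score_vanishes_at_fit(rng):
    for _ in range(5):
        data = random_survival_dataset(rng, n=80)
        fit = fit_coxph(data)
        assert fit.converged
        assert np.max(np.abs(score(data, fit.beta))) < 1e-8
        assert fit.n_events == data.n_events


def test_matches_established_implementation(rng):
    """Estimates and standard errors agree with lifelines (Breslow-
    equivalent on tie-free data) to 1e-4 on random datasets."""
    import pandas as pd
    from lifelines import CoxPHFitter

    for _ in range(50):
        data = random_survival_dataset(rng, n=100, p=2)
        fit = fit_coxph(data)
        df = pd.DataFrame(
            {"t": data.time, "e": data.status,
             "v0": data.covariates[:, 0], "v1": data.covariates[:, 1]}
        )
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(
            fit.beta, ref.params_[["v0", "v1"]].to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(
            fit.se, ref.standard_errors_[["v0", "v1"]].to_numpy(), atol=1e-4
        )


def test_invariance_under_monotone_time_transform_and_permutation(rng):
    data = random_survival_dataset(rng, n=60)
    fit = fit_coxph(data)
    warped = SurvivalDataset(
        time=np.exp(data.time), status=data.status, covariates=data.covariates,
        names=data.names,
    )
    np.testing.assert_allclose(fit_coxph(warped).beta, fit.beta, atol=1e-10)
    perm = rng.permutation(data.n)
    shuffled = SurvivalDataset(
        time=data.time[perm], status=data.status[perm],
        covariates=data.covariates[perm], names=data.names,
    )
    np.testing.assert_allclose(fit_coxph(shuffled).beta, fit.beta, atol=1e-10)


# ---------------------------------------------------------------------------
# degenerate inputs


def test_no_events_raises():
    data = SurvivalDataset(time=[1.0, 2.0], status=[0, 0],
                           covariates=[[1.0], [0.0]], names=("x",))
    with pytest.raises(NoEventsError):
        fit_coxph(data)


def test_constant_covariate_raises_singularity(rng):
    data = SurvivalDataset(
        time=rng.exponential(1, 20), status=np.ones(20, dtype=int),
        covariates=np.ones((20, 1)), names=("x",),
    )
    with pytest.raises(SingularInformationError):
        fit_coxph(data)


def test_nonfinite_beta_rejected(three_record_data):
    with pytest.raises(ValueError):
        log_partial_likelihood(three_record_data, [np.inf])


def test_extreme_beta_does_not_overflow(three_record_data):
    assert np.isfinite(log_partial_likelihood(three_record_data, [500.0]))
    assert np.isfinite(log_partial_likelihood(three_record_data, [-500.0]))


# ---------------------------------------------------------------------------
# Wald machinery


def test_wald_null_coefficient(rng):
    data = random_survival_dataset(rng, n=200)
    fit = fit_coxph(data)
    # build a synthetic fit record at beta=0 to check the identities
    from rsscox.coxph import CoxFit

    fit0 = CoxFit(beta=np.array([0.0]), information=np.array([[4.0]]),
                  se=np.array([0.5]), loglik=0.0, n_events=10, converged=True,
                  n_iter=1, names=("x",))
    w = wald(fit0, 0)
    assert w.hr == 1.0
    assert not w.reject
    assert w.ci_low * w.ci_high == pytest.approx(1.0)  # symmetric on log scale


def test_wald_interval_arithmetic():
    from rsscox.coxph import CoxFit

    fit = CoxFit(beta=np.array([0.5]), information=np.array([[100.0]]),
                 se=np.array([0.1]), loglik=0.0, n_events=10, converged=True,
                 n_iter=1, names=("x",))
    w = wald(fit, 0, level=0.95)
    assert w.ci_low == pytest.approx(np.exp(0.5 - 1.959964 * 0.1), abs=1e-4)
    assert w.ci_high == pytest.approx(np.exp(0.5 + 1.959964 * 0.1), abs=1e-4)
    assert (w.ci_low, w.ci_high) == pytest.approx((1.3552, 2.0057), abs=1e-3)
    assert w.ci_length == pytest.approx(w.ci_high - w.ci_low)
    assert w.reject


def test_wald_refuses_nonconvergent():
    from rsscox.coxph import CoxFit

    bad = CoxFit(beta=np.array([0.5]), information=np.array([[1.0]]),
                 se=np.array([1.0]), loglik=0.0, n_events=10, converged=False,
                 n_iter=50, names=("x",))
    with pytest.raises(NotConvergedError):
        wald(bad, 0)


# ---------------------------------------------------------------------------
# exponential full likelihood


def test_parametric_loglik_single_records():
    censored = SurvivalDataset(time=[1.0], status=[0], covariates=[[0.0]], names=("x",))
    event = SurvivalDataset(time=[1.0], status=[1], covariates=[[0.0]], names=("x",))
    assert parametric_loglik(censored, 1.0) == pytest.approx(-1.0)  # log S(1)
    assert parametric_loglik(event, 1.0) == pytest.approx(-1.0)  # log f(1)
    with pytest.raises(ValueError):
        parametric_loglik(event, 0.0)


def test_parametric_mle_closed_form(rng):
    for _ in range(10):
        data = random_survival_dataset(rng, n=50)
        closed = data.n_events / data.time.sum()
        res = optimize.minimize_scalar(
            lambda lam: -parametric_loglik(data, lam),
            bounds=(1e-8, 100.0), method="bounded",
            options={"xatol": 1e-12},
        )
        # derivative-free maximizers locate x only to ~sqrt(eps); the
        # likelihood-scale check below is the sharp one
        assert res.x == pytest.approx(closed, abs=1e-7)
        assert parametric_loglik(data, closed) >= parametric_loglik(data, res.x) - 1e-10


# ---------------------------------------------------------------------------
# estimator interface


def test_estimator_interface(rng):
    from sklearn.base import clone

    params = GeneratorParams(beta1=0.2, beta2=0.5)
    df = draw_units(params, 300, rng)
    X = df[["x", "y"]].to_numpy()
    y = np.empty(len(df), dtype=[("event", bool), ("time", float)])
    y["event"] = df["status"].to_numpy().astype(bool)
    y["time"] = df["time"].to_numpy()

    est = CoxPH(tol=1e-10)
    assert clone(est).get_params() == est.get_params()
    est.fit(X, y)
    assert est.converged_
    assert est.coef_.shape == (2,)
    assert est.se_.shape == (2,)
    assert est.n_events_ == df["status"].sum()
    # agrees with the functional API
    data = SurvivalDataset.from_dataframe(df)
    np.testing.assert_allclose(est.coef_, fit_coxph(data).beta, atol=1e-10)
    # predict returns the linear predictor
    np.testing.assert_allclose(est.predict(X[:5]), X[:5] @ est.coef_)
    w = est.wald_test(0)
    assert w.hr == pytest.approx(np.exp(est.coef_[0]))


def test_estimator_accepts_two_column_y(rng):
    df = draw_units(GeneratorParams(), 200, rng)
    est = CoxPH().fit(df[["x", "y"]].to_numpy(),
                      df[["time", "status"]].to_numpy())
    assert est.converged_


def test_consistency_of_risk_coefficient_under_srs():
    """The mean risk-factor estimate approaches the truth (0.5) as the
    SRS sample grows; the large-sample deviation is below the small-sample
    one and small in absolute terms (finite-sample bias ~ 1/n, so the
    midpoint is dominated by Monte-Carlo noise and only the endpoints are
    compared)."""
    params = GeneratorParams(beta1=0.2, beta2=0.5)
    rng = np.random.default_rng(2718)
    deviations = {}
    for n in (100, 400, 1600):
        betas = []
        for _ in range(500):
            df = draw_units(params, n, rng)
            data = SurvivalDataset.from_dataframe(df)
            betas.append(fit_coxph(data).beta[0])
        deviations[n] = abs(np.mean(betas) - 0.5)
    assert deviations[1600] < deviations[100]
    assert deviations[1600] < 0.01
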