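import numpy as np
import pandas as pd
import pytest
import lifelines

import margcrisk as mc
from margcrisk.estimator import _log_pseudolik, _Workspace


def test_fractional_event_invariants(sim_small, sim_fit):
    data, _ = sim_small
    frac = sim_fit.frac
    w = frac.weight_r
    cens = data.delta == 0
    np.testing.assert_array_equal(w[cens], 0.0)
    fails = data.delta == 1
    np.testing.assert_allclose(w[fails].sum(axis=1), 1.0, atol=1e-12)
    obs = fails & (data.r == 1)
    np.testing.assert_array_equal(w[obs, data.cause[obs] - 1], 1.0)
    # bookkeeping: total cause-1 mass = observed cause-1 count + sum of pi_1 over missing
    miss = fails & (data.r == 0)
    pi1 = mc.predict_pi(sim_fit.gamma_fit)[:, 0]
    expected = (data.cause == 1).sum() + pi1[miss].sum()
    assert w[:, 0].sum() == pytest.approx(expected, rel=1e-12)


def test_risk_average_reduces_to_simple_mean_and_single_subject(toy_dataset):
    data = toy_dataset
    # at t just after 0, all at risk; equal cluster sizes not required at beta=0
    # for the acm (unweighted) mode, where E_n is the plain mean
    S0, E = mc.risk_average(data, np.zeros(2), 1e-9, mode="acm")
    np.testing.assert_allclose(E, data.Z.mean(axis=0), atol=1e-12)
    assert S0 == pytest.approx(data.n_subjects)
    # only the last survivor at risk: its own covariates regardless of beta
    tmax = data.time.max()
    _, E1 = mc.risk_average(data, np.array([2.3, -1.1]), tmax, mode="tcm")
    np.testing.assert_allclose(E1, data.Z[np.argmax(data.time)], atol=1e-12)


def test_risk_average_matches_brute_force_sum(sim_small, sim_fit):
    data, _ = sim_small
    beta = np.array([0.4, -0.3])
    t = 0.8
    M = data.cluster_sizes
    v = 1.0 / M[data.cluster_codes]
    at_risk = data.time >= t
    w = v * np.exp(data.Z @ beta) * at_risk
    S0, E = mc.risk_average(data, beta, t, mode="tcm")
    assert S0 == pytest.approx(w.sum(), rel=1e-12)
    np.testing.assert_allclose(E, (w[:, None] * data.Z).sum(axis=0) / w.sum(), rtol=1e-12)


def test_pseudoscore_zero_without_failures():
    df = pd.DataFrame(
        {"cluster": [0, 1], "time": [1.0, 2.0], "delta": 0, "cause": 0, "r": 1, "z1": [0.1, -0.2]}
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    fr = mc.FractionalEvents(np.zeros((2, 1)))
    np.testing.assert_array_equal(mc.pseudoscore(data, fr, np.zeros(1), 1), 0.0)


def test_pseudoscore_vanishes_at_fitted_beta(sim_fit):
    for l in (1, 2):
        G = mc.pseudoscore(sim_fit.data, sim_fit.frac, sim_fit.beta[l - 1], l)
        assert np.max(np.abs(G)) < 1e-9


def test_fit_beta_matches_grid_search_on_tiny_data():
    """1-d brute-force maximizer of the weighted log pseudolikelihood."""
    df = pd.DataFrame(
        {
            "cluster": [0, 0, 1, 1],
            "time": [0.5, 1.5, 1.0, 2.0],
            "delta": [1, 0, 1, 1],
            "cause": [1, 0, 1, 1],
            "r": 1,
            "z1": [1.0, 0.0, 0.0, 1.0],
        }
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    frac = mc.FractionalEvents(((data.delta == 1).astype(float))[:, None])
    beta, _ = mc.fit_beta(data, frac, 1)
    ws = _Workspace(data, frac, "tcm")
    grid = np.linspace(beta[0] - 0.5, beta[0] + 0.5, 20001)
    lls = [_log_pseudolik(ws, 1, np.array([b])) for b in grid]
    assert beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)


def test_cause_specific_cox_reduction(singleton_data, singleton_fit):
    """All M_i = 1, no missing: the estimator is cause-specific Cox regression."""
    df = singleton_data.df
    for l in (1, 2):
        dfl = df.copy()
        dfl["ev"] = (df["cause"] == l).astype(int)
        cph = lifelines.CoxPHFitter().fit(dfl[["time", "ev", "z1", "z2"]], "time", "ev")
        np.testing.assert_allclose(
            singleton_fit.beta[l - 1], cph.params_.values, atol=2e-6
        )


def test_weighted_cox_equivalence_with_fractional_events(sim_small, sim_fit):
    """beta_hat equals a Cox fit with case weights 1/M_i and fractional
    events expanded into (event, censored) row pairs with split weights."""
    data, _ = sim_small
    l = 1
    v = 1.0 / data.cluster_sizes[data.cluster_codes]
    r1 = sim_fit.frac.weight_r[:, l - 1]
    rows = []
    for i in range(data.n_subjects):
        if data.delta[i] == 1 and 0 < r1[i]:
            rows.append((data.time[i], 1, v[i] * r1[i], data.Z[i, 0], data.Z[i, 1]))
            if r1[i] < 1:
                rows.append((data.time[i], 0, v[i] * (1 - r1[i]), data.Z[i, 0], data.Z[i, 1]))
        else:
            rows.append((data.time[i], 0, v[i], data.Z[i, 0], data.Z[i, 1]))
    dfw = pd.DataFrame(rows, columns=["time", "ev", "w", "z1", "z2"])
    cph = lifelines.CoxPHFitter().fit(dfw, "time", "ev", weights_col="w", robust=True)
    np.testing.assert_allclose(sim_fit.beta[l - 1], cph.params_.values, atol=5e-6)


def test_breslow_hand_computed_jump():
    """Two clusters (sizes 1, 2), one failure in the size-2 cluster at t=1
    with all three at risk: jump = (1/2) / (1 + (1/2)*2) = 0.25 at beta=0."""
    df = pd.DataFrame(
        {
            "cluster": [0, 1, 1],
            "time": [2.0, 1.0, 3.0],
            "delta": [0, 1, 0],
            "cause": [0, 1, 0],
            "r": 1,
            "z1": [0.0, 0.0, 0.0],
        }
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    frac = mc.FractionalEvents((data.delta == 1).astype(float)[:, None])
    lam = mc.breslow(data, frac, np.zeros(1), 1)
    np.testing.assert_allclose(lam.jump_times, [1.0])
    assert lam.jump_sizes[0] == pytest.approx(0.25)


def test_breslow_reduces_to_nelson_aalen(singleton_data):
    """beta = 0, singletons, no missing: Breslow = Nelson-Aalen."""
    data = singleton_data
    fr = mc.FractionalEvents((data.delta == 1).astype(float)[:, None])
    one_cause = mc.ClusteredDataset(
        data.df.assign(cause=data.delta), z_cols=("z1", "z2"), n_causes=1
    )
    lam = mc.breslow(one_cause, fr, np.zeros(2), 1)
    naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
        data.time, event_observed=data.delta
    )
    t_check = np.quantile(data.time[data.delta == 1], [0.25, 0.5, 0.75])
    ours = lam(t_check)
    theirs = np.interp(t_check, naf.cumulative_hazard_.index.values,
                       naf.cumulative_hazard_.iloc[:, 0].values)
    np.testing.assert_allclose(ours, theirs, rtol=1e-10)


def test_cif_single_jump_and_mass_conservation(sim_fit):
    # total incidence stays below 1 over the horizon of scientific interest;
    # the exponential-form plug-in is not exactly mass-conserving in the far
    # tail where risk sets are tiny and Breslow jumps are large
    F = mc.cif(sim_fit, np.zeros(2))
    total = F[0](2.0) + F[1](2.0)
    assert 0 < total <= 1.0
    # nondecreasing, zero at 0
    for f in F:
        assert f(0.0) == 0.0
        assert np.all(np.diff(f.values) >= -1e-15)
    with pytest.raises(ValueError):
        mc.cif(sim_fit, np.zeros(3))


def test_cif_uses_left_limit_of_survival_factor():
    """k=1, single jump dLambda = 0.3 at t=1: F(1) = exp(0) * 0.3."""
    df = pd.DataFrame(
        {"cluster": [0, 1, 2], "time": [1.0, 1.2, 1.4], "delta": [1, 0, 0],
         "cause": [1, 0, 0], "r": 1, "z1": 0.0}
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    fr = mc.FractionalEvents((data.delta == 1).astype(float)[:, None])
    gf = None
    fit = mc.MppleFit(
        data=data, gamma_fit=gf, frac=fr, mode="tcm",
        beta=[np.zeros(1)], info=[np.eye(1)],
        Lambda=[mc.StepFunction([1.0], [0.3])],
    )
    F = mc.cif(fit, np.zeros(1))[0]
    assert F(1.0) == pytest.approx(0.3)


def test_acm_and_tcm_agree_iff_cluster_sizes_equal(sim_small):
    data, _ = sim_small
    spec = mc.PiModelSpec(features=("time", "z1", "z2"))
    tcm = mc.fit_mpple(data, pi_spec=spec, mode="tcm")
    acm = mc.fit_mpple(data, pi_spec=spec, mode="acm")
    assert np.abs(np.concatenate(tcm.beta) - np.concatenate(acm.beta)).max() > 1e-4
    # equal cluster sizes: identical estimates (truncate every cluster to 20)
    dfe = data.df.groupby("cluster", sort=False).head(20)
    equal = mc.ClusteredDataset(dfe, z_cols=("z1", "z2"), n_causes=2)
    t2 = mc.fit_mpple(equal, pi_spec=spec, mode="tcm")
    a2 = mc.fit_mpple(equal, pi_spec=spec, mode="acm")
    np.testing.assert_allclose(np.concatenate(t2.beta), np.concatenate(a2.beta), atol=1e-8)
    for l in (1, 2):
        np.testing.assert_allclose(t2.Lambda[l - 1].values, a2.Lambda[l - 1].values, atol=1e-8)


def test_marginal_parameter_recovery_scenario1():
    """One larger scenario-1 fit recovers the attenuated marginal coefficient
    alpha*beta = -0.25 and Lambda'(t) = sqrt(t) within sampling error."""
    cfg = mc.ScenarioConfig(scenario=1, n_clusters=300, seed=11)
    data, _ = mc.generate(cfg)
    fit = mc.fit_mpple(data, pi_spec=mc.PiModelSpec(features=("time", "z1", "z2")))
    assert fit.beta[0][0] == pytest.approx(-0.25, abs=0.04)
    assert fit.beta[0][1] == pytest.approx(0.0, abs=0.08)
    assert fit.Lambda[0](1.0) == pytest.approx(1.0, abs=0.12)
    assert fit.Lambda[0](0.25) == pytest.approx(0.5, abs=0.08)
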