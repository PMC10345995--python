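import numpy as np
import pandas as pd
import pytest
import lifelines

import margcrisk as mc


@pytest.fixture(scope="module")
def singleton_infl(singleton_fit):
    return mc.InfluenceSet(singleton_fit)


@pytest.fixture(scope="module")
def sim_infl(sim_fit):
    return mc.InfluenceSet(sim_fit)


def test_robust_cox_se_oracle(singleton_data, singleton_fit, singleton_infl):
    """All M_i = 1, no missing, independent data: sandwich SEs equal the
    robust (clustered) Cox SEs from an established implementation."""
    df = singleton_data.df
    for l in (1, 2):
        dfl = df.copy()
        dfl["ev"] = (df["cause"] == l).astype(int)
        cph = lifelines.CoxPHFitter().fit(dfl[["time", "ev", "z1", "z2"]], "time", "ev", robust=True)
        np.testing.assert_allclose(
            singleton_infl.beta_se(l), cph.standard_errors_.values, atol=5e-5
        )


def test_no_missing_influence_has_no_gamma_correction(singleton_fit, singleton_infl):
    """Without missing causes the gamma propagation term vanishes, so the
    beta influence is exactly the information-standardized score residual."""
    infl = singleton_infl.beta_influence(1)
    # cluster influences average to ~0 (score equation at the solution)
    assert np.max(np.abs(infl.mean(axis=0))) < 1e-8
    # Sigma is symmetric PSD
    S = singleton_infl.Sigma(1)
    np.testing.assert_allclose(S, S.T)
    assert np.all(np.linalg.eigvalsh(S) >= -1e-12)


def test_influence_curves_vanish_at_time_zero(sim_infl):
    _, A = sim_infl.lambda_influence(1, times=[0.0])
    np.testing.assert_array_equal(A, 0.0)
    assert sim_infl.cumhaz_se(1, [0.0])[0] == 0.0
    _, seF = sim_infl.cif_se(1, (0.0, 0.0), times=[0.0])
    assert seF[0] == 0.0
    with pytest.raises(ValueError, match="outside"):
        sim_infl.lambda_influence(1, times=[sim_infl.fit.data.tau + 1.0])


def test_nelson_aalen_variance_oracle():
    """k=1, singletons, near-null covariate effect: the cumulative-hazard
    variance tracks the Nelson-Aalen variance estimator."""
    rng = np.random.default_rng(21)
    N = 2000
    z = rng.normal(0, 1, N)
    T = rng.exponential(1.0, N)
    U = rng.exponential(2.0, N)
    X = np.minimum(T, U)
    delta = (T <= U).astype(int)
    df = pd.DataFrame(
        {"cluster": np.arange(N), "time": X, "delta": delta, "cause": delta, "r": 1, "z1": z}
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    fit = mc.fit_mpple(data)
    infl = mc.InfluenceSet(fit)
    tgrid = np.array([0.5, 1.0, 1.5])
    ours = infl.cumhaz_se(1, tgrid)
    # textbook Nelson-Aalen variance: sum_{u <= t} dN(u) / Y(u)^2
    ev_times = np.sort(X[delta == 1])
    Y = N - np.searchsorted(np.sort(X), ev_times, side="left")
    var_at = np.cumsum(1.0 / Y.astype(float) ** 2)
    theirs = np.sqrt(var_at[np.searchsorted(ev_times, tgrid, side="right") - 1])
    np.testing.assert_allclose(ours, theirs, rtol=0.05)


def test_single_cause_cif_delta_method_identity():
    """k=1: var{F_hat(t)} ~ e^{-2 Lambda} var{Lambda_hat(t)} (delta method
    on F = 1 - e^{-Lambda}), up to discretization of the product integral."""
    rng = np.random.default_rng(22)
    N = 1500
    z = rng.normal(0, 1, N)
    T = rng.exponential(1.0, N) / np.exp(0.3 * z)
    U = rng.exponential(1.5, N)
    X = np.minimum(T, U)
    delta = (T <= U).astype(int)
    df = pd.DataFrame(
        {"cluster": np.arange(N), "time": X, "delta": delta, "cause": delta, "r": 1, "z1": z}
    )
    data = mc.ClusteredDataset(df, z_cols=("z1",), n_causes=1)
    fit = mc.fit_mpple(data)
    infl = mc.InfluenceSet(fit)
    tgrid = np.array([0.5, 1.0])
    se_L = infl.cumhaz_se(1, tgrid)
    _, se_F = infl.cif_se(1, (0.0,), times=tgrid)
    lam = fit.Lambda[0](tgrid)
    np.testing.assert_allclose(se_F, np.exp(-lam) * se_L, rtol=0.03)


def test_band_contains_pointwise_ci_and_is_seed_reproducible(sim_fit, sim_infl):
    rng = np.random.default_rng(33)
    band = mc.cumhaz_band(sim_fit, 1, infl=sim_infl, weight="ep", n_draws=400, rng=rng)
    assert np.all(band.band_lower <= band.point_lower + 1e-12)
    assert np.all(band.band_upper >= band.point_upper - 1e-12)
    assert np.all(band.band_lower >= 0)
    assert band.c_alpha >= 1.9
    b2 = mc.cumhaz_band(sim_fit, 1, infl=sim_infl, weight="ep", n_draws=400,
                        rng=np.random.default_rng(33))
    np.testing.assert_array_equal(band.band_lower, b2.band_lower)
    assert band.covers(band.estimate)


def test_cif_band_limits_inside_unit_interval(sim_fit, sim_infl):
    band = mc.cif_band(sim_fit, 1, (0.0, 0.0), infl=sim_infl, weight="hw",
                       n_draws=400, rng=1)
    assert np.all((band.band_lower >= 0) & (band.band_upper <= 1))
    assert np.all(band.band_lower <= band.estimate)
    assert np.all(band.estimate <= band.band_upper)
    meta = band.metadata()
    assert meta["transform"] == "cloglog" and meta["weight"] == "hw"


def test_degenerate_single_point_domain_gives_normal_quantile(sim_fit, sim_infl):
    """Sup over a single time point: c_alpha is the 97.5% quantile of |N(0,1)|."""
    u, A = sim_infl.lambda_influence(1)
    t_mid = u[len(u) // 2]
    band = mc.multiplier_band(
        A, u, sim_fit.Lambda[0].values, sim_fit.data.n_clusters,
        transform="log", weight="ep", n_draws=4000, domain=(t_mid, t_mid),
        rng=np.random.default_rng(7),
    )
    assert band.c_alpha == pytest.approx(1.96, abs=0.08)


def test_c_alpha_monotone_in_alpha(sim_fit, sim_infl):
    u, A = sim_infl.lambda_influence(1)
    est = sim_fit.Lambda[0].values
    n = sim_fit.data.n_clusters
    kw = dict(transform="log", weight="ep", n_draws=500)
    c05 = mc.multiplier_band(A, u, est, n, alpha=0.05, rng=np.random.default_rng(3), **kw).c_alpha
    c10 = mc.multiplier_band(A, u, est, n, alpha=0.10, rng=np.random.default_rng(3), **kw).c_alpha
    assert c05 >= c10


def test_band_rejects_too_few_draws(sim_fit, sim_infl):
    with pytest.raises(ValueError, match="at least 100"):
        mc.cumhaz_band(sim_fit, 1, infl=sim_infl, n_draws=50)
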