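"""Variance estimation and simultaneous confidence bands for the two-step
partial pseudolikelihood estimator.

All quantities rest on cluster-level empirical influence functions.  Writing
the estimator as a two-stage M-estimator -- step 1 solves the weighted
cause-model score for gamma, step 2 solves the partial pseudoscore
G_{n,l}(beta; gamma_hat) = 0 -- a Taylor expansion gives

    beta_hat_l - beta_0l  ~  n^{-1} sum_i  H_l^{-1} { g_il + D_l I_g^{-1} u_i },

where g_il is cluster i's (1/M_i-weighted) pseudoscore residual, u_i its
cluster-aggregated step-1 score, H_l the pseudoscore information, I_g the
step-1 information, and D_l = dG_{n,l}/dgamma' picks up the propagation of
the gamma estimate through the fractional event weights.  The analogous
expansions for the Breslow estimator and the cumulative incidence function
(functional delta method through the plug-in CIF formula) give per-cluster
influence curves over the event-time grid.  Cluster-level aggregation makes
the resulting sandwich variances valid under arbitrary within-cluster
dependence and, through the 1/M_i weights, under informative cluster size.

Simultaneous bands use the multiplier (wild) bootstrap: perturbing the
influence curves with i.i.d. standard normal cluster multipliers xi_i
reproduces the limiting Gaussian process, and the band critical value is the
1-alpha quantile of the sup of the weighted, transformed perturbed process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import MppleFit, _Workspace

__all__ = ["InfluenceSet", "BandResult", "multiplier_band", "cumhaz_band", "cif_band"]

_Z975 = stats.norm.ppf(0.975)


class InfluenceSet:
    """Cluster-level empirical influence functions of a converged fit.

    Conventions: every influence is on the scale
    ``estimate - truth ~ n^{-1} sum_i infl_i``, so the limiting variance of
    sqrt(n)(estimate - truth) is the mean of squared cluster influences and
    the standard error divides once more by sqrt(n).
    """

    def __init__(self, fit: MppleFit):
        self.fit = fit
        data = fit.data
        self.n = data.n_clusters
        self.ws = _Workspace(data, fit.frac, fit.mode)
        gf = fit.gamma_fit
        # step-1 pieces: cluster-aggregated scores (always 1/M-weighted, as
        # gamma itself is fitted with 1/M weights in both modes); absent when
        # no cause model was needed (complete data)
        if gf is None:
            self.u_gamma = np.zeros((self.n, 0))
            self.gamma_infl = np.zeros((self.n, 0))
        else:
            M = data.cluster_sizes
            v_tcm = 1.0 / M[data.cluster_codes]
            dg = gf.score_contrib.shape[1]
            u_cl = np.zeros((self.n, dg))
            np.add.at(u_cl, data.cluster_codes, v_tcm[:, None] * gf.score_contrib)
            self.u_gamma = u_cl  # (n, dg)
            self.gamma_infl = np.linalg.solve(gf.info_bar, u_cl.T).T  # I_g^{-1} u_i
        self._beta_cache: dict[int, np.ndarray] = {}
        self._lambda_cache: dict[int, tuple] = {}

    # ------------------------------------------------------------------ beta
    def beta_influence(self, l: int) -> np.ndarray:
        """Cluster influence vectors for beta_hat_l; shape (n, p)."""
        if l in self._beta_cache:
            return self._beta_cache[l]
        ws, fit = self.ws, self.fit
        beta = fit.beta[l - 1]
        H = fit.info[l - 1]
        u, ev_idx, u_inv = ws.event_grid(l)
        S0, S1, _ = ws.risk_sums(beta, u)
        E = S1 / S0[:, None]
        lam = fit.Lambda[l - 1]
        # cumulative Breslow sums at each subject's own time (jumps at u <= X)
        cum0 = np.concatenate([[0.0], np.cumsum(lam.jump_sizes)])
        cumE = np.concatenate([np.zeros((1, ws.p)), np.cumsum(E * lam.jump_sizes[:, None], axis=0)])
        pos = np.searchsorted(u, ws.x, side="right")
        exb = np.exp(ws.Z @ beta)
        # martingale-type score residuals:  r dN (Z - E) - Y e^{bZ} int (Z - E) dLambda
        sr = -exb[:, None] * (ws.Z * cum0[pos, None] - cumE[pos])
        ev_r = ws.r[ev_idx, l - 1]
        np.add.at(sr, ev_idx, ev_r[:, None] * (ws.Z[ev_idx] - E[u_inv]))
        g_cl = np.zeros((self.n, ws.p))
        np.add.at(g_cl, ws.cluster, ws.v[:, None] * sr)
        # gamma propagation: D_l = dG/dgamma' over missing-cause failures
        miss = ws.r_obs[ev_idx] == 0
        D = np.zeros((ws.p, self.u_gamma.shape[1]))
        if miss.any():
            dpi = self.fit.gamma_fit.dpi_dgamma(l)[self.ws.order][ev_idx[miss]]
            resid = ws.Z[ev_idx[miss]] - E[u_inv[miss]]
            D = (ws.v[ev_idx[miss], None] * resid).T @ dpi / self.n
        infl = np.linalg.solve(H, (g_cl + self.gamma_infl @ D.T).T).T
        self._beta_cache[l] = infl
        return infl

    def Sigma(self, l: int) -> np.ndarray:
        """Limit covariance of sqrt(n)(beta_hat_l - beta_0l)."""
        infl = self.beta_influence(l)
        return infl.T @ infl / self.n

    def beta_cov(self, l: int) -> np.ndarray:
        """Sandwich covariance matrix of beta_hat_l."""
        return self.Sigma(l) / self.n

    def beta_se(self, l: int) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov(l)))

    # ---------------------------------------------------------------- Lambda
    def lambda_jump_influence(self, l: int):
        """Per-jump cluster influences of the Breslow estimator.

        Returns ``(u, a)`` with ``u`` the cause-l jump times and ``a`` of
        shape (n, len(u)); cumulating ``a`` over time gives the influence of
        Lambda_hat_l(t).
        """
        if l in self._lambda_cache:
            return self._lambda_cache[l]
        ws, fit = self.ws, self.fit
        beta = fit.beta[l - 1]
        lam = fit.Lambda[l - 1]
        u = lam.jump_times
        D_t = len(u)
        u_all, ev_idx, u_inv = ws.event_grid(l)
        assert np.array_equal(u_all, u)
        S0, S1, _ = ws.risk_sums(beta, u)
        S0n = S0 / self.n
        E = S1 / S0[:, None]
        dlam = lam.jump_sizes
        # event-mass and risk-profile matrices by cluster
        C = np.zeros((self.n, D_t))
        np.add.at(C, (ws.cluster[ev_idx], u_inv), ws.v[ev_idx] * ws.r[ev_idx, l - 1])
        w_risk = ws.v * np.exp(ws.Z @ beta)
        last = np.searchsorted(u, ws.x, side="right") - 1  # at risk for grid slots <= last
        RS = np.zeros((self.n, D_t))
        keep = last >= 0
        np.add.at(RS, (ws.cluster[keep], last[keep]), w_risk[keep])
        RS = np.cumsum(RS[:, ::-1], axis=1)[:, ::-1]
        a = (C - dlam[None, :] * RS) / S0n[None, :]
        # beta propagation: d dLambda_d / d beta' = -dLambda_d E_d
        binfl = self.beta_influence(l)
        a -= binfl @ (E * dlam[:, None]).T
        # gamma propagation through the fractional event masses
        miss = ws.r_obs[ev_idx] == 0
        if miss.any():
            dpi = self.fit.gamma_fit.dpi_dgamma(l)[ws.order][ev_idx[miss]]
            dC = np.zeros((D_t, dpi.shape[1]))
            np.add.at(dC, u_inv[miss], ws.v[ev_idx[miss], None] * dpi)
            dC /= S0[:, None]
            a += self.gamma_infl @ dC.T
        self._lambda_cache[l] = (u, a)
        return u, a

    def lambda_influence(self, l: int, times=None):
        """Cumulative cluster influence curves of Lambda_hat_l on a grid."""
        u, a = self.lambda_jump_influence(l)
        A = np.cumsum(a, axis=1)
        if times is None:
            return u, A
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() > self.fit.data.tau):
            raise ValueError("time grid outside [0, tau]")
        pos = np.searchsorted(u, times, side="right")
        out = np.zeros((self.n, len(times)))
        nz = pos > 0
        out[:, nz] = A[:, pos[nz] - 1]
        return times, out

    def cumhaz_se(self, l: int, times):
        """Pointwise standard errors of Lambda_hat_l(t)."""
        _, A = self.lambda_influence(l, times)
        return np.sqrt((A**2).mean(axis=0) / self.n)

    # ------------------------------------------------------------------- CIF
    def cif_influence(self, l: int, z0):
        """Cluster influence curves of F_hat_l(t; z0) on the pooled event grid.

        Assembled from the beta- and Lambda-influences of *all* causes via
        the functional delta method applied to the plug-in CIF formula.
        Returns ``(grid, cum_infl, F_values)``.
        """
        fit = self.fit
        z0 = np.asarray(z0, dtype=float)
        k = fit.n_causes
        lam_z = [fit.cumhaz(m, z0) for m in range(1, k + 1)]
        ez = [float(np.exp(fit.beta[m - 1] @ z0)) for m in range(1, k + 1)]
        # the CIF (and its influence) jumps only at cause-l event times
        u_l, a_l = self.lambda_jump_influence(l)
        J_l = lam_z[l - 1].jump_sizes
        tot_left = np.sum([f.left_limit(u_l) for f in lam_z], axis=0)
        S_left = np.exp(-tot_left)
        f_jump = S_left * J_l
        binfl_z0 = [self.beta_influence(m) @ z0 for m in range(1, k + 1)]  # (n,) each
        # jump term: S(u-) d[ e^{b'z0} dLambda_l ]
        per_jump = S_left[None, :] * (ez[l - 1] * a_l + J_l[None, :] * binfl_z0[l - 1][:, None])
        # survival term: - f_d * sum_m { influence of Lambda_m(u-; z0) }
        surv = np.zeros((self.n, len(u_l)))
        for m in range(1, k + 1):
            u_m, a_m = self.lambda_jump_influence(m)
            A_m = np.cumsum(a_m, axis=1)
            pos = np.searchsorted(u_m, u_l, side="left")  # strictly earlier jumps
            A_left = np.zeros((self.n, len(u_l)))
            nz = pos > 0
            A_left[:, nz] = A_m[:, pos[nz] - 1]
            lam_left = lam_z[m - 1].left_limit(u_l)
            surv += ez[m - 1] * A_left + lam_left[None, :] * binfl_z0[m - 1][:, None]
        per_jump -= f_jump[None, :] * surv
        cum_infl = np.cumsum(per_jump, axis=1)
        F_values = np.cumsum(f_jump)
        return u_l, cum_infl, F_values

    def cif_se(self, l: int, z0, times=None):
        """Pointwise standard errors of F_hat_l(t; z0)."""
        grid, cum, F = self.cif_influence(l, z0)
        se = np.sqrt((cum**2).mean(axis=0) / self.n)
        if times is None:
            return grid, se
        pos = np.searchsorted(grid, np.asarray(times, dtype=float), side="right")
        out = np.zeros(len(pos))
        nz = pos > 0
        out[nz] = se[pos[nz] - 1]
        return np.asarray(times, dtype=float), out


@dataclass
class BandResult:
    """Pointwise intervals and a simultaneous band on a time grid."""

    times: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    point_lower: np.ndarray
    point_upper: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    c_alpha: float
    transform: str
    weight: str
    alpha: float
    domain: tuple
    n_draws: int

    def covers(self, truth) -> bool:
        """Whole-domain containment of a true curve by the simultaneous band."""
        truth = np.asarray(truth, dtype=float)
        return bool(np.all((self.band_lower <= truth) & (truth <= self.band_upper)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "se": self.se,
                "point_lower": self.point_lower,
                "point_upper": self.point_upper,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
            }
        )

    def metadata(self) -> dict:
        return {
            "c_alpha": float(self.c_alpha),
            "transform": self.transform,
            "weight": self.weight,
            "alpha": float(self.alpha),
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "n_draws": int(self.n_draws),
        }


def _transform_limits(est, half, transform):
    """g^{-1}[ g(est) +/- half ] with limit ordering handled per transform."""
    if transform == "log":
        return est * np.exp(-half), est * np.exp(half)
    if transform == "cloglog":
        # g(x) = log(-log x); larger g means smaller x
        return est ** np.exp(half), est ** np.exp(-half)
    raise ValueError(f"unknown transform {transform!r}")


def multiplier_sup_draws(cum_infl: np.ndarray, n: int, n_draws: int, rng) -> np.ndarray:
    """Realizations of the multiplier process W_hat on the influence grid.

    Each draw is n^{-1/2} sum_i xi_i * infl_i(t) with xi_i ~ N(0, 1);
    returns an (n_draws, grid) matrix.
    """
    xi = rng.standard_normal((n_draws, n))
    return (xi @ cum_infl) / np.sqrt(n)


def multiplier_band(
    cum_infl: np.ndarray,
    times: np.ndarray,
    estimate: np.ndarray,
    n: int,
    transform: str = "log",
    weight: str = "ep",
    alpha: float = 0.05,
    n_draws: int = 1000,
    domain: tuple | None = None,
    rng=None,
    _draws: np.ndarray | None = None,
) -> BandResult:
    """Transformed pointwise CIs and a simultaneous multiplier-bootstrap band.

    Parameters mirror the estimator: ``cum_infl`` is the (n_clusters, grid)
    matrix of cumulative cluster influence curves, ``estimate`` the step
    estimate on the same grid.  ``weight`` selects the equal-precision
    ("ep", weight 1/sd) or Hall-Wellner ("hw", weight 1/(1+var)) sup
    weighting; ``transform`` is "log" (cumulative hazards) or "cloglog"
    (cumulative incidence).  The band domain defaults to the full grid and
    is trimmed where the transform is undefined or the variance vanishes.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    if weight not in ("ep", "hw"):
        raise ValueError("weight must be 'ep' or 'hw'")
    rng = np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    sigma = np.sqrt((cum_infl**2).mean(axis=0))  # sd of the sqrt(n)-scaled limit
    valid = sigma > 0
    if transform == "log":
        valid &= estimate > 0
    else:
        valid &= (estimate > 0) & (estimate < 1)
    if domain is not None:
        valid &= (times >= domain[0]) & (times <= domain[1])
    if not valid.any():
        raise ValueError("empty band domain after trimming")
    if domain is not None and valid.sum() < ((times >= domain[0]) & (times <= domain[1])).sum():
        warnings.warn("band domain trimmed where the transform or variance is degenerate")
    idx = np.flatnonzero(valid)
    t, est, sig = times[idx], estimate[idx], sigma[idx]
    A = cum_infl[:, idx]
    W = _draws[:, idx] if _draws is not None else multiplier_sup_draws(A, n, n_draws, rng)
    # q |g'| reduces to 1/sd (EP) or 1/(1+var) (HW) for both transforms
    wfun = 1.0 / sig if weight == "ep" else 1.0 / (1.0 + sig**2)
    sups = np.max(wfun[None, :] * np.abs(W), axis=1)
    c_alpha = float(np.quantile(sups, 1.0 - alpha))
    se = sig / np.sqrt(n)
    if transform == "log":
        dg = 1.0 / est
    else:
        dg = 1.0 / np.abs(est * np.log(est))
    # band half-width on the g scale inverts the same sup weight q(t)
    half_band = c_alpha * dg / (wfun * np.sqrt(n))
    half_point = stats.norm.ppf(1 - alpha / 2) * dg * se
    bl, bu = _transform_limits(est, half_band, transform)
    pl, pu = _transform_limits(est, half_point, transform)
    return BandResult(
        times=t,
        estimate=est,
        se=se,
        point_lower=pl,
        point_upper=pu,
        band_lower=bl,
        band_upper=bu,
        c_alpha=c_alpha,
        transform=transform,
        weight=weight,
        alpha=alpha,
        domain=(float(t[0]), float(t[-1])),
        n_draws=W.shape[0],
    )


def _default_domain(fit: MppleFit):
    """10th-90th percentile of the observed failure times (all causes)."""
    ev = fit.data.time[fit.data.delta == 1]
    return tuple(np.quantile(ev, [0.10, 0.90]))


def cumhaz_band(
    fit: MppleFit,
    l: int,
    infl: InfluenceSet | None = None,
    weight: str = "ep",
    alpha: float = 0.05,
    n_draws: int = 1000,
    domain: tuple | None = None,
    rng=None,
) -> BandResult:
    """Simultaneous band for the cause-l baseline cumulative hazard (log transform)."""
    infl = infl or InfluenceSet(fit)
    u, A = infl.lambda_influence(l)
    if domain is None:
        domain = _default_domain(fit)
    return multiplier_band(
        A, u, fit.Lambda[l - 1].values, fit.data.n_clusters,
        transform="log", weight=weight, alpha=alpha, n_draws=n_draws, domain=domain, rng=rng,
    )


def cif_band(
    fit: MppleFit,
    l: int,
    z0,
    infl: InfluenceSet | None = None,
    weight: str = "hw",
    alpha: float = 0.05,
    n_draws: int = 1000,
    domain: tuple | None = None,
    rng=None,
) -> BandResult:
    """Simultaneous band for the cause-l CIF at covariate z0 (cloglog transform)."""
    infl = infl or InfluenceSet(fit)
    grid, cum, F = infl.cif_influence(l, z0)
    if domain is None:
        domain = _default_domain(fit)
    return multiplier_band(
        cum, grid, F, fit.data.n_clusters,
        transform="cloglog", weight=weight, alpha=alpha, n_draws=n_draws, domain=domain, rng=rng,
    )
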