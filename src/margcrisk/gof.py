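"""Goodness of fit for the parametric cause-probability model.

The diagnostic is the cumulative residual process

    Res_l(t) = n^{-1} sum_i M_i^{-1} sum_j R_ij { N_ijl(t) - pi_l(W_ij, gamma_hat) N_ij(t) },

the 1/M-weighted cumulative difference, among complete cases, between
observed cause-l indicators and fitted probabilities.  Under a correctly
specified model the process is centered at zero for every t; because
gamma_hat solves the weighted score equation, the residual at tau vanishes
exactly along any direction spanned by the model design (in particular, at
tau for an intercept-containing model).

The test statistic is sup_t |sqrt(n) Res_l(t)|.  Its null distribution is
simulated with the multiplier method: per-cluster residual contributions,
corrected for the variability of gamma_hat through the step-1 influence
vectors, are perturbed by i.i.d. standard normal cluster multipliers.  The
95% quantile of the simulated sups also yields a null band around f(t) = 0
for graphical assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClusteredDataset
from .missingness import MissingnessFit, predict_pi
from .stepfun import StepFunction

__all__ = ["ResidualProcess", "residual_process", "gof_test"]


@dataclass
class ResidualProcess:
    """Observed cumulative residual process and (optionally) its null law."""

    process: StepFunction
    cause: int
    sup_stat: float | None = None  # sup_t |sqrt(n) Res(t)|
    p_value: float | None = None
    null_band: float | None = None  # half-width of the 95% null band for Res(t)
    n_draws: int = 0

    def summary(self) -> dict:
        return {
            "cause": self.cause,
            "sup_statistic": None if self.sup_stat is None else float(self.sup_stat),
            "p_value": None if self.p_value is None else float(self.p_value),
            "null_band_halfwidth": None if self.null_band is None else float(self.null_band),
            "n_draws": self.n_draws,
        }


def _residual_pieces(data: ClusteredDataset, gamma_fit: MissingnessFit, l: int):
    """Grid, per-event residual jumps and cluster bookkeeping arrays."""
    cc = (data.delta == 1) & (data.r == 1)
    idx = np.flatnonzero(cc)
    pi = predict_pi(gamma_fit)[idx, l - 1]
    y = (data.cause[idx] == l).astype(float)
    M = data.cluster_sizes
    v = 1.0 / M[data.cluster_codes[idx]]
    order = np.argsort(data.time[idx], kind="stable")
    idx, pi, y, v = idx[order], pi[order], y[order], v[order]
    times = data.time[idx]
    grid, inv = np.unique(times, return_inverse=True)
    return grid, inv, idx, pi, y, v


def residual_process(data: ClusteredDataset, gamma_fit: MissingnessFit, l: int) -> ResidualProcess:
    """Observed cumulative residual process for cause l (no test)."""
    grid, inv, _, pi, y, v = _residual_pieces(data, gamma_fit, l)
    jumps = np.zeros(len(grid))
    np.add.at(jumps, inv, v * (y - pi) / data.n_clusters)
    return ResidualProcess(process=StepFunction(grid, jumps), cause=l)


def gof_test(
    data: ClusteredDataset,
    gamma_fit: MissingnessFit,
    l: int = 1,
    n_draws: int = 1000,
    rng=None,
) -> ResidualProcess:
    """Simulation-based sup test of the cause-probability model for cause l.

    Returns the residual process together with the sup statistic, its
    multiplier p-value, and the 95% null-band half-width.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(rng)
    n = data.n_clusters
    grid, inv, idx, pi, y, v = _residual_pieces(data, gamma_fit, l)
    D_t = len(grid)
    jumps = np.zeros(D_t)
    np.add.at(jumps, inv, v * (y - pi) / n)
    res = StepFunction(grid, jumps)
    obs = float(np.sqrt(n) * np.max(np.abs(res.values)))

    # per-cluster residual curves
    cl = data.cluster_codes[idx]
    rho_j = np.zeros((n, D_t))
    np.add.at(rho_j, (cl, inv), v * (y - pi))
    rho = np.cumsum(rho_j, axis=1)
    # gamma-variability correction: dRes/dgamma' = -Dres(t)
    dpi = gamma_fit.dpi_dgamma(l)[idx]
    dres_j = np.zeros((D_t, dpi.shape[1]))
    np.add.at(dres_j, inv, v[:, None] * dpi)
    Dres = np.cumsum(dres_j, axis=0) / n
    # step-1 cluster influences I_g^{-1} u_i
    M = data.cluster_sizes
    v_all = 1.0 / M[data.cluster_codes]
    u_cl = np.zeros((n, dpi.shape[1]))
    np.add.at(u_cl, data.cluster_codes, v_all[:, None] * gamma_fit.score_contrib)
    ginfl = np.linalg.solve(gamma_fit.info_bar, u_cl.T).T
    infl = rho - ginfl @ Dres.T
    infl -= infl.mean(axis=0, keepdims=True)

    xi = rng.standard_normal((n_draws, n))
    W = (xi @ infl) / np.sqrt(n)
    sups = np.max(np.abs(W), axis=1)
    p_value = float((np.sum(sups >= obs) + 1) / (n_draws + 1))
    band = float(np.quantile(sups, 0.95) / np.sqrt(n))
    return ResidualProcess(
        process=res, cause=l, sup_stat=obs, p_value=p_value, null_band=band, n_draws=n_draws
    )
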