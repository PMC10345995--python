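"""Step 2 of the two-step estimator: maximum partial pseudolikelihood for the
marginal proportional cause-specific hazards model.

Failures with a missing cause enter each cause-l risk/score sum fractionally,
through the conditional expectation of the cause-specific counting process
given the observed data:

    dN~_ijl(t) = { R Delta_l + (1 - R) pi_l(W, gamma_hat) } dN_ij(t),

so the per-subject, per-cause event weight is ``r_ijl = Delta_ijl`` when the
cause is observed and ``pi_l(W, gamma_hat)`` when it is missing.  All sums
are weighted by the inverse cluster size 1/M_i ("tcm" mode, inference for the
typical cluster member under informative cluster size); "acm" mode drops the
1/M_i weight from the pseudoscore and the Breslow estimator and targets the
all-cluster-members population.

beta_hat_l solves the partial pseudoscore equation G_{n,l}(beta; gamma_hat)=0
by Newton-Raphson with the analytic information and step-halving; the
baseline cumulative hazard is the Breslow-type step-function estimator; the
covariate-specific cumulative incidence functions follow by plugging the
estimated hazards into the product-integral-free representation
F_l(t; z0) = int_0^t exp{-sum_m Lambda_m(u-; z0)} dLambda_l(u; z0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ClusteredDataset
from .missingness import MissingnessFit, PiModelSpec, fit_gamma, predict_pi
from .stepfun import StepFunction

__all__ = [
    "FractionalEvents",
    "MppleFit",
    "fractional_events",
    "risk_average",
    "pseudoscore",
    "fit_beta",
    "breslow",
    "cif",
    "fit_mpple",
]


@dataclass
class FractionalEvents:
    """Per-subject, per-cause event weights r_ijl in [0, 1].

    ``weight_r[s, l-1]`` multiplies subject s's counting-process increment
    for cause l: the cause indicator when observed, pi_l(W, gamma_hat) when
    the cause is missing, and 0 for censored subjects.
    """

    weight_r: np.ndarray  # (N, k)


def fractional_events(data: ClusteredDataset, gamma_fit: MissingnessFit | None) -> FractionalEvents:
    """Build the fractional event weights from the fitted cause model.

    ``gamma_fit=None`` is allowed when no cause is missing: the weights are
    then the observed cause indicators.
    """
    k = data.n_causes
    delta = data.delta
    cause = data.cause
    r_obs = data.r
    if gamma_fit is None:
        if np.any((delta == 1) & (r_obs == 0)):
            raise ValueError("missing causes present: a fitted cause model is required")
        pi = np.full((data.n_subjects, k), np.nan)
    else:
        pi = predict_pi(gamma_fit)
    w = np.zeros((data.n_subjects, k))
    for l in range(1, k + 1):
        w[:, l - 1] = np.where(
            delta == 0, 0.0, np.where(r_obs == 1, (cause == l).astype(float), pi[:, l - 1])
        )
    return FractionalEvents(weight_r=w)


class _Workspace:
    """Time-sorted design arrays shared by the score, Breslow and influence code.

    Subjects are sorted by follow-up time (ascending, stable).  Risk-set
    sums at a time t are suffix sums over the sorted arrays, retrieved by
    binary search; this keeps every pass over the data O(N log N).
    """

    def __init__(self, data: ClusteredDataset, frac: FractionalEvents, mode: str = "tcm"):
        if mode not in ("tcm", "acm"):
            raise ValueError("mode must be 'tcm' or 'acm'")
        self.data = data
        self.mode = mode
        order = np.argsort(data.time, kind="stable")
        self.order = order
        self.x = data.time[order]
        self.delta = data.delta[order]
        self.cluster = data.cluster_codes[order]
        self.Z = data.Z[order]
        self.r = frac.weight_r[order]
        self.r_obs = data.r[order]
        M = data.cluster_sizes
        self.v = (1.0 / M[self.cluster]) if mode == "tcm" else np.ones(len(order))
        self.n = data.n_clusters
        self.N, self.p = self.Z.shape
        self.k = data.n_causes

    def event_grid(self, l: int):
        """Unique cause-l event times and per-event bookkeeping.

        Returns (u, ev_idx, u_inv): unique times with positive fractional
        cause-l mass, indices of the contributing (sorted) subjects, and the
        map from those subjects to their unique-time slot.
        """
        mask = (self.delta == 1) & (self.r[:, l - 1] > 0)
        ev_idx = np.flatnonzero(mask)
        u, u_inv = np.unique(self.x[ev_idx], return_inverse=True)
        return u, ev_idx, u_inv

    def risk_sums(self, beta: np.ndarray, times: np.ndarray, with_s2: bool = False):
        """Weighted risk-set sums S0, S1 (and S2) at the given times.

        S0(t) = sum_s v_s Y_s(t) e^{beta'Z_s}; S1 stacks the Z-weighted sum,
        S2 the outer-product sum.  No 1/n normalization is applied.
        """
        w = self.v * np.exp(self.Z @ beta)
        # suffix sums over subjects with X >= t
        s0_suf = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s1_suf = np.concatenate([np.cumsum((w[:, None] * self.Z)[::-1], axis=0)[::-1], np.zeros((1, self.p))])
        idx = np.searchsorted(self.x, times, side="left")
        S0 = s0_suf[idx]
        S1 = s1_suf[idx]
        if not with_s2:
            return S0, S1, None
        ZZ = self.Z[:, :, None] * self.Z[:, None, :]
        s2_suf = np.concatenate(
            [np.cumsum((w[:, None, None] * ZZ)[::-1], axis=0)[::-1], np.zeros((1, self.p, self.p))]
        )
        return S0, S1, s2_suf[idx]


def risk_average(
    data: ClusteredDataset, beta_l: np.ndarray, t, mode: str = "tcm", frac: FractionalEvents | None = None
):
    """(S0(t), E_n(t, beta_l)): weighted risk-set size and at-risk covariate average.

    E_n is the 1/M-weighted (or unweighted, in "acm" mode) average of Z over
    subjects still at risk at t, tilted by exp(beta'Z).  An empty risk set
    yields S0 = 0 and a NaN average (the score integral skips such times).
    """
    if frac is None:
        frac = FractionalEvents(np.zeros((data.n_subjects, data.n_causes)))
    ws = _Workspace(data, frac, mode)
    times = np.atleast_1d(np.asarray(t, dtype=float))
    S0, S1, _ = ws.risk_sums(np.asarray(beta_l, dtype=float), times)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = S1 / S0[:, None]
    if np.ndim(t) == 0:
        return float(S0[0]), E[0]
    return S0, E


def _score_info(ws: _Workspace, l: int, beta: np.ndarray, with_info: bool = True):
    """Partial pseudoscore G_{n,l}(beta) and (optionally) the information.

    G = n^{-1} sum over cause-l events of v_s r_sl {Z_s - E_n(X_s, beta)};
    the information is the negative Jacobian, n^{-1} sum of
    v r {S2/S0 - E E'} at the event times.
    """
    u, ev_idx, u_inv = ws.event_grid(l)
    S0, S1, S2 = ws.risk_sums(beta, u, with_s2=with_info)
    E = S1 / S0[:, None]
    w_ev = ws.v[ev_idx] * ws.r[ev_idx, l - 1]
    resid = ws.Z[ev_idx] - E[u_inv]
    G = (w_ev[:, None] * resid).sum(axis=0) / ws.n
    if not with_info:
        return G, None
    V = S2 / S0[:, None, None] - E[:, :, None] * E[:, None, :]
    w_u = np.zeros(len(u))
    np.add.at(w_u, u_inv, w_ev)
    H = (w_u[:, None, None] * V).sum(axis=0) / ws.n
    return G, H


def pseudoscore(
    data: ClusteredDataset,
    frac: FractionalEvents,
    beta_l: np.ndarray,
    l: int,
    mode: str = "tcm",
) -> np.ndarray:
    """Partial pseudoscore vector G_{n,l}(beta_l; gamma_hat)."""
    ws = _Workspace(data, frac, mode)
    if not ((ws.delta == 1) & (ws.r[:, l - 1] > 0)).any():
        return np.zeros(data.Z.shape[1])
    return _score_info(ws, l, np.asarray(beta_l, dtype=float), with_info=False)[0]


def _log_pseudolik(ws: _Workspace, l: int, beta: np.ndarray) -> float:
    """Weighted log partial pseudolikelihood (used for step-halving only)."""
    u, ev_idx, u_inv = ws.event_grid(l)
    S0, _, _ = ws.risk_sums(beta, u)
    w_ev = ws.v[ev_idx] * ws.r[ev_idx, l - 1]
    return float(np.sum(w_ev * (ws.Z[ev_idx] @ beta - np.log(S0[u_inv]))) / ws.n)


def fit_beta(
    data: ClusteredDataset,
    frac: FractionalEvents,
    l: int,
    mode: str = "tcm",
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
):
    """Solve G_{n,l}(beta) = 0 by Newton-Raphson with step-halving.

    Returns ``(beta_hat, info)`` where ``info`` is the negative Jacobian of
    the pseudoscore at the solution (average-over-clusters scale).
    """
    ws = _Workspace(data, frac, mode)
    p = ws.p
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    G, H = _score_info(ws, l, beta)
    for _ in range(max_iter):
        if np.max(np.abs(G)) < tol:
            return beta, H
        try:
            step = np.linalg.solve(H, G)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information for cause {l}") from exc
        # step-halving on the log pseudolikelihood
        ll0 = _log_pseudolik(ws, l, beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _log_pseudolik(ws, l, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        G, H = _score_info(ws, l, beta)
    if np.max(np.abs(G)) < tol:
        return beta, H
    raise RuntimeError(f"Newton iterations for cause {l} did not converge (|G| = {np.max(np.abs(G)):.2e})")


def breslow(
    data: ClusteredDataset,
    frac: FractionalEvents,
    beta_hat_l: np.ndarray,
    l: int,
    mode: str = "tcm",
) -> StepFunction:
    """Breslow-type estimator of the cause-l marginal baseline cumulative hazard.

    Jumps at the unique cause-l event times with height
    sum_{ties} v r_l / S0(u); weight normalizations cancel between numerator
    and denominator, so no 1/n factor appears.
    """
    ws = _Workspace(data, frac, mode)
    beta = np.asarray(beta_hat_l, dtype=float)
    u, ev_idx, u_inv = ws.event_grid(l)
    if len(u) == 0:
        return StepFunction(np.empty(0), np.empty(0))
    S0, _, _ = ws.risk_sums(beta, u)
    num = np.zeros(len(u))
    np.add.at(num, u_inv, ws.v[ev_idx] * ws.r[ev_idx, l - 1])
    return StepFunction(u, num / S0)


@dataclass
class MppleFit:
    """Converged two-step fit: per-cause coefficients and baseline hazards."""

    data: ClusteredDataset
    gamma_fit: MissingnessFit
    frac: FractionalEvents
    mode: str
    beta: list  # per-cause coefficient vectors
    info: list  # per-cause information matrices (negative score Jacobians)
    Lambda: list  # per-cause Breslow StepFunctions
    n_iter_gamma: int = 0

    @property
    def n_causes(self):
        return self.data.n_causes

    def cumhaz(self, l: int, z0=None) -> StepFunction:
        """Lambda_hat_l, optionally covariate-specific: Lambda_l(t) e^{beta_l'z0}."""
        base = self.Lambda[l - 1]
        if z0 is None:
            return base
        z0 = np.asarray(z0, dtype=float)
        return base.scaled(float(np.exp(self.beta[l - 1] @ z0)))

    def summary(self, covariance=None) -> dict:
        """Coefficient table as a JSON-able dict (optionally with SEs/CIs)."""
        out = {"mode": self.mode, "n_clusters": self.data.n_clusters, "causes": {}}
        for l in range(1, self.n_causes + 1):
            entry = {"coef": {}, "n_events": float(self.frac.weight_r[:, l - 1].sum())}
            for j, name in enumerate(self.data.z_cols):
                b = float(self.beta[l - 1][j])
                cell = {"estimate": b, "hr": float(np.exp(b))}
                if covariance is not None:
                    se = float(np.sqrt(covariance[l - 1][j, j]))
                    cell.update(
                        se=se,
                        hr_ci_95=[float(np.exp(b - 1.959963984540054 * se)),
                                  float(np.exp(b + 1.959963984540054 * se))],
                    )
                entry["coef"][name] = cell
            out["causes"][f"cause_{l}"] = entry
        return out


def cif(fit: MppleFit, z0) -> list[StepFunction]:
    """Covariate-specific cumulative incidence functions for all causes.

    F_hat_l(t; z0) accumulates S(u-) dLambda_l(u; z0) over the pooled event
    times, with the survival factor S(u-) = exp{-sum_m Lambda_m(u-; z0)}
    evaluated at the left limit, so sum_l F_l(t; z0) <= 1 for all t.
    """
    z0 = np.asarray(z0, dtype=float)
    if z0.shape != (len(fit.data.z_cols),):
        raise ValueError(f"z0 must have length {len(fit.data.z_cols)}")
    k = fit.n_causes
    lam_z = [fit.cumhaz(l, z0) for l in range(1, k + 1)]
    pooled = np.unique(np.concatenate([f.jump_times for f in lam_z]))
    # all-cause cumulative hazard at left limits of the pooled grid
    tot_left = np.zeros(len(pooled))
    for f in lam_z:
        tot_left += f.left_limit(pooled)
    S_left = np.exp(-tot_left)
    out = []
    for f in lam_z:
        jumps = np.zeros(len(pooled))
        pos = np.searchsorted(pooled, f.jump_times)
        jumps[pos] = f.jump_sizes
        out.append(StepFunction(pooled, S_left * jumps))
    return out


def fit_mpple(
    data: ClusteredDataset,
    pi_spec: PiModelSpec | None = None,
    gamma_fit: MissingnessFit | None = None,
    mode: str = "tcm",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> MppleFit:
    """Run the full two-step procedure on a dataset.

    Either a :class:`PiModelSpec` (step 1 is fitted here) or an existing
    :class:`MissingnessFit` must be supplied, unless no cause is missing, in
    which case step 1 is skipped and the event weights are the observed cause
    indicators.
    """
    if gamma_fit is None and pi_spec is not None:
        gamma_fit = fit_gamma(data, pi_spec)
    elif gamma_fit is None and np.any((data.delta == 1) & (data.r == 0)):
        raise ValueError("missing causes present: a pi-model specification is required")
    frac = fractional_events(data, gamma_fit)
    betas, infos, lams = [], [], []
    for l in range(1, data.n_causes + 1):
        b, H = fit_beta(data, frac, l, mode=mode, tol=tol, max_iter=max_iter)
        betas.append(b)
        infos.append(H)
        lams.append(breslow(data, frac, b, l, mode=mode))
    return MppleFit(
        data=data,
        gamma_fit=gamma_fit,
        frac=frac,
        mode=mode,
        beta=betas,
        info=infos,
        Lambda=lams,
        n_iter_gamma=0 if gamma_fit is None else gamma_fit.n_iter,
    )
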