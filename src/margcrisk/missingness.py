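"""Step 1 of the two-step estimator: the parametric model for the cause
probability given failure, pi_l(W, gamma), fitted on the complete cases.

Under the missing-at-random assumption, ``P(C = l | failure, W)`` does not
depend on the missingness indicator, so gamma can be estimated from the
complete-case failures (delta = 1, r = 1) alone.  Estimation uses
inverse-cluster-size (1/M_i) weighted estimating equations under working
independence: a weighted binary logit for k = 2 causes, or a
baseline-category multinomial logit (cause k as reference) for k > 2.

The fit also carries the pieces needed downstream for two-stage variance
estimation: the cluster-averaged information matrix, per-subject score
contributions, and per-subject influence vectors omega_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ClusteredDataset

__all__ = ["PiModelSpec", "MissingnessFit", "build_design", "fit_gamma", "predict_pi"]


@dataclass(frozen=True)
class PiModelSpec:
    """Design specification for the cause-probability model.

    ``features`` is a sequence of terms building the design vector from
    W = (X, Z, A); an intercept is always included first.  Each term is
    either ``"time"`` (the raw follow-up time), ``"log(time)"``, or the name
    of a covariate column (scientific or auxiliary).
    """

    features: Sequence[str] = ("time",)
    n_causes: int = 2

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def names(self):
        return ("intercept",) + self.features

    def n_params(self) -> int:
        """Total parameter dimension: (k - 1) stacked design vectors."""
        return (self.n_causes - 1) * (1 + len(self.features))


def build_design(data: ClusteredDataset, spec: PiModelSpec, complete_only: bool = True):
    """Design matrix for the pi model.

    Returns ``(X, y, mask)`` where rows of ``X`` are design vectors, ``y``
    is the observed cause, and ``mask`` selects complete-case failures.
    With ``complete_only=False`` rows cover all subjects (used to evaluate
    pi for failures with a missing cause).
    """
    cols = [np.ones(data.n_subjects)]
    for f in spec.features:
        if f == "time":
            cols.append(data.time)
        elif f == "log(time)":
            cols.append(np.log(data.time))
        else:
            if f in data.z_cols:
                cols.append(data.df[f].to_numpy(dtype=float))
            elif f in data.a_cols:
                cols.append(data.df[f].to_numpy(dtype=float))
            else:
                raise ValueError(f"pi-model feature {f!r} is not a covariate column")
    X = np.column_stack(cols)
    mask = (data.delta == 1) & (data.r == 1)
    if complete_only:
        if not mask.any():
            raise ValueError("no complete-case failures to fit the cause model on")
        return X[mask], data.cause[mask], mask
    return X, data.cause, mask


@dataclass
class MissingnessFit:
    """Fitted cause-probability model with influence bookkeeping.

    ``gamma`` is the stacked parameter vector (categories 1..k-1, reference
    k), ``omega`` holds the per-subject influence contributions
    ``omega_ij = Ibar^{-1} s_ij`` (zero off the complete cases), with
    ``Ibar`` the 1/M-weighted information averaged over clusters, so that
    ``gamma_hat - gamma_0 ~ n^{-1} sum_i M_i^{-1} sum_j omega_ij``.
    """

    gamma: np.ndarray
    spec: PiModelSpec
    sandwich_cov: np.ndarray
    info_bar: np.ndarray
    design_all: np.ndarray
    pi_all: np.ndarray
    score_contrib: np.ndarray
    omega: np.ndarray
    n_complete: int
    n_iter: int
    converged: bool
    separation: bool = False
    se: np.ndarray = field(init=False)

    def __post_init__(self):
        self.se = np.sqrt(np.diag(self.sandwich_cov))

    @property
    def n_causes(self):
        return self.spec.n_causes

    def dpi_dgamma(self, l: int) -> np.ndarray:
        """d pi_l / d gamma' for every subject; shape (N, dim(gamma)).

        Baseline-category multinomial derivative: for stacked block m,
        ``d pi_l / d gamma_m = pi_l (1{l=m} - pi_m) x``.
        """
        k = self.n_causes
        X, pi = self.design_all, self.pi_all
        blocks = []
        pil = pi[:, l - 1]
        for m in range(1, k):
            coef = pil * ((1.0 if l == m else 0.0) - pi[:, m - 1])
            blocks.append(coef[:, None] * X)
        return np.hstack(blocks)

    def summary(self) -> dict:
        """Coefficient table (per non-reference category) as a JSON-able dict."""
        from scipy import stats

        d = self.design_all.shape[1]
        names = self.spec.names
        out = {}
        for m in range(1, self.n_causes):
            g = self.gamma[(m - 1) * d : m * d]
            s = self.se[(m - 1) * d : m * d]
            z = g / s
            p = 2 * stats.norm.sf(np.abs(z))
            out[f"cause_{m}"] = {
                name: {"estimate": float(gi), "se": float(si), "p_value": float(pi_)}
                for name, gi, si, pi_ in zip(names, g, s, p)
            }
        return out


def _pi_matrix(X: np.ndarray, gamma: np.ndarray, k: int) -> np.ndarray:
    """Category probabilities (N, k) under the baseline-category logit."""
    d = X.shape[1]
    eta = np.column_stack([X @ gamma[(m - 1) * d : m * d] for m in range(1, k)])
    eta = np.clip(eta, -500, 500)
    expeta = np.exp(eta)
    denom = 1.0 + expeta.sum(axis=1)
    pi = np.empty((X.shape[0], k))
    pi[:, : k - 1] = expeta / denom[:, None]
    pi[:, k - 1] = 1.0 / denom
    return pi


def fit_gamma(
    data: ClusteredDataset,
    spec: PiModelSpec,
    tol_score: float = 1e-8,
    tol_rel: float = 1e-10,
    max_iter: int = 100,
) -> MissingnessFit:
    """Fit gamma by 1/M_i-weighted multinomial logistic estimating equations.

    Newton iterations on the weighted score, initialized at zero, under a
    working independence correlation.  The sandwich covariance aggregates
    scores at cluster level, so it is valid under arbitrary within-cluster
    dependence.
    """
    k = spec.n_causes
    if k < 2:
        raise ValueError("need at least two competing causes")
    Xcc, ycc, mask = build_design(data, spec, complete_only=True)
    observed = np.unique(ycc)
    if observed.size < 2:
        raise ValueError("all observed causes identical; gamma is not identifiable")
    d = Xcc.shape[1]
    dg = (k - 1) * d
    M = data.cluster_sizes
    v = 1.0 / M[data.cluster_codes]  # per-subject weight
    vcc = v[mask]
    Ycc = np.column_stack([(ycc == m).astype(float) for m in range(1, k)])

    gamma = np.zeros(dg)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = _pi_matrix(Xcc, gamma, k)[:, : k - 1]
        resid = Ycc - pi  # (ncc, k-1)
        # stacked weighted score and information
        U = np.concatenate([(vcc * resid[:, m])[:, None].T @ Xcc for m in range(k - 1)], axis=None)
        I = np.zeros((dg, dg))
        for m in range(k - 1):
            for m2 in range(k - 1):
                w = pi[:, m] * ((1.0 if m == m2 else 0.0) - pi[:, m2]) * vcc
                I[m * d : (m + 1) * d, m2 * d : (m2 + 1) * d] = (Xcc * w[:, None]).T @ Xcc
        step = np.linalg.solve(I, U)
        gamma_new = gamma + step
        rel = np.max(np.abs(step)) / max(1.0, np.max(np.abs(gamma_new)))
        gamma = gamma_new
        if np.max(np.abs(U)) < tol_score * max(1.0, vcc.sum()) or rel < tol_rel:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"cause-probability model did not converge in {max_iter} iterations")

    n = data.n_clusters
    pi_cc = _pi_matrix(Xcc, gamma, k)
    separation = bool(np.any(pi_cc[np.arange(len(ycc)), ycc - 1] < 1e-10))
    if separation:
        warnings.warn("possible separation: fitted cause probabilities ~ 0 at convergence")

    # per-subject stacked score contributions s_ij (all subjects; 0 off complete cases)
    Xall = build_design(data, spec, complete_only=False)[0]
    pi_all = _pi_matrix(Xall, gamma, k)
    resid_cc = Ycc - pi_cc[:, : k - 1]
    s = np.zeros((data.n_subjects, dg))
    s_cc = np.hstack([resid_cc[:, m][:, None] * Xcc for m in range(k - 1)])
    s[mask] = s_cc
    # information averaged over clusters and per-subject influence omega
    Ibar = I / n
    omega = np.linalg.solve(Ibar, s.T).T
    # cluster-aggregated sandwich
    u_cl = np.zeros((n, dg))
    np.add.at(u_cl, data.cluster_codes, v[:, None] * s)
    meat = u_cl.T @ u_cl / n
    Ibar_inv = np.linalg.inv(Ibar)
    cov = Ibar_inv @ meat @ Ibar_inv / n

    return MissingnessFit(
        gamma=gamma,
        spec=spec,
        sandwich_cov=cov,
        info_bar=Ibar,
        design_all=Xall,
        pi_all=pi_all,
        score_contrib=s,
        omega=omega,
        n_complete=int(mask.sum()),
        n_iter=it,
        converged=converged,
        separation=separation,
    )


def predict_pi(fit: MissingnessFit, data: ClusteredDataset | None = None, l: int | None = None):
    """Fitted cause probabilities pi_l(W, gamma_hat).

    With ``data=None`` the probabilities stored at fit time are used.
    Returns the (N, k) matrix, or the column for cause ``l`` if given.
    """
    if data is None:
        pi = fit.pi_all
    else:
        X = build_design(data, fit.spec, complete_only=False)[0]
        pi = _pi_matrix(X, fit.gamma, fit.n_causes)
    if l is None:
        return pi
    if not 1 <= l <= fit.n_causes:
        raise ValueError(f"cause index {l} out of range")
    return pi[:, l - 1]
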