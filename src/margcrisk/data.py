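"""Domain types, validation and CSV I/O for clustered competing risks data
with missing causes of failure.

Each subject record carries the follow-up time ``X = T ^ U``, the any-cause
failure indicator ``delta``, the observed cause ``eps = delta * r * C`` (0 =
censored or missing), the cause-observation indicator ``r``, scientific
covariates ``Z`` and optional auxiliary covariates ``A``.  Censored records
always have the cause status observed (``delta = 0  =>  r = 1``), mirroring
the convention that right-censoring status is never missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "ClusteredDataset",
    "read_dataset",
    "write_dataset",
    "cause_counting",
]

#: default CSV column names
DEFAULT_SCHEMA = {
    "cluster": "cluster",
    "time": "time",
    "delta": "delta",
    "cause": "cause",
    "r": "r",
}


class SubjectRecord(NamedTuple):
    """One subject's observed data (a row view of :class:`ClusteredDataset`)."""

    cluster_id: object
    time_X: float
    delta: int
    cause_eps: int
    r_obs: int
    Z: np.ndarray
    A: np.ndarray


@dataclass
class ClusteredDataset:
    """Clustered competing risks data, one row per subject, grouped by cluster.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``cluster, time, delta, cause, r`` plus covariate columns.
        Rows are stored grouped by cluster in first-appearance order.
    z_cols : sequence of str
        Names of the scientific covariate columns (length p >= 1).
    a_cols : sequence of str
        Names of the auxiliary covariate columns (may be empty).
    n_causes : int
        Number of competing causes k >= 1.
    tau : float, optional
        Study horizon; defaults to the maximum observed time.
    """

    df: pd.DataFrame
    z_cols: Sequence[str]
    a_cols: Sequence[str] = field(default_factory=tuple)
    n_causes: int = 2
    tau: float | None = None

    def __post_init__(self):
        self.z_cols = tuple(self.z_cols)
        self.a_cols = tuple(self.a_cols)
        df = self.df
        required = ["cluster", "time", "delta", "cause", "r"]
        for c in required + list(self.z_cols) + list(self.a_cols):
            if c not in df.columns:
                raise ValueError(f"missing required column {c!r}")
        # group rows by cluster, preserving first-appearance order
        codes, uniques = pd.factorize(df["cluster"], sort=False)
        order = np.argsort(codes, kind="stable")
        if not np.array_equal(order, np.arange(len(df))):
            df = df.iloc[order].reset_index(drop=True)
            codes = codes[order]
        self.df = df.reset_index(drop=True)
        self._codes = codes
        self._cluster_ids = np.asarray(uniques)

        t = self.time
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all follow-up times must be positive and finite")
        d = self.delta
        if not np.isin(d, [0, 1]).all():
            raise ValueError("delta must be 0/1")
        r = self.r
        if not np.isin(r, [0, 1]).all():
            raise ValueError("r must be 0/1")
        c = self.cause
        if c.min() < 0 or c.max() > self.n_causes:
            raise ValueError(f"cause codes must lie in 0..{self.n_causes}")
        if np.any((d == 0) & (r == 0)):
            raise ValueError("censored records must have r = 1 (censoring status is always observed)")
        if np.any((d == 0) & (c != 0)):
            raise ValueError("censored records must have cause 0")
        if np.any((d == 1) & (r == 1) & (c == 0)):
            raise ValueError("observed failures must carry a cause in 1..k")
        if np.any((d == 1) & (r == 0) & (c != 0)):
            raise ValueError("failures with unobserved cause must have cause 0")
        if self.tau is None:
            self.tau = float(t.max())
        elif t.max() > self.tau:
            raise ValueError("observed times exceed the study horizon tau")

    # -- array accessors -------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self._cluster_ids)

    @property
    def cluster_ids(self):
        return self._cluster_ids

    @property
    def cluster_codes(self):
        """Integer cluster index 0..n-1 per subject."""
        return self._codes

    @property
    def cluster_sizes(self):
        """Observed cluster sizes M_i (record counts per cluster)."""
        return np.bincount(self._codes, minlength=self.n_clusters)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def time(self):
        return self.df["time"].to_numpy(dtype=float)

    @property
    def delta(self):
        return self.df["delta"].to_numpy(dtype=int)

    @property
    def cause(self):
        return self.df["cause"].to_numpy(dtype=int)

    @property
    def r(self):
        return self.df["r"].to_numpy(dtype=int)

    @property
    def Z(self):
        return self.df[list(self.z_cols)].to_numpy(dtype=float)

    @property
    def A(self):
        if not self.a_cols:
            return np.empty((len(self.df), 0))
        return self.df[list(self.a_cols)].to_numpy(dtype=float)

    # -- counting processes ----------------------------------------------
    def N(self, t):
        """Any-cause counting process N_ij(t) = I(X <= t, delta = 1)."""
        return ((self.time <= t) & (self.delta == 1)).astype(int)

    def Y(self, t):
        """At-risk process Y_ij(t) = I(X >= t)."""
        return (self.time >= t).astype(int)

    def records(self):
        """Iterate over :class:`SubjectRecord` views."""
        Z, A = self.Z, self.A
        for i, row in enumerate(self.df.itertuples(index=False)):
            yield SubjectRecord(
                cluster_id=getattr(row, "cluster"),
                time_X=float(getattr(row, "time")),
                delta=int(getattr(row, "delta")),
                cause_eps=int(getattr(row, "cause")),
                r_obs=int(getattr(row, "r")),
                Z=Z[i],
                A=A[i],
            )


def cause_counting(data: ClusteredDataset, l: int, t: float):
    """Cause-specific counting process N_ijl(t) = I(X <= t, C = l, delta = 1).

    Only failures with an *observed* cause contribute; a failure with a
    missing cause has ``N_ijl(t) = 0`` for every l.
    """
    if not 1 <= l <= data.n_causes:
        raise ValueError(f"cause index {l} out of range 1..{data.n_causes}")
    return ((data.cause == l) & (data.time <= t)).astype(int)


def read_dataset(
    path,
    schema: dict | None = None,
    n_causes: int = 2,
    z_cols: Sequence[str] | None = None,
    a_cols: Sequence[str] = (),
    tau: float | None = None,
) -> ClusteredDataset:
    """Read a one-row-per-subject CSV into a validated :class:`ClusteredDataset`.

    ``schema`` maps the canonical names (cluster, time, delta, cause, r) to
    the file's column names.  Covariate columns default to every numeric
    column not claimed by the schema, all treated as scientific (``Z``).
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path)
    rename = {v: k for k, v in sch.items() if v in df.columns}
    missing = [v for k, v in sch.items() if v not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    df = df.rename(columns=rename)
    if z_cols is None:
        z_cols = [c for c in df.columns if c not in DEFAULT_SCHEMA and c not in a_cols]
    return ClusteredDataset(df, z_cols=z_cols, a_cols=a_cols, n_causes=n_causes, tau=tau)


def write_dataset(data: ClusteredDataset, path) -> None:
    """Write a dataset to CSV, re-readable by :func:`read_dataset`."""
    cols = ["cluster", "time", "delta", "cause", "r"] + list(data.z_cols) + list(data.a_cols)
    data.df[cols].to_csv(path, index=False)
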