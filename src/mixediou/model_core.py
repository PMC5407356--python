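"""Data model and marginal covariance for the linear mixed IOU model.

The model, for subject ``i`` with ``n_i`` visits at times ``t_ij``::

    Y_i = X_i beta + Z_i b_i + W_i + eps_i

with mutually independent ``b_i ~ N(0, G)`` (unstructured, q x q),
``W_i`` the IOU process evaluated at the subject's times, and
``eps_i ~ N(0, sigma^2 I)``.  The marginal covariance of ``Y_i`` is::

    V_i = Z_i G Z_i' + Gamma_i + sigma^2 I

For REML the residual variance is profiled out by writing
``V_i = sigma^2 V*_i`` with ``V*_i = Z G* Z' + Gamma*(alpha, a*) + I``,
where ``G* = G/sigma^2`` and the IOU amplitude is scaled likewise
(``omega* = omega/sigma^2`` or ``tau*^2 = tau^2/sigma^2``).  The reduced
parameter vector ``theta`` holds the log-Cholesky encoding of ``G*``, the
chosen coordinate of ``alpha`` and the scaled amplitude coordinate.

All times are stored internally in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .iou_cov import IOUParameterization, IOUParams, iou_cov_matrix

__all__ = [
    "TIME_UNIT_MONTHS",
    "to_months",
    "LongDataset",
    "VarianceParams",
    "FixedEffects",
    "marginal_cov",
    "log_cholesky_encode",
    "log_cholesky_decode",
    "split_sigma",
    "merge_sigma",
    "difference_from_first",
]

#: Months per declared unit.
TIME_UNIT_MONTHS = {"days": 1.0 / 30.4375, "months": 1.0, "years": 12.0}

RandomSpec = Literal["intercept", "slope"]


def to_months(t, unit: str):
    """Convert times in a declared unit to the internal month scale."""
    try:
        factor = TIME_UNIT_MONTHS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNIT_MONTHS)}"
        ) from None
    return np.asarray(t, dtype=float) * factor


@dataclass
class LongDataset:
    """Long-format longitudinal data, one block per subject.

    Per subject: visit times (months, nonnegative, sorted), responses, a
    fixed-effects design ``X_i`` (n_i x p) and a random-effects design
    ``Z_i`` (n_i x q).  ``p`` and ``q`` are constant across subjects.
    """

    ids: list
    times: list[np.ndarray]
    y: list[np.ndarray]
    X: list[np.ndarray]
    Z: list[np.ndarray]
    fixed_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.ids)
        if not (len(self.times) == len(self.y) == len(self.X) == len(self.Z) == m):
            raise ValueError("per-subject lists must all have the same length")
        if m == 0:
            raise ValueError("dataset must contain at least one subject")
        p = self.X[0].shape[1]
        q = self.Z[0].shape[1]
        for i in range(m):
            t, yi, Xi, Zi = self.times[i], self.y[i], self.X[i], self.Z[i]
            n = len(t)
            if n < 1:
                raise ValueError(f"subject {self.ids[i]!r} has no measurements")
            if not (len(yi) == Xi.shape[0] == Zi.shape[0] == n):
                raise ValueError(f"inconsistent row counts for subject {self.ids[i]!r}")
            if Xi.shape[1] != p or Zi.shape[1] != q:
                raise ValueError("p and q must be constant across subjects")
            if not np.all(np.isfinite(t)) or not np.all(np.isfinite(yi)):
                raise ValueError(f"non-finite values for subject {self.ids[i]!r}")
            if np.any(t < 0):
                raise ValueError(
                    f"negative time for subject {self.ids[i]!r}; the IOU model needs a "
                    "natural time zero — shift the origin or difference from a first "
                    "measurement (difference_from_first)"
                )
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times for subject {self.ids[i]!r} are not sorted")

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.X[0].shape[1]

    @property
    def q(self) -> int:
        return self.Z[0].shape[1]

    @property
    def n_obs(self) -> int:
        return int(sum(len(t) for t in self.times))

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten back to a long-format table (times in months)."""
        frames = []
        for i in range(self.m):
            d = {"id": self.ids[i], "time": self.times[i], "y": self.y[i]}
            for j, name in enumerate(self.fixed_names):
                d[name] = self.X[i][:, j]
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fixed: Sequence[str] = ("time",),
        random: RandomSpec = "intercept",
        time_unit: str = "months",
        id_col: str = "id",
        time_col: str = "time",
        y_col: str = "y",
        intercept: bool = True,
        sort_within: bool = True,
    ) -> "LongDataset":
        """Build a dataset from a long-format table.

        ``fixed`` lists covariate columns (the time column may appear by
        name); an intercept column is prepended unless ``intercept=False``.
        ``random`` selects a random intercept or random intercept + slope.
        """
        for col in (id_col, time_col, y_col):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} not found in data")
        for col in fixed:
            if col not in df.columns and col != time_col:
                raise ValueError(f"fixed-effect column {col!r} not found in data")
        ids, times, ys, Xs, Zs = [], [], [], [], []
        fixed_names = (["const"] if intercept else []) + list(fixed)
        for sid, grp in df.groupby(id_col, sort=True):
            if sort_within:
                grp = grp.sort_values(time_col, kind="stable")
            t = to_months(grp[time_col].to_numpy(), time_unit)
            y = grp[y_col].to_numpy(dtype=float)
            cols = []
            if intercept:
                cols.append(np.ones(len(t)))
            for c in fixed:
                cols.append(t if c == time_col else grp[c].to_numpy(dtype=float))
            X = np.column_stack(cols)
            Z = np.ones((len(t), 1)) if random == "intercept" else np.column_stack([np.ones(len(t)), t])
            ids.append(sid)
            times.append(t)
            ys.append(y)
            Xs.append(X)
            Zs.append(Z)
        return cls(ids, times, ys, Xs, Zs, fixed_names)


def difference_from_first(df: pd.DataFrame, id_col: str = "id", time_col: str = "time",
                          y_col: str = "y") -> pd.DataFrame:
    """Workaround for unknown natural time zero: model differences.

    For each subject, subtracts the first (earliest) measurement from both
    the response and the time axis and drops that first row.  The differenced
    data have a natural zero at the reference measurement.
    """
    out = []
    for _, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(time_col, kind="stable")
        if len(grp) < 2:
            continue
        first = grp.iloc[0]
        rest = grp.iloc[1:].copy()
        rest[time_col] = rest[time_col] - first[time_col]
        rest[y_col] = rest[y_col] - first[y_col]
        out.append(rest)
    if not out:
        raise ValueError("no subject has at least two measurements to difference")
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class VarianceParams:
    """Full variance-parameter set ``(G, alpha, amplitude, sigma^2)``."""

    G: np.ndarray
    iou: IOUParams
    sigma2: float

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        object.__setattr__(self, "G", G)
        if G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(G, G.T, atol=1e-12):
            raise ValueError("G must be symmetric")
        try:
            np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            raise ValueError("G must be positive definite") from None
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def q(self) -> int:
        return self.G.shape[0]


@dataclass(frozen=True)
class FixedEffects:
    """GLS fixed-effect estimates and their covariance."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def marginal_cov(subject_times: np.ndarray, vp: VarianceParams, Z: np.ndarray) -> np.ndarray:
    """Marginal covariance ``V_i = Z G Z' + Gamma_i + sigma^2 I``."""
    t = np.atleast_1d(np.asarray(subject_times, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != t.size:
        raise ValueError(f"Z has {Z.shape[0]} rows but there are {t.size} times")
    if Z.shape[1] != vp.q:
        raise ValueError(f"Z has {Z.shape[1]} columns but G is {vp.q}x{vp.q}")
    V = Z @ vp.G @ Z.T + iou_cov_matrix(t, vp.iou) + vp.sigma2 * np.eye(t.size)
    return V


# ---------------------------------------------------------------------------
# log-Cholesky encoding of a PD matrix: lower-triangular Cholesky factor,
# row-major lower triangle, with the diagonal stored as logarithms.
# ---------------------------------------------------------------------------


def _tril_indices(q: int):
    return [(i, j) for i in range(q) for j in range(i + 1)]


def log_cholesky_encode(G: np.ndarray) -> np.ndarray:
    G = np.atleast_2d(np.asarray(G, dtype=float))
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        raise ValueError("matrix is not positive definite") from None
    return np.array([np.log(L[i, i]) if i == j else L[i, j] for i, j in _tril_indices(G.shape[0])])


def log_cholesky_decode(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    # q(q+1)/2 = len(v)
    q = int(round((np.sqrt(8 * len(v) + 1) - 1) / 2))
    if q * (q + 1) // 2 != len(v):
        raise ValueError(f"vector length {len(v)} is not a triangular number")
    L = np.zeros((q, q))
    for k, (i, j) in enumerate(_tril_indices(q)):
        L[i, j] = np.exp(v[k]) if i == j else v[k]
    return L @ L.T


def chol_from_log_vector(v: np.ndarray) -> np.ndarray:
    """The lower Cholesky factor encoded by a log-Cholesky vector."""
    v = np.asarray(v, dtype=float)
    q = int(round((np.sqrt(8 * len(v) + 1) - 1) / 2))
    L = np.zeros((q, q))
    for k, (i, j) in enumerate(_tril_indices(q)):
        L[i, j] = np.exp(v[k]) if i == j else v[k]
    return L


@dataclass(frozen=True)
class ReducedTheta:
    """Reduced (sigma^2-profiled) parameter vector for REML.

    Layout of ``vector``: log-Cholesky of ``G* = G/sigma^2`` (q(q+1)/2
    entries), then the IOU scale coordinate, then the scaled amplitude
    coordinate (``omega* = omega/sigma^2`` or ``tau* = tau/sigma``).
    """

    vector: np.ndarray
    q: int
    parameterization: IOUParameterization

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if len(v) != self.q * (self.q + 1) // 2 + 2:
            raise ValueError("theta vector length inconsistent with q")
        if not np.all(np.isfinite(v)):
            raise ValueError("theta must be finite")

    @property
    def n_chol(self) -> int:
        return self.q * (self.q + 1) // 2

    @property
    def g_star(self) -> np.ndarray:
        return log_cholesky_decode(self.vector[: self.n_chol])

    @property
    def alpha(self) -> float:
        return self.parameterization.coord_to_alpha(self.vector[self.n_chol])

    @property
    def amplitude_star(self) -> float:
        return float(self.vector[self.n_chol + 1])


def split_sigma(
    vp: VarianceParams, parameterization: IOUParameterization | None = None
) -> tuple[ReducedTheta, float]:
    """Factor ``V = sigma^2 V*``: return the reduced theta and sigma^2."""
    par = parameterization or IOUParameterization()
    s2 = vp.sigma2
    gv = log_cholesky_encode(vp.G / s2)
    if par.amplitude_coord == "omega":
        amp = vp.iou.omega / s2
    else:
        amp = vp.iou.tau / np.sqrt(s2)
    if amp <= 0:
        raise ValueError("scaled amplitude must be positive")
    vec = np.concatenate([gv, [par.alpha_to_coord(vp.iou.alpha), amp]])
    return ReducedTheta(vec, vp.q, par), s2


def merge_sigma(theta: ReducedTheta, sigma2: float) -> VarianceParams:
    """Inverse of :func:`split_sigma`."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    par = theta.parameterization
    G = theta.g_star * sigma2
    amp = theta.amplitude_star
    if amp <= 0:
        raise ValueError("scaled amplitude must be positive")
    if par.amplitude_coord == "omega":
        iou = IOUParams(theta.alpha, amp * sigma2, "omega")
    else:
        iou = IOUParams(theta.alpha, amp * np.sqrt(sigma2), "tau")
    return VarianceParams(G, iou, float(sigma2))
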