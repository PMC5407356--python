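"""Integrated Ornstein-Uhlenbeck (IOU) covariance kernel.

The IOU process ``W(t)`` is the time integral of a stationary
Ornstein-Uhlenbeck velocity process with mean-reversion rate ``alpha`` and
diffusion scale ``tau``.  It is the serial-correlation component of the
linear mixed IOU model for longitudinal biomarkers: nonstationary, with
``Var W(0) = 0``, and governed by a single *derivative tracking* parameter
``alpha`` — small ``alpha`` means a subject's trajectory keeps its slope
over long periods (strong tracking), large ``alpha`` means the increments
decorrelate quickly (weak tracking, approaching Brownian motion).

Closed forms (times ``s <= t``, all nonnegative)::

    Var W(t)       = (tau^2/alpha^3) (alpha t + e^{-alpha t} - 1)
    Cov(W(s),W(t)) = (tau^2/(2 alpha^3)) (2 alpha s + e^{-alpha s}
                     + e^{-alpha t} - 1 - e^{-alpha (t-s)})

Two limits anchor the parameterization:

* ``alpha -> inf`` with ``omega = tau^2/alpha^2`` fixed: Brownian motion,
  ``Cov -> omega * min(s, t)``.
* ``alpha -> 0`` with ``c = tau^2/(2 alpha)`` fixed: a random-slope
  conditional-independence model, ``Cov -> c * s * t``.

The amplitude may therefore be expressed either as ``tau`` (diffusion
scale) or as ``omega`` (Brownian-motion-limit scale); both are supported
throughout, with ``omega = tau^2 / alpha^2``.

Times are in months unless converted by the caller (see
:func:`mixediou.model_core.to_months`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "IOUParams",
    "IOUParameterization",
    "PARAMETERIZATIONS",
    "iou_variance",
    "iou_covariance",
    "iou_cov_matrix",
    "iou_cov_matrix_unit",
    "iou_cov_matrix_dalpha",
    "iou_cov_matrix_d2alpha",
    "rescale_equivalent",
    "convert_parameterization",
]

AmplitudeKind = Literal["tau", "omega"]
ScaleCoord = Literal["alpha", "log_alpha", "inv_alpha"]

# Switch-over for the Taylor expansion of f(u) = u + e^{-u} - 1; below this
# the direct evaluation loses ~8 digits to cancellation.
_SMALL_U = 1e-4


@dataclass(frozen=True)
class IOUParams:
    """IOU process parameters.

    Parameters
    ----------
    alpha : float
        Mean-reversion / derivative-tracking rate, in inverse time units
        (per month by default).  Must be positive.
    amplitude_value : float
        Value of the amplitude parameter. Must be positive.
    amplitude_kind : {"tau", "omega"}
        Whether ``amplitude_value`` is the diffusion scale ``tau`` or the
        Brownian-limit scale ``omega = tau^2/alpha^2``.
    """

    alpha: float
    amplitude_value: float
    amplitude_kind: AmplitudeKind = "omega"

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not np.isfinite(self.amplitude_value) or self.amplitude_value <= 0:
            raise ValueError(
                f"amplitude_value must be a positive finite real, got {self.amplitude_value}"
            )
        if self.amplitude_kind not in ("tau", "omega"):
            raise ValueError(f"amplitude_kind must be 'tau' or 'omega', got {self.amplitude_kind}")

    @property
    def omega(self) -> float:
        """Brownian-motion-limit scale ``omega = tau^2/alpha^2``."""
        if self.amplitude_kind == "omega":
            return self.amplitude_value
        return self.amplitude_value**2 / self.alpha**2

    @property
    def tau(self) -> float:
        """Diffusion scale ``tau = omega^{1/2} alpha``."""
        if self.amplitude_kind == "tau":
            return self.amplitude_value
        return float(np.sqrt(self.amplitude_value) * self.alpha)

    def as_omega(self) -> "IOUParams":
        return IOUParams(self.alpha, self.omega, "omega")

    def as_tau(self) -> "IOUParams":
        return IOUParams(self.alpha, self.tau, "tau")


@dataclass(frozen=True)
class IOUParameterization:
    """One of the six coordinate systems for the IOU parameter pair.

    ``scale_coord`` transforms ``alpha`` (identity, log, or reciprocal);
    ``amplitude_coord`` selects ``tau`` or ``omega`` as the amplitude.
    """

    scale_coord: ScaleCoord = "alpha"
    amplitude_coord: AmplitudeKind = "omega"

    def __post_init__(self) -> None:
        if self.scale_coord not in ("alpha", "log_alpha", "inv_alpha"):
            raise ValueError(f"unknown scale_coord {self.scale_coord!r}")
        if self.amplitude_coord not in ("tau", "omega"):
            raise ValueError(f"unknown amplitude_coord {self.amplitude_coord!r}")

    # -- alpha <-> coordinate ------------------------------------------------
    def alpha_to_coord(self, alpha: float) -> float:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.scale_coord == "alpha":
            return float(alpha)
        if self.scale_coord == "log_alpha":
            return float(np.log(alpha))
        return 1.0 / alpha

    def coord_to_alpha(self, c: float) -> float:
        if self.scale_coord == "alpha":
            if c <= 0:
                raise ValueError("alpha coordinate must be positive")
            return float(c)
        if self.scale_coord == "log_alpha":
            return float(np.exp(c))
        if c <= 0:
            raise ValueError("inv_alpha coordinate must be positive")
        return 1.0 / c

    def dalpha_dcoord(self, c: float) -> float:
        """d alpha / d coordinate, at coordinate value ``c``."""
        if self.scale_coord == "alpha":
            return 1.0
        if self.scale_coord == "log_alpha":
            return float(np.exp(c))
        return -1.0 / c**2

    def d2alpha_dcoord2(self, c: float) -> float:
        if self.scale_coord == "alpha":
            return 0.0
        if self.scale_coord == "log_alpha":
            return float(np.exp(c))
        return 2.0 / c**3

    def to_params(self, coords: Sequence[float]) -> IOUParams:
        c, a = float(coords[0]), float(coords[1])
        return IOUParams(self.coord_to_alpha(c), a, self.amplitude_coord)

    def from_params(self, p: IOUParams) -> np.ndarray:
        amp = p.tau if self.amplitude_coord == "tau" else p.omega
        return np.array([self.alpha_to_coord(p.alpha), amp])


#: All six parameterizations, in a fixed order.
PARAMETERIZATIONS: tuple[IOUParameterization, ...] = tuple(
    IOUParameterization(s, a)
    for s, a in product(("alpha", "log_alpha", "inv_alpha"), ("tau", "omega"))
)


def convert_parameterization(
    x: Sequence[float], from_: IOUParameterization, to: IOUParameterization
) -> np.ndarray:
    """Map a coordinate vector between two of the six parameterizations."""
    return to.from_params(from_.to_params(x))


# ---------------------------------------------------------------------------
# Stable kernel primitives.
#
# f(u) = u + e^{-u} - 1  (>= 0, ~u^2/2 near 0); f'(u) = 1 - e^{-u};
# f''(u) = e^{-u}.  The covariance factors, for u = alpha*min(s,t) and
# d = alpha*|t-s|, as
#
#   Cov = (omega / (2 alpha)) * g(u, d),
#   g(u, d) = f(u) (1 + e^{-d}) - u expm1(-d),
#
# which is a sum of nonnegative terms: no cancellation anywhere once f is
# evaluated stably.
# ---------------------------------------------------------------------------


def _f(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    out = u + np.expm1(-u)
    small = u < _SMALL_U
    if np.any(small):
        us = u[small]
        # 4-term Taylor series; relative error < 1e-20 for u < 1e-4
        out = np.array(out, copy=True)
        out[small] = us**2 / 2 - us**3 / 6 + us**4 / 24 - us**5 / 120
    return out


def _fp(u: np.ndarray) -> np.ndarray:
    """f'(u) = 1 - e^{-u}, stable (= -expm1(-u))."""
    return -np.expm1(-np.asarray(u, dtype=float))


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return t


def iou_variance(t, p: IOUParams):
    """Variance of the IOU process at time ``t`` (scalar or array)."""
    t = _check_times(t)
    return p.omega / p.alpha * _f(p.alpha * t)


def iou_covariance(s, t, p: IOUParams):
    """Covariance of the IOU process between times ``s`` and ``t``."""
    s = _check_times(s)
    t = _check_times(t)
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    a = p.alpha
    u = a * lo
    d = a * (hi - lo)
    g = _f(u) * (1.0 + np.exp(-d)) - u * np.expm1(-d)
    return p.omega / (2.0 * a) * g


def iou_cov_matrix(times, p: IOUParams) -> np.ndarray:
    """IOU Gram matrix on a vector of times (symmetric PSD)."""
    times = np.atleast_1d(_check_times(times))
    if times.size == 0:
        return np.empty((0, 0))
    s = times[:, None]
    t = times[None, :]
    return iou_covariance(s, t, p)


# -- unit-amplitude matrices and their alpha-derivatives --------------------
# Used by the REML engine: Gamma(alpha, omega) = omega * Gamma0(alpha), so
# derivative bookkeeping only needs d/dalpha of the unit matrix.


def iou_cov_matrix_unit(times: np.ndarray, alpha: float) -> np.ndarray:
    """IOU Gram matrix with ``omega = 1``."""
    return iou_cov_matrix(times, IOUParams(alpha, 1.0, "omega"))


def _ud(times: np.ndarray, alpha: float):
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lo = np.minimum(times[:, None], times[None, :])
    hi = np.maximum(times[:, None], times[None, :])
    return lo, hi - lo, alpha * lo, alpha * (hi - lo)


def iou_cov_matrix_dalpha(times: np.ndarray, alpha: float) -> np.ndarray:
    """d/dalpha of the unit-omega IOU Gram matrix."""
    lo, dd, u, d = _ud(times, alpha)
    ed = np.exp(-d)
    f = _f(u)
    fp = _fp(u)
    g = f * (1.0 + ed) - u * np.expm1(-d)
    g_u = fp * (1.0 + ed) - np.expm1(-d)
    g_d = ed * (u - f)
    # Cov = g/(2 alpha); chain rule through u = alpha*lo, d = alpha*dd
    return 0.5 * (-g / alpha**2 + (g_u * lo + g_d * dd) / alpha)


def iou_cov_matrix_d2alpha(times: np.ndarray, alpha: float) -> np.ndarray:
    """d^2/dalpha^2 of the unit-omega IOU Gram matrix."""
    lo, dd, u, d = _ud(times, alpha)
    ed = np.exp(-d)
    eu = np.exp(-u)
    f = _f(u)
    fp = _fp(u)
    g = f * (1.0 + ed) - u * np.expm1(-d)
    g_u = fp * (1.0 + ed) - np.expm1(-d)
    g_d = ed * (u - f)
    g_uu = eu * (1.0 + ed)
    g_ud = ed * eu
    g_dd = -g_d
    lin = g_u * lo + g_d * dd
    quad = g_uu * lo**2 + 2.0 * g_ud * lo * dd + g_dd * dd**2
    return 0.5 * (2.0 * g / alpha**3 - 2.0 * lin / alpha**2 + quad / alpha)


def rescale_equivalent(p: IOUParams, Q: float) -> IOUParams:
    """IOU parameters equivalent under a time rescaling ``t -> Q t``.

    The IOU covariance is nonstationary, so a design observed at ``Q``-times
    wider spacing carries the same covariance matrix when ``alpha -> alpha/Q``
    and ``omega -> omega/Q`` (equivalently ``tau^2 -> tau^2/Q^3``)::

        iou_cov_matrix(Q * times, rescale_equivalent(p, Q))
            == iou_cov_matrix(times, p)

    E.g. monthly-spacing weak tracking ``alpha = 20.7`` corresponds to
    ``alpha = 1.725`` on a yearly grid (``Q = 12``).
    """
    if not np.isfinite(Q) or Q <= 0:
        raise ValueError(f"Q must be a positive finite real, got {Q}")
    out = IOUParams(p.alpha / Q, p.omega / Q, "omega")
    return out if p.amplitude_kind == "omega" else out.as_tau()
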