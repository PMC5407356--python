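"""Simulators for balanced and unbalanced longitudinal IOU designs.

Balanced designs follow the HIV-cohort template: ``m`` subjects, ``n``
fourth-root CD4 responses each, observed every ``k`` months from the
natural time zero (seroconversion), generated from a linear mixed IOU
model with a linear population slope.

Unbalanced designs reproduce a 1489-subject cohort layout (150 subjects
with 2 measurements, 224 with 5, 372 with 10, 743 with 20 — 20,000
observations in total) under two visit-time mechanisms:

* *target visits* — intended 3-monthly follow-up; consecutive intervals are
  Normal in days (mean 91.3 d, SD 31.07 d, so 95% of intervals fall
  between about 1 and 5 months), redrawn below the 7-day floor;
* *intermittent dropout* — subjects with few measurements have long,
  lognormally distributed gaps (95% of intervals between 6 and 18 months);
  subjects with 10 or 20 measurements follow the target-visit day model.

Visit times are independent of responses, so the missingness they induce
is non-informative (MAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import yaml

from .iou_cov import IOUParams
from .model_core import LongDataset, VarianceParams, marginal_cov

__all__ = [
    "BalancedDesign",
    "UnbalancedDesign",
    "TruthParams",
    "tracking_truth",
    "gen_balanced",
    "gen_target_visits",
    "gen_intermittent_dropout",
    "sample_response",
]

DAYS_PER_MONTH = 30.4375

# Scenario-1 interval model (days): Normal centred on the 3-month target
# with 95% mass on [30.4, 152.2] days (1 to 5 months).
TARGET_MEAN_DAYS = 91.3
TARGET_SD_DAYS = 31.07
MIN_INTERVAL_DAYS = 7.0

# Scenario-2 interval model (months) for sparsely measured subjects:
# lognormal with 95% mass on [6, 18] months (median sqrt(6*18)).
LOGNORM_MU = float(np.log(np.sqrt(6.0 * 18.0)))
LOGNORM_SIGMA = float((np.log(18.0) - np.log(6.0)) / (2 * 1.959964))


@dataclass(frozen=True)
class BalancedDesign:
    """``m`` subjects x ``n`` visits at ``k``-month spacing."""

    m: int
    n: int
    k: float
    offset: float = 0.0  # first visit at `offset` months (0 => t = k*(j-1))

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.k <= 0:
            raise ValueError("need m,n >= 1 and k > 0")

    def times(self) -> np.ndarray:
        return self.offset + self.k * np.arange(self.n, dtype=float)


@dataclass(frozen=True)
class UnbalancedDesign:
    """Groups of (subject count, measurements per subject)."""

    groups: tuple[tuple[int, int], ...] = ((150, 2), (224, 5), (372, 10), (743, 20))
    interval_model: Literal["target_visits", "intermittent_dropout"] = "target_visits"
    min_interval_days: float = MIN_INTERVAL_DAYS

    def __post_init__(self) -> None:
        for cnt, n in self.groups:
            if cnt < 1 or n < 1:
                raise ValueError("group counts and sizes must be positive")

    @property
    def n_subjects(self) -> int:
        return sum(c for c, _ in self.groups)

    @property
    def n_obs(self) -> int:
        return sum(c * n for c, n in self.groups)


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters: fixed effects plus the variance set."""

    beta: np.ndarray
    variance: VarianceParams
    label: str = ""


def tracking_truth(level: str, random: str = "intercept",
                   G: np.ndarray | None = None) -> TruthParams:
    """Truth set for a named derivative-tracking level (weak/moderate/strong).

    Values are loaded from the package's ``tracking.yaml`` transcription
    table.  ``G`` overrides the random-effects covariance (e.g. for
    random-slope models); by default a random intercept with variance
    0.1156 is used.
    """
    cfg = yaml.safe_load(resources.files("mixediou").joinpath("tracking.yaml").read_text())
    try:
        lvl = cfg["tracking"][level]
    except KeyError:
        raise ValueError(f"unknown tracking level {level!r}; choose from {sorted(cfg['tracking'])}")
    if G is None:
        G = np.array([[cfg["sigma_b2"]]]) if random == "intercept" else np.array(
            [[cfg["sigma_b2"], 0.0], [0.0, 1e-4]]
        )
    vp = VarianceParams(G, IOUParams(lvl["alpha"], lvl["omega"], "omega"), cfg["sigma2"])
    return TruthParams(np.asarray(cfg["beta"], dtype=float), vp, label=level)


# ---------------------------------------------------------------------------
# Visit-time generation
# ---------------------------------------------------------------------------


def _draw_intervals_days(rng: np.random.Generator, n: int, min_days: float) -> np.ndarray:
    """Target-visit intervals in days, redrawn until >= the floor."""
    out = rng.normal(TARGET_MEAN_DAYS, TARGET_SD_DAYS, size=n)
    bad = out < min_days
    while np.any(bad):
        out[bad] = rng.normal(TARGET_MEAN_DAYS, TARGET_SD_DAYS, size=int(bad.sum()))
        bad = out < min_days
    return out


def _draw_intervals_lognormal_months(rng: np.random.Generator, n: int, min_days: float) -> np.ndarray:
    """Intermittent-dropout intervals in months for sparse subjects."""
    min_months = min_days / DAYS_PER_MONTH
    out = rng.lognormal(LOGNORM_MU, LOGNORM_SIGMA, size=n)
    bad = out < min_months
    while np.any(bad):
        out[bad] = rng.lognormal(LOGNORM_MU, LOGNORM_SIGMA, size=int(bad.sum()))
        bad = out < min_months
    return out


def gen_target_visits(design: UnbalancedDesign, seed) -> list[np.ndarray]:
    """Per-subject visit-time vectors (months) under the target-visit model."""
    rng = np.random.default_rng(seed)
    times = []
    for count, n in design.groups:
        for _ in range(count):
            gaps = _draw_intervals_days(rng, n - 1, design.min_interval_days) / DAYS_PER_MONTH
            times.append(np.concatenate([[0.0], np.cumsum(gaps)]))
    return times


def gen_intermittent_dropout(design: UnbalancedDesign, seed) -> list[np.ndarray]:
    """Per-subject visit times (months) under the intermittent-dropout model."""
    rng = np.random.default_rng(seed)
    times = []
    for count, n in design.groups:
        sparse = n <= 5
        for _ in range(count):
            if sparse:
                gaps = _draw_intervals_lognormal_months(rng, n - 1, design.min_interval_days)
            else:
                gaps = _draw_intervals_days(rng, n - 1, design.min_interval_days) / DAYS_PER_MONTH
            times.append(np.concatenate([[0.0], np.cumsum(gaps)]))
    return times


def gen_unbalanced_times(design: UnbalancedDesign, seed) -> list[np.ndarray]:
    if design.interval_model == "target_visits":
        return gen_target_visits(design, seed)
    return gen_intermittent_dropout(design, seed)


# ---------------------------------------------------------------------------
# Response sampling
# ---------------------------------------------------------------------------


def _design_matrices(t: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(t.size), t])
    Z = X[:, :q].copy()
    return X, Z


def sample_response(times: list[np.ndarray], truth: TruthParams, seed) -> LongDataset:
    """Draw responses per subject from N(X beta, V) given visit times."""
    rng = np.random.default_rng(seed)
    q = truth.variance.q
    ids, ys, Xs, Zs = [], [], [], []
    chol_cache: dict[bytes, np.ndarray] = {}
    for i, t in enumerate(times):
        X, Z = _design_matrices(t, q)
        key = t.tobytes()
        L = chol_cache.get(key)
        if L is None:
            V = marginal_cov(t, truth.variance, Z)
            L = np.linalg.cholesky(V)
            chol_cache[key] = L
        y = X @ truth.beta + L @ rng.standard_normal(t.size)
        ids.append(i)
        ys.append(y)
        Xs.append(X)
        Zs.append(Z)
    return LongDataset(ids, list(times), ys, Xs, Zs, ["const", "time"])


def gen_balanced(design: BalancedDesign, truth: TruthParams, seed) -> LongDataset:
    """Balanced dataset: shared time grid, vectorized multivariate draws."""
    t = design.times()
    q = truth.variance.q
    X, Z = _design_matrices(t, q)
    V = marginal_cov(t, truth.variance, Z)
    L = np.linalg.cholesky(V)
    rng = np.random.default_rng(seed)
    mean = X @ truth.beta
    Y = mean[None, :] + rng.standard_normal((design.m, design.n)) @ L.T
    ids = list(range(design.m))
    times = [t] * design.m
    ys = [Y[i] for i in range(design.m)]
    return LongDataset(ids, times, ys, [X] * design.m, [Z] * design.m, ["const", "time"])


def gen_unbalanced(design: UnbalancedDesign, truth: TruthParams, seed) -> LongDataset:
    """Unbalanced dataset: visit times then responses, from one seed."""
    ss = np.random.SeedSequence(seed)
    t_seed, y_seed = ss.spawn(2)
    times = gen_unbalanced_times(design, t_seed)
    return sample_response(times, truth, y_seed)
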