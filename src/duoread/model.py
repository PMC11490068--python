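"""Probabilistic core of the reader model.

Each reader ``j`` carries two fixed effects on the logit scale: ``r_neg``
governs recall decisions on cancer-free (negative) examinations and
``r_pos`` on cancer (positive) examinations.  Each examination adds a
latent case effect ``C ~ Normal(0, sigma^2)`` shared by every reader who
assesses it; the class-specific scales are ``sigma_neg`` and ``sigma_pos``.
The conditional probability that reader ``j`` flags case ``k`` is

    a_jk = logistic(r_j + C_k)

and marginal (per-reader) rates are expectations of ``a_jk`` over the case
effect distribution, evaluated here by Monte Carlo integration.  Positive
and negative cases are treated as completely independent: they never share
case effects, and the two classes can be analyzed separately.

Disagreement within a reader pair on a case is ``a1(1-a2) + a2(1-a1)``,
and the pair's combined recall probability — any reader flagging counts
as a recall for the pair — is ``a1 + a2 - a1*a2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError

__all__ = [
    "ReaderEffect",
    "CaseEffectScale",
    "ModelParameters",
    "MonteCarloConfig",
    "logistic_link",
    "conditional_abnormal_probability",
    "marginal_abnormal_rate",
    "conditional_disagreement",
    "marginal_disagreement",
    "paired_positive_probability",
    "case_effect_sample",
]


def _require_finite(name: str, value) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return value


def _require_probability(name: str, value) -> float:
    value = _require_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise InvalidArgumentError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ReaderEffect:
    """Fixed logit-scale effects of one reader (negative and positive cases)."""

    reader_id: str
    r_neg: float
    r_pos: float

    def __post_init__(self) -> None:
        _require_finite("r_neg", self.r_neg)
        _require_finite("r_pos", self.r_pos)


@dataclass(frozen=True)
class CaseEffectScale:
    """Standard deviations of the latent case effects, one per case class."""

    sigma_neg: float
    sigma_pos: float

    def __post_init__(self) -> None:
        for name in ("sigma_neg", "sigma_pos"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise InvalidArgumentError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: every reader's effects plus the case-effect scales."""

    readers: tuple[ReaderEffect, ...]
    scale: CaseEffectScale

    def __post_init__(self) -> None:
        object.__setattr__(self, "readers", tuple(self.readers))
        if len(self.readers) < 1:
            raise InvalidArgumentError("ModelParameters needs at least one reader")
        ids = [r.reader_id for r in self.readers]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("reader_ids must be unique")

    @property
    def reader_ids(self) -> tuple[str, ...]:
        return tuple(r.reader_id for r in self.readers)

    @property
    def r_neg(self) -> np.ndarray:
        return np.array([r.r_neg for r in self.readers], dtype=float)

    @property
    def r_pos(self) -> np.ndarray:
        return np.array([r.r_pos for r in self.readers], dtype=float)

    def effect(self, reader_id: str) -> ReaderEffect:
        for r in self.readers:
            if r.reader_id == reader_id:
                return r
        raise KeyError(reader_id)


@dataclass(frozen=True)
class MonteCarloConfig:
    """Size and seed of the case-effect sample used for marginalization.

    The default sample size of 1,000,000 keeps the coefficient of variation
    of marginal-rate estimates well below 1% at screening-realistic
    operating points; fitting and tests may configure it down.
    """

    n_samples: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_samples) < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        object.__setattr__(self, "n_samples", int(self.n_samples))
        object.__setattr__(self, "seed", int(self.seed))


def case_effect_sample(mc: MonteCarloConfig) -> np.ndarray:
    """Standard-normal draws underlying the case-effect integral.

    The same array can be reused across likelihood evaluations (common
    random numbers), which makes the Monte-Carlo likelihood surface
    deterministic and lets a derivative-free optimizer converge.
    """
    return np.random.default_rng(mc.seed).standard_normal(mc.n_samples)


def logistic_link(q):
    """Logistic link ``exp(q) / (1 + exp(q))``, overflow-safe for large ``|q|``."""
    arr = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("logistic_link requires finite input")
    out = expit(arr)
    return float(out) if np.isscalar(q) or arr.ndim == 0 else out


def conditional_abnormal_probability(effect: float, case_effect: float):
    """Probability a reader flags a specific case: logistic(r + C)."""
    r = np.asarray(effect, dtype=float)
    c = np.asarray(case_effect, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(c))):
        raise InvalidArgumentError("effect and case_effect must be finite")
    return logistic_link(r + c)


def marginal_abnormal_rate(
    effect: float, sigma: float, mc: MonteCarloConfig = MonteCarloConfig()
) -> float:
    """Per-reader abnormal-interpretation rate, marginalized over case effects.

    Evaluates ``E[logistic(r + sigma Z)]`` with ``Z`` standard normal by
    Monte Carlo with ``mc.n_samples`` draws from ``mc.seed``.  ``sigma = 0``
    short-circuits to the exact value ``logistic(r)``.
    """
    r = _require_finite("effect", effect)
    sigma = _require_finite("sigma", sigma)
    if sigma < 0:
        raise InvalidArgumentError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0.0:
        return float(expit(r))
    z = case_effect_sample(mc)
    return float(np.mean(expit(r + sigma * z)))


def conditional_disagreement(a1: float, a2: float):
    """Probability two readers disagree on one case: a1(1-a2) + a2(1-a1)."""
    p1 = np.asarray(a1, dtype=float)
    p2 = np.asarray(a2, dtype=float)
    for name, p in (("a1", p1), ("a2", p2)):
        if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise InvalidArgumentError(f"{name} must lie in [0, 1]")
    out = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float(out) if out.ndim == 0 else out


def marginal_disagreement(
    r1: float, r2: float, sigma: float, mc: MonteCarloConfig = MonteCarloConfig()
) -> float:
    """Pair disagreement rate marginalized over the shared case effect.

    Within each Monte-Carlo draw the same case effect is applied to both
    readers — the case is shared, which is what induces the positive
    correlation between the two assessments.  ``sigma = 0`` returns the
    closed form on the (then equal to conditional) marginal rates.
    """
    r1 = _require_finite("r1", r1)
    r2 = _require_finite("r2", r2)
    sigma = _require_finite("sigma", sigma)
    if sigma < 0:
        raise InvalidArgumentError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0.0:
        return float(conditional_disagreement(expit(r1), expit(r2)))
    z = case_effect_sample(mc)
    a1 = expit(r1 + sigma * z)
    a2 = expit(r2 + sigma * z)
    return float(np.mean(a1 * (1.0 - a2) + a2 * (1.0 - a1)))


def paired_positive_probability(a1: float, a2: float):
    """Pair recall probability under the any-reader-flags rule: a1 + a2 - a1*a2."""
    p1 = np.asarray(a1, dtype=float)
    p2 = np.asarray(a2, dtype=float)
    for name, p in (("a1", p1), ("a2", p2)):
        if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise InvalidArgumentError(f"{name} must lie in [0, 1]")
    out = p1 + p2 - p1 * p2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Vectorized internals shared with the fitting module.  They take a fixed
# standard-normal sample so that one draw serves a whole optimization.
# ---------------------------------------------------------------------------


def _marginal_rates(r: np.ndarray, sigma: float, z: np.ndarray) -> np.ndarray:
    """Marginal rate of each reader effect in ``r`` given the shared sample ``z``."""
    if sigma == 0.0:
        return expit(np.asarray(r, dtype=float))
    return expit(np.asarray(r, dtype=float)[:, None] + sigma * z[None, :]).mean(axis=1)


def _pair_disagreement_rates(
    r1: np.ndarray, r2: np.ndarray, sigma: float, z: np.ndarray
) -> np.ndarray:
    """Marginal disagreement rate for each pair (r1[i], r2[i]) with shared case effects."""
    r1 = np.asarray(r1, dtype=float)[:, None]
    r2 = np.asarray(r2, dtype=float)[:, None]
    if sigma == 0.0:
        a1 = expit(r1[:, 0])
        a2 = expit(r2[:, 0])
        return a1 * (1.0 - a2) + a2 * (1.0 - a1)
    a1 = expit(r1 + sigma * z[None, :])
    a2 = expit(r2 + sigma * z[None, :])
    return (a1 * (1.0 - a2) + a2 * (1.0 - a1)).mean(axis=1)
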