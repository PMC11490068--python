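"""Reader pairing strategies and the screening-day scheduler.

Seven pairing strategies are supported, operating on each day's reader
pool using the modeled marginal TPR/FPR as metrics:

* similar TPR / similar FPR / similar composite — sort readers by the
  metric and pair consecutive readers (1st with 2nd, 3rd with 4th, ...),
  which is also the perfect matching minimizing the total within-pair
  metric gap;
* opposite TPR / opposite FPR / opposite composite — split the sorted pool
  at the median and pair the i-th lowest of the lower half with the i-th
  lowest of the upper half, so every pair straddles the median;
* random — a uniformly random perfect matching.

The composite score is ``TPR + FPR * slope`` where the slope comes from an
ordinary-least-squares regression of TPR on FPR across the pool, capturing
the usual positive TPR/FPR association in one ranking axis.

The scheduler mimics a year of organized screening: by default 365 days of
4,000 examinations in 32 batches; each day a random set of 16 readers is
drawn from the population, formed into 8 pairs by the chosen strategy, and
batches are assigned round-robin so every pair reads the same number of
batches.  The reader-pool stream is seeded independently of the pairing
stream, so schedules built for different strategies from the same seed
share their days, pools, and examinations and differ only in the pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRegressionError, InvalidArgumentError, InvalidPoolError
from .model import ModelParameters

__all__ = [
    "PairingStrategy",
    "ScheduleConfig",
    "DaySchedule",
    "similarity_pairing",
    "opposite_pairing",
    "composite_scores",
    "random_pairing",
    "build_year_schedule",
]

_POOL_STREAM = 101
_PAIRING_STREAM = 202


class PairingStrategy(str, Enum):
    SIMILAR_TPR = "similar_tpr"
    SIMILAR_FPR = "similar_fpr"
    SIMILAR_COMPOSITE = "similar_composite"
    OPPOSITE_TPR = "opposite_tpr"
    OPPOSITE_FPR = "opposite_fpr"
    OPPOSITE_COMPOSITE = "opposite_composite"
    RANDOM = "random"


def _sorted_ids(metric_by_reader: Mapping[str, float]) -> list[str]:
    n = len(metric_by_reader)
    if n < 2 or n % 2:
        raise InvalidPoolError(f"pool must have an even number (>= 2) of readers, got {n}")
    # ties broken by reader id so the ordering is total and stable
    return [k for k, _ in sorted(metric_by_reader.items(), key=lambda kv: (kv[1], str(kv[0])))]


def similarity_pairing(metric_by_reader: Mapping[str, float]) -> list[tuple[str, str]]:
    """Pair consecutive readers in metric order (minimal total within-pair gap)."""
    order = _sorted_ids(metric_by_reader)
    return [(order[i], order[i + 1]) for i in range(0, len(order), 2)]


def opposite_pairing(metric_by_reader: Mapping[str, float]) -> list[tuple[str, str]]:
    """Pair the i-th lowest below-median reader with the i-th lowest above-median one."""
    order = _sorted_ids(metric_by_reader)
    half = len(order) // 2
    return [(order[i], order[i + half]) for i in range(half)]


def composite_scores(
    tpr_by_reader: Mapping[str, float], fpr_by_reader: Mapping[str, float]
) -> dict[str, float]:
    """Composite ranking score ``TPR + FPR * slope`` per reader.

    The slope is the OLS slope of TPR regressed on FPR across the pool.
    Identical FPR values leave the regression undefined.
    """
    ids = list(tpr_by_reader)
    if set(ids) != set(fpr_by_reader):
        raise InvalidArgumentError("tpr and fpr mappings must cover the same readers")
    if len(ids) < 2:
        raise InvalidArgumentError("composite scores need at least 2 readers")
    fpr = np.array([fpr_by_reader[i] for i in ids], dtype=float)
    tpr = np.array([tpr_by_reader[i] for i in ids], dtype=float)
    if np.ptp(fpr) == 0.0:
        raise DegenerateRegressionError("all FPR values identical: slope undefined")
    slope = float(np.polyfit(fpr, tpr, 1)[0])
    return {i: float(t + f * slope) for i, t, f in zip(ids, tpr, fpr)}


def random_pairing(
    reader_ids: Sequence[str], rng: np.random.Generator | int
) -> list[tuple[str, str]]:
    """Uniformly random perfect matching of the pool, reproducible from the seed."""
    n = len(reader_ids)
    if n < 2 or n % 2:
        raise InvalidPoolError(f"pool must have an even number (>= 2) of readers, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = [reader_ids[i] for i in rng.permutation(n)]
    return [(perm[i], perm[i + 1]) for i in range(0, n, 2)]


@dataclass(frozen=True)
class ScheduleConfig:
    """Shape of the simulated screening year."""

    n_days: int = 365
    exams_per_day: int = 4000
    batches_per_day: int = 32
    readers_per_day: int = 16
    prevalence: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.exams_per_day < 1:
            raise InvalidArgumentError("n_days and exams_per_day must be >= 1")
        if self.readers_per_day < 2 or self.readers_per_day % 2:
            raise InvalidArgumentError("readers_per_day must be even and >= 2")
        n_pairs = self.readers_per_day // 2
        if self.batches_per_day % n_pairs:
            raise InvalidArgumentError(
                "batches_per_day must be divisible by readers_per_day/2 "
                f"({self.batches_per_day} % {n_pairs} != 0)"
            )
        if self.exams_per_day % self.batches_per_day:
            raise InvalidArgumentError(
                "exams_per_day must be divisible by batches_per_day "
                f"({self.exams_per_day} % {self.batches_per_day} != 0)"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidArgumentError(f"prevalence must be in (0, 1), got {self.prevalence}")

    @property
    def n_pairs_per_day(self) -> int:
        return self.readers_per_day // 2

    @property
    def exams_per_batch(self) -> int:
        return self.exams_per_day // self.batches_per_day


@dataclass(frozen=True)
class DaySchedule:
    """One simulated screening day: pool, pairs, and exam/batch assignment maps."""

    day: int
    reader_ids: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    batch_to_pair: np.ndarray  # batch index -> pair index
    exam_to_batch: np.ndarray  # exam index -> batch index

    def pair_of_exam(self) -> np.ndarray:
        return self.batch_to_pair[self.exam_to_batch]


def _rates_lookup(rates) -> tuple[dict[str, float], dict[str, float]]:
    if isinstance(rates, pd.DataFrame):
        if "reader_id" in rates.columns:
            rates = rates.set_index("reader_id")
        return rates["tpr"].to_dict(), rates["fpr"].to_dict()
    # mapping reader_id -> (tpr, fpr)
    tpr = {k: v[0] for k, v in rates.items()}
    fpr = {k: v[1] for k, v in rates.items()}
    return tpr, fpr


def build_year_schedule(
    cfg: ScheduleConfig,
    population: ModelParameters,
    strategy: PairingStrategy | str,
    fitted_rates,
    seed: int | None = None,
) -> list[DaySchedule]:
    """Build one schedule per day for a whole simulated year.

    ``fitted_rates`` supplies the modeled marginal TPR/FPR used as pairing
    metrics — a DataFrame with columns ``tpr``/``fpr`` indexed by reader id
    (or with a ``reader_id`` column), or a mapping id -> (tpr, fpr).  Reader
    pools are drawn from a stream independent of the pairing stream, so all
    strategies built from the same seed see identical pools and exams.
    """
    strategy = PairingStrategy(strategy)
    ids = list(population.reader_ids)
    if len(ids) < cfg.readers_per_day:
        raise InvalidArgumentError(
            f"population has {len(ids)} readers, need >= {cfg.readers_per_day}"
        )
    tpr, fpr = _rates_lookup(fitted_rates)
    missing = [i for i in ids if i not in tpr or i not in fpr]
    if missing:
        raise InvalidArgumentError(f"fitted_rates missing reader(s) {missing[:5]}")
    seed = cfg.seed if seed is None else seed
    pool_rng = np.random.default_rng(np.random.SeedSequence([seed, _POOL_STREAM]))
    pair_rng = np.random.default_rng(np.random.SeedSequence([seed, _PAIRING_STREAM]))

    n_pairs = cfg.n_pairs_per_day
    batch_to_pair = np.arange(cfg.batches_per_day) % n_pairs
    exam_to_batch = np.arange(cfg.exams_per_day) // cfg.exams_per_batch

    days = []
    for day in range(cfg.n_days):
        pool = [ids[i] for i in pool_rng.choice(len(ids), cfg.readers_per_day, replace=False)]
        pool_tpr = {i: tpr[i] for i in pool}
        pool_fpr = {i: fpr[i] for i in pool}
        if strategy is PairingStrategy.SIMILAR_TPR:
            pairs = similarity_pairing(pool_tpr)
        elif strategy is PairingStrategy.OPPOSITE_TPR:
            pairs = opposite_pairing(pool_tpr)
        elif strategy is PairingStrategy.SIMILAR_FPR:
            pairs = similarity_pairing(pool_fpr)
        elif strategy is PairingStrategy.OPPOSITE_FPR:
            pairs = opposite_pairing(pool_fpr)
        elif strategy is PairingStrategy.SIMILAR_COMPOSITE:
            pairs = similarity_pairing(composite_scores(pool_tpr, pool_fpr))
        elif strategy is PairingStrategy.OPPOSITE_COMPOSITE:
            pairs = opposite_pairing(composite_scores(pool_tpr, pool_fpr))
        else:
            pairs = random_pairing(pool, pair_rng)
        days.append(
            DaySchedule(
                day=day,
                reader_ids=tuple(pool),
                pairs=tuple(pairs),
                batch_to_pair=batch_to_pair,
                exam_to_batch=exam_to_batch,
            )
        )
    return days
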