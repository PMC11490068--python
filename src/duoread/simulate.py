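"""Screening simulation: group endpoints, outcome sampling, and inference.

Given a schedule and model parameters, each examination receives a case
status (Bernoulli at the configured prevalence), a single latent case
effect shared by its readers, the two conditional recall probabilities
``a1, a2``, and the pair recall probability ``p = a1 + a2 - a1*a2`` (any
reader flagging counts as a pair recall).  The group endpoints are the
means of ``p`` over positive exams (group TPR) and negative exams (group
FPR); the individual-reading benchmark uses a single reader's ``a``
instead.

The case-status and case-effect streams are derived from the master seed
and the day index only — never from the pairing strategy — so strategies
compared at the same seed face literally identical examinations.  A SHA-256
checksum over those streams is attached to every outcome so the invariant
can be asserted.

Uncertainty is quantified by bootstrap resampling of examinations,
stratified by case status (TPR and FPR are stratum means), with percentile
intervals Bonferroni-adjusted for the number of planned comparisons.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidArgumentError
from .model import ModelParameters
from .pairing import DaySchedule, PairingStrategy, ScheduleConfig, build_year_schedule

__all__ = [
    "ExamOutcome",
    "StrategyOutcome",
    "BinaryOutcomeCounts",
    "simulate_strategy",
    "simulate_individual",
    "sample_binary_outcomes",
    "bootstrap_group_rates",
    "recall_and_cdr",
    "run_strategy_comparison",
    "RESULT_COLUMNS",
]

_STATUS_STREAM = 11
_CASE_NEG_STREAM = 12
_CASE_POS_STREAM = 13
_DECISION_STREAM = 14
_BOOT_STREAM = 15

RESULT_COLUMNS = [
    "strategy",
    "tpr",
    "tpr_lo",
    "tpr_hi",
    "fpr",
    "fpr_lo",
    "fpr_hi",
    "tp",
    "fp",
    "concordant_positive",
    "concordant_negative",
    "discordant",
    "rr_per_1000",
    "cdr_per_1000",
    "exam_checksum",
]


@dataclass(frozen=True)
class ExamOutcome:
    """One simulated examination's probabilities under its assigned pair."""

    exam_id: str
    case_status: str
    a1: float
    a2: float
    p_positive: float


@dataclass
class StrategyOutcome:
    """Group endpoints of one strategy (or of individual reading)."""

    strategy: str
    tpr: float
    fpr: float
    n_pos: int
    n_neg: int
    exam_checksum: str
    tpr_ci: tuple[float, float] | None = None
    fpr_ci: tuple[float, float] | None = None
    tp: int | None = None
    fp: int | None = None
    concordant_positive: int | None = None
    concordant_negative: int | None = None
    discordant: int | None = None
    rr_per_1000: float | None = None
    cdr_per_1000: float | None = None


@dataclass(frozen=True)
class BinaryOutcomeCounts:
    """Sampled 0/1 decisions classified into concordance categories."""

    concordant_positive: int
    concordant_negative: int
    discordant: int
    tp: int
    fp: int


def _day_case_stream(seed: int, day: int, n: int, prevalence: float, sigma_neg: float, sigma_pos: float):
    """Case statuses and shared case effects for one day, strategy-independent."""
    status = (
        np.random.default_rng(np.random.SeedSequence([seed, _STATUS_STREAM, day])).random(n)
        < prevalence
    )
    z_neg = np.random.default_rng(
        np.random.SeedSequence([seed, _CASE_NEG_STREAM, day])
    ).standard_normal(n)
    z_pos = np.random.default_rng(
        np.random.SeedSequence([seed, _CASE_POS_STREAM, day])
    ).standard_normal(n)
    c = np.where(status, sigma_pos * z_pos, sigma_neg * z_neg)
    return status, c


def _effect_arrays(params: ModelParameters) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    index = {rid: i for i, rid in enumerate(params.reader_ids)}
    return index, params.r_neg, params.r_pos


def _finalize(
    name: str, frames: list[pd.DataFrame], checksum: "hashlib._Hash"
) -> tuple[pd.DataFrame, StrategyOutcome]:
    df = pd.concat(frames, ignore_index=True)
    pos = df["case_status"] == "positive"
    n_pos = int(pos.sum())
    n_neg = int(len(df) - n_pos)
    tpr = float(df.loc[pos, "p_positive"].mean()) if n_pos else float("nan")
    fpr = float(df.loc[~pos, "p_positive"].mean()) if n_neg else float("nan")
    out = StrategyOutcome(
        strategy=name,
        tpr=tpr,
        fpr=fpr,
        n_pos=n_pos,
        n_neg=n_neg,
        exam_checksum=checksum.hexdigest(),
    )
    return df, out


def simulate_strategy(
    params: ModelParameters,
    schedule: Sequence[DaySchedule],
    prevalence: float,
    seed: int,
    strategy_name: str = "paired",
) -> tuple[pd.DataFrame, StrategyOutcome]:
    """Run the paired simulation over a schedule.

    Returns the per-exam outcome table (``day, exam_id, case_status,
    reader_id_1, reader_id_2, a1, a2, p_positive``) and the group endpoint
    summary.  A stratum with zero exams yields NaN for its rate rather than
    a fabricated value.
    """
    if not 0.0 < prevalence < 1.0:
        raise InvalidArgumentError("prevalence must be in (0, 1)")
    index, r_neg, r_pos = _effect_arrays(params)
    checksum = hashlib.sha256()
    frames = []
    for day in schedule:
        n = len(day.exam_to_batch)
        status, c = _day_case_stream(
            seed, day.day, n, prevalence, params.scale.sigma_neg, params.scale.sigma_pos
        )
        checksum.update(status.tobytes())
        checksum.update(c.tobytes())
        pair_idx = day.pair_of_exam()
        i1 = np.array([index[p[0]] for p in day.pairs])[pair_idx]
        i2 = np.array([index[p[1]] for p in day.pairs])[pair_idx]
        e1 = np.where(status, r_pos[i1], r_neg[i1])
        e2 = np.where(status, r_pos[i2], r_neg[i2])
        a1 = expit(e1 + c)
        a2 = expit(e2 + c)
        p = a1 + a2 - a1 * a2
        ids = np.array(params.reader_ids)
        frames.append(
            pd.DataFrame(
                {
                    "day": day.day,
                    "exam_id": [f"D{day.day:03d}E{i:05d}" for i in range(n)],
                    "case_status": np.where(status, "positive", "negative"),
                    "reader_id_1": ids[i1],
                    "reader_id_2": ids[i2],
                    "a1": a1,
                    "a2": a2,
                    "p_positive": p,
                }
            )
        )
    return _finalize(strategy_name, frames, checksum)


def simulate_individual(
    params: ModelParameters,
    schedule: Sequence[DaySchedule],
    prevalence: float,
    seed: int,
) -> tuple[pd.DataFrame, StrategyOutcome]:
    """Single-reading benchmark on the same examinations and case effects.

    Each batch is assigned one of the day's readers round-robin, so reader
    loads stay balanced; the exam streams are identical to those seen by
    the paired strategies at the same seed.
    """
    if not 0.0 < prevalence < 1.0:
        raise InvalidArgumentError("prevalence must be in (0, 1)")
    index, r_neg, r_pos = _effect_arrays(params)
    checksum = hashlib.sha256()
    frames = []
    for day in schedule:
        n = len(day.exam_to_batch)
        status, c = _day_case_stream(
            seed, day.day, n, prevalence, params.scale.sigma_neg, params.scale.sigma_pos
        )
        checksum.update(status.tobytes())
        checksum.update(c.tobytes())
        n_readers = len(day.reader_ids)
        reader_of_batch = np.arange(len(day.batch_to_pair)) % n_readers
        ridx = np.array([index[r] for r in day.reader_ids])[reader_of_batch[day.exam_to_batch]]
        e = np.where(status, r_pos[ridx], r_neg[ridx])
        a = expit(e + c)
        ids = np.array(params.reader_ids)
        frames.append(
            pd.DataFrame(
                {
                    "day": day.day,
                    "exam_id": [f"D{day.day:03d}E{i:05d}" for i in range(n)],
                    "case_status": np.where(status, "positive", "negative"),
                    "reader_id": ids[ridx],
                    "p_positive": a,
                }
            )
        )
    return _finalize("individual", frames, checksum)


def sample_binary_outcomes(outcomes: pd.DataFrame, seed: int) -> BinaryOutcomeCounts:
    """Sample 0/1 decisions from the per-exam probabilities.

    For paired outcomes (columns ``a1, a2``) each reader's decision is
    Bernoulli at their conditional probability, exams are classified as
    concordant positive / concordant negative / discordant, and the pair
    recall is "any reader flagged".  For individual outcomes (column
    ``p_positive`` only) a single decision is sampled and the concordance
    split is not applicable (reported as 0/0/0 split into positives and
    negatives via tp/fp only).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _DECISION_STREAM]))
    pos = (outcomes["case_status"] == "positive").to_numpy()
    if "a1" in outcomes.columns and "a2" in outcomes.columns:
        a1 = outcomes["a1"].to_numpy()
        a2 = outcomes["a2"].to_numpy()
        y1 = rng.random(len(a1)) < a1
        y2 = rng.random(len(a2)) < a2
        flagged = y1 | y2
        return BinaryOutcomeCounts(
            concordant_positive=int(np.sum(y1 & y2)),
            concordant_negative=int(np.sum(~y1 & ~y2)),
            discordant=int(np.sum(y1 != y2)),
            tp=int(np.sum(flagged & pos)),
            fp=int(np.sum(flagged & ~pos)),
        )
    if "p_positive" not in outcomes.columns:
        raise InvalidArgumentError("outcomes need columns a1/a2 or p_positive")
    a = outcomes["p_positive"].to_numpy()
    y = rng.random(len(a)) < a
    return BinaryOutcomeCounts(
        concordant_positive=0,
        concordant_negative=0,
        discordant=0,
        tp=int(np.sum(y & pos)),
        fp=int(np.sum(y & ~pos)),
    )


def bootstrap_group_rates(
    outcomes: pd.DataFrame,
    n_boot: int = 1000,
    conf: float = 0.95,
    n_comparisons: int = 1,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for the group TPR and FPR.

    Examinations are resampled with replacement within each case-status
    stratum.  With ``n_comparisons`` planned contrasts the per-comparison
    level is Bonferroni-adjusted to ``1 - (1 - conf)/n_comparisons``.
    """
    if n_boot < 1 or n_comparisons < 1:
        raise InvalidArgumentError("n_boot and n_comparisons must be >= 1")
    if not 0.0 < conf < 1.0:
        raise InvalidArgumentError("conf must be in (0, 1)")
    alpha = (1.0 - conf) / n_comparisons
    rng = np.random.default_rng(np.random.SeedSequence([seed, _BOOT_STREAM]))
    out: dict[str, tuple[float, float]] = {}
    for label, status in (("tpr", "positive"), ("fpr", "negative")):
        v = outcomes.loc[outcomes["case_status"] == status, "p_positive"].to_numpy()
        n = len(v)
        if n == 0:
            raise InvalidArgumentError(f"no {status} examinations to resample")
        if n * n_boot <= 5_000_000:
            w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
            means = (w @ v) / n
        else:  # large runs: resample indices one replicate at a time
            means = np.empty(n_boot)
            for b in range(n_boot):
                means[b] = v[rng.integers(0, n, n)].mean()
        lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
        out[label] = (float(lo), float(hi))
    return out


def recall_and_cdr(tpr: float, fpr: float, prevalence: float) -> tuple[float, float]:
    """Recall rate and cancer-detection rate per 1,000 examinations.

    RR/1000 = 1000 (prevalence * TPR + (1 - prevalence) * FPR);
    CDR/1000 = 1000 * prevalence * TPR.
    """
    for name, v in (("tpr", tpr), ("fpr", fpr), ("prevalence", prevalence)):
        if not np.isfinite(v) or not 0.0 <= v <= 1.0:
            raise InvalidArgumentError(f"{name} must lie in [0, 1], got {v!r}")
    rr = 1000.0 * (prevalence * tpr + (1.0 - prevalence) * fpr)
    cdr = 1000.0 * prevalence * tpr
    return rr, cdr


def run_strategy_comparison(
    population: ModelParameters,
    rates,
    cfg: ScheduleConfig,
    n_boot: int = 1000,
    seed: int | None = None,
    strategies: Sequence[PairingStrategy | str] | None = None,
    include_individual: bool = True,
) -> tuple[pd.DataFrame, dict[str, StrategyOutcome]]:
    """Simulate every pairing strategy plus individual reading on shared exams.

    Returns a result table (one row per strategy, columns
    :data:`RESULT_COLUMNS`) and the underlying outcome objects.  Confidence
    intervals are Bonferroni-adjusted for 6 comparisons for paired rows
    (the six non-random strategies against random) and 7 for the individual
    row (every paired strategy against individual reading).  Bernoulli
    decision sampling shares its stream across strategies so TP/FP count
    differences are paired comparisons.
    """
    seed = cfg.seed if seed is None else seed
    if strategies is None:
        strategies = list(PairingStrategy)
    outcomes: dict[str, StrategyOutcome] = {}
    rows = []
    for strat in strategies:
        strat = PairingStrategy(strat)
        schedule = build_year_schedule(cfg, population, strat, rates, seed)
        df, out = simulate_strategy(population, schedule, cfg.prevalence, seed, strat.value)
        ci = bootstrap_group_rates(df, n_boot=n_boot, n_comparisons=6, seed=seed)
        out.tpr_ci, out.fpr_ci = ci["tpr"], ci["fpr"]
        counts = sample_binary_outcomes(df, seed)
        out.tp, out.fp = counts.tp, counts.fp
        out.concordant_positive = counts.concordant_positive
        out.concordant_negative = counts.concordant_negative
        out.discordant = counts.discordant
        out.rr_per_1000, out.cdr_per_1000 = recall_and_cdr(out.tpr, out.fpr, cfg.prevalence)
        outcomes[strat.value] = out
    if include_individual:
        schedule = build_year_schedule(cfg, population, PairingStrategy.RANDOM, rates, seed)
        df, out = simulate_individual(population, schedule, cfg.prevalence, seed)
        ci = bootstrap_group_rates(df, n_boot=n_boot, n_comparisons=7, seed=seed)
        out.tpr_ci, out.fpr_ci = ci["tpr"], ci["fpr"]
        counts = sample_binary_outcomes(df, seed)
        out.tp, out.fp = counts.tp, counts.fp
        out.rr_per_1000, out.cdr_per_1000 = recall_and_cdr(out.tpr, out.fpr, cfg.prevalence)
        outcomes["individual"] = out
    for out in outcomes.values():
        rows.append(
            {
                "strategy": out.strategy,
                "tpr": out.tpr,
                "tpr_lo": out.tpr_ci[0],
                "tpr_hi": out.tpr_ci[1],
                "fpr": out.fpr,
                "fpr_lo": out.fpr_ci[0],
                "fpr_hi": out.fpr_ci[1],
                "tp": out.tp,
                "fp": out.fp,
                "concordant_positive": out.concordant_positive,
                "concordant_negative": out.concordant_negative,
                "discordant": out.discordant,
                "rr_per_1000": out.rr_per_1000,
                "cdr_per_1000": out.cdr_per_1000,
                "exam_checksum": out.exam_checksum,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), outcomes
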