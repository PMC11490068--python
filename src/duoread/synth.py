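"""Synthetic reader populations and double-read screening datasets.

Real double-reading registries (exam id, case status, reader, recall
decision) are confidential, so every downstream stage of this package is
exercised on data generated from the model itself.  The generator emulates
the structure the analysis assumes: each examination is read by exactly two
readers out of a pool, cancer prevalence is a few per 1,000, reader
operating points are heterogeneous with TPR and FPR positively associated,
and pair coverage is sparse relative to all possible pairs.

Default population parameters are picked so a default run is magnitude-
realistic for organized mammography screening: mean individual FPR around
4-5%, mean individual TPR around 65-70%, prevalence 6 per 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import AllExcludedError, InvalidArgumentError, MalformedDataError
from .fitting import (
    ObservedCounts,
    PairCounts,
    ReaderCounts,
    aggregate_reading_records,
)
from .model import (
    CaseEffectScale,
    ModelParameters,
    MonteCarloConfig,
    ReaderEffect,
    _marginal_rates,
    case_effect_sample,
)

__all__ = [
    "ReadingRecord",
    "PopulationConfig",
    "DatasetConfig",
    "generate_reader_population",
    "generate_reading_records",
    "apply_exclusion_criteria",
    "filter_reading_records",
    "write_records",
    "read_records",
]

RECORD_CSV_COLUMNS = ("exam_id", "case_status", "reader_id", "decision", "day", "batch")


@dataclass(frozen=True)
class ReadingRecord:
    """One reader's binary decision (1 = recall) on one examination."""

    exam_id: str
    case_status: str
    reader_id: str
    decision: int
    day: int | None = None
    batch: int | None = None

    def __post_init__(self) -> None:
        if self.decision not in (0, 1):
            raise InvalidArgumentError("decision must be 0 or 1")
        if self.case_status not in ("positive", "negative"):
            raise InvalidArgumentError("case_status must be 'positive' or 'negative'")


@dataclass(frozen=True)
class PopulationConfig:
    """Generating distribution of a reader population.

    Reader effects are drawn from a bivariate normal on the logit scale;
    a positive ``correlation`` reproduces the commonly observed pattern of
    high-TPR readers also having higher FPR.  Defaults give marginal FPR
    near 4-5% and TPR near 65-70% once the case-effect scales are applied.
    """

    n_readers: int
    mean_r_neg: float = -3.3
    sd_r_neg: float = 0.3
    mean_r_pos: float = 1.0
    sd_r_pos: float = 0.5
    correlation: float = 0.8
    sigma_neg: float = 1.0
    sigma_pos: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise InvalidArgumentError("n_readers must be >= 2")
        if self.sd_r_neg < 0 or self.sd_r_pos < 0:
            raise InvalidArgumentError("standard deviations must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise InvalidArgumentError("correlation must lie in [-1, 1]")
        if self.sigma_neg < 0 or self.sigma_pos < 0:
            raise InvalidArgumentError("case-effect scales must be >= 0")


@dataclass(frozen=True)
class DatasetConfig:
    """Shape of a generated double-read dataset.

    Every exam is read by exactly two readers.  ``chained`` assigns exams
    round-robin to the fixed pairs (reader i, reader i+1, wrapping), which
    guarantees identifiability with few pairs; ``random_rotation`` reshuffles
    the pool into pairs every ``rotation_block`` exams, emulating registry-
    style sparse and uneven pair coverage.
    """

    n_exams: int
    prevalence: float = 0.006
    pair_scheme: str = "chained"
    rotation_block: int = 1000
    seed: int = 0
    reads_per_exam: int = 2

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise InvalidArgumentError("n_exams must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidArgumentError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.pair_scheme not in ("chained", "random_rotation"):
            raise InvalidArgumentError("pair_scheme must be 'chained' or 'random_rotation'")
        if self.reads_per_exam != 2:
            raise InvalidArgumentError("reads_per_exam is fixed at 2")
        if self.rotation_block < 1:
            raise InvalidArgumentError("rotation_block must be >= 1")


def generate_reader_population(
    cfg: PopulationConfig, rate_mc_samples: int = 200_000
) -> tuple[ModelParameters, pd.DataFrame]:
    """Draw a reader population and compute each reader's implied marginal rates.

    Returns the ground-truth :class:`ModelParameters` and a DataFrame indexed
    by ``reader_id`` with columns ``r_neg, r_pos, fpr, tpr`` (marginal rates
    evaluated by Monte Carlo over the case-effect distributions).
    """
    rng = np.random.default_rng(cfg.seed)
    cov = np.array(
        [
            [cfg.sd_r_neg**2, cfg.correlation * cfg.sd_r_neg * cfg.sd_r_pos],
            [cfg.correlation * cfg.sd_r_neg * cfg.sd_r_pos, cfg.sd_r_pos**2],
        ]
    )
    draws = rng.multivariate_normal([cfg.mean_r_neg, cfg.mean_r_pos], cov, size=cfg.n_readers)
    width = max(2, len(str(cfg.n_readers)))
    ids = [f"R{i:0{width}d}" for i in range(1, cfg.n_readers + 1)]
    readers = tuple(
        ReaderEffect(rid, float(rn), float(rp)) for rid, (rn, rp) in zip(ids, draws)
    )
    params = ModelParameters(readers, CaseEffectScale(cfg.sigma_neg, cfg.sigma_pos))
    s_neg, s_pos = np.random.SeedSequence([cfg.seed, 915]).spawn(2)
    z_neg = np.random.default_rng(s_neg).standard_normal(rate_mc_samples)
    z_pos = np.random.default_rng(s_pos).standard_normal(rate_mc_samples)
    fpr = _marginal_rates(params.r_neg, cfg.sigma_neg, z_neg)
    tpr = _marginal_rates(params.r_pos, cfg.sigma_pos, z_pos)
    rates = pd.DataFrame(
        {"r_neg": draws[:, 0], "r_pos": draws[:, 1], "fpr": fpr, "tpr": tpr},
        index=pd.Index(ids, name="reader_id"),
    )
    return params, rates


def _chained_pairs(n_readers: int) -> np.ndarray:
    if n_readers == 2:
        return np.array([[0, 1]])
    return np.array([[i, (i + 1) % n_readers] for i in range(n_readers)])


def generate_reading_records(truth: ModelParameters, cfg: DatasetConfig) -> pd.DataFrame:
    """Simulate a double-read dataset from ground-truth parameters.

    For each exam: case status ~ Bernoulli(prevalence); one case effect
    drawn from the matching class scale and shared by both assigned readers;
    each decision ~ Bernoulli(logistic(r + C)).  Positive and negative case
    effects come from independent streams.  Returns a long DataFrame with
    two rows per exam (columns ``exam_id, case_status, reader_id, decision,
    day, batch``; day/batch are NA here).
    """
    J = len(truth.readers)
    if J < 2:
        raise InvalidArgumentError("need at least 2 readers to double-read")
    n = cfg.n_exams
    root = np.random.SeedSequence(cfg.seed)
    s_status, s_cneg, s_cpos, s_dec, s_pair = root.spawn(5)
    status = np.random.default_rng(s_status).random(n) < cfg.prevalence

    if cfg.pair_scheme == "chained":
        pair_table = _chained_pairs(J)
        pair_of_exam = np.arange(n) % len(pair_table)
        i1 = pair_table[pair_of_exam, 0]
        i2 = pair_table[pair_of_exam, 1]
    else:
        if J % 2:
            raise InvalidArgumentError("random_rotation requires an even number of readers")
        rng_pair = np.random.default_rng(s_pair)
        i1 = np.empty(n, dtype=int)
        i2 = np.empty(n, dtype=int)
        for start in range(0, n, cfg.rotation_block):
            stop = min(start + cfg.rotation_block, n)
            perm = rng_pair.permutation(J).reshape(-1, 2)
            local = (np.arange(stop - start)) % len(perm)
            i1[start:stop] = perm[local, 0]
            i2[start:stop] = perm[local, 1]

    z_neg = np.random.default_rng(s_cneg).standard_normal(n)
    z_pos = np.random.default_rng(s_cpos).standard_normal(n)
    c = np.where(status, truth.scale.sigma_pos * z_pos, truth.scale.sigma_neg * z_neg)

    r_neg = truth.r_neg
    r_pos = truth.r_pos
    eff1 = np.where(status, r_pos[i1], r_neg[i1])
    eff2 = np.where(status, r_pos[i2], r_neg[i2])
    rng_dec = np.random.default_rng(s_dec)
    d1 = (rng_dec.random(n) < expit(eff1 + c)).astype(int)
    d2 = (rng_dec.random(n) < expit(eff2 + c)).astype(int)

    width = len(str(max(n - 1, 1)))
    exam_ids = np.array([f"E{i:0{width}d}" for i in range(n)])
    ids = np.array(truth.reader_ids)
    status_str = np.where(status, "positive", "negative")
    df = pd.DataFrame(
        {
            "exam_id": np.repeat(exam_ids, 2),
            "case_status": np.repeat(status_str, 2),
            "reader_id": np.column_stack([ids[i1], ids[i2]]).ravel(),
            "decision": np.column_stack([d1, d2]).ravel(),
            "day": pd.array([pd.NA] * (2 * n), dtype="Int64"),
            "batch": pd.array([pd.NA] * (2 * n), dtype="Int64"),
        }
    )
    return df


def apply_exclusion_criteria(
    counts: ObservedCounts, min_positive_reads_per_pair: int = 17
) -> ObservedCounts:
    """Apply the fit-eligibility filters to aggregated counts.

    Removes readers with no true positive or no false positive, readers
    whose abnormal calls equal their reads in either class (a rate of
    exactly 0 or 1 is outside the logistic model), and pairs with fewer
    than ``min_positive_reads_per_pair`` jointly read positive exams.
    Pairs referencing a removed reader are dropped as well.  The operation
    is idempotent.
    """
    keep = []
    for r in counts.readers:
        ok = (
            r.a_pos > 0
            and r.a_neg > 0
            and r.a_pos < r.k_pos
            and r.a_neg < r.k_neg
        )
        if ok:
            keep.append(r)
    if not keep:
        raise AllExcludedError("exclusion criteria removed every reader")
    kept_ids = {r.reader_id for r in keep}
    pairs = tuple(
        p
        for p in counts.pairs
        if p.reader_id_1 in kept_ids
        and p.reader_id_2 in kept_ids
        and p.k_pos >= min_positive_reads_per_pair
    )
    return ObservedCounts(tuple(keep), pairs)


def filter_reading_records(
    records: pd.DataFrame, min_positive_reads_per_pair: int = 17, max_rounds: int = 100
) -> tuple[pd.DataFrame, ObservedCounts]:
    """Record-level exclusion with cascading recomputation.

    Rows of an excluded reader are dropped (the co-reader's row survives as
    a single read); exams read by an under-volume pair are dropped entirely.
    Counts are re-aggregated after each removal round until stable.
    """
    df = records.copy()
    for _ in range(max_rounds):
        if len(df) == 0:
            raise AllExcludedError("exclusion criteria removed every record")
        counts = aggregate_reading_records(df)
        bad_readers = {
            r.reader_id
            for r in counts.readers
            if r.a_pos == 0 or r.a_neg == 0 or r.a_pos == r.k_pos or r.a_neg == r.k_neg
        }
        bad_pairs = {p.key for p in counts.pairs if p.k_pos < min_positive_reads_per_pair}
        if not bad_readers and not bad_pairs:
            return df, counts
        if bad_readers:
            df = df[~df["reader_id"].isin(bad_readers)]
        if bad_pairs and len(df):
            two = df.groupby("exam_id")["reader_id"].transform("size") == 2
            dual = df[two].sort_values(["exam_id", "reader_id"])
            pair_of_exam = dual.groupby("exam_id")["reader_id"].agg(tuple)
            drop_exams = pair_of_exam[pair_of_exam.isin(bad_pairs)].index
            df = df[~df["exam_id"].isin(drop_exams)]
    raise AllExcludedError("exclusion cascade did not stabilize")


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write reading records as CSV in the package's canonical dialect."""
    out = df.copy()
    for col in RECORD_CSV_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[list(RECORD_CSV_COLUMNS)].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a reading-records CSV, validating the canonical header."""
    df = pd.read_csv(
        path,
        dtype={"exam_id": str, "case_status": str, "reader_id": str},
    )
    missing = [c for c in ("exam_id", "case_status", "reader_id", "decision") if c not in df.columns]
    if missing:
        raise MalformedDataError(f"records CSV missing required column(s): {missing}")
    df["decision"] = df["decision"].astype(int)
    for col in ("day", "batch"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
        else:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df
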