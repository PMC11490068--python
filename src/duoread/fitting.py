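"""Likelihood construction, maximum-likelihood fitting, and fit diagnostics.

The sufficient statistics are binomial count tables: per reader, the number
of negative/positive examinations read (``K``) and the abnormal calls among
them (``A``); per observed reader pair, the jointly read examinations and
the disagreements (``D``).  Both the single-reader and the pair counts are
binomial in the marginal rates implied by the latent-trait model, so the
log-likelihood for one case class is

    sum_j [ A_j ln a_j + (K_j - A_j) ln(1 - a_j) ]
  + sum_(j,j') [ D_jj' ln d_jj' + (K_jj' - D_jj') ln(1 - d_jj') ]

up to a parameter-free log-factorial constant that is dropped.  The pair
term is essential: single-reader rates alone cannot separate the reader
effects from the case-effect scale, so a fit without any pair counts is
refused as not identifiable.

Positive and negative cases are completely independent and are fitted as
two separate optimizations.  Each one maximizes the likelihood over
``(r_1, ..., r_J, log sigma)`` with Powell's derivative-free method; the
case-effect scale is optimized on the log scale to keep it positive.  The
Monte-Carlo case-effect sample is drawn once per class and held fixed for
the whole optimization (common random numbers), which makes the objective
a deterministic function of the parameters.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import (
    DegenerateLikelihoodError,
    InvalidArgumentError,
    MalformedDataError,
    NonConvergenceError,
    NotIdentifiableError,
)
from .model import (
    CaseEffectScale,
    ModelParameters,
    MonteCarloConfig,
    ReaderEffect,
    _marginal_rates,
    _pair_disagreement_rates,
)

__all__ = [
    "ReaderCounts",
    "PairCounts",
    "ObservedCounts",
    "FitConfig",
    "RateEstimate",
    "DirectRates",
    "FittedModel",
    "FitDiagnostics",
    "aggregate_reading_records",
    "agresti_coull_estimate",
    "direct_rates",
    "negative_log_likelihood",
    "fit_model",
    "evaluate_fit",
    "save_parameters",
    "load_parameters",
]

RECORD_COLUMNS = ("exam_id", "case_status", "reader_id", "decision")


@dataclass(frozen=True)
class ReaderCounts:
    """Binomial counts of one reader: reads and abnormal calls per case class."""

    reader_id: str
    k_neg: int
    a_neg: int
    k_pos: int
    a_pos: int

    def __post_init__(self) -> None:
        if not (0 <= self.a_neg <= self.k_neg):
            raise InvalidArgumentError(
                f"reader {self.reader_id}: need 0 <= a_neg <= k_neg"
            )
        if not (0 <= self.a_pos <= self.k_pos):
            raise InvalidArgumentError(
                f"reader {self.reader_id}: need 0 <= a_pos <= k_pos"
            )


@dataclass(frozen=True)
class PairCounts:
    """Joint reads and disagreements of one unordered reader pair."""

    reader_id_1: str
    reader_id_2: str
    k_neg: int
    d_neg: int
    k_pos: int
    d_pos: int

    def __post_init__(self) -> None:
        if self.reader_id_1 == self.reader_id_2:
            raise InvalidArgumentError("pair reader ids must be distinct")
        # canonical order so the pair is genuinely unordered
        if str(self.reader_id_2) < str(self.reader_id_1):
            object.__setattr__(self, "reader_id_1", self.reader_id_2)
            object.__setattr__(self, "reader_id_2", self.reader_id_1)
        if not (0 <= self.d_neg <= self.k_neg and 0 <= self.d_pos <= self.k_pos):
            raise InvalidArgumentError("need 0 <= d <= k in each case class")

    @property
    def key(self) -> tuple[str, str]:
        return (self.reader_id_1, self.reader_id_2)


@dataclass(frozen=True)
class ObservedCounts:
    """The model's sufficient statistics: all reader and pair count tables."""

    readers: tuple[ReaderCounts, ...]
    pairs: tuple[PairCounts, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "readers", tuple(self.readers))
        object.__setattr__(self, "pairs", tuple(self.pairs))
        ids = {r.reader_id for r in self.readers}
        if len(ids) != len(self.readers):
            raise InvalidArgumentError("duplicate reader_id in counts")
        for p in self.pairs:
            if p.reader_id_1 not in ids or p.reader_id_2 not in ids:
                raise InvalidArgumentError(
                    f"pair {p.key} references a reader without ReaderCounts"
                )

    @property
    def reader_ids(self) -> tuple[str, ...]:
        return tuple(r.reader_id for r in self.readers)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        if not rows:
            raise MalformedDataError("empty reading-record collection")
        if hasattr(rows[0], "exam_id"):
            df = pd.DataFrame(
                {
                    "exam_id": [r.exam_id for r in rows],
                    "case_status": [r.case_status for r in rows],
                    "reader_id": [r.reader_id for r in rows],
                    "decision": [r.decision for r in rows],
                }
            )
        else:
            df = pd.DataFrame(rows)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedDataError(f"records missing required column(s): {missing}")
    if len(df) == 0:
        raise MalformedDataError("empty reading-record collection")
    return df


def aggregate_reading_records(records) -> ObservedCounts:
    """Reduce per-assessment rows to the binomial sufficient statistics.

    Accepts a DataFrame (or iterable of record objects/dicts) with columns
    ``exam_id, case_status, reader_id, decision``.  Every exam must be read
    by exactly 1 or 2 distinct readers; single-read exams contribute to the
    reader counts only.
    """
    df = _records_frame(records)
    if not set(df["decision"].unique()) <= {0, 1}:
        raise MalformedDataError("decisions must be 0 or 1")
    if not set(df["case_status"].unique()) <= {"positive", "negative"}:
        raise MalformedDataError("case_status must be 'positive' or 'negative'")
    if df.duplicated(["exam_id", "reader_id"]).any():
        raise MalformedDataError("duplicate (exam_id, reader_id) rows")
    per_exam = df.groupby("exam_id", sort=False)
    n_readers = per_exam["reader_id"].nunique()
    if (n_readers > 2).any():
        bad = n_readers[n_readers > 2].index[0]
        raise MalformedDataError(f"exam {bad!r} has more than 2 readers")
    if (per_exam["case_status"].nunique() > 1).any():
        raise MalformedDataError("an exam carries inconsistent case_status")

    df = df.copy()
    df["decision"] = df["decision"].astype(int)
    grp = df.groupby(["reader_id", "case_status"])["decision"].agg(["count", "sum"])
    readers = []
    for rid in sorted(df["reader_id"].unique(), key=str):
        k_neg = a_neg = k_pos = a_pos = 0
        if (rid, "negative") in grp.index:
            k_neg, a_neg = grp.loc[(rid, "negative")]
        if (rid, "positive") in grp.index:
            k_pos, a_pos = grp.loc[(rid, "positive")]
        readers.append(
            ReaderCounts(str(rid), int(k_neg), int(a_neg), int(k_pos), int(a_pos))
        )

    sizes = per_exam["reader_id"].transform("size")
    dual = df[sizes == 2].sort_values(["exam_id", "reader_id"])
    pairs: list[PairCounts] = []
    if len(dual):
        wide = dual.groupby("exam_id", sort=False).agg(
            r1=("reader_id", "first"),
            r2=("reader_id", "last"),
            d1=("decision", "first"),
            d2=("decision", "last"),
            status=("case_status", "first"),
        )
        wide["disagree"] = (wide["d1"] != wide["d2"]).astype(int)
        pg = wide.groupby(["r1", "r2", "status"])["disagree"].agg(["count", "sum"])
        keys = sorted({(r1, r2) for r1, r2, _ in pg.index})
        for r1, r2 in keys:
            k_neg = d_neg = k_pos = d_pos = 0
            if (r1, r2, "negative") in pg.index:
                k_neg, d_neg = pg.loc[(r1, r2, "negative")]
            if (r1, r2, "positive") in pg.index:
                k_pos, d_pos = pg.loc[(r1, r2, "positive")]
            pairs.append(
                PairCounts(str(r1), str(r2), int(k_neg), int(d_neg), int(k_pos), int(d_pos))
            )
    return ObservedCounts(tuple(readers), tuple(pairs))


@dataclass(frozen=True)
class RateEstimate:
    """An Agresti-Coull adjusted proportion with its confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    method: str = "agresti_coull"


def agresti_coull_estimate(successes: int, trials: int, conf: float = 0.95) -> RateEstimate:
    """Adjusted proportion ``(A + z^2/2) / (K + z^2)`` with a Wald-type interval.

    The adjustment adds ``z^2/2`` pseudo-successes and ``z^2`` pseudo-trials,
    pulling the point estimate toward 1/2 and keeping intervals sensible at
    A = 0 or A = K.  The interval is clipped to [0, 1].
    """
    if trials < 1:
        raise InvalidArgumentError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise InvalidArgumentError("need 0 <= successes <= trials")
    if not 0 < conf < 1:
        raise InvalidArgumentError("conf must be in (0, 1)")
    z = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    n_adj = trials + z * z
    p_adj = (successes + z * z / 2.0) / n_adj
    half = z * math.sqrt(p_adj * (1.0 - p_adj) / n_adj)
    return RateEstimate(
        rate=p_adj,
        ci_low=max(0.0, p_adj - half),
        ci_high=min(1.0, p_adj + half),
    )


@dataclass(frozen=True)
class DirectRates:
    """Direct (model-free) per-reader and per-pair rate estimates.

    A reader or pair with zero trials in a case class is simply absent from
    the corresponding mapping rather than given a fabricated value.
    """

    tpr: Mapping[str, RateEstimate]
    fpr: Mapping[str, RateEstimate]
    disagreement_neg: Mapping[tuple[str, str], RateEstimate]
    disagreement_pos: Mapping[tuple[str, str], RateEstimate]


def direct_rates(counts: ObservedCounts, conf: float = 0.95) -> DirectRates:
    """Agresti-Coull adjusted TPR/FPR per reader and disagreement rate per pair."""
    tpr, fpr = {}, {}
    for r in counts.readers:
        if r.k_pos > 0:
            tpr[r.reader_id] = agresti_coull_estimate(r.a_pos, r.k_pos, conf)
        if r.k_neg > 0:
            fpr[r.reader_id] = agresti_coull_estimate(r.a_neg, r.k_neg, conf)
    d_neg, d_pos = {}, {}
    for p in counts.pairs:
        if p.k_neg > 0:
            d_neg[p.key] = agresti_coull_estimate(p.d_neg, p.k_neg, conf)
        if p.k_pos > 0:
            d_pos[p.key] = agresti_coull_estimate(p.d_pos, p.k_pos, conf)
    return DirectRates(tpr, fpr, d_neg, d_pos)


@dataclass(frozen=True)
class FitConfig:
    """Controls for the Powell maximum-likelihood fit.

    ``f_tol`` is Powell's fractional convergence tolerance on the objective.
    ``fix_sigma`` pins the case-effect scale (both classes) instead of
    optimizing it — useful for degenerate or toy instances.
    """

    f_tol: float = 1e-4
    max_iterations: int | None = None
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    init: str = "from_direct_estimates"
    init_params: ModelParameters | None = None
    fix_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.f_tol <= 0:
            raise InvalidArgumentError("f_tol must be > 0")
        if self.init not in ("from_direct_estimates", "user_supplied"):
            raise InvalidArgumentError("init must be from_direct_estimates or user_supplied")
        if self.init == "user_supplied" and self.init_params is None:
            raise InvalidArgumentError("user_supplied init requires init_params")
        if self.fix_sigma is not None and self.fix_sigma < 0:
            raise InvalidArgumentError("fix_sigma must be >= 0")


@dataclass(frozen=True)
class FittedModel:
    """Maximum-likelihood parameters and the marginal rates they imply."""

    params: ModelParameters
    marginal_tpr: Mapping[str, float]
    marginal_fpr: Mapping[str, float]
    pair_disagreement_neg: Mapping[tuple[str, str], float]
    pair_disagreement_pos: Mapping[tuple[str, str], float]
    nll: float
    nll_neg: float
    nll_pos: float
    nll_history_neg: tuple[float, ...]
    nll_history_pos: tuple[float, ...]
    converged: bool


@dataclass(frozen=True)
class FitDiagnostics:
    """Pearson correlations between modeled and directly observed rates.

    ``None`` marks a coefficient that is undefined (fewer than 3 paired
    points or zero variance in either vector).
    """

    pearson_tpr: float | None
    pearson_fpr: float | None
    pearson_disagree_pos: float | None
    pearson_disagree_neg: float | None


def _class_streams(mc: MonteCarloConfig) -> tuple[np.ndarray, np.ndarray]:
    """Independent case-effect samples for the negative and positive classes."""
    s_neg, s_pos = np.random.SeedSequence(mc.seed).spawn(2)
    z_neg = np.random.default_rng(s_neg).standard_normal(mc.n_samples)
    z_pos = np.random.default_rng(s_pos).standard_normal(mc.n_samples)
    return z_neg, z_pos


def _binom_nll(k: np.ndarray, a: np.ndarray, rate: np.ndarray) -> float:
    return -float(np.sum(a * np.log(rate) + (k - a) * np.log1p(-rate)))


def _class_nll(
    r: np.ndarray,
    sigma: float,
    z: np.ndarray,
    k_reader: np.ndarray,
    a_reader: np.ndarray,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    k_pair: np.ndarray,
    d_pair: np.ndarray,
    clip: float | None = None,
) -> float:
    rates = _marginal_rates(r, sigma, z)
    if len(pair_i):
        drates = _pair_disagreement_rates(r[pair_i], r[pair_j], sigma, z)
    else:
        drates = np.empty(0)
    if clip is not None:
        rates = np.clip(rates, clip, 1.0 - clip)
        drates = np.clip(drates, clip, 1.0 - clip)
    else:
        used = np.concatenate(
            [rates[k_reader > 0], drates[k_pair > 0] if len(drates) else np.empty(0)]
        )
        if np.any(used <= 0.0) or np.any(used >= 1.0):
            raise DegenerateLikelihoodError(
                "a marginal rate reached exactly 0 or 1 at the evaluated parameters"
            )
    nll = 0.0
    m = k_reader > 0
    if m.any():
        nll += _binom_nll(k_reader[m], a_reader[m], rates[m])
    mp = k_pair > 0
    if len(drates) and mp.any():
        nll += _binom_nll(k_pair[mp], d_pair[mp], drates[mp])
    return nll


def _counts_arrays(counts: ObservedCounts, cls: str):
    ids = list(counts.reader_ids)
    idx = {rid: i for i, rid in enumerate(ids)}
    if cls == "neg":
        k_reader = np.array([r.k_neg for r in counts.readers], dtype=float)
        a_reader = np.array([r.a_neg for r in counts.readers], dtype=float)
        k_pair = np.array([p.k_neg for p in counts.pairs], dtype=float)
        d_pair = np.array([p.d_neg for p in counts.pairs], dtype=float)
    else:
        k_reader = np.array([r.k_pos for r in counts.readers], dtype=float)
        a_reader = np.array([r.a_pos for r in counts.readers], dtype=float)
        k_pair = np.array([p.k_pos for p in counts.pairs], dtype=float)
        d_pair = np.array([p.d_pos for p in counts.pairs], dtype=float)
    pair_i = np.array([idx[p.reader_id_1] for p in counts.pairs], dtype=int)
    pair_j = np.array([idx[p.reader_id_2] for p in counts.pairs], dtype=int)
    return k_reader, a_reader, pair_i, pair_j, k_pair, d_pair


def negative_log_likelihood(
    params: ModelParameters, counts: ObservedCounts, mc: MonteCarloConfig
) -> float:
    """Negative binomial log-likelihood of both case classes (constant dropped).

    The Monte-Carlo case-effect samples are derived deterministically from
    ``mc.seed`` (independent streams for the two classes), so repeated calls
    with the same configuration are bit-identical.
    """
    order = {rid: i for i, rid in enumerate(params.reader_ids)}
    missing = [rid for rid in counts.reader_ids if rid not in order]
    if missing:
        raise InvalidArgumentError(f"no ReaderEffect for reader(s) {missing}")
    sel = np.array([order[rid] for rid in counts.reader_ids], dtype=int)
    r_neg = params.r_neg[sel]
    r_pos = params.r_pos[sel]
    z_neg, z_pos = _class_streams(mc)
    total = 0.0
    for cls, r, sigma, z in (
        ("neg", r_neg, params.scale.sigma_neg, z_neg),
        ("pos", r_pos, params.scale.sigma_pos, z_pos),
    ):
        total += _class_nll(r, sigma, z, *_counts_arrays(counts, cls))
    return total


_EXCLUSION_HINT = (
    "apply_exclusion_criteria first: every reader needs at least 1 and fewer "
    "than all abnormal calls in each case class"
)


def _check_fit_preconditions(counts: ObservedCounts) -> None:
    if not counts.pairs:
        raise NotIdentifiableError(
            "no pair counts: the model is not identifiable from single-reader rates alone"
        )
    for r in counts.readers:
        ok = (
            r.k_pos > 0
            and r.k_neg > 0
            and 0 < r.a_pos < r.k_pos
            and 0 < r.a_neg < r.k_neg
        )
        if not ok:
            raise InvalidArgumentError(f"reader {r.reader_id} fails fit preconditions; {_EXCLUSION_HINT}")


def fit_model(counts: ObservedCounts, config: FitConfig = FitConfig()) -> FittedModel:
    """Maximize the binomial log-likelihood with Powell's method.

    The two case classes are independent fits over ``(r_1..r_J, log sigma)``.
    Initialization takes each reader effect at the logit of its
    Agresti-Coull adjusted direct rate and sigma at 1.  Marginal rates of
    the fitted model are evaluated on the same case-effect sample used
    during optimization.
    """
    _check_fit_preconditions(counts)
    ids = list(counts.reader_ids)
    J = len(ids)
    z_neg, z_pos = _class_streams(config.mc)
    dr = direct_rates(counts)

    results = {}
    for cls, z in (("neg", z_neg), ("pos", z_pos)):
        k_reader, a_reader, pair_i, pair_j, k_pair, d_pair = _counts_arrays(counts, cls)
        if config.init == "user_supplied":
            p0 = config.init_params
            order = {rid: i for i, rid in enumerate(p0.reader_ids)}
            sel = np.array([order[rid] for rid in ids], dtype=int)
            r0 = (p0.r_neg if cls == "neg" else p0.r_pos)[sel]
            sigma0 = p0.scale.sigma_neg if cls == "neg" else p0.scale.sigma_pos
        else:
            est = dr.fpr if cls == "neg" else dr.tpr
            r0 = np.array([logit(est[rid].rate) for rid in ids])
            sigma0 = 1.0

        fixed_sigma = config.fix_sigma
        if fixed_sigma is None:
            x0 = np.concatenate([r0, [np.log(max(sigma0, 1e-3))]])

            def objective(x):
                return _class_nll(
                    x[:J], float(np.exp(x[J])), z,
                    k_reader, a_reader, pair_i, pair_j, k_pair, d_pair,
                    clip=1e-12,
                )
        else:
            x0 = np.asarray(r0, dtype=float)

            def objective(x):
                return _class_nll(
                    x, fixed_sigma, z,
                    k_reader, a_reader, pair_i, pair_j, k_pair, d_pair,
                    clip=1e-12,
                )

        history = [objective(x0)]
        options = {"ftol": config.f_tol, "xtol": 1e-6}
        if config.max_iterations is not None:
            options["maxiter"] = config.max_iterations
        res = minimize(
            objective,
            x0,
            method="Powell",
            options=options,
            callback=lambda xk: history.append(objective(xk)),
        )
        if not res.success:
            raise NonConvergenceError(f"{cls}-class Powell fit did not converge: {res.message}")
        if res.fun > history[0] + 1e-9:
            raise NonConvergenceError(f"{cls}-class fit ended above its initialization")
        r_hat = np.asarray(res.x[:J] if fixed_sigma is None else res.x, dtype=float)
        sigma_hat = float(np.exp(res.x[J])) if fixed_sigma is None else float(fixed_sigma)
        rates_hat = _marginal_rates(r_hat, sigma_hat, z)
        if len(pair_i):
            drates_hat = _pair_disagreement_rates(r_hat[pair_i], r_hat[pair_j], sigma_hat, z)
        else:
            drates_hat = np.empty(0)
        results[cls] = (r_hat, sigma_hat, rates_hat, drates_hat, float(res.fun), tuple(history))

    r_neg_hat, sigma_neg_hat, fpr_hat, dneg_hat, nll_neg, hist_neg = results["neg"]
    r_pos_hat, sigma_pos_hat, tpr_hat, dpos_hat, nll_pos, hist_pos = results["pos"]
    params = ModelParameters(
        readers=tuple(
            ReaderEffect(rid, float(rn), float(rp))
            for rid, rn, rp in zip(ids, r_neg_hat, r_pos_hat)
        ),
        scale=CaseEffectScale(sigma_neg_hat, sigma_pos_hat),
    )
    pair_keys = [p.key for p in counts.pairs]
    return FittedModel(
        params=params,
        marginal_tpr={rid: float(v) for rid, v in zip(ids, tpr_hat)},
        marginal_fpr={rid: float(v) for rid, v in zip(ids, fpr_hat)},
        pair_disagreement_neg={k: float(v) for k, v in zip(pair_keys, dneg_hat)},
        pair_disagreement_pos={k: float(v) for k, v in zip(pair_keys, dpos_hat)},
        nll=nll_neg + nll_pos,
        nll_neg=nll_neg,
        nll_pos=nll_pos,
        nll_history_neg=hist_neg,
        nll_history_pos=hist_pos,
        converged=True,
    )


def _pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return None
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_fit(fitted: FittedModel, counts: ObservedCounts, conf: float = 0.95) -> FitDiagnostics:
    """Correlate modeled rates with Agresti-Coull adjusted observed rates."""
    dr = direct_rates(counts, conf)
    tpr_pairs = [
        (fitted.marginal_tpr[rid], dr.tpr[rid].rate)
        for rid in counts.reader_ids
        if rid in dr.tpr and rid in fitted.marginal_tpr
    ]
    fpr_pairs = [
        (fitted.marginal_fpr[rid], dr.fpr[rid].rate)
        for rid in counts.reader_ids
        if rid in dr.fpr and rid in fitted.marginal_fpr
    ]
    dpos_pairs = [
        (fitted.pair_disagreement_pos[k], dr.disagreement_pos[k].rate)
        for k in fitted.pair_disagreement_pos
        if k in dr.disagreement_pos
    ]
    dneg_pairs = [
        (fitted.pair_disagreement_neg[k], dr.disagreement_neg[k].rate)
        for k in fitted.pair_disagreement_neg
        if k in dr.disagreement_neg
    ]

    def corr(pairs):
        if not pairs:
            return None
        xs, ys = zip(*pairs)
        return _pearson(xs, ys)

    return FitDiagnostics(
        pearson_tpr=corr(tpr_pairs),
        pearson_fpr=corr(fpr_pairs),
        pearson_disagree_pos=corr(dpos_pairs),
        pearson_disagree_neg=corr(dneg_pairs),
    )


def save_parameters(
    params: ModelParameters,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
    extra_meta: Mapping | None = None,
) -> None:
    """Write reader effects as CSV plus a JSON sidecar for the scales and metadata."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reader_id", "r_neg", "r_pos"])
        for r in params.readers:
            w.writerow([r.reader_id, repr(r.r_neg), repr(r.r_pos)])
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = {
        "sigma_neg": params.scale.sigma_neg,
        "sigma_pos": params.scale.sigma_pos,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_parameters(
    csv_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[ModelParameters, dict]:
    """Read parameters written by :func:`save_parameters`; returns (params, metadata)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype={"reader_id": str})
    for col in ("reader_id", "r_neg", "r_pos"):
        if col not in df.columns:
            raise MalformedDataError(f"parameter CSV missing column {col!r}")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    params = ModelParameters(
        readers=tuple(
            ReaderEffect(str(row.reader_id), float(row.r_neg), float(row.r_pos))
            for row in df.itertuples()
        ),
        scale=CaseEffectScale(float(meta["sigma_neg"]), float(meta["sigma_pos"])),
    )
    return params, meta
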