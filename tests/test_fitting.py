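"""Tests for aggregation, direct estimates, the likelihood, and the fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import duoread as dr
from duoread.errors import (
    DegenerateLikelihoodError,
    InvalidArgumentError,
    MalformedDataError,
    NotIdentifiableError,
)


def _toy_records():
    # R1, R2 both read e1(neg), e2(neg), e3(pos), e4(pos)
    # R1 decisions 1,0,1,0 ; R2 decisions 0,0,1,1
    rows = []
    decisions = {"R1": [1, 0, 1, 0], "R2": [0, 0, 1, 1]}
    statuses = ["negative", "negative", "positive", "positive"]
    for rid, ds in decisions.items():
        for i, (s, d) in enumerate(zip(statuses, ds), start=1):
            rows.append(
                {"exam_id": f"e{i}", "case_status": s, "reader_id": rid, "decision": d}
            )
    return pd.DataFrame(rows)


class TestAggregation:
    def test_hand_counted_toy_example(self):
        counts = dr.aggregate_reading_records(_toy_records())
        by_id = {r.reader_id: r for r in counts.readers}
        assert (by_id["R1"].k_neg, by_id["R1"].a_neg) == (2, 1)
        assert (by_id["R1"].k_pos, by_id["R1"].a_pos) == (2, 1)
        assert (by_id["R2"].k_neg, by_id["R2"].a_neg) == (2, 0)
        assert (by_id["R2"].k_pos, by_id["R2"].a_pos) == (2, 2)
        assert len(counts.pairs) == 1
        p = counts.pairs[0]
        assert (p.k_neg, p.d_neg, p.k_pos, p.d_pos) == (2, 1, 2, 1)

    def test_single_read_exams_contribute_no_pairs(self):
        df = pd.DataFrame(
            [
                {"exam_id": "e1", "case_status": "negative", "reader_id": "R1", "decision": 0},
                {"exam_id": "e2", "case_status": "positive", "reader_id": "R2", "decision": 1},
            ]
        )
        counts = dr.aggregate_reading_records(df)
        assert len(counts.pairs) == 0
        assert {r.reader_id for r in counts.readers} == {"R1", "R2"}

    def test_empty_input_rejected(self):
        with pytest.raises(MalformedDataError):
            dr.aggregate_reading_records(pd.DataFrame(columns=["exam_id"]))
        with pytest.raises(MalformedDataError):
            dr.aggregate_reading_records([])

    def test_three_readers_on_one_exam_rejected(self):
        df = _toy_records()
        extra = pd.DataFrame(
            [{"exam_id": "e1", "case_status": "negative", "reader_id": "R3", "decision": 0}]
        )
        with pytest.raises(MalformedDataError):
            dr.aggregate_reading_records(pd.concat([df, extra]))

    def test_duplicate_reader_exam_row_rejected(self):
        df = _toy_records()
        with pytest.raises(MalformedDataError):
            dr.aggregate_reading_records(pd.concat([df, df.iloc[[0]]]))


class TestAgrestiCoull:
    def test_symmetric_counts_stay_centered(self):
        est = dr.agresti_coull_estimate(5, 10)
        assert est.rate == pytest.approx(0.5, abs=1e-12)

    def test_zero_successes_adjusted_value(self):
        # (0 + z^2/2) / (10 + z^2) with z = 1.959964
        est = dr.agresti_coull_estimate(0, 10)
        assert est.rate == pytest.approx(0.139, abs=1e-3)
        assert est.ci_low >= 0.0

    def test_interval_clipped_to_unit_range(self):
        est = dr.agresti_coull_estimate(10, 10)
        assert est.ci_high <= 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dr.agresti_coull_estimate(0, 0)

    @pytest.mark.parametrize("a, k", [(1, 50), (49, 50), (3, 9), (200, 400)])
    def test_adjustment_shrinks_toward_half(self, a, k):
        raw = a / k
        adj = dr.agresti_coull_estimate(a, k).rate
        if raw == 0.5:
            assert adj == pytest.approx(0.5)
        else:
            assert abs(adj - 0.5) < abs(raw - 0.5)


class TestDirectRates:
    def test_toy_raw_rates_before_adjustment(self):
        counts = dr.aggregate_reading_records(_toy_records())
        by_id = {r.reader_id: r for r in counts.readers}
        assert by_id["R1"].a_neg / by_id["R1"].k_neg == 0.5
        assert by_id["R2"].a_pos / by_id["R2"].k_pos == 1.0

    def test_composes_agresti_coull_per_cell(self):
        counts = dr.aggregate_reading_records(_toy_records())
        rates = dr.direct_rates(counts, 0.95)
        assert rates.fpr["R1"].rate == dr.agresti_coull_estimate(1, 2).rate
        assert rates.tpr["R2"].rate == dr.agresti_coull_estimate(2, 2).rate
        assert rates.disagreement_neg[("R1", "R2")].rate == dr.agresti_coull_estimate(1, 2).rate

    def test_zero_trial_class_reported_missing(self):
        counts = dr.ObservedCounts(
            readers=(dr.ReaderCounts("R1", 10, 2, 0, 0),), pairs=()
        )
        rates = dr.direct_rates(counts)
        assert "R1" in rates.fpr
        assert "R1" not in rates.tpr


class TestNegativeLogLikelihood:
    def _one_reader_counts(self):
        return dr.ObservedCounts(
            readers=(dr.ReaderCounts("R1", 0, 0, 10, 5),), pairs=()
        )

    def _params(self, r_pos):
        return dr.ModelParameters(
            readers=(dr.ReaderEffect("R1", 0.0, r_pos),),
            scale=dr.CaseEffectScale(0.0, 0.0),
        )

    def test_balanced_binomial_value(self):
        # -[5 ln 0.5 + 5 ln 0.5] = 10 ln 2
        nll = dr.negative_log_likelihood(
            self._params(0.0), self._one_reader_counts(), dr.MonteCarloConfig(10, 0)
        )
        assert nll == pytest.approx(10 * np.log(2), abs=1e-9)

    def test_minimized_at_observed_rate(self):
        counts = self._one_reader_counts()
        mc = dr.MonteCarloConfig(10, 0)
        grid = np.linspace(-2, 2, 41)
        vals = [dr.negative_log_likelihood(self._params(r), counts, mc) for r in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(0.0, abs=1e-9)

    def test_pair_term_penalizes_mismatched_disagreement(self):
        # with sigma=0 and both readers at rate a, disagreement is 2a(1-a);
        # D = K * 2a(1-a) at a=0.5 means any move away from r=0 raises the NLL
        counts = dr.ObservedCounts(
            readers=(
                dr.ReaderCounts("R1", 0, 0, 10, 5),
                dr.ReaderCounts("R2", 0, 0, 10, 5),
            ),
            pairs=(dr.PairCounts("R1", "R2", 0, 0, 10, 5),),
        )
        mc = dr.MonteCarloConfig(10, 0)

        def nll_at(r):
            params = dr.ModelParameters(
                readers=(dr.ReaderEffect("R1", 0, r), dr.ReaderEffect("R2", 0, r)),
                scale=dr.CaseEffectScale(0.0, 0.0),
            )
            return dr.negative_log_likelihood(params, counts, mc)

        base = nll_at(0.0)
        for r in (-1.0, -0.5, 0.5, 1.0):
            assert nll_at(r) > base

    def test_degenerate_rate_signalled(self):
        with pytest.raises(DegenerateLikelihoodError):
            dr.negative_log_likelihood(
                self._params(-800.0), self._one_reader_counts(), dr.MonteCarloConfig(10, 0)
            )


class TestFitModel:
    def test_no_pairs_is_not_identifiable(self):
        counts = dr.ObservedCounts(
            readers=(dr.ReaderCounts("R1", 100, 5, 50, 30),), pairs=()
        )
        with pytest.raises(NotIdentifiableError):
            dr.fit_model(counts)

    def test_precondition_violation_rejected(self):
        counts = dr.ObservedCounts(
            readers=(
                dr.ReaderCounts("R1", 100, 0, 50, 30),  # zero false positives
                dr.ReaderCounts("R2", 100, 5, 50, 30),
            ),
            pairs=(dr.PairCounts("R1", "R2", 100, 10, 50, 20),),
        )
        with pytest.raises(InvalidArgumentError):
            dr.fit_model(counts)

    def test_tiny_instance_matches_brute_force_grid(self):
        # 2 readers, K <= 5 per class, sigma fixed at 0: the fitted rates
        # must agree with an exhaustive grid search over (r1, r2)
        counts = dr.ObservedCounts(
            readers=(
                dr.ReaderCounts("R1", 5, 2, 5, 3),
                dr.ReaderCounts("R2", 5, 1, 5, 4),
            ),
            pairs=(dr.PairCounts("R1", "R2", 5, 2, 5, 1),),
        )
        fitted = dr.fit_model(
            counts,
            dr.FitConfig(mc=dr.MonteCarloConfig(10, 0), fix_sigma=0.0),
        )

        grid = np.linspace(-3, 3, 121)
        R1, R2 = np.meshgrid(grid, grid, indexing="ij")

        def class_nll(k1, a1c, k2, a2c, kp, dp):
            p1, p2 = expit(R1), expit(R2)
            d = p1 * (1 - p2) + p2 * (1 - p1)
            return -(
                a1c * np.log(p1) + (k1 - a1c) * np.log1p(-p1)
                + a2c * np.log(p2) + (k2 - a2c) * np.log1p(-p2)
                + dp * np.log(d) + (kp - dp) * np.log1p(-d)
            )

        for cls, (model_rates,) in {
            "neg": [(fitted.marginal_fpr)],
            "pos": [(fitted.marginal_tpr)],
        }.items():
            r1c = counts.readers[0]
            r2c = counts.readers[1]
            pc = counts.pairs[0]
            if cls == "neg":
                nll = class_nll(r1c.k_neg, r1c.a_neg, r2c.k_neg, r2c.a_neg, pc.k_neg, pc.d_neg)
            else:
                nll = class_nll(r1c.k_pos, r1c.a_pos, r2c.k_pos, r2c.a_pos, pc.k_pos, pc.d_pos)
            i, j = np.unravel_index(np.argmin(nll), nll.shape)
            assert model_rates["R1"] == pytest.approx(expit(grid[i]), abs=1e-2)
            assert model_rates["R2"] == pytest.approx(expit(grid[j]), abs=1e-2)

    def test_nll_decreases_monotonically(self, recovery_harness):
        for hist in (
            recovery_harness["fitted"].nll_history_neg,
            recovery_harness["fitted"].nll_history_pos,
        ):
            diffs = np.diff(hist)
            assert np.all(diffs <= 1e-7)
            assert hist[-1] <= hist[0]

    def test_stable_under_mc_seed_change(self):
        # refit with a different common-random-numbers seed: marginal rates
        # move by less than 3 combined MC standard errors
        pop, _ = dr.generate_reader_population(dr.PopulationConfig(n_readers=4, seed=8))
        rec = dr.generate_reading_records(
            pop, dr.DatasetConfig(n_exams=20_000, prevalence=0.02, seed=8)
        )
        counts = dr.apply_exclusion_criteria(dr.aggregate_reading_records(rec), 17)
        n = 20_000
        f1 = dr.fit_model(counts, dr.FitConfig(mc=dr.MonteCarloConfig(n, 1)))
        f2 = dr.fit_model(counts, dr.FitConfig(mc=dr.MonteCarloConfig(n, 2)))
        for rid in counts.reader_ids:
            for rates1, rates2 in (
                (f1.marginal_fpr, f2.marginal_fpr),
                (f1.marginal_tpr, f2.marginal_tpr),
            ):
                a = rates1[rid]
                se = np.sqrt(2.0) * np.sqrt(a * (1 - a) / n)  # conservative combined MC SE
                assert abs(a - rates2[rid]) < 3 * se

    def test_holdout_pair_disagreement_calibrated(self, recovery_harness):
        # the fitted model predicts fresh data's pair disagreement within
        # binomial noise: calibration consistency on a new seed
        fitted = recovery_harness["fitted"]
        truth = recovery_harness["truth"]
        fresh = dr.generate_reading_records(
            fitted.params, dr.DatasetConfig(n_exams=40_000, prevalence=0.01, seed=901)
        )
        fresh_counts = dr.aggregate_reading_records(fresh)
        for p in fresh_counts.pairs:
            if p.k_neg < 100:
                continue
            pred = fitted.pair_disagreement_neg.get(p.key)
            if pred is None:
                continue
            se = np.sqrt(pred * (1 - pred) / p.k_neg)
            assert abs(p.d_neg / p.k_neg - pred) < 4 * se


class TestEvaluateFit:
    def test_perfect_agreement_gives_unit_correlations(self):
        counts = dr.ObservedCounts(
            readers=tuple(
                dr.ReaderCounts(f"R{i}", 1000, 10 * (i + 1), 100, 20 + 10 * i)
                for i in range(4)
            ),
            pairs=(dr.PairCounts("R0", "R1", 500, 30, 50, 10),
                   dr.PairCounts("R1", "R2", 500, 40, 50, 15),
                   dr.PairCounts("R2", "R3", 500, 50, 50, 20)),
        )
        rates = dr.direct_rates(counts)
        fitted = dr.FittedModel(
            params=dr.ModelParameters(
                readers=tuple(dr.ReaderEffect(f"R{i}", -3, 1) for i in range(4)),
                scale=dr.CaseEffectScale(1, 1),
            ),
            marginal_tpr={k: v.rate for k, v in rates.tpr.items()},
            marginal_fpr={k: v.rate for k, v in rates.fpr.items()},
            pair_disagreement_neg={k: v.rate for k, v in rates.disagreement_neg.items()},
            pair_disagreement_pos={k: v.rate for k, v in rates.disagreement_pos.items()},
            nll=0.0, nll_neg=0.0, nll_pos=0.0,
            nll_history_neg=(), nll_history_pos=(), converged=True,
        )
        diag = dr.evaluate_fit(fitted, counts)
        for v in (diag.pearson_tpr, diag.pearson_fpr,
                  diag.pearson_disagree_pos, diag.pearson_disagree_neg):
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_constant_modeled_rates_flagged_undefined(self):
        counts = dr.ObservedCounts(
            readers=tuple(
                dr.ReaderCounts(f"R{i}", 1000, 10 * (i + 1), 100, 20 + 10 * i)
                for i in range(4)
            ),
            pairs=(),
        )
        fitted = dr.FittedModel(
            params=dr.ModelParameters(
                readers=tuple(dr.ReaderEffect(f"R{i}", -3, 1) for i in range(4)),
                scale=dr.CaseEffectScale(1, 1),
            ),
            marginal_tpr={f"R{i}": 0.6 for i in range(4)},
            marginal_fpr={f"R{i}": 0.05 for i in range(4)},
            pair_disagreement_neg={}, pair_disagreement_pos={},
            nll=0.0, nll_neg=0.0, nll_pos=0.0,
            nll_history_neg=(), nll_history_pos=(), converged=True,
        )
        diag = dr.evaluate_fit(fitted, counts)
        assert diag.pearson_tpr is None
        assert diag.pearson_fpr is None
        assert diag.pearson_disagree_neg is None

    def test_recovery_harness_correlations(self, recovery_harness):
        # single-reader rates and negative-case disagreement correlate tightly
        # with the direct estimates; positive-case disagreement is depressed by
        # sparse positives (about 100 per pair), matching screening experience
        diag = dr.evaluate_fit(recovery_harness["fitted"], recovery_harness["counts"])
        assert diag.pearson_tpr >= 0.9
        assert diag.pearson_fpr >= 0.9
        assert diag.pearson_disagree_neg >= 0.9
        assert diag.pearson_disagree_pos > 0.5


class TestParameterIO:
    def test_round_trip(self, tmp_path):
        params = dr.ModelParameters(
            readers=(dr.ReaderEffect("R1", -3.25, 1.125), dr.ReaderEffect("R2", -2.5, 0.75)),
            scale=dr.CaseEffectScale(1.0, 1.5),
        )
        path = tmp_path / "params.csv"
        dr.save_parameters(params, path, extra_meta={"nll": 12.5})
        loaded, meta = dr.load_parameters(path)
        assert loaded == params
        assert meta["nll"] == 12.5
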