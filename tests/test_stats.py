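"""Agreement statistics: closed-form, enumeration and simulation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from blebvol import stats
from blebvol.exceptions import (
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
    InvariantError,
)


def _series(a, b, c=None, design=None):
    conds = {"c1": a, "c2": b}
    if c is not None:
        conds["c3"] = c
        design = design or "three_condition_repeated"
    design = design or "two_condition_paired"
    rows = []
    for cond, vals in conds.items():
        for i, v in enumerate(vals):
            rows.append({"subject_id": i, "condition": cond, "volume_ul": v})
    return stats.MeasurementSeries(records=pd.DataFrame(rows), design=design)


class TestMeasurementSeries:
    def test_incomplete_pairing_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": [0, 1, 0],
                "condition": ["a", "a", "b"],
                "volume_ul": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(DesignError):
            stats.MeasurementSeries(records=df, design="two_condition_paired")

    def test_duplicate_cell_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": [0, 0, 0, 1, 1],
                "condition": ["a", "a", "b", "a", "b"],
                "volume_ul": [1.0, 1.5, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(DesignError):
            stats.MeasurementSeries(records=df, design="two_condition_paired")

    def test_single_subject_rejected(self):
        df = pd.DataFrame(
            {"subject_id": [0, 0], "condition": ["a", "b"], "volume_ul": [1.0, 2.0]}
        )
        with pytest.raises(InsufficientDataError):
            stats.MeasurementSeries(records=df, design="two_condition_paired")


class TestPairedT:
    def test_identical_conditions(self):
        rep = stats.paired_t(_series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_constant_nonzero_differences_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            stats.paired_t(_series([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0]))

    def test_closed_form_example(self):
        # differences {1, −1, 2, 0, 3}: t = d̄/(s_d/√n) = 1.4142, p = 0.2302
        b = [10.0, 11.0, 12.0, 13.0, 14.0]
        a = [11.0, 10.0, 14.0, 13.0, 17.0]
        rep = stats.paired_t(_series(a, b))
        assert abs(rep.statistic) == pytest.approx(1.4142, abs=1e-4)
        assert rep.p_value == pytest.approx(0.2302, abs=1e-4)

    def test_matches_direct_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 8)
            rep = stats.paired_t(_series(list(d + 5), [5.0] * 8))
            t = d.mean() / (d.std(ddof=1) / np.sqrt(8))
            from scipy import stats as sps

            assert rep.statistic == pytest.approx(t)
            assert rep.p_value == pytest.approx(2 * sps.t.sf(abs(t), 7))


class TestWilcoxon:
    def test_symmetric_pair_p_is_one(self):
        rep = stats.wilcoxon_signed_rank(_series([1.0, -1.0], [0.0, 0.0]))
        assert rep.p_value == 1.0

    def test_all_positive_n5_exact(self):
        # all five differences positive: one-tailed 1/32, two-tailed 1/16
        rep = stats.wilcoxon_signed_rank(
            _series([1.0, 2.0, 3.0, 4.0, 5.0], [0.5, 1.2, 2.1, 3.3, 4.4])
        )
        assert rep.p_value == pytest.approx(0.0625)

    def test_identical_conditions_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            stats.wilcoxon_signed_rank(_series([1.0, 2.0], [1.0, 2.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_sign_enumeration(self, seed):
        """Enumerate all 2^n signed-rank sums for the exact two-sided p."""
        rng = np.random.default_rng(seed)
        n = 7
        d = rng.normal(0.4, 1.0, n)
        while len(np.unique(np.abs(d))) < n or (d == 0).any():
            d = rng.normal(0.4, 1.0, n)
        rep = stats.wilcoxon_signed_rank(_series(list(d + 9), [9.0] * n))
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_plus = ranks[d > 0].sum()
        total = n * (n + 1) / 2
        w_obs = min(w_plus, total - w_plus)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, total - w) <= w_obs:
                count += 1
        assert rep.p_value == pytest.approx(count / 2**n)


class TestICC:
    def test_duplicated_measurements_give_perfect_agreement(self):
        rep = stats.icc_absolute_agreement(
            _series([10.0, 20.0, 30.0, 40.0], [10.0, 20.0, 30.0, 40.0])
        )
        assert rep.icc == pytest.approx(1.0, abs=1e-9)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(4)
        n = 200
        rep = stats.icc_absolute_agreement(
            _series(list(rng.normal(0, 1, n)), list(rng.normal(0, 1, n)),
                    design="two_rater")
        )
        assert abs(rep.icc_raw) < 0.1

    def test_variance_component_recovery(self):
        # subject σ² = 4, error σ² = 1 → ICC = 4/5
        rng = np.random.default_rng(5)
        n = 500
        subj = rng.normal(0, 2.0, n)
        a = subj + rng.normal(0, 1.0, n)
        b = subj + rng.normal(0, 1.0, n)
        rep = stats.icc_absolute_agreement(_series(list(a), list(b)))
        assert rep.icc == pytest.approx(0.8, abs=0.05)
        lo, hi = rep.icc_ci
        assert lo <= rep.icc <= hi

    def test_negative_estimate_truncated_but_raw_kept(self):
        # anti-correlated raters force a negative raw ICC
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [5.0, 4.0, 3.0, 2.0, 1.0]
        rep = stats.icc_absolute_agreement(_series(a, b))
        assert rep.icc == 0.0
        assert rep.icc_raw < 0.0


class TestWilksLambda:
    def test_three_identical_conditions(self):
        v = [10.0, 12.0, 14.0, 16.0]
        rep = stats.wilks_lambda_repeated(_series(v, v, v))
        assert rep.statistic == 1.0
        assert rep.p_value == 1.0

    def test_zero_covariance_contrasts_reduce_to_closed_form(self):
        # contrast vectors d1, d2 constructed with zero sample covariance:
        # T² = n·(d̄1²/s1² + d̄2²/s2²)
        d1 = np.array([1.0, 2.0, 1.0, 2.0])
        d2 = np.array([3.0, 3.0, 4.0, 4.0])
        c3 = np.zeros(4)
        c2 = d2
        c1 = d1 + d2
        rep = stats.wilks_lambda_repeated(_series(list(c1), list(c2), list(c3)))
        n = 4
        t2 = n * (d1.mean() ** 2 / d1.var(ddof=1) + d2.mean() ** 2 / d2.var(ddof=1))
        lam = 1 / (1 + t2 / (n - 1))
        assert rep.statistic == pytest.approx(lam)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.wilks_lambda_repeated(
                _series([1.0, 2.0], [2.0, 1.0], [1.5, 2.5])
            )


class TestCV:
    def test_printed_delivery_device_cv(self):
        # mean 49.2, SD 4.7 → CV 9.55%, printed as 10%
        assert 4.7 / 49.2 * 100 == pytest.approx(9.55, abs=0.01)

    def test_two_value_closed_form(self):
        assert stats.coefficient_of_variation([40.0, 60.0]) == pytest.approx(28.28, abs=0.01)

    def test_constant_values_give_zero(self):
        assert stats.coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(InvariantError):
            stats.coefficient_of_variation([-1.0, 1.0])


class TestDeliveryAccuracy:
    def test_summary_fields(self):
        out = stats.delivery_accuracy([40.0, 60.0], intended_ul=50.0)
        assert out["percent_error"] == pytest.approx(0.0)
        assert out["cv_pct"] == pytest.approx(28.28, abs=0.01)
        assert out["n"] == 2

    def test_underdelivery_is_negative(self):
        out = stats.delivery_accuracy([45.0, 47.0], intended_ul=50.0)
        assert out["percent_error"] < 0


class TestSurgeonVsMeasured:
    def test_perfect_agreement(self):
        losses = [(10.0, 10.0), (20.0, 20.0), (30.0, 30.0), (40.0, 40.0)]
        rep = stats.surgeon_vs_measured(losses)
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0
        assert rep.icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_offset_attenuates_icc(self):
        # surgeon misses an independent loss component; as its variance
        # dominates, agreement collapses toward 0
        rng = np.random.default_rng(6)
        n = 40
        surgeon = rng.uniform(0, 10, n)
        measured = surgeon + rng.normal(40, 25, n)
        rep = stats.surgeon_vs_measured(list(zip(surgeon, measured)))
        assert rep.icc < 0.3
        assert rep.p_value < 0.001

    def test_constant_surgeon_estimate_gives_no_agreement(self):
        rng = np.random.default_rng(7)
        measured = rng.uniform(20, 80, 30)
        rep = stats.surgeon_vs_measured([(0.0, m) for m in measured])
        assert rep.icc < 0.2


def test_unit_rescaling_leaves_tests_invariant():
    rng = np.random.default_rng(8)
    a = list(rng.normal(30, 10, 12))
    b = list(rng.normal(31, 10, 12))
    for scale in (1.0, 1000.0):  # μL → nL
        s = _series([x * scale for x in a], [x * scale for x in b])
        if scale == 1.0:
            base_t = stats.paired_t(s)
            base_w = stats.wilcoxon_signed_rank(s)
            base_i = stats.icc_absolute_agreement(s)
        else:
            assert stats.paired_t(s).p_value == pytest.approx(base_t.p_value)
            assert stats.wilcoxon_signed_rank(s).p_value == pytest.approx(base_w.p_value)
            assert stats.icc_absolute_agreement(s).icc == pytest.approx(base_i.icc, abs=1e-9)
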