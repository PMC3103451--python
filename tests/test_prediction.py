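import math

import numpy as np
import pandas as pd
import pytest

from refluxpred.prediction import (
    DayPredictionResult,
    optimize_day,
    prediction_rates_at_level,
    predict_cohort,
    select_best_day,
    sweep_day,
)


def brute_force_sweep(scores, flags, step, score_max):
    """Oracle: recompute every level's groups by direct counting."""
    scores = np.asarray(scores, float)
    flags = np.asarray(flags, bool)
    keep = ~np.isnan(scores)
    scores, flags = scores[keep], flags[keep]
    rows = []
    k = 0
    while k * step <= score_max + 1e-9:
        level = k * step
        low = scores <= level + 1e-9
        n_low, n_high = int(low.sum()), int((~low).sum())
        rows.append(
            {
                "level": level,
                "n_low": n_low,
                "n_resp_low": int(flags[low].sum()),
                "response_rate": flags[low].mean() if n_low else math.nan,
                "n_high": n_high,
                "n_nonresp_high": int((~flags[~low]).sum()),
                "nonresponse_rate": (~flags[~low]).mean() if n_high else math.nan,
            }
        )
        k += 1
    return pd.DataFrame(rows)


def brute_force_optimum(scores, flags, step, score_max, min_group):
    """Oracle: full scan of the level grid with explicit tie-breaks
    (max rate, then max coverage, then the boundary-hugging level)."""
    table = brute_force_sweep(scores, flags, step, score_max)
    low_ok = table[table["n_low"] >= max(min_group, 1)]
    high_ok = table[table["n_high"] >= max(min_group, 1)]
    if low_ok.empty or high_ok.empty:
        return None
    tie_low = low_ok[low_ok["response_rate"] >= low_ok["response_rate"].max() - 1e-12]
    tie_low = tie_low[tie_low["n_low"] == tie_low["n_low"].max()]
    tie_high = high_ok[
        high_ok["nonresponse_rate"] >= high_ok["nonresponse_rate"].max() - 1e-12
    ]
    tie_high = tie_high[tie_high["n_high"] == tie_high["n_high"].max()]
    L = tie_low["level"].min()
    U = tie_high["level"].max()
    return L, U, tie_low["response_rate"].max(), tie_high["nonresponse_rate"].max()


class TestRatesAtLevel:
    def test_six_patient_hand_count(self):
        scores = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        flags = pd.Series([True, True, True, False, False, False])
        rr, nr, n_low, n_high = prediction_rates_at_level(scores, flags, 3.0)
        assert (rr, nr, n_low, n_high) == (1.0, 1.0, 3, 3)

    def test_published_day10_gi_group_reproduces_rate(self):
        # 1043 patients at/below the level, 914 of them responders -> 87.6%
        scores = np.concatenate([np.full(1043, 1.0), np.full(154, 9.0)])
        flags = np.concatenate(
            [
                np.repeat([True, False], [914, 1043 - 914]),
                np.repeat([False, True], [108, 154 - 108]),
            ]
        )
        rr, nr, n_low, n_high = prediction_rates_at_level(scores, flags, 1.47)
        assert n_low == 1043 and n_high == 154
        assert round(100 * rr, 1) == 87.6
        assert rr == pytest.approx(914 / 1043)
        assert nr == pytest.approx(108 / 154)

    def test_empty_low_group_rate_undefined_not_fabricated(self):
        rr, nr, n_low, _ = prediction_rates_at_level(
            pd.Series([5.0, 6.0]), pd.Series([True, False]), 0.5
        )
        assert n_low == 0 and math.isnan(rr) and nr == 0.5

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            prediction_rates_at_level(pd.Series(dtype=float), pd.Series(dtype=bool), 1)
        with pytest.raises(ValueError, match="level"):
            prediction_rates_at_level(pd.Series([1.0]), pd.Series([True]), -0.5)


class TestSweep:
    def test_grid_size_for_gi_maximum(self):
        sweep = sweep_day(pd.Series([1.0]), pd.Series([True]), 0.01, 30.77)
        assert sweep.levels.size == 3078  # floor(30.77/0.01) + 1
        assert sweep.levels[0] == 0.0
        assert sweep.levels[-1] == pytest.approx(30.77)

    def test_all_responders_rate_one_everywhere_supported(self):
        scores = pd.Series(np.linspace(0, 5, 20))
        sweep = sweep_day(scores, pd.Series([True] * 20), 0.5, 5.0)
        assert np.all(sweep.response_rate[sweep.n_low > 0] == 1.0)

    def test_matches_brute_force_on_random_cohort(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(0, 5, 50).round(2)
        flags = rng.random(50) < 0.6
        sweep = sweep_day(scores, flags, 0.05, 5.0)
        oracle = brute_force_sweep(scores, flags, 0.05, 5.0)
        np.testing.assert_array_equal(sweep.n_low, oracle["n_low"])
        np.testing.assert_array_equal(sweep.n_resp_low, oracle["n_resp_low"])
        np.testing.assert_array_equal(sweep.n_high, oracle["n_high"])
        np.testing.assert_allclose(
            sweep.response_rate, oracle["response_rate"], equal_nan=True
        )
        np.testing.assert_allclose(
            sweep.nonresponse_rate, oracle["nonresponse_rate"], equal_nan=True
        )

    def test_conservation_of_responders_at_every_level(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 30.77, 200)
        flags = rng.random(200) < 0.7
        sweep = sweep_day(scores, flags, 0.01, 30.77)
        resp_high = (sweep.n_high - sweep.n_nonresp_high)
        assert np.all(sweep.n_resp_low + resp_high == flags.sum())
        assert np.all(np.diff(sweep.n_low) >= 0)

    def test_missing_scores_excluded_from_denominators(self):
        scores = pd.Series([1.0, np.nan, 3.0])
        sweep = sweep_day(scores, pd.Series([True, True, False]), 1.0, 4.0)
        assert sweep.n_patients == 2

    def test_step_validation(self):
        with pytest.raises(ValueError, match="step"):
            sweep_day(pd.Series([1.0]), pd.Series([True]), 0.0, 5.0)


class TestOptimize:
    @pytest.mark.parametrize("seed", range(6))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        scores = rng.uniform(0, 30.77, n).round(2)
        flags = rng.random(n) < rng.uniform(0.3, 0.8)
        min_group = int(rng.integers(1, 15))
        sweep = sweep_day(scores, flags, 0.01, 30.77)
        got = optimize_day(sweep, min_group=min_group)
        oracle = brute_force_optimum(scores, flags, 0.01, 30.77, min_group)
        assert oracle is not None
        L, U, rr, nr = oracle
        assert got.response_level == pytest.approx(L)
        assert got.nonresponse_level == pytest.approx(U)
        assert got.response_rate == pytest.approx(rr)
        assert got.nonresponse_rate == pytest.approx(nr)

    def test_separated_toy_finds_boundary_levels(self):
        # responders all score < 2, non-responders all > 8
        scores = np.array([0.5, 1.0, 1.9, 8.5, 9.0, 9.9])
        flags = np.array([True, True, True, False, False, False])
        sweep = sweep_day(scores, flags, 0.01, 10.0)
        res = optimize_day(sweep, min_group=1)
        assert res.admissible
        assert res.response_rate == 1.0 and res.nonresponse_rate == 1.0
        # L hugs the responder boundary (grid point at the top responder
        # score), U the non-responder boundary (last level below 8.5)
        assert res.response_level == pytest.approx(1.90)
        assert res.nonresponse_level == pytest.approx(8.49)
        assert res.indeterminate_width == pytest.approx(6.59)

    def test_all_responders_degenerate_tiebreak(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        flags = np.array([True] * 4)
        res = optimize_day(sweep_day(scores, flags, 1.0, 4.0), min_group=1)
        # non-response rate is 0 wherever defined; smallest qualifying level wins
        assert res.nonresponse_rate == 0.0
        assert res.nonresponse_level == 0.0

    def test_min_group_unattainable_flags_inadmissible(self):
        scores = np.array([1.0, 2.0])
        flags = np.array([True, False])
        res = optimize_day(sweep_day(scores, flags, 1.0, 4.0), min_group=5)
        assert not res.admissible and "no level" in res.reason

    def test_grid_boundary_perturbation_is_local(self):
        # nudging one score across a cell boundary by < step/2 may only
        # shift counts at that single boundary level
        scores = np.array([1.0, 2.0, 3.0])
        flags = np.array([True, True, False])
        s1 = sweep_day(scores, flags, 0.01, 4.0)
        scores2 = scores.copy()
        scores2[1] += 0.004
        s2 = sweep_day(scores2, flags, 0.01, 4.0)
        changed = np.flatnonzero(s1.n_low != s2.n_low)
        assert changed.size <= 1
        assert all(s1.levels[i] == pytest.approx(2.0) for i in changed)
        assert np.all(np.abs(s1.n_low - s2.n_low) <= 1)


class TestSelectBestDay:
    @staticmethod
    def result(day, width, kind="gi", admissible=True):
        return DayPredictionResult(
            day=day,
            score_kind=kind,
            admissible=admissible,
            response_level=1.0,
            nonresponse_level=1.0 + width,
            response_rate=0.9,
            nonresponse_rate=0.7,
            n_low=100,
            n_high=50,
        )

    def test_single_admissible_day_selected(self):
        summary = select_best_day([self.result(4, 2.0)])
        assert summary.best["gi"].day == 4

    def test_narrowest_zone_wins_and_baseline_reported_separately(self):
        summary = select_best_day(
            [
                self.result(0, 0.5),
                self.result(3, 4.0),
                self.result(10, 1.0),
            ]
        )
        assert summary.best["gi"].day == 10
        assert summary.baseline["gi"].day == 0  # never competes

    def test_equal_width_ties_break_to_earlier_day(self):
        summary = select_best_day([self.result(7, 2.0), self.result(4, 2.0)])
        assert summary.best["gi"].day == 4

    def test_no_admissible_day_yields_explicit_no_prediction(self):
        summary = select_best_day([self.result(4, 2.0, admissible=False)])
        assert "gi" not in summary.best

    def test_constructed_cohort_best_day_verified_by_brute_force(self):
        # Build daily scores where separation sharpens with day: the last
        # candidate day must give the narrowest indeterminate zone.
        rng = np.random.default_rng(5)
        n = 120
        flags = rng.random(n) < 0.6
        rows = []
        for day in range(0, 11):
            spread = 4.0 - 0.35 * day
            centre = np.where(flags, 1.0, 7.0)
            scores = np.clip(centre + rng.uniform(-spread, spread, n), 0, 10)
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": [f"P{i}" for i in range(n)],
                        "day": day,
                        "gi": scores,
                        "wso": 0.0,
                        "total": scores,
                    }
                )
            )
        daily = pd.concat(rows, ignore_index=True)
        statuses = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "horizon_day": 56,
                "is_responder": flags,
            }
        )
        summary = predict_cohort(
            daily, statuses, score_kinds=("gi",), step=0.05, min_group=10
        )
        widths = {}
        for day in range(1, 11):
            sub = daily[daily["day"] == day].set_index("patient_id")
            oracle = brute_force_optimum(
                sub["gi"].to_numpy(),
                statuses.set_index("patient_id")["is_responder"]
                .reindex(sub.index)
                .to_numpy(),
                0.05,
                30.77,
                10,
            )
            if oracle and oracle[0] <= oracle[1]:
                widths[day] = oracle[1] - oracle[0]
        best_day = min(widths, key=lambda d: (widths[d], d))
        assert summary.best["gi"].day == best_day
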