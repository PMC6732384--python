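"""Rate transformation, relative diversification, second-for-third
comparison rates, and changepoint detection."""

import numpy as np
import pytest

import palaeocr as pc
from palaeocr.occurrences import IncidenceMatrix, TimeBinScheme
from palaeocr.rates import changepoint_single, prob_to_rate


class TestProbToRate:
    def test_no_loss_gives_zero(self):
        assert prob_to_rate(1.0, 2.3) == 0.0

    def test_unit_rate(self):
        assert prob_to_rate(np.exp(-1.0), 1.0) == pytest.approx(1.0)

    def test_hand_value(self):
        assert prob_to_rate(0.8, 2.3) == pytest.approx(0.09702, abs=5e-6)

    def test_zero_probability_is_censored_infinity(self):
        assert prob_to_rate(0.0, 2.0) == np.inf

    def test_probability_above_one_rejected(self):
        with pytest.raises(ValueError):
            prob_to_rate(1.2, 2.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            prob_to_rate(0.5, 0.0)

    def test_strictly_decreasing_in_prob_and_scales_inversely_in_dt(self):
        probs = np.linspace(0.05, 1.0, 25)
        rates = prob_to_rate(probs, 2.0)
        assert (np.diff(rates) < 0).all()
        assert np.allclose(prob_to_rate(probs, 4.0), rates / 2.0)

    def test_round_trip_recovers_probability(self):
        probs = np.linspace(0.01, 1.0, 50)
        dt = 2.3
        assert np.allclose(np.exp(-prob_to_rate(probs, dt) * dt), probs,
                           atol=1e-12)


class TestEvolutionaryRates:
    def test_unit_survival_gives_zero_extinction(self, stable_bundle):
        fit = stable_bundle.pradel
        import copy
        f = copy.deepcopy(fit)
        f.params["survival"] = np.ones_like(f.params["survival"])
        rs = pc.evolutionary_rates(f, stable_bundle.config.scheme)
        assert np.allclose(np.nan_to_num(rs.series("extinction_rate")), 0.0)

    def test_hand_value_between_midpoints(self):
        # phi = 0.9 between midpoints 2.5 Myr apart -> 0.04214 per Myr
        assert prob_to_rate(0.9, 2.5) == pytest.approx(0.04214, abs=5e-6)

    def test_recovers_true_rates_within_ci(self, stable_bundle):
        rs = pc.evolutionary_rates(stable_bundle.pradel,
                                   stable_bundle.config.scheme)
        tab = rs.table
        ext = tab[tab["metric"] == "extinction_rate"]
        true_ext = stable_bundle.truth.extinction_rates
        inside = (ext["ci_low"].to_numpy() <= true_ext) & \
            (true_ext <= ext["ci_high"].to_numpy())
        assert inside.mean() >= 0.8

    def test_scheme_mismatch_rejected(self, stable_bundle):
        other = TimeBinScheme.uniform(10, 3.0)
        with pytest.raises(ValueError, match="do not match"):
            pc.evolutionary_rates(stable_bundle.pradel, other)

    def test_csv_round_trip(self, stable_bundle, tmp_path):
        import pandas as pd
        rs = pc.evolutionary_rates(stable_bundle.pradel,
                                   stable_bundle.config.scheme)
        path = tmp_path / "rates.csv"
        rs.to_csv(path)
        back = pd.read_csv(path, comment="#")
        assert len(back) == len(rs.table)


class TestRelativeDiversification:
    @pytest.mark.parametrize("prev,cur,expect", [
        (50, 100, 0.5), (100, 100, 0.0), (150, 100, -0.5),
    ])
    def test_hand_values(self, prev, cur, expect):
        out = pc.relative_diversification([prev, cur])
        assert np.isnan(out[0])
        assert out[1] == pytest.approx(expect)

    def test_zero_richness_flagged_undefined(self):
        out = pc.relative_diversification([10, 0, 5])
        assert np.isnan(out[1])

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(0)
        n = rng.integers(1, 500, 50).astype(float)
        out = pc.relative_diversification(n)
        assert np.nanmax(out) <= 1.0


class TestAlroy2f3:
    def test_no_turnover_gives_zero_rates(self):
        mat = IncidenceMatrix([f"g{i}" for i in range(5)],
                              TimeBinScheme.uniform(6, 2.0),
                              np.ones((5, 6), dtype=int))
        rs = pc.alroy_2f3_rates(mat)
        ext = rs.series("extinction_2f3_raw")
        ori = rs.series("origination_2f3_raw")
        assert np.allclose(ext[np.isfinite(ext)], 0.0)
        assert np.allclose(ori[np.isfinite(ori)], 0.0)
        # edge bins undefined by construction
        assert np.isnan(ext[[0, -2, -1]]).all()
        assert np.isnan(ori[[0, 1, -1]]).all()

    def test_reversal_duality(self):
        rng = np.random.default_rng(21)
        cells = (rng.random((40, 8)) < 0.5).astype(int)
        cells[cells.sum(axis=1) == 0, 0] = 1
        mat = IncidenceMatrix([f"g{i}" for i in range(40)],
                              TimeBinScheme.uniform(8, 2.0), cells)
        fwd = pc.alroy_2f3_rates(mat)
        rev = pc.alroy_2f3_rates(mat.reversed())
        np.testing.assert_allclose(fwd.series("origination_2f3_raw"),
                                   rev.series("extinction_2f3_raw")[::-1])

    def test_hand_computed_fixture(self):
        # 4 genera, 5 bins; focal bin 1 counts worked out by hand:
        # t2d=2 (g0,g1), part=1 (g3), s1d: g1 (1,1,0,0 over bins 0..3),
        # s2d: g3 (1,0,1,0), s3d: none -> E = (1 - 1)/3 = 0
        # focal bin 2: t2d=2 (g0,g2), part=0, s1d: g2? (1,1,0,0 over 1..4)
        cells = np.array([
            [1, 1, 1, 1, 1],   # g0 range-through
            [1, 1, 0, 0, 0],   # g1 early extinction
            [0, 1, 1, 0, 0],   # g2 short range
            [1, 0, 1, 0, 0],   # g3 part-timer at bin 1
        ])
        mat = IncidenceMatrix(list("abcd"), TimeBinScheme.uniform(5, 2.0),
                              cells)
        rs = pc.alroy_2f3_rates(mat)
        ext = rs.series("extinction_2f3_raw")
        # bin 1: s1d = {g1}; s2d = {g3}; s3d = {} -> substitute mid(1,1,0)=1
        assert ext[1] == pytest.approx(np.log(1 / (1 - 0.0)))
        # bin 2: t2d = {g0,g2}=2, part=0, s1d = {g2}=1, s2d=0, s3d=0
        # -> E = (1 - 0)/2, rate = ln(1/(1-0.5))
        assert ext[2] == pytest.approx(np.log(2.0))

    def test_too_few_bins_rejected(self):
        mat = IncidenceMatrix(["a"], TimeBinScheme.uniform(3, 2.0),
                              np.array([[1, 1, 1]]))
        with pytest.raises(ValueError, match="at least 4"):
            pc.alroy_2f3_rates(mat)

    def test_tracks_cr_rates_on_volatile_truth(self, volatile_bundle):
        """Cross-method consistency: where the true rates vary, the 2f3
        extinction series and the CR-derived one should agree in rank."""
        from scipy.stats import spearmanr
        rs_cr = pc.evolutionary_rates(volatile_bundle.pradel,
                                      volatile_bundle.config.scheme)
        cr_ext = rs_cr.series("extinction_rate")
        rs_23 = pc.alroy_2f3_rates(volatile_bundle.matrix)
        ext23 = rs_23.series("extinction_2f3_per_myr")
        ok = np.isfinite(cr_ext) & np.isfinite(ext23)
        rho = spearmanr(cr_ext[ok], ext23[ok]).statistic
        assert ok.sum() >= 6
        assert rho >= 0.7


class TestChangepoint:
    def test_exact_step_found_at_boundary(self):
        res = changepoint_single([5, 5, 5, 1, 1, 1])
        assert res.found and res.index == 3
        assert res.mean_before == pytest.approx(5.0)
        assert res.mean_after == pytest.approx(1.0)

    def test_constant_series_has_no_changepoint(self):
        assert not changepoint_single([2.0] * 12).found

    def test_weak_noise_only_series_rejected(self):
        rng = np.random.default_rng(1)
        res = changepoint_single(rng.normal(0, 1, 40))
        # a pure-noise series should usually be rejected; at minimum the
        # penalized gain must be small compared to a real step
        step = changepoint_single(np.r_[np.zeros(20), np.full(20, 3.0)])
        assert step.penalized_gain > max(res.penalized_gain, 0.0) + 10

    def test_too_few_finite_values_rejected(self):
        with pytest.raises(ValueError, match="6 finite"):
            changepoint_single([1.0, 2.0, np.nan, 3.0, 4.0, np.nan, 5.0])

    def test_nans_dropped_but_index_is_original(self):
        vals = [np.nan, 5, 5, 5, np.nan, 5, 1, 1, 1, 1, np.nan]
        res = changepoint_single(vals)
        assert res.found and res.index == 6

    def test_noisy_step_located_within_one_bin(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.r_[np.full(15, 2.0), np.full(15, 0.5)] + rng.normal(0, 0.3, 30)
            res = changepoint_single(x)
            hits += bool(res.found and abs(res.index - 15) <= 1)
        assert hits >= 90

    def test_midpoint_boundary_age_reported(self):
        res = changepoint_single([5, 5, 5, 1, 1, 1],
                                 midpoints=[11, 9, 7, 5, 3, 1])
        assert res.boundary_age == pytest.approx(6.0)
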