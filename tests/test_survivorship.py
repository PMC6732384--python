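"""Cohort survivorship curves and the longevity readings l_bw/l_fw/l_o."""

import numpy as np
import pytest

import palaeocr as pc
from palaeocr.cr import CRFit, FitOptions
from palaeocr.occurrences import TimeBinScheme
from palaeocr.survivorship import (cohort_fraction_curve, longevity_series,
                                   survivorship_levels)


def _chain_fit(k, phi, gamma, duration=2.0):
    """A CRFit carrying fixed probability chains (no data behind it)."""
    scheme = TimeBinScheme.uniform(k, duration)
    return CRFit(model="Pradel", scheme=scheme, n_genera=1,
                 observed_richness=np.ones(k, int),
                 params={"survival": np.full(k - 1, float(phi)),
                         "seniority": np.full(k - 1, float(gamma)),
                         "detection": np.full(k, 0.5)},
                 se_link={}, ci_low={}, ci_high={}, loglik=0.0,
                 converged=True, n_evaluations=0)


class TestCohortCurve:
    def test_immortal_cohort_is_flat(self):
        curve = cohort_fraction_curve(_chain_fit(6, 1.0, 1.0), 3)
        assert np.allclose(curve.fraction, 1.0)

    def test_posterior_fractions_are_geometric(self):
        curve = cohort_fraction_curve(_chain_fit(6, 0.9, 0.8), 0)
        assert np.allclose(curve.posterior(),
                           [1.0, 0.9, 0.81, 0.729, 0.6561, 0.59049])

    def test_antecedent_fractions_use_seniority(self):
        curve = cohort_fraction_curve(_chain_fit(5, 0.9, 0.8), 4)
        assert np.allclose(curve.antecedent()[::-1],
                           [1.0, 0.8, 0.64, 0.512, 0.4096])

    def test_curve_non_increasing_away_from_focal_bin(self, stable_bundle):
        for t_i in range(stable_bundle.pradel.k):
            c = cohort_fraction_curve(stable_bundle.pradel, t_i)
            assert (np.diff(c.posterior()) <= 1e-12).all()
            assert (np.diff(c.antecedent()) >= -1e-12).all()
            assert c.fraction[t_i] == 1.0

    def test_out_of_range_focal_bin_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cohort_fraction_curve(_chain_fit(5, 0.9, 0.9), 7)

    def test_refit_mode_needs_data(self, stable_bundle):
        with pytest.raises(ValueError, match="needs the incidence"):
            cohort_fraction_curve(stable_bundle.pradel, 3, mode="refit")

    def test_refit_mode_close_to_chain_mode(self, stable_bundle):
        chain = cohort_fraction_curve(stable_bundle.pradel, 4)
        refit = cohort_fraction_curve(stable_bundle.pradel, 4, mode="refit",
                                      data=stable_bundle.matrix)
        assert np.nanmax(np.abs(chain.fraction - refit.fraction)) < 0.15

    def test_tracks_true_cohort_survival(self):
        """Modelled posterior fractions stay near the realized cohort
        survival of the generator (mean abs error < 0.05 over replicates)."""
        errs = []
        for seed in range(20):
            cfg = pc.scenario("stable", n_super=1000, seed=seed)
            table, truth = pc.simulate_occurrences(cfg)
            mat = pc.bin_occurrences(table, cfg.scheme)
            fit = pc.fit_pradel(mat, FitOptions(n_restarts=1, seed=seed,
                                                compute_ci=False))
            t_i = 3
            curve = cohort_fraction_curve(fit, t_i)
            # realized survival of the true bin-3 cohort
            alive3 = (truth.entry_bin <= t_i) & (truth.exit_bin >= t_i)
            denom = alive3.sum()
            for k_off in range(1, 4):
                frac_true = ((alive3 & (truth.exit_bin >= t_i + k_off)).sum()
                             / denom)
                errs.append(abs(curve.fraction[t_i + k_off] - frac_true))
        assert np.mean(errs) < 0.05


class TestSurvivorshipLevels:
    def test_worked_geometric_example(self):
        # phi = 0.9 on uniform 2-Myr bins: posterior fractions
        # 0.9, 0.81, 0.729, 0.6561 ...; midpoint-to-distal-boundary readings
        curve = cohort_fraction_curve(_chain_fit(10, 0.9, 0.9), 2)
        lv = survivorship_levels(curve, curve_scheme(10))
        assert lv[0.7][1] == pytest.approx(7.0)   # offset +3 (0.729 >= 0.7)
        assert lv[0.9][1] == pytest.approx(3.0)   # tie at 0.9 inclusive

    def test_level_below_adjacent_bin_reads_half_focal_duration(self):
        curve = cohort_fraction_curve(_chain_fit(8, 0.5, 0.5), 3)
        lv = survivorship_levels(curve, curve_scheme(8), levels=(0.9,))
        l_bw, l_fw, cbw, cfw = lv[0.9]
        assert l_fw == pytest.approx(1.0)
        assert l_bw == pytest.approx(1.0)
        assert not (cbw or cfw)

    def test_flat_curve_censored_at_both_edges(self):
        curve = cohort_fraction_curve(_chain_fit(6, 1.0, 1.0), 3)
        lv = survivorship_levels(curve, curve_scheme(6))
        for q, (l_bw, l_fw, cbw, cfw) in lv.items():
            assert cbw and cfw

    def test_invalid_level_rejected(self):
        curve = cohort_fraction_curve(_chain_fit(6, 0.9, 0.9), 2)
        with pytest.raises(ValueError, match="strictly between"):
            survivorship_levels(curve, curve_scheme(6), levels=(1.5,))


def curve_scheme(k):
    return TimeBinScheme.uniform(k, 2.0)


class TestLongevitySeries:
    def test_overall_longevity_is_exact_sum(self, stable_bundle):
        surv = longevity_series(stable_bundle.pradel,
                                stable_bundle.config.scheme)
        assert np.allclose(surv.table["l_o"],
                           surv.table["l_bw"] + surv.table["l_fw"])

    def test_level_ordering_at_every_bin(self, stable_bundle, volatile_bundle):
        for bundle in (stable_bundle, volatile_bundle):
            surv = longevity_series(bundle.pradel, bundle.config.scheme)
            for col in ("l_fw", "l_bw"):
                s50 = surv.series(col, 0.5)
                s70 = surv.series(col, 0.7)
                s90 = surv.series(col, 0.9)
                assert (s90 <= s70 + 1e-9).all()
                assert (s70 <= s50 + 1e-9).all()

    def test_censoring_propagates_to_overall(self, stable_bundle):
        surv = longevity_series(stable_bundle.pradel,
                                stable_bundle.config.scheme)
        t = surv.table
        assert ((t["censored_bw"] | t["censored_fw"])
                == t["censored_o"]).all()

    def test_time_reversal_swaps_backward_and_forward(self):
        cfg = pc.scenario("volatile", n_super=800, seed=4)
        table, _ = pc.simulate_occurrences(cfg)
        mat = pc.bin_occurrences(table, cfg.scheme)
        opts = FitOptions(n_restarts=1, seed=0, compute_ci=False)
        fwd = longevity_series(pc.fit_pradel(mat, opts), cfg.scheme)
        rmat = mat.reversed()
        rev = longevity_series(pc.fit_pradel(rmat, opts), rmat.scheme)
        for q in (0.5, 0.7, 0.9):
            np.testing.assert_allclose(fwd.series("l_fw", q),
                                       rev.series("l_bw", q)[::-1], atol=1e-6)
            np.testing.assert_allclose(fwd.series("l_bw", q),
                                       rev.series("l_fw", q)[::-1], atol=1e-6)

    def test_csv_output(self, stable_bundle, tmp_path):
        import pandas as pd
        surv = longevity_series(stable_bundle.pradel,
                                stable_bundle.config.scheme)
        path = tmp_path / "surv.csv"
        surv.to_csv(path)
        back = pd.read_csv(path, comment="#")
        assert set(back.columns) >= {"bin_index", "level", "l_bw", "l_fw",
                                     "l_o"}
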