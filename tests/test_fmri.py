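"""HRF construction, LSS beta-series estimation, band regressors, and the
random-intercept coupling model."""
import numpy as np
import pandas as pd
import pytest

from thetareset import (SimulationConfig, build_band_regressors, canonical_hrf,
                        cosine_drift_basis, estimate_lsa_beta_series,
                        estimate_lss_beta_series, fdr_correct, fit_pooled_ols,
                        fit_random_intercept_lme, sample_bold_timeseries,
                        simulate_band_power_table, simulate_coupled_bold)
from thetareset.fmri import BAND_ORDER, BetaSeries


class TestCanonicalHRF:
    def test_shape_contract(self):
        hrf, dhrf = canonical_hrf(2.0)
        assert hrf.sum() > 0
        assert hrf.min() < 0                    # post-peak undershoot
        assert len(dhrf) == len(hrf)

    def test_peak_near_five_seconds(self):
        hrf, _ = canonical_hrf(0.1)
        assert np.argmax(hrf) * 0.1 == pytest.approx(5.0, abs=0.2)

    def test_invalid_tr_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


def test_cosine_drift_cutoff_controls_order():
    basis = cosine_drift_basis(200, 2.0, cutoff=128.0)
    assert basis.shape == (200, int(2 * 400 / 128))
    assert cosine_drift_basis(20, 2.0, cutoff=128.0).shape[1] == 0


class TestLSS:
    def _events(self, onsets):
        return pd.DataFrame({"onset": onsets, "duration": np.ones(len(onsets)),
                             "trial_id": np.arange(len(onsets))})

    def test_isolated_events_recovered_exactly(self):
        onsets = 15.0 + 40.0 * np.arange(5)
        amps = np.array([2.0, -1.0, 0.5, 3.0, 1.5])
        bold = sample_bold_timeseries(onsets, np.ones(5), amps, 2.0)
        bs = estimate_lss_beta_series(bold, self._events(onsets), 2.0,
                                      highpass_cutoff=None)
        assert np.allclose(bs.table["beta"], amps, atol=1e-8)

    def test_lss_equals_lsa_without_overlap(self):
        # ISI a whole number of TRs so every sampled response is identical
        onsets = 16.0 + 44.0 * np.arange(4)
        amps = np.array([1.0, 2.0, -0.5, 0.7])
        bold = sample_bold_timeseries(onsets, np.ones(4), amps, 2.0)
        ev = self._events(onsets)
        lss = estimate_lss_beta_series(bold, ev, 2.0, highpass_cutoff=None)
        lsa = estimate_lsa_beta_series(bold, ev, 2.0, highpass_cutoff=None)
        assert np.allclose(lss.table["beta"], lsa.table["beta"], atol=1e-8)

    def test_duplicate_events_flagged_not_silently_estimated(self):
        """Two trials at the same onset make own and other regressors
        collinear; the affected betas must come back flagged as NaN."""
        onsets = np.array([15.0, 15.0])
        bold = sample_bold_timeseries(onsets, np.ones(2), np.ones(2), 2.0)
        bs = estimate_lss_beta_series(bold, self._events(onsets), 2.0)
        assert bs.table["flagged"].all()
        assert bs.table["beta"].isna().all()

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            estimate_lss_beta_series(np.zeros(50), self._events([10.0]), 2.0)

    def test_short_scan_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            estimate_lss_beta_series(np.zeros(5),
                                     self._events([10.0, 30.0]), 2.0)


class TestBandRegressors:
    def _table(self, rng, n_subj=4, n_trials=30):
        cfg = SimulationConfig(n_subjects=n_subj,
                               n_trials_per_condition=n_trials // 2,
                               include_nomaze=False,
                               seed=int(rng.integers(2 ** 31)))
        return simulate_band_power_table(cfg)

    def test_centering_within_subject(self, rng):
        regs = build_band_regressors(self._table(rng))
        means = regs.groupby("subject_id")[list(BAND_ORDER)].mean()
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-12)

    def test_centering_preserves_correlations(self, rng):
        raw = self._table(rng)
        regs = build_band_regressors(raw)
        for a, b in [("5-6", "7-8"), ("1-4", "11-12")]:
            r_raw = np.corrcoef(raw[a] - raw.groupby("subject_id")[a]
                                .transform("mean"), raw[b] -
                                raw.groupby("subject_id")[b]
                                .transform("mean"))[0, 1]
            r_cen = np.corrcoef(regs[a], regs[b])[0, 1]
            assert r_cen == pytest.approx(r_raw, abs=1e-10)

    def test_generator_bands_only_mildly_collinear(self, rng):
        regs = build_band_regressors(self._table(rng, n_subj=10, n_trials=96))
        corr = regs[list(BAND_ORDER)].corr().to_numpy()
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off_diag).max() < 0.7

    def test_constant_column_flagged_degenerate(self, rng):
        raw = self._table(rng)
        raw["7-8"] = 3.14
        regs = build_band_regressors(raw)
        assert regs.attrs["degenerate_bands"] == ["7-8"]
        assert np.allclose(regs["7-8"], 0.0)

    def test_missing_band_rejected(self, rng):
        with pytest.raises(ValueError, match="missing band"):
            build_band_regressors(self._table(rng).drop(columns="9-10"))


def _coupled(cfg, seed):
    bp = simulate_band_power_table(cfg, np.random.default_rng(seed))
    ds = simulate_coupled_bold(
        bp[["trial_id", "subject_id", "condition", "alley"]], cfg, bp,
        rng=np.random.default_rng(seed + 1))
    return bp, ds


class TestRandomInterceptLME:
    def test_noise_free_coupling_recovered_exactly(self):
        cfg = SimulationConfig(
            n_subjects=5, n_trials_per_condition=10, subject_intercept_sd=0.0,
            bold_noise_sd=0.0, include_nomaze=False,
            coupling_weights={"1-4": 0, "5-6": 0, "7-8": 2.0, "9-10": 0,
                              "11-12": 0}, seed=6)
        bp, ds = _coupled(cfg, 6)
        regs = build_band_regressors(bp)
        fit = fit_random_intercept_lme(ds.true_betas, regs)
        tab = fit.table.set_index("regressor")
        assert tab.loc["7-8", "beta_raw"] == pytest.approx(2.0, abs=1e-8)
        # standardized beta = raw weight rescaled by the grand SDs of the
        # (centred) predictor and the outcome
        sd_ratio = regs["7-8"].std(ddof=1) / ds.true_betas["beta"].std(ddof=1)
        assert tab.loc["7-8", "beta"] == pytest.approx(2.0 * sd_ratio,
                                                       rel=1e-6)

    def test_matches_ols_oracle_with_variance_pinned_to_zero(self):
        cfg = SimulationConfig(n_subjects=8, n_trials_per_condition=15,
                               subject_intercept_sd=0.0, seed=9)
        bp, ds = _coupled(cfg, 9)
        regs = build_band_regressors(bp)
        tb = ds.true_betas[ds.true_betas["condition"] == "maze"]
        fit = fit_random_intercept_lme(tb, regs,
                                       force_zero_random_effects=True)
        ols = fit_pooled_ols(tb, regs)
        assert np.allclose(fit.table["beta_raw"], ols["beta_raw"], atol=1e-8)

    def test_recovers_variance_components(self):
        cfg = SimulationConfig(n_subjects=25, n_trials_per_condition=48,
                               include_nomaze=False, seed=13)
        bp, ds = _coupled(cfg, 13)
        regs = build_band_regressors(bp)
        fit = fit_random_intercept_lme(ds.true_betas, regs)
        assert fit.converged
        # generative values: intercept sd 0.5, residual sd 0.85
        assert np.sqrt(fit.random_intercept_var) == pytest.approx(0.5,
                                                                  abs=0.15)

    def test_null_coupling_holds_nominal_level(self):
        """With zero coupling weights the per-band raw-p rejection rate
        stays near the nominal 5%."""
        from thetareset.validation import lme_null_calibration
        rate = lme_null_calibration(np.random.default_rng(77), n_reps=150)
        assert 0.02 <= rate <= 0.08

    def test_minimum_design_requirements(self):
        cfg = SimulationConfig(n_subjects=2, n_trials_per_condition=10,
                               include_nomaze=False, seed=3)
        bp, ds = _coupled(cfg, 3)
        regs = build_band_regressors(bp)
        with pytest.raises(ValueError, match="3 subjects"):
            fit_random_intercept_lme(ds.true_betas, regs)

    def test_beta_series_uniqueness_enforced(self):
        t = pd.DataFrame({"subject_id": [0, 0], "region_id": ["r", "r"],
                          "trial_id": [1, 1], "beta": [0.1, 0.2]})
        with pytest.raises(ValueError, match="one row per"):
            BetaSeries(t)


class TestFDR:
    def test_uniform_ladder_collapses_to_largest(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_single_p_unchanged(self):
        assert fdr_correct([0.123])[0] == pytest.approx(0.123)

    def test_two_value_step_up(self):
        assert np.allclose(fdr_correct([0.001, 0.9]), [0.002, 0.9])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=20)
        adj = fdr_correct(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])
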