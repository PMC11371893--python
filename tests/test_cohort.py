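"""Synthetic cohort generator: marginals, copula, inverse geometry round trips."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from coroqca.cohort import (
    SAMPLED_METRICS,
    CohortConfig,
    SplitNormal,
    VesselDraw,
    build_area_profile,
    build_vffr_profile,
    default_config,
    fit_marginal,
    generate_cohort,
    sample_event_times,
    sample_metrics,
)
from coroqca.errors import ConfigError
from coroqca.hemodynamics import delta_vffr, distal_vffr
from coroqca.lesion import quantify_vessel


class TestFitMarginal:
    def test_symmetric_triplet_unbounded(self):
        d = fit_marginal(-1.0, 0.0, 1.0)
        assert d.m == pytest.approx(0.0)
        assert d.s1 == pytest.approx(1.4826, abs=2e-4)
        assert d.s2 == pytest.approx(d.s1)
        assert d.median() == pytest.approx(0.0, abs=1e-12)

    def test_quantile_function_returns_triplet(self):
        # numeric-inversion oracle: ppf at the quartile levels must return the
        # configured triplet, and cdf must invert ppf
        for trip, bounds in [
            ((0.34, 0.41, 0.51), (0.0, 1.0)),
            ((0.04, 0.08, 0.13), (0.0, 1.0)),  # strong truncation at 0
            ((21.9, 25.9, 29.8), (1.0, 60.0)),
        ]:
            d = fit_marginal(*trip, support_bounds=bounds)
            assert np.allclose(d.ppf([0.25, 0.5, 0.75]), trip, rtol=5e-3)
            p = np.linspace(0.01, 0.99, 23)
            assert np.allclose(d.cdf(d.ppf(p)), p, atol=1e-9)

    def test_sampled_median_matches_printed_value(self, rng):
        d = fit_marginal(0.34, 0.41, 0.51, support_bounds=(0.0, 1.0))
        x = d.rvs(rng, 100_000)
        assert np.median(x) == pytest.approx(0.41, abs=0.002)
        assert x.min() > 0 and x.max() < 1

    def test_non_increasing_triplet_rejected(self):
        with pytest.raises(ConfigError):
            fit_marginal(0.5, 0.4, 0.6)

    def test_triplet_outside_support_rejected(self):
        with pytest.raises(ConfigError):
            fit_marginal(0.2, 0.5, 1.2, support_bounds=(0.0, 1.0))

    def test_splitnormal_scale_validation(self):
        with pytest.raises(ConfigError):
            SplitNormal(0.0, -1.0, 1.0)


class TestSampleMetrics:
    def test_pooled_spearman_targets(self):
        cfg = default_config()
        lat = sample_metrics(cfg, np.random.default_rng(0), {"FCL": 30_000, "NCL": 30_000})
        rho_dv = spearmanr(lat.MLR, lat.dvffr)[0]
        rho_v = spearmanr(lat.MLR, lat.vffr)[0]
        assert rho_dv == pytest.approx(-0.26, abs=0.03)
        assert rho_v == pytest.approx(0.15, abs=0.03)

    def test_zero_targets_give_independence(self):
        cfg = replace(
            default_config(),
            spearman_targets=((("MLR", "dvffr"), 0.0), (("MLR", "vffr"), 0.0)),
        )
        lat = sample_metrics(cfg, np.random.default_rng(0), {"FCL": 30_000, "NCL": 30_000})
        assert abs(spearmanr(lat.MLR, lat.dvffr)[0]) < 0.02
        assert abs(spearmanr(lat.MLR, lat.vffr)[0]) < 0.02

    def test_deterministic_given_seed(self):
        cfg = default_config()
        a = sample_metrics(cfg, np.random.default_rng(7))
        b = sample_metrics(cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_sampled_marginal_recovery(self):
        """Sampled quartiles against the configured triplets (5%; PLSL 15%
        because conditioning on PLSL < 0.95·LSL removes upper-tail PLSL mass —
        the printed PLSL/LSL marginals put ~10% of independent-style draws in
        the infeasible corner, so the constrained marginal must shift)."""
        cfg = default_config()
        lat = sample_metrics(cfg, np.random.default_rng(1), {"FCL": 20_000, "NCL": 20_000})
        for group in ("FCL", "NCL"):
            sub = lat[lat.group == group]
            for name in SAMPLED_METRICS:
                q = np.percentile(sub[name], [25, 50, 75])
                trip = np.array(cfg.quantiles[group][name])
                tol = 0.15 if name == "PLSL" else 0.05
                assert np.all(np.abs(q / trip - 1) < tol), (group, name, q, trip)

    def test_plsl_feasible(self):
        lat = sample_metrics(default_config(), np.random.default_rng(2), {"FCL": 5000})
        assert ((lat.PLSL > 0.05 * lat.LSL) & (lat.PLSL < 0.95 * lat.LSL)).all()

    def test_non_pd_copula_rejected(self):
        with pytest.raises(ConfigError, match="positive definite"):
            CohortConfig(
                feasibility_spearman=(
                    (("MLR", "MLA"), 0.99),
                    (("MLR", "LSL"), 0.99),
                    (("MLA", "LSL"), -0.99),
                )
            )


def _draw(**kw):
    base = dict(
        vessel_id="T1", MLR=0.40, MLA=2.4, LSL=14.0, PLSL=7.0, dvffr=0.08, vffr=0.84
    )
    base.update(kw)
    return VesselDraw(**base)


class TestGeometryRoundTrip:
    def test_example_vessel_round_trip(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(), rng, cfg)
        m = quantify_vessel(profile)
        assert m.MLR == pytest.approx(0.40, abs=0.01)
        assert m.LSL == pytest.approx(14.0, abs=0.28)
        assert m.PLSL == pytest.approx(7.0, abs=0.14)

    def test_noiseless_round_trip_tight(self, rng):
        cfg = replace(default_config(), noise_rel=0.0)
        profile, nominal = build_area_profile(_draw(), rng, cfg)
        m = quantify_vessel(profile)
        assert m.MLR == pytest.approx(0.40, abs=1e-3)

    def test_infeasible_draw_jittered_or_skipped(self, rng):
        cfg = default_config()
        out = build_area_profile(_draw(PLSL=13.9, LSL=14.0), rng, cfg)
        if out is not None:
            profile, nominal = out
            assert 0.1 * nominal.LSL <= nominal.PLSL <= 0.9 * nominal.LSL

    def test_vffr_round_trip(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(), rng, cfg)
        m = quantify_vessel(profile)
        vprof = build_vffr_profile(nominal, profile, m.segment, cfg)
        assert delta_vffr(vprof, m.segment) == pytest.approx(0.08, abs=0.005)
        assert distal_vffr(vprof) == pytest.approx(0.84, abs=1e-6)
        assert np.all(np.diff(vprof.v) <= 1e-12)  # nonincreasing

    def test_vffr_zero_gradient_outside_lesion(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(dvffr=0.0), rng, cfg)
        m = quantify_vessel(profile)
        vprof = build_vffr_profile(nominal, profile, m.segment, cfg)
        assert delta_vffr(vprof, m.segment) == pytest.approx(0.0, abs=1e-12)
        assert distal_vffr(vprof) == pytest.approx(0.84, abs=1e-9)

    def test_vffr_no_loss_limit(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(vffr=1.0), rng, cfg)
        m = quantify_vessel(profile)
        vprof = build_vffr_profile(nominal, profile, m.segment, cfg)
        assert np.all(vprof.v == 1.0)

    def test_vffr_clip_warns(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(dvffr=0.3, vffr=0.9), rng, cfg)
        m = quantify_vessel(profile)
        with pytest.warns(UserWarning, match="clipped"):
            vprof = build_vffr_profile(nominal, profile, m.segment, cfg)
        assert delta_vffr(vprof, m.segment) == pytest.approx(0.10, abs=0.005)

    def test_vffr_without_lesion_uniform_decay(self, rng):
        cfg = default_config()
        profile, nominal = build_area_profile(_draw(), rng, cfg)
        with pytest.warns(UserWarning, match="no lesion"):
            vprof = build_vffr_profile(nominal, profile, None, cfg)
        assert distal_vffr(vprof) == pytest.approx(0.84, abs=1e-9)
        assert np.all(np.diff(vprof.v) <= 0)


class TestEventTimes:
    def test_bounds_respected(self):
        pt = sample_event_times(default_config(), np.random.default_rng(0), 5000)
        assert pt.time_months.between(1, 60).all()

    def test_nstemi_count_exact(self):
        pt = sample_event_times(default_config(), np.random.default_rng(0))
        assert (pt.mi_type == "NSTEMI").sum() == 52  # round(0.65 * 80)

    def test_median_close_to_configured(self):
        pt = sample_event_times(default_config(), np.random.default_rng(3), 50_000)
        assert pt.time_months.median() == pytest.approx(25.9, abs=0.15)


class TestGenerateCohort:
    def test_structure_and_counts(self, default_table):
        t = default_table
        assert len(t) == 188
        assert t.patient_id.nunique() == 80
        assert int(t.event.sum()) == 80
        assert (t.groupby("patient_id").size().mean()) == pytest.approx(2.35)
        counts = t[t.group == "NCL"].groupby("patient_id").size()
        assert sorted(counts.value_counts().to_dict().items()) == [(1, 52), (2, 28)]

    def test_ncl_share_patient_censoring_time(self, default_table):
        per_patient = default_table.groupby("patient_id").time_months.nunique()
        assert (per_patient == 1).all()

    def test_no_ncl_config(self):
        cfg = replace(default_config(), n_patients=12, n_fcl=12, n_ncl=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = generate_cohort(cfg, keep_profiles=False).table
        assert len(t) == 12
        assert (t.groupby("patient_id").size() == 1).all()

    def test_determinism_same_seed(self):
        cfg = replace(default_config(), n_patients=20, n_fcl=20, n_ncl=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_cohort(cfg, keep_profiles=False).table
            b = generate_cohort(cfg, keep_profiles=False).table
        pd.testing.assert_frame_equal(a, b)

    def test_fcl_ncl_invariant_validation(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_patients=80, n_fcl=70)

    def test_table_round_trips_measured_values(self, default_cohort):
        """Re-quantifying a generated profile reproduces its table row exactly."""
        t = default_cohort.table
        for vid in t.vessel_id.iloc[[0, 50, 150]]:
            row = t[t.vessel_id == vid].iloc[0]
            m = quantify_vessel(default_cohort.area_profiles[vid])
            assert m.MLR == pytest.approx(row.MLR, abs=1e-12)
            assert m.LSL == pytest.approx(row.LSL, abs=1e-12)
            vprof = default_cohort.vffr_profiles[vid]
            assert delta_vffr(vprof, m.segment) == pytest.approx(row.dvffr, abs=1e-9)
            assert distal_vffr(vprof) == pytest.approx(row.vffr, abs=1e-12)

    def test_measured_vs_latent_within_tolerance(self, default_table):
        t = default_table
        assert (t.MLR - t.latent_MLR).abs().max() <= 0.01
        assert ((t.LSL - t.latent_LSL) / t.latent_LSL).abs().max() <= 0.03
        assert ((t.PLSL - t.latent_PLSL) / t.latent_PLSL).abs().max() <= 0.03
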