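"""GAMMAR estimation: design construction, degenerate-limit oracles,
whitening, prediction and explained-variance summaries."""

import numpy as np
import pytest

from cyclexpo import (
    ModelSpec,
    bayes_r2,
    build_design,
    fit_gammar,
    ma3_theoretical_acf,
    predict_exposure,
    residual_diagnostics,
)
from cyclexpo.pipeline import simulate_study
from cyclexpo.segmentation import merge_streams, segment_one_minute
from cyclexpo.synthetic import simulate_sensor_records, simulate_trip

from test_synthetic import _flat_scenario


def _simple_segments(small_network, scenario, minutes=120, seed=21, participant="I", day="Monday"):
    trace = simulate_trip(small_network, minutes, 17.0, start_clock=60, seed=seed)
    recs = simulate_sensor_records(
        trace, scenario, participant, day, seed=seed + 1, network=small_network
    )
    track = merge_streams(trace, recs, trip_id=f"t{seed}", participant=participant, day=day)
    return segment_one_minute(track, small_network)


class TestBuildDesign:
    def test_reference_coding_residential_omitted(self, study_small):
        _, _, segments = study_small
        d = build_design(segments, ModelSpec(response="no2_ugm3"))
        assert "residential" not in d.columns
        for rt in ("primary", "secondary", "tertiary"):
            assert rt in d.columns

    def test_all_residential_road_columns_zero(self, small_network, scenario):
        from cyclexpo import make_road_network

        net = make_road_network(30, type_mix={"residential": 1.0}, seed=4)
        segs = _simple_segments(net, scenario)
        d = build_design(segs, ModelSpec(response="noise_db", spline_space=0, spline_time=0))
        for rt in ("primary", "secondary", "tertiary", "trunk_motorway", "unclassified_service"):
            col = d.X[:, d.columns.index(rt)]
            assert np.all(col == 0.0)

    def test_noise_design_has_no_weather_columns(self, study_small):
        _, _, segments = study_small
        d = build_design(segments, ModelSpec(response="noise_db"))
        assert "humidity" not in d.columns and "wind" not in d.columns
        with pytest.raises(ValueError):
            ModelSpec(response="noise_db", fixed=("humidity", "speed"))

    def test_spline_bases_are_centred(self, study_small):
        _, _, segments = study_small
        d = build_design(segments, ModelSpec(response="no2_ugm3"))
        smooth_cols = d.X[:, d.smooth_mask]
        assert np.all(np.abs(smooth_cols.mean(axis=0)) < 1e-9)

    def test_observation_order_preserved_within_trips(self, study_small):
        _, _, segments = study_small
        d = build_design(segments, ModelSpec(response="no2_ugm3"))
        for s, e in d.trip_slices:
            idx = d.frame["segment_index"].to_numpy()[s:e]
            assert np.all(np.diff(idx) == 1)

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(response="pm25")


class TestDegenerateFits:
    def test_ols_oracle_on_noise_free_linear_data(self, small_network):
        """With no smooths, no random effects and no MA term, the fit must
        equal ordinary least squares to 1e-6."""
        sc = _flat_scenario(scale=1e-300)
        sc.beta_fixed["noise_db"] = {"primary": 2.0, "speed": -0.5}
        segs = _simple_segments(small_network, sc, minutes=150)
        spec = ModelSpec(
            response="noise_db",
            fixed=("speed",) + tuple(
                t for t in ("trunk_motorway", "primary", "secondary", "tertiary", "unclassified_service")
            ),
            spline_time=0,
            spline_space=0,
            ma_order=0,
            likelihood="gaussian",
            include_random=False,
        )
        d = build_design(segs, spec)
        m = fit_gammar(d)
        beta_ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        for i, name in enumerate(d.columns):
            assert m.estimates[name][0] == pytest.approx(beta_ols[i], abs=1e-6)

    def test_intercept_only_constant_response(self, small_network):
        sc = _flat_scenario(scale=1e-300, intercept=64.25)
        segs = _simple_segments(small_network, sc, minutes=60)
        spec = ModelSpec(
            response="noise_db",
            fixed=(),
            spline_time=0,
            spline_space=0,
            ma_order=0,
            likelihood="gaussian",
            include_random=False,
        )
        m = fit_gammar(build_design(segs, spec))
        assert m.estimates["intercept"][0] == pytest.approx(64.25, abs=1e-9)

    def test_too_few_observations_rejected(self, small_network, scenario):
        segs = _simple_segments(small_network, scenario, minutes=40)
        with pytest.raises(ValueError):
            fit_gammar(build_design(segs, ModelSpec(response="no2_ugm3")))


class TestWhitening:
    def test_residual_acf_small_on_well_specified_data(self, fitted_noise):
        assert fitted_noise.converged
        assert all(abs(a) < 0.1 for a in fitted_noise.resid_acf)

    def test_ignoring_ma_leaves_generating_acf(self, study_small):
        """Deliberately dropping the MA term leaves residual lag-1
        autocorrelation at the generating MA(3) rho_1."""
        _, _, segments = study_small
        spec = ModelSpec(response="noise_db", ma_order=0)
        m = fit_gammar(build_design(segments, spec))
        rho1 = ma3_theoretical_acf((0.61, 0.20, 0.08), 1)
        assert m.resid_acf[0] == pytest.approx(rho1, abs=0.08)

    def test_independent_error_data_acf_in_white_noise_band(self, small_network):
        sc = _flat_scenario(ma=(0.0, 0.0, 0.0), scale=2.0, df=50.0)
        segs = []
        for k in range(4):
            segs.extend(_simple_segments(small_network, sc, minutes=150, seed=60 + k))
        spec = ModelSpec(
            response="noise_db", fixed=(), spline_time=0, spline_space=0,
            ma_order=0, likelihood="gaussian", include_random=False,
        )
        m = fit_gammar(build_design(segs, spec))
        n = sum(e - s for s, e in m._design.trip_slices)
        assert all(abs(a) < 2.5 / np.sqrt(n) * 2 for a in m.resid_acf)

    def test_ma_intervals_ordered(self, fitted_noise):
        for est, lo, hi in fitted_noise.ma_coefs:
            assert lo <= est <= hi


class TestBackendEquivalence:
    def test_two_stage_equals_mixed_model_without_ma(self, small_network):
        """On MA-free Gaussian data the two-stage fit agrees with a one-stage
        linear mixed model (statsmodels MixedLM) within interval overlap."""
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import VCSpec

        sc = _flat_scenario(ma=(0.0, 0.0, 0.0), scale=3.0, df=200.0)
        sc.beta_fixed["noise_db"] = {"primary": 3.0, "speed": -0.1}
        for r in sc.random_participant:
            sc.random_participant[r] = {"I": 1.0, "II": -1.0, "III": 0.3}
        segs = []
        for k, (p, day) in enumerate(
            [("I", "Monday"), ("II", "Tuesday"), ("III", "Friday"), ("I", "Saturday")]
        ):
            segs.extend(
                _simple_segments(small_network, sc, minutes=150, seed=80 + k, participant=p, day=day)
            )
        spec = ModelSpec(
            response="noise_db", spline_time=0, spline_space=0,
            ma_order=0, likelihood="gaussian",
        )
        d = build_design(segs, spec)
        ours = fit_gammar(d)

        mats, names, colnames = [], [], []
        for nm, Z, lv in (
            ("day", d.Zd, d.day_levels),
            ("participant", d.Zp, d.participant_levels),
        ):
            if Z is not None:
                mats.append([Z])
                names.append(nm)
                colnames.append([lv])
        ref = sm.MixedLM(
            d.y, d.X, groups=np.zeros(len(d.y)), exog_vc=VCSpec(names, colnames, mats)
        ).fit(reml=True)
        for i, name in enumerate(d.columns):
            est, lo, hi = ours.estimates[name]
            assert lo <= ref.fe_params[i] <= hi
            assert abs(est - ref.fe_params[i]) < 0.15 * max(1.0, abs(ref.fe_params[i]))

    def test_fit_is_deterministic(self, study_small):
        _, _, segments = study_small
        spec = ModelSpec(response="noise_db")
        a = fit_gammar(build_design(segments, spec))
        b = fit_gammar(build_design(segments, spec))
        assert a.estimates == b.estimates
        assert a.ma_coefs == b.ma_coefs


class TestPrediction:
    def test_null_predictor_returns_intercept(self, small_network, scenario):
        segs = _simple_segments(small_network, scenario, minutes=100)
        spec = ModelSpec(
            response="noise_db", spline_time=0, spline_space=0,
            ma_order=0, likelihood="gaussian", include_random=False,
        )
        m = fit_gammar(build_design(segs, spec))
        x0, y0 = segs[0].midpoint_xy
        val = predict_exposure(m, {}, (x0, y0), clock_min=100.0)
        assert val == pytest.approx(m.estimates["intercept"][0], abs=1e-12)

    def test_one_minute_on_primary_adds_its_coefficient(self, fitted_no2):
        x0 = y0 = 2500.0
        base = predict_exposure(fitted_no2, {"primary": 0.0}, (x0, y0), 180.0)
        prim = predict_exposure(fitted_no2, {"primary": 1.0}, (x0, y0), 180.0)
        assert prim - base == pytest.approx(fitted_no2.estimates["primary"][0], abs=1e-9)

    def test_random_intercept_shift(self, fitted_no2):
        xy, clock = (2500.0, 2500.0), 180.0
        base = predict_exposure(fitted_no2, {}, xy, clock, include_random=False)
        shifted = predict_exposure(
            fitted_no2, {}, xy, clock, include_random=True, participant="III"
        )
        expected = fitted_no2.random_intercepts["participant"]["III"][0]
        assert shifted - base == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_warns(self, fitted_no2):
        with pytest.warns(UserWarning):
            predict_exposure(fitted_no2, {}, (1e7, 1e7), 180.0)

    def test_estimate_intervals_ordered(self, fitted_no2):
        for est, lo, hi in fitted_no2.estimates.values():
            assert lo <= est <= hi


class TestExplainedVariance:
    def test_marginal_never_exceeds_conditional(self, fitted_noise, fitted_no2):
        for m in (fitted_noise, fitted_no2):
            assert bayes_r2(m, "marginal") <= bayes_r2(m, "conditional") + 1e-12

    def test_pure_noise_response_r2_near_zero(self, small_network):
        sc = _flat_scenario(ma=(0.0, 0.0, 0.0), scale=5.0, df=100.0)
        segs = []
        for k in range(3):
            segs.extend(_simple_segments(small_network, sc, minutes=150, seed=90 + k))
        spec = ModelSpec(
            response="noise_db", spline_time=4, spline_space=9,
            ma_order=0, likelihood="gaussian", include_random=False,
        )
        m = fit_gammar(build_design(segs, spec))
        assert bayes_r2(m, "marginal") < 0.1

    def test_noiseless_response_r2_near_one(self, small_network):
        sc = _flat_scenario(scale=1e-300)
        sc.beta_fixed["noise_db"] = {"primary": 5.0, "speed": 0.5}
        segs = _simple_segments(small_network, sc, minutes=150)
        spec = ModelSpec(
            response="noise_db", spline_time=0, spline_space=0,
            ma_order=0, likelihood="gaussian", include_random=False,
        )
        m = fit_gammar(build_design(segs, spec))
        assert bayes_r2(m, "marginal") > 0.95


def test_residual_diagnostics_reports_heavy_tails(fitted_noise):
    diag = residual_diagnostics(fitted_noise)
    assert len(diag["acf"]) == 3
    # t4 innovations are leptokurtic; the whitened innovations should show it
    assert diag["excess_kurtosis"] > 0.5
    assert 0.0 <= diag["prop_beyond_3sd"] <= 0.2
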