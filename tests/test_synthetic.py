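"""Generator tests: network construction, trip traces, scenario defaults and
the statistical structure of simulated sensor streams."""

import math

import numpy as np
import pytest

from cyclexpo import (
    DAYS,
    PARTICIPANTS,
    ROAD_TYPES,
    ScenarioParams,
    default_scenario,
    ma3_theoretical_acf,
    make_road_network,
    simulate_sensor_records,
    simulate_trip,
)
from cyclexpo.descriptives import acf_index
from cyclexpo.synthetic import (
    GaussianBumpField,
    TemporalPulse,
    zero_field,
    zero_pulse,
)


def _flat_scenario(ma=(0.61, 0.20, 0.08), scale=2.3, df=30.0, intercept=70.0):
    """Scenario with no fixed effects, no smooth fields and no random
    intercepts: the response is intercept + MA(3) noise."""
    return ScenarioParams(
        beta_fixed={r: {} for r in ("noise_db", "no2_ugm3", "inhaled_ug")},
        intercepts={"noise_db": intercept, "no2_ugm3": 200.0, "inhaled_ug": 7.0},
        random_day={r: {d: 0.0 for d in DAYS} for r in ("noise_db", "no2_ugm3", "inhaled_ug")},
        random_participant={
            r: {p: 0.0 for p in PARTICIPANTS} for r in ("noise_db", "no2_ugm3", "inhaled_ug")
        },
        ma_coefs={"noise_db": ma, "no2_ugm3": ma, "inhaled_ug": ma},
        resid_scale={"noise_db": scale, "no2_ugm3": scale, "inhaled_ug": scale},
        student_df=df,
        spatial_field={r: zero_field() for r in ("noise_db", "no2_ugm3", "inhaled_ug")},
        temporal_profile={r: zero_pulse() for r in ("noise_db", "no2_ugm3", "inhaled_ug")},
        ve_model={"a": 35.0, "b": 0.0, "c": 0.0, "lo": 10.0, "hi": 80.0},
    )


class TestRoadNetwork:
    def test_seed_reproducibility(self):
        a = make_road_network(50, seed=3)
        b = make_road_network(50, seed=3)
        assert [e.edge_id for e in a.edges] == [e.edge_id for e in b.edges]
        assert [e.road_type for e in a.edges] == [e.road_type for e in b.edges]
        assert all(
            ea.geometry.equals(eb.geometry) for ea, eb in zip(a.edges, b.edges)
        )

    def test_degenerate_mix_all_residential(self):
        net = make_road_network(30, type_mix={"residential": 1.0}, seed=1)
        assert all(e.road_type == "residential" for e in net.edges)

    def test_uniform_mix_frequencies_within_3se(self):
        net = make_road_network(100, seed=5)
        m = len(net.edges)
        p = 1.0 / len(ROAD_TYPES)
        se = math.sqrt(p * (1 - p) / m)
        for t in ROAD_TYPES:
            freq = sum(e.road_type == t for e in net.edges) / m
            assert abs(freq - p) < 3 * se

    def test_connected_and_planar_invariants(self):
        import networkx as nx

        net = make_road_network(60, seed=2)
        assert nx.is_connected(net.graph)
        assert all(len(e.geometry.coords) >= 2 for e in net.edges)

    @pytest.mark.parametrize(
        "kwargs", [{"n_nodes": 3}, {"n_nodes": 10, "type_mix": [0.5, 0.5, 0, 0, 0, 0.5]}]
    )
    def test_bad_parameterization_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_road_network(**kwargs, seed=0)


class TestSimulateTrip:
    def test_one_hz_fix_count(self, small_network):
        trace = simulate_trip(small_network, 10, 15.0, start_clock=60, seed=1)
        assert len(trace) == 600

    def test_constant_speed_displacement_250m(self, small_network):
        # at a constant 15 km/h a cyclist covers exactly 250 m per minute
        trace = simulate_trip(small_network, 1, 15.0, start_clock=0, seed=4, speed_cv=0.0)
        along = sum(
            math.hypot(b.x - a.x, b.y - a.y) for a, b in zip(trace[:-1], trace[1:])
        )
        assert along == pytest.approx(250.0 * 59 / 60, rel=0.02)

    def test_seed_reproducibility(self, small_network):
        t1 = simulate_trip(small_network, 3, 17.0, start_clock=100, seed=9)
        t2 = simulate_trip(small_network, 3, 17.0, start_clock=100, seed=9)
        assert t1 == t2

    def test_timestamps_strictly_increasing_and_edges_tagged(self, small_network):
        trace = simulate_trip(small_network, 2, 17.0, start_clock=30, seed=2)
        ts = [f.timestamp for f in trace]
        assert all(b > a for a, b in zip(ts[:-1], ts[1:]))
        ids = {e.edge_id for e in small_network.edges}
        assert all(f.edge_id in ids for f in trace)

    def test_zero_duration_rejected(self, small_network):
        with pytest.raises(ValueError):
            simulate_trip(small_network, 0, 15.0, start_clock=0, seed=0)


class TestDefaultScenario:
    def test_fixed_effect_point_values(self, scenario):
        assert scenario.beta_fixed["no2_ugm3"]["primary"] == 47.21
        assert scenario.beta_fixed["noise_db"]["primary"] == 3.35
        assert scenario.beta_fixed["no2_ugm3"]["humidity"] == 2.13
        assert scenario.beta_fixed["no2_ugm3"]["wind"] == -1.60
        assert scenario.beta_fixed["no2_ugm3"]["speed"] == -1.65
        assert scenario.intercepts == {
            "noise_db": 76.51,
            "no2_ugm3": 115.62,
            "inhaled_ug": 1.73,
        }

    def test_ma_coefficients(self, scenario):
        assert scenario.ma_coefs["noise_db"] == (0.61, 0.20, 0.08)
        assert scenario.ma_coefs["no2_ugm3"] == (0.57, 0.18, 0.08)
        assert scenario.ma_coefs["inhaled_ug"] == (0.68, 0.31, 0.14)

    def test_smooth_field_amplitudes(self, scenario):
        # peak-to-trough extents of the generating fields
        assert scenario.spatial_field["noise_db"].amplitude() == pytest.approx(4.5, rel=0.1)
        assert scenario.spatial_field["no2_ugm3"].amplitude() == pytest.approx(70.0, rel=0.1)
        assert scenario.spatial_field["inhaled_ug"].amplitude() == pytest.approx(2.45, rel=0.1)
        assert scenario.temporal_profile["no2_ugm3"].amplitude() == pytest.approx(100.0, rel=0.05)

    def test_random_intercepts_match_roster(self, scenario):
        assert scenario.random_participant["no2_ugm3"]["III"] == 36.25
        assert scenario.random_day["no2_ugm3"]["Tuesday"] == 22.80
        assert set(scenario.random_day["noise_db"]) == set(DAYS)

    def test_ventilation_at_mean_speed(self, scenario):
        # ~34 L/min at the 17 km/h mean riding speed on the flat
        assert float(scenario.ve_mean(17.0, 0.0)) == pytest.approx(33.6, abs=0.01)

    def test_yaml_round_trip(self, scenario, tmp_path):
        path = tmp_path / "scenario.yaml"
        scenario.to_yaml(path)
        back = ScenarioParams.from_yaml(path)
        assert back.to_dict() == scenario.to_dict()

    def test_invalid_parameters_rejected(self, scenario):
        d = scenario.to_dict()
        d["ma_coefs"]["noise_db"] = [0.5, 0.2]
        with pytest.raises(ValueError):
            ScenarioParams.from_dict(d)
        d2 = scenario.to_dict()
        d2["student_df"] = 1.5
        with pytest.raises(ValueError):
            ScenarioParams.from_dict(d2)


class TestSimulateSensorRecords:
    def test_degenerate_generator_returns_intercept(self, small_network):
        sc = _flat_scenario(scale=1e-300)
        trace = simulate_trip(small_network, 5, 15.0, start_clock=0, seed=3, speed_cv=0.0)
        recs = simulate_sensor_records(
            trace, sc, "I", "Monday", seed=1, network=small_network
        )
        assert len(recs) == 5
        assert all(r.laeq_1min == 70.0 for r in recs)
        assert all(r.no2_ugm3 == 200.0 for r in recs)
        assert all(r.ve_lmin == 35.0 for r in recs)

    def test_seed_determinism(self, small_network, scenario):
        trace = simulate_trip(small_network, 5, 17.0, start_clock=0, seed=3)
        a = simulate_sensor_records(trace, scenario, "I", "Monday", seed=8, network=small_network)
        b = simulate_sensor_records(trace, scenario, "I", "Monday", seed=8, network=small_network)
        assert a == b

    def test_unknown_participant_or_day_rejected(self, small_network, scenario):
        trace = simulate_trip(small_network, 2, 17.0, start_clock=0, seed=3)
        with pytest.raises(KeyError):
            simulate_sensor_records(trace, scenario, "IV", "Monday", seed=0, network=small_network)
        with pytest.raises(KeyError):
            simulate_sensor_records(trace, scenario, "I", "Thursday", seed=0, network=small_network)

    def test_ma3_residual_autocorrelation_matches_theory(self, small_network):
        # ~5,000 simulated minutes; residual = record - intercept. The sample
        # ACF at lags 1-3 must match the closed-form MA(3) autocorrelation
        # rho_k = (theta_k + sum theta_i theta_{i+k}) / (1 + sum theta_i^2)
        # within 3 SE (Bartlett).
        theta = (0.61, 0.20, 0.08)
        sc = _flat_scenario(ma=theta, scale=2.3, df=30.0)
        resid, tids = [], []
        for k in range(10):
            trace = simulate_trip(small_network, 500, 17.0, start_clock=0, seed=100 + k)
            recs = simulate_sensor_records(
                trace, sc, "I", DAYS[k % 5], seed=200 + k, network=small_network
            )
            resid.extend([r.laeq_1min - 70.0 for r in recs])
            tids.extend([k] * len(recs))
        n = len(resid)
        assert n == 5000
        rho = [ma3_theoretical_acf(theta, k) for k in (1, 2, 3)]
        bartlett_se = math.sqrt((1 + 2 * sum(r * r for r in rho)) / n)
        for k in (1, 2, 3):
            sample = acf_index(resid, k, trip_ids=tids)
            assert abs(sample - rho[k - 1]) < 3 * bartlett_se

    def test_mean_structure_inhalation_identity(self, scenario):
        # inhalation mean structure is (VE x 0.001) x NO2 mean structure
        cov = {"speed": 17.0, "slope": 1.0, "humidity": 46.0, "wind": 9.0, "primary": 0.5}
        mu = scenario.mean_structure(cov, (2500.0, 2500.0), 300.0, "II", "Friday")
        ve = float(scenario.ve_mean(17.0, 1.0))
        assert mu["inhaled_ug"] == pytest.approx((ve * 0.001) * mu["no2_ugm3"], abs=1e-12)


def test_ma3_theoretical_acf_closed_form():
    # independent brute-force check of the MA ACF formula by long simulation
    rng = np.random.default_rng(0)
    theta = (0.5, 0.3, 0.1)
    e = rng.standard_normal(400_003)
    x = e[3:] + theta[0] * e[2:-1] + theta[1] * e[1:-2] + theta[2] * e[:-3]
    for k in (1, 2, 3, 4):
        sample = float(np.corrcoef(x[:-k], x[k:])[0, 1])
        assert abs(sample - ma3_theoretical_acf(theta, k)) < 0.01


def test_external_format_round_trips(small_network, tmp_path):
    from cyclexpo.synthetic import (
        network_from_geojson,
        network_to_geojson,
        trace_from_csv,
        trace_to_csv,
        trace_to_gpx,
    )

    network_to_geojson(small_network, tmp_path / "net.geojson")
    back = network_from_geojson(tmp_path / "net.geojson")
    assert [e.edge_id for e in back.edges] == [e.edge_id for e in small_network.edges]
    assert [e.road_type for e in back.edges] == [e.road_type for e in small_network.edges]

    trace = simulate_trip(small_network, 2, 17.0, start_clock=30, seed=1)
    trace_to_csv(trace, tmp_path / "trace.csv")
    back_trace = trace_from_csv(tmp_path / "trace.csv")
    assert len(back_trace) == len(trace)
    for a, b in zip(back_trace, trace):
        assert a.timestamp == b.timestamp and a.edge_id == b.edge_id
        assert a.x == pytest.approx(b.x, abs=1e-9)
        assert a.y == pytest.approx(b.y, abs=1e-9)
    trace_to_gpx(trace, tmp_path / "trace.gpx")
    text = (tmp_path / "trace.gpx").read_text()
    assert "<trkpt" in text and "<time>" in text


def test_gaussian_field_centred_and_finite(scenario):
    f = scenario.spatial_field["no2_ugm3"]
    g = np.linspace(0, scenario.extent, 41)
    gx, gy = np.meshgrid(g, g)
    assert abs(float(np.mean(f(gx, gy)))) < 1e-9
    p = scenario.temporal_profile["no2_ugm3"]
    t = np.linspace(0, 600, 601)
    assert abs(float(np.mean(p(t)))) < 1e-9
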