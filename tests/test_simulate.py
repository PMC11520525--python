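"""Fleet simulator: determinism, exactness under zero noise, schedule
structure, GPS gating, energy accounting, two-tag stationary behaviour."""

import numpy as np
import pytest

from tagsync.records import SyncMethod
from tagsync.simulate import (
    EnergyModel,
    EventLog,
    ScenarioConfig,
    bat_scenario_config,
    energy_account,
    gps_gate,
    relative_error_trace,
    run_scenario,
    stationary_two_tag_experiment,
    two_tag_config,
    zero_noise_models,
)


def _exact_two_tag(ppm_a, ppm_b, horizon_s, **overrides):
    """Noise-free, quantisation-free two-tag scenario for exact arithmetic."""
    kw = dict(
        noise=zero_noise_models(),
        round_rel_ms=False,
        initial_sync=False,
        mcu_ppm_max=0.0,
        seed=11,
    )
    kw.update(overrides)
    return two_tag_config(ppm_a=ppm_a, ppm_b=ppm_b, horizon_s=horizon_s, **kw)


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_logs(self):
        cfg = bat_scenario_config(n_tags=5, n_gateways=1, days=0.05, seed=42)
        a = run_scenario(cfg).dumps()
        b = run_scenario(bat_scenario_config(n_tags=5, n_gateways=1, days=0.05, seed=42)).dumps()
        assert a == b

    def test_different_seed_changes_the_log(self):
        a = run_scenario(bat_scenario_config(n_tags=5, n_gateways=1, days=0.05, seed=1)).dumps()
        b = run_scenario(bat_scenario_config(n_tags=5, n_gateways=1, days=0.05, seed=2)).dumps()
        assert a != b

    def test_jsonl_roundtrip(self, tmp_path):
        cfg = ScenarioConfig(n_devices=2, horizon_s=1200.0, seed=3)
        log = run_scenario(cfg)
        path = tmp_path / "events.jsonl"
        log.to_jsonl(path)
        assert EventLog.from_jsonl(path).dumps() == log.dumps()


class TestExactArithmetic:
    def test_perfect_clocks_measure_zero_everywhere(self):
        cfg = _exact_two_tag(0.0, 0.0, horizon_s=6 * 3600.0)
        log = stationary_two_tag_experiment(cfg)
        devs = log.deviations_frame()
        assert len(devs) > 0
        assert np.allclose(devs.deviation_ms, 0.0, atol=1e-9)

    def test_zero_noise_deviations_equal_relative_clock_error(self):
        """With every noise source off, measured deviations reduce to the
        true relative clock error (drift alone explains everything)."""
        cfg = _exact_two_tag(3.0, -2.0, horizon_s=4 * 3600.0, proximity_resync=False)
        log = stationary_two_tag_experiment(cfg)
        snaps = log.snapshots_frame().set_index(["device_id", "t_s"]).T_error_s
        for rec in log.by_kind("deviation"):
            truth = (
                snaps[(rec["receiver"], rec["t_s"])] - snaps[(rec["sender"], rec["t_s"])]
            ) * 1e3
            # tolerance covers the second-order (rate x error) term of the
            # window-start displacement; everything first-order is exact
            assert rec["deviation_ms"] == pytest.approx(truth, abs=1e-3)

    def test_single_drifting_device_matches_budget_after_one_day(self):
        cfg = ScenarioConfig(
            n_devices=1,
            horizon_s=86_400.0,
            device_ppm=(3.0,),
            noise=zero_noise_models(),
            initial_sync=False,
            seed=0,
        )
        snaps = run_scenario(cfg).snapshots_frame()
        final = snaps[snaps.t_s == 86_400].iloc[0]
        assert final.T_error_s == pytest.approx(3e-6 * 86_400, abs=1e-12)  # 0.2592 s
        assert final.T_off_s == 0.0


class TestSchedule:
    def test_wakeups_every_full_five_minutes(self):
        cfg = ScenarioConfig(n_devices=3, horizon_s=86_400.0, period_s=300, seed=5)
        log = run_scenario(cfg)
        wakeups = log.by_kind("wakeup")
        per_device = len(wakeups) / 3
        assert per_device == 288  # 86,400 / 300
        assert all(w["t_s"] % 300 == 0 for w in wakeups)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="multiple of 60"):
            ScenarioConfig(period_s=47)
        with pytest.raises(ValueError, match="does not fit"):
            ScenarioConfig(message_spacing_ms=150.0)  # 8 x 150 > 800
        with pytest.raises(ValueError, match="probability"):
            ScenarioConfig(msg_loss_prob=1.5)
        with pytest.raises(ValueError, match="device_ppm"):
            ScenarioConfig(n_devices=3, device_ppm=(1.0,))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = bat_scenario_config(n_tags=4, n_gateways=1, days=0.1, seed=9)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(str(path))
        assert ScenarioConfig.from_yaml(str(path)) == cfg


class TestGpsGating:
    def test_gate_logic(self):
        assert gps_gate([]) is True  # no gateway seen -> GPS attempted
        assert gps_gate(["gw0"]) is False

    def test_gps_only_fires_away_from_gateways(self):
        cfg = bat_scenario_config(
            n_tags=6, n_gateways=2, days=0.2, seed=7, p_exit_per_window=0.2
        )
        log = run_scenario(cfg)
        attempts = log.by_kind("gps_attempt")
        assert attempts, "scenario should produce GPS attempts outside"
        # inside tags participate, see a gateway, and must not attempt GPS
        wakeups = {
            (w["event_id"], w["device_id"]): w for w in log.by_kind("wakeup")
        }
        for a in attempts:
            w = wakeups[(a["event_id"], a["device_id"])]
            assert w["location"] == "OUTSIDE" or w["missed"]

    def test_failed_fix_leaves_clock_drifting(self):
        cfg = ScenarioConfig(
            n_devices=1,
            horizon_s=3600.0,
            device_ppm=(3.0,),
            noise=zero_noise_models(),
            initial_sync=False,
            gps_enabled=True,
            markov_location=True,
            start_outside_prob=1.0,
            gps_fix_probability_outside=0.0,
            seed=2,
        )
        log = run_scenario(cfg)
        assert all(not a["success"] for a in log.by_kind("gps_attempt"))
        assert log.by_kind("sync") == []
        final = log.snapshots_frame().iloc[-1]
        assert final.T_error_s == pytest.approx(3e-6 * final.t_s)


class TestEnergy:
    def test_empty_log_zero_duration(self):
        assert energy_account(EventLog(), EnergyModel(), 0.0) == 0.0

    def test_keep_alive_only_one_day(self):
        # 720 nW for 24 h = 0.72 uW x 24 h = 17.28 uWh
        assert energy_account(EventLog(), EnergyModel(), 86_400.0) == pytest.approx(17.28)

    def test_sync_events_add_their_costs(self):
        log = EventLog()
        common = dict(
            reference_time_s=0.0, measured_deviation_ms=0.0, applied=True,
            post_sync_T_off_ms=0.0,
        )
        log.append("sync", device_id="a", method="GPS", **common)
        log.append("sync", device_id="a", method="PROXIMITY", **common)
        log.append("sync", device_id="a", method="WIFI_NTP", **common)
        total = energy_account(log, EnergyModel(), 86_400.0)
        assert total == pytest.approx(2 * 6.5 + 412.5 + 17.28)

    def test_additive_and_order_invariant(self):
        log = EventLog()
        common = dict(
            reference_time_s=0.0, measured_deviation_ms=0.0, applied=True,
            post_sync_T_off_ms=0.0,
        )
        log.append("sync", device_id="a", method="GPS", **common)
        log.append("sync", device_id="b", method="WIFI_NTP", **common)
        shuffled = EventLog(list(reversed(log.records)))
        model = EnergyModel()
        assert energy_account(log, model, 100.0) == energy_account(shuffled, model, 100.0)
        per_device = energy_account(log, model, 100.0, device_id="a") + energy_account(
            log, model, 100.0, device_id="b"
        )
        assert per_device == pytest.approx(
            energy_account(log, model, 100.0) + 0.72 * 100.0 / 3600.0
        )

    def test_wifi_schedule_consumes_wifi_energy(self):
        cfg = ScenarioConfig(
            n_devices=1,
            horizon_s=7200.0,
            noise=zero_noise_models(),
            wifi_sync_period_s=3600,
            seed=0,
        )
        log = run_scenario(cfg)
        wifi = [r for r in log.by_kind("sync") if r["method"] == "WIFI_NTP"]
        assert len(wifi) == 2


class TestTwoTagStationary:
    def test_validation(self):
        with pytest.raises(ValueError, match="exactly 2"):
            stationary_two_tag_experiment(ScenarioConfig(n_devices=3, period_s=3600))
        with pytest.raises(ValueError, match="full UTC hour"):
            stationary_two_tag_experiment(ScenarioConfig(n_devices=2, period_s=300))

    def test_no_relative_drift_never_resyncs(self):
        cfg = _exact_two_tag(1.5, 1.5, horizon_s=3 * 86_400.0)
        log = stationary_two_tag_experiment(cfg)
        assert log.by_kind("sync") == []

    def test_first_resync_at_analytic_crossing_time(self):
        """Relative rate r crosses the 50 ms threshold at 0.05 / (r x 1e-6) s;
        the resync lands on the first hourly exchange after that."""
        r = 3.0  # ppm relative drift
        cfg = _exact_two_tag(3.0, 0.0, horizon_s=6 * 86_400.0)
        log = stationary_two_tag_experiment(cfg)
        syncs = log.by_kind("sync")
        assert syncs
        crossing = 0.05 / (r * 1e-6)  # 16,666.7 s
        expected = np.ceil(crossing / 3600.0) * 3600.0  # 18,000 s
        assert syncs[0]["reference_time_s"] == pytest.approx(expected, abs=2.0)
        assert syncs[0]["method"] == "PROXIMITY"

    def test_relative_error_bounded_after_first_sync(self):
        """Post-first-sync relative error stays under
        threshold + r*P + 2*(airtime mismatch + quantisation + noise p99)."""
        cfg = two_tag_config(ppm_a=2.0, ppm_b=-1.0, seed=123)
        log = stationary_two_tag_experiment(cfg)
        syncs = log.by_kind("sync")
        prox = [s for s in syncs if s["method"] == "PROXIMITY"]
        assert prox
        trace = relative_error_trace(log, "tag00", "tag01")
        after = trace[trace.t_s > prox[0]["reference_time_s"]]
        r_ppm, period = 3.0, 3600.0
        noise_p99 = 5.0 + (2.0 / np.log(2)) * np.log(50)  # Laplace(5, 2/ln2)
        bound = 50.0 + r_ppm * 1e-6 * period * 1e3 + 2 * (0.0 + 1.0 + noise_p99)
        assert np.abs(after.relative_error_ms).max() <= bound

    def test_group_follows_trusted_clock(self):
        """The adopting tag inherits the reference's last-sync stamp."""
        cfg = _exact_two_tag(3.0, 0.0, horizon_s=6 * 86_400.0)
        log = stationary_two_tag_experiment(cfg)
        syncs = [s for s in log.by_kind("sync") if s["method"] == "PROXIMITY"]
        # tie on the initial stamp: tag00 is reference, tag01 adopts
        assert all(s["device_id"] == "tag01" for s in syncs)


class TestMissedWindows:
    def test_accurate_clocks_never_miss(self):
        cfg = _exact_two_tag(3.0, -3.0, horizon_s=2 * 3600.0)
        log = stationary_two_tag_experiment(cfg)
        assert all(not w["missed"] for w in log.by_kind("wakeup"))

    def test_runaway_clock_misses_the_window_entirely(self):
        """A clock error beyond the 800 ms window means the device exchanges
        nothing that event (and its partner finds nobody to talk to)."""
        from tagsync.clock import ClockSpec

        cfg = ScenarioConfig(
            n_devices=2,
            horizon_s=2 * 3600.0,
            period_s=3600,
            clock_spec=ClockSpec(max_drift_ppm=300.0),
            device_ppm=(300.0, 0.0),  # 1.08 s error after the first hour
            noise=zero_noise_models(),
            round_rel_ms=False,
            initial_sync=False,
            mcu_ppm_max=0.0,
            seed=4,
        )
        log = run_scenario(cfg)
        # with one runaway clock, neither tag has an overlapping partner
        assert all(w["missed"] for w in log.by_kind("wakeup"))
        assert log.by_kind("deviation") == []
        assert log.by_kind("sync") == []
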