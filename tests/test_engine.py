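"""Countercurrent train: transfers, splits, ledgers, steady state."""

import numpy as np
import pytest

from sacchsim.engine import (StageState, TrainConfig, centrifuge_split,
                             detect_steady_state, initialize_train,
                             react_window, run_train, system_conversion,
                             transfer_cycle)
from sacchsim.kinetics import BatchState, simulate_batch
from sacchsim.partition import PartitionParameters


@pytest.fixture(scope="module")
def short_run(kp, pp):
    """Ten cycles of the 5 mg/g train, shared across ledger tests."""
    cfg = TrainConfig(operation_days=20.0)
    return cfg, run_train(cfg, kp, pp)


class TestInitialization:
    def test_default_loading(self, train2_cfg):
        stages = initialize_train(train2_cfg)
        assert len(stages) == 8
        for st in stages:
            assert np.sum(st.particles_g) == pytest.approx(25.0)
            assert st.liquid_volume == pytest.approx(0.225)
            assert st.glucose_mass == 0.0
            assert st.particle_x[0] == 0.0
            # nominal startup enzyme: loading x initial solids
            assert st.enzyme_total == pytest.approx(5.0 * 25.0 / 1000.0)

    def test_enzyme_free_startup(self, train2_cfg):
        stages = initialize_train(
            train2_cfg.replace(initial_enzyme_mode="none"))
        assert all(st.enzyme_total == 0.0 for st in stages)

    def test_empty_solids_still_runs(self, kp, pp):
        cfg = TrainConfig(initial_solids_g=0.0, operation_days=4.0)
        res = run_train(cfg, kp, pp)
        assert len(res.time_days) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(enzyme_stage=9)
        with pytest.raises(ValueError):
            TrainConfig(cake_moisture=1.0)
        with pytest.raises(ValueError):
            TrainConfig(initial_enzyme_mode="half")


class TestCentrifugeSplit:
    def make_stage(self, dry=20.0, v=0.2, glucose=10.0, enzyme=0.05):
        st = StageState(liquid_volume=v, glucose_mass=glucose,
                        enzyme_liquid=enzyme)
        st.add_particles(dry, x=0.0)
        return st

    def test_dry_split_carries_no_liquid(self, pp):
        cake, sup = centrifuge_split(self.make_stage(), 0.0, pp)
        assert cake.liquid_L == 0.0
        assert cake.glucose_g == 0.0
        assert sup.liquid_L == pytest.approx(0.2)

    def test_wet_cake_mass_from_moisture(self, pp):
        # 20 g dry at 75% moisture -> 80 g wet cake, 60 g entrained liquid
        cake, sup = centrifuge_split(self.make_stage(), 0.75, pp)
        assert cake.wet_mass == pytest.approx(80.0)
        assert cake.liquid_L == pytest.approx(0.060)
        assert sup.liquid_L == pytest.approx(0.140)

    def test_full_absorption_sends_all_enzyme_with_cake(self):
        pp_all = PartitionParameters(d1=0.0, d2=0.0, d3=1.0)
        cake, sup = centrifuge_split(self.make_stage(), 0.75, pp_all)
        assert sup.enzyme_g == pytest.approx(0.0)
        assert cake.enzyme_g == pytest.approx(0.05)

    def test_split_conserves_everything(self, pp):
        st = self.make_stage()
        cake, sup = centrifuge_split(st, 0.75, pp)
        assert cake.liquid_L + sup.liquid_L == pytest.approx(0.2)
        assert cake.glucose_g + sup.glucose_g == pytest.approx(10.0)
        assert cake.enzyme_g + sup.enzyme_g == pytest.approx(0.05)


class TestReactWindow:
    def test_zero_enzyme_changes_nothing(self, kp, train2_cfg):
        stages = initialize_train(
            train2_cfg.replace(initial_enzyme_mode="none"))
        produced, decayed = react_window(stages, 48.0, kp, train2_cfg)
        assert np.allclose(produced, 0.0)
        assert np.allclose(decayed, 0.0)
        assert all(st.glucose_mass == 0.0 for st in stages)

    def test_one_stage_equals_batch_between_feeds(self, kp, pp):
        cfg = TrainConfig(n_stages=1, enzyme_stage=1)
        stages = initialize_train(cfg)
        e0 = stages[0].enzyme_conc
        gx0 = stages[0].distribution.equivalent_glucose
        react_window(stages, 48.0, kp, cfg)
        batch = simulate_batch(BatchState(Gx=gx0, E=e0), 48.0, kp, n_out=2)
        assert stages[0].glucose_conc == pytest.approx(batch.G1.iloc[-1],
                                                       rel=1e-6)
        assert stages[0].enzyme_conc == pytest.approx(batch.E.iloc[-1],
                                                      rel=1e-6)

    def test_window_conserves_equivalent_glucose(self, kp, train2_cfg):
        stages = initialize_train(train2_cfg)
        before = [st.distribution.equivalent_glucose * st.liquid_volume
                  + st.glucose_mass for st in stages]
        produced, _ = react_window(stages, 48.0, kp, train2_cfg)
        after = [st.distribution.equivalent_glucose * st.liquid_volume
                 + st.glucose_mass for st in stages]
        assert np.allclose(after, before, rtol=1e-6)
        assert np.all(produced > 0)


class TestTransferCycle:
    def test_idle_train_only_receives_feeds(self, pp):
        cfg = TrainConfig(initial_solids_g=0.0, initial_liquid_L=0.1,
                          initial_enzyme_mode="none", sampling_enabled=False)
        stages = initialize_train(cfg)
        ledger = transfer_cycle(stages, cfg, pp)
        assert ledger["glucose_out_product"] == 0.0
        assert ledger["glucose_out_cake"] == 0.0
        assert np.sum(stages[0].particles_g) == pytest.approx(
            cfg.solids_feed_g)
        assert ledger["enzyme_dosed_g"] == pytest.approx(0.05)

    def test_sampling_removes_one_ml_per_stage(self, pp, train2_cfg):
        stages = initialize_train(train2_cfg)
        ledger = transfer_cycle(stages, train2_cfg, pp)
        assert ledger["liquid_out_samples_L"] == pytest.approx(0.008)

    def test_liquid_moves_back_to_front(self, kp, pp):
        # glucose planted in stage N shows up in stage N-1 after a transfer
        cfg = TrainConfig(initial_enzyme_mode="none", sampling_enabled=False)
        stages = initialize_train(cfg)
        stages[-1].glucose_mass = 9.0
        transfer_cycle(stages, cfg, pp)
        assert stages[-2].glucose_mass > 0.0
        assert stages[-1].glucose_mass < 9.0

    def test_solids_move_front_to_back(self, kp, pp):
        cfg = TrainConfig(initial_enzyme_mode="none", sampling_enabled=False,
                          initial_solids_g=30.0)  # above retention target
        stages = initialize_train(cfg)
        transfer_cycle(stages, cfg, pp)
        # stage 2 now holds a mix: its own retained cake plus stage-1 excess
        assert stages[1].particles_g.size >= 1
        assert np.sum(stages[0].particles_g) < 30.0 + cfg.solids_feed_g


class TestLedgers:
    def test_glucose_ledger_closes(self, short_run):
        cfg, res = short_run
        led = res.ledger
        produced = led["glucose_produced_g"].sum()
        out = (led["glucose_out_product"] + led["glucose_out_cake"]
               + led["glucose_out_samples"]).sum()
        held = led["glucose_held_g"].iloc[-1]
        assert out + held == pytest.approx(produced, rel=1e-6)

    def test_enzyme_ledger_closes(self, short_run):
        cfg, res = short_run
        led = res.ledger
        dosed = led["enzyme_dosed_g"].sum() + 8 * 5.0 * 25.0 / 1000.0
        out = (led["enzyme_out_product"] + led["enzyme_out_cake"]
               + led["enzyme_out_samples"]).sum()
        sunk = led["enzyme_decayed_g"].sum() + led["enzyme_held_g"].iloc[-1]
        assert out + sunk == pytest.approx(dosed, rel=1e-6)

    def test_liquid_ledger_closes(self, short_run):
        cfg, res = short_run
        led = res.ledger
        fed = led["liquid_fed_L"].sum() + 8 * cfg.initial_liquid_L
        out = (led["liquid_out_product_L"] + led["liquid_out_cake_L"]
               + led["liquid_out_samples_L"]).sum()
        assert out + led["liquid_held_L"].iloc[-1] == pytest.approx(
            fed, rel=1e-6)

    def test_particle_ledger_closes(self, short_run):
        cfg, res = short_run
        led = res.ledger
        fed = led["solids_fed_g"].sum() + 8 * cfg.initial_solids_g
        held = sum(np.sum(st.particles_g) for st in res.final_stages)
        assert led["particles_out_g"].sum() + held == pytest.approx(
            fed, rel=1e-6)


class TestRunTrain:
    def test_deterministic(self, kp, pp):
        cfg = TrainConfig(operation_days=8.0)
        a = run_train(cfg, kp, pp)
        b = run_train(cfg, kp, pp)
        assert np.array_equal(a.stage_glucose, b.stage_glucose)
        assert np.array_equal(a.stage_enzyme, b.stage_enzyme)

    def test_glucose_profile_monotone_at_steady(self, kp, pp):
        res = run_train(TrainConfig(operation_days=120.0,
                                    initial_enzyme_mode="none"), kp, pp)
        profile = res.steady_stage_profile()
        assert np.all(np.diff(profile) <= 1e-6)  # Stage 1 richest

    def test_system_conversion_arithmetic(self, train2_cfg):
        import pandas as pd
        led = pd.DataFrame([{
            "glucose_out_product": 4.0, "glucose_out_cake": 0.30,
            "glucose_out_samples": 0.06,
            "eq_glucose_fed_g": train2_cfg.feed_equivalent_glucose_g}])
        # 4.36 g out of 10 g solids at 78.5% glucan (as equivalent glucose)
        assert system_conversion(led, train2_cfg) == pytest.approx(50.0,
                                                                   abs=0.05)

    def test_system_conversion_zero_feed_is_an_error(self, train2_cfg):
        import pandas as pd
        led = pd.DataFrame([{"glucose_out_product": 1.0,
                             "glucose_out_cake": 0.0,
                             "glucose_out_samples": 0.0,
                             "eq_glucose_fed_g": 0.0}])
        with pytest.raises(ValueError):
            system_conversion(led, train2_cfg)


class TestSteadyStateDetection:
    def test_constant_series_first_eligible_index(self):
        series = np.full((20, 3), 50.0)
        assert detect_steady_state(series, window_cycles=5, tol=0.01) == 5

    def test_growing_series_never_steady(self):
        series = 10.0 * 1.1 ** np.arange(30)[:, None] * np.ones((30, 2))
        assert detect_steady_state(series, window_cycles=5, tol=0.01) is None

    def test_geometric_convergence_detected_near_analytic_point(self):
        # g_c = 100*(1 - 0.8^c): relative window change < tol once
        # 0.8^(c-w) * (1-0.8^w) < tol approx
        w, tol, r = 6, 0.01, 0.8
        series = 100.0 * (1.0 - r ** np.arange(60, dtype=float))[:, None]
        got = detect_steady_state(series, window_cycles=w, tol=tol)
        analytic = w + np.log(tol / (1 - r ** w)) / np.log(r)
        assert got is not None
        assert abs(got - analytic) <= w

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            detect_steady_state(np.empty((0, 2)), 5)
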