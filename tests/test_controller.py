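"""Gradient-descent controller: updates, normalisation, κ damping."""

import numpy as np
import pytest

import rdfbias as rb
from rdfbias.controller import (BiasSchedule, ControllerState, gradient,
                                kappa_vector, update_multipliers)
from rdfbias.engine import EngineConfig, MDEngine
from rdfbias.frames import Frame
from rdfbias.engine import lattice_positions


def make_state(grid, target_values, lam=None):
    target = rb.RDFHistogram(grid, target_values)
    bias = rb.BiasState(grid, lam if lam is not None else np.zeros(grid.n_bins))
    return ControllerState(bias=bias, target=target)


class TestGradient:
    def test_identical_histograms_give_zero(self):
        g = rb.RDFGrid(5, 0.2)
        h = rb.RDFHistogram(g, np.arange(5, dtype=float))
        assert np.all(gradient(h, h) == 0.0)

    def test_pointwise_difference(self):
        g = rb.RDFGrid(3, 0.2)
        t = rb.RDFHistogram(g, np.array([2.0, 0.0, 0.0]))
        a = rb.RDFHistogram(g, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(gradient(t, a), [1.0, 0.0, 0.0])

    def test_antisymmetry(self, rng):
        g = rb.RDFGrid(8, 0.2)
        a = rb.RDFHistogram(g, rng.uniform(0, 3, 8))
        b = rb.RDFHistogram(g, rng.uniform(0, 3, 8))
        assert np.allclose(gradient(a, b), -gradient(b, a))

    def test_grid_mismatch_rejected(self):
        a = rb.RDFHistogram(rb.RDFGrid(5, 0.2), np.zeros(5))
        b = rb.RDFHistogram(rb.RDFGrid(5, 0.3), np.zeros(5))
        with pytest.raises(ValueError):
            gradient(a, b)


class TestKappa:
    def test_mode_none_is_all_ones(self):
        sched = BiasSchedule(kappa_mode="none", kappa_factor=0.25)
        assert np.all(kappa_vector(np.array([-1.0, 0.0, 2.0]), sched) == 1.0)

    def test_anti_contraction_damps_negative_virial_bins(self):
        sched = BiasSchedule(kappa_mode="anti_contraction", kappa_factor=0.25)
        out = kappa_vector(np.array([-1.0, 0.0, 2.0]), sched)
        assert np.allclose(out, [0.25, 1.0, 1.0])

    def test_anti_expansion_damps_positive_virial_bins(self):
        sched = BiasSchedule(kappa_mode="anti_expansion", kappa_factor=0.25)
        out = kappa_vector(np.array([-1.0, 0.0, 2.0]), sched)
        assert np.allclose(out, [1.0, 1.0, 0.25])

    def test_quarter_factor_preset_takes_two_values(self):
        sched = BiasSchedule(kappa_mode="anti_contraction", kappa_factor=0.25)
        out = kappa_vector(np.array([-3.0, 1.0, -0.5, 0.2]), sched)
        assert set(out.tolist()) == {0.25, 1.0}


class TestUpdate:
    def test_perfect_match_is_noop(self):
        g = rb.RDFGrid(4, 0.2)
        state = make_state(g, np.ones(4))
        state.avg_g.add(rb.RDFHistogram(g, np.ones(4)))
        update_multipliers(state, BiasSchedule(gamma=5.0))
        assert np.all(state.bias.lambda_hat == 0.0)
        assert state.update_count == 1
        assert state.mae_history == [0.0]

    def test_l1_budget_is_exactly_gamma_kt(self, rng):
        """With κ≡1 the ℓ1 norm of each update equals γ·k_BT exactly."""
        g = rb.RDFGrid(12, 0.2)
        for gamma, k_t in [(5.0, 1.0), (2.5, 0.7), (10.0, 1.3)]:
            state = make_state(g, rng.uniform(0, 3, 12))
            state.avg_g.add(rb.RDFHistogram(g, rng.uniform(0, 3, 12)))
            before = state.bias.lambda_hat.copy()
            update_multipliers(state, BiasSchedule(gamma=gamma), k_t=k_t)
            change = state.bias.lambda_hat - before
            assert np.abs(change).sum() == pytest.approx(gamma * k_t, rel=1e-12)

    def test_two_bin_split_follows_normalised_difference(self):
        g = rb.RDFGrid(2, 0.2)
        state = make_state(g, np.array([1.2, 0.8]))
        state.avg_g.add(rb.RDFHistogram(g, np.array([1.0, 1.0])))
        update_multipliers(state, BiasSchedule(gamma=1.0, window=10))
        # Δg = (+0.2, −0.2): changes (−½, +½)·γ·k_BT
        assert np.allclose(state.bias.lambda_hat, [-0.5, 0.5])

    def test_under_represented_bins_get_lower_lambda(self):
        """Where the target exceeds the measured RDF, λ̂ must decrease
        (energetic reward for configurations filling that bin)."""
        g = rb.RDFGrid(3, 0.2)
        state = make_state(g, np.array([2.0, 1.0, 1.0]))
        state.avg_g.add(rb.RDFHistogram(g, np.ones(3)))
        update_multipliers(state, BiasSchedule(gamma=5.0))
        assert state.bias.lambda_hat[0] < 0.0
        assert np.all(state.bias.lambda_hat[1:] == 0.0)

    def test_averages_reset_after_update(self, rng):
        g = rb.RDFGrid(5, 0.2)
        state = make_state(g, rng.uniform(0, 2, 5))
        state.avg_g.add(rb.RDFHistogram(g, rng.uniform(0, 2, 5)))
        state.avg_virial_per_bin += 3.0
        update_multipliers(state, BiasSchedule())
        assert state.avg_g.count == 0
        assert np.all(state.avg_virial_per_bin == 0.0)

    def test_kappa_scales_individual_bins(self):
        g = rb.RDFGrid(2, 0.2)
        state = make_state(g, np.array([1.2, 0.8]))
        state.avg_g.add(rb.RDFHistogram(g, np.array([1.0, 1.0])))
        state.avg_virial_per_bin = np.array([-1.0, 1.0])
        sched = BiasSchedule(gamma=1.0, kappa_mode="anti_contraction",
                             kappa_factor=0.5)
        update_multipliers(state, sched)
        assert np.allclose(state.bias.lambda_hat, [-0.25, 0.5])


class TestScheduleValidation:
    def test_window_must_be_multiple_of_sample_every(self):
        with pytest.raises(ValueError):
            BiasSchedule(sample_every=10, window=105)

    def test_known_cadences_are_expressible(self):
        """The published cadences map directly onto schedule fields:
        liquid matching (sample 10 / window 100 / γ 10) and
        liquid-to-solid (sample 10 / window 1000 / equilibrate 100)."""
        liquid = BiasSchedule(sample_every=10, window=100, gamma=10.0)
        assert liquid.samples_per_window == 10
        ice = BiasSchedule(sample_every=10, window=1000, equilibrate=100,
                           gamma=2.5)
        assert ice.samples_per_window == 100
        assert ice.window + ice.equilibrate == 1100  # steps per update cycle

    def test_bad_kappa_rejected(self):
        with pytest.raises(ValueError):
            BiasSchedule(kappa_mode="sideways")
        with pytest.raises(ValueError):
            BiasSchedule(kappa_factor=0.0)


class TestControllerIntegration:
    def test_disabled_bias_matches_plain_run(self):
        """γ = 0 (multipliers stay zero) reproduces the unbiased
        trajectory bit for bit under the same seed."""
        n, box_len = 48, 4.0
        cfg = EngineConfig(temperature=1.0, seed=21)
        box = np.full(3, box_len)

        def fresh_engine(with_bias):
            frame = Frame(lattice_positions(n, box), box)
            providers = [rb.LJProvider(cfg.lj_params)]
            if with_bias:
                providers.append(rb.MaxEntBiasProvider(
                    rb.BiasState(rb.RDFGrid(20, 0.1))
                ))
            return MDEngine(frame, cfg, providers)

        plain = fresh_engine(False)
        plain.step(300)
        grid = rb.RDFGrid(20, 0.1)
        biased = fresh_engine(True)
        state = ControllerState(
            bias=biased.providers[1].state,
            target=rb.RDFHistogram(grid, np.ones(20)),
        )
        ctrl = rb.Controller(biased, state,
                             BiasSchedule(sample_every=10, window=100, gamma=0.0))
        ctrl.run_cycle()
        ctrl.run_cycle()
        ctrl.run_cycle()
        assert np.array_equal(plain.state.frame.positions,
                              biased.state.frame.positions)

    def test_update_cadence_counts_steps(self):
        n, box_len = 32, 3.5
        cfg = EngineConfig(temperature=1.0, seed=4)
        box = np.full(3, box_len)
        frame = Frame(lattice_positions(n, box), box)
        grid = rb.RDFGrid(15, 0.1)
        bias = rb.BiasState(grid)
        engine = MDEngine(frame, cfg, providers=[
            rb.LJProvider(cfg.lj_params), rb.MaxEntBiasProvider(bias),
        ])
        state = ControllerState(bias=bias,
                                target=rb.RDFHistogram(grid, np.ones(15)))
        sched = BiasSchedule(sample_every=5, window=50, equilibrate=10, gamma=1.0)
        ctrl = rb.Controller(engine, state, sched)
        ctrl.run_cycle()
        assert engine.state.step == 60  # window + equilibrate
        assert state.update_count == 1
        ctrl.run_cycle()
        assert engine.state.step == 120
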