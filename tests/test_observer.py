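"""Observer gain synthesis, certification, and state-bounding runs."""

import dataclasses

import numpy as np
import pytest

import pkbound as pb
from pkbound.observer import _observer_matrices


def _independent_certificate(interval, L):
    """Recheck a gain with plain eigenvalue and sign tests (no package helpers)."""
    for M in (
        interval.A_hi - np.outer(L, interval.c_lo),
        interval.A_lo - np.outer(L, interval.c_hi),
    ):
        off = M[~np.eye(M.shape[0], dtype=bool)]
        if off.min() < -1e-9:
            return False
        if np.max(np.linalg.eigvals(M).real) >= 0:
            return False
    return bool(np.all(np.asarray(L) >= 0))


class TestSynthesizeGain:
    def test_zero_strategy_is_always_certified_open_loop(self, interval3_no_tenside):
        gain = pb.synthesize_gain(interval3_no_tenside, "zero")
        assert gain.certified
        np.testing.assert_array_equal(gain.L, np.zeros(3))

    def test_max_feedback_respects_structural_zeros_observed_tissue(self, interval3_no_tenside):
        # entries (1,3) and (2,3) of A are structural zeros, so feedback on the
        # measured tissue compartment is only admissible through L3
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback")
        assert gain.certified
        assert gain.L[0] == pytest.approx(0.0, abs=1e-12)
        assert gain.L[1] == pytest.approx(0.0, abs=1e-12)
        assert gain.L[2] > 0

    def test_max_feedback_observed_git_constraints(self, reference):
        p = reference["params_three_compartment_no_tenside"]
        m = pb.build_three_compartment(p["ka"], p["ke1"], p["k23"], p["ke3"], 50, observed=1)
        iv = pb.expand_uncertainty(m, pb.UncertaintySpec(delta=0.1))
        gain = pb.synthesize_gain(iv, "max_feedback")
        assert gain.certified
        # (3,1) of A is a structural zero -> L3 forced to zero;
        # (2,1) >= 0 caps L2 at A_hi[2,1]/c_lo[1] = 0.0407/0.9
        assert gain.L[2] == pytest.approx(0.0, abs=1e-12)
        assert gain.L[1] <= 0.0407 / 0.9 + 1e-9

    def test_certified_gains_pass_independent_check(
        self, interval3_no_tenside, interval3_tenside, interval_no_tenside
    ):
        for iv in (interval3_no_tenside, interval3_tenside, interval_no_tenside):
            for strategy in ("zero", "max_feedback"):
                gain = pb.synthesize_gain(iv, strategy)
                assert gain.certified
                assert _independent_certificate(iv, gain.L)


class TestRunObservers:
    def test_zero_gain_reduces_to_envelope_simulation(self, interval3_no_tenside):
        gain = pb.synthesize_gain(interval3_no_tenside, "zero")
        obs = pb.run_observers(
            interval3_no_tenside, gain, lambda t: np.zeros_like(np.asarray(t)),
            horizon=12, step=0.01,
        )
        env = pb.envelope_simulate(interval3_no_tenside, horizon=12, step=0.01)
        np.testing.assert_allclose(obs.upper.states, env.upper.states, atol=1e-9)
        np.testing.assert_allclose(obs.lower.states, env.lower.states, atol=1e-9)

    def test_uncertified_gain_is_refused(self, interval3_no_tenside):
        gain = pb.certify_gain(interval3_no_tenside, [0.0, 0.0, 0.0])
        broken = dataclasses.replace(gain, certified=False)
        with pytest.raises(ValueError, match="uncertified"):
            pb.run_observers(interval3_no_tenside, broken, lambda t: np.zeros_like(np.asarray(t)))

    def test_zero_signal_zero_bounds(self, interval3_no_tenside):
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback")
        z = np.zeros(3)
        obs = pb.run_observers(
            interval3_no_tenside, gain, lambda t: np.zeros_like(np.asarray(t)),
            x0_bounds=(z, z), horizon=6, step=0.01,
        )
        assert np.max(np.abs(obs.upper.states)) == 0
        assert np.max(np.abs(obs.lower.states)) == 0

    def test_nominal_plant_stays_within_observer_bounds(
        self, interval3_no_tenside, three_cpt_no_tenside
    ):
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback")
        bounds, plant = pb.run_observers_with_model(
            interval3_no_tenside, gain, three_cpt_no_tenside, horizon=12, step=0.01
        )
        assert np.max(plant.states - bounds.upper.states) <= 1e-6
        assert np.max(bounds.lower.states - plant.states) <= 1e-6

    def test_monte_carlo_containment_with_exact_output(self, interval3_no_tenside):
        # any in-interval system, wired by its exact output into the observers,
        # stays between the bounds at every grid point
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback")
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            system = pb.sample_interval_system(interval3_no_tenside, rng)
            bounds, plant = pb.run_observers_with_model(
                interval3_no_tenside, gain, system, horizon=12, step=0.02
            )
            worst = max(
                worst,
                float(np.max(plant.states - bounds.upper.states)),
                float(np.max(bounds.lower.states - plant.states)),
            )
            assert np.min(bounds.lower.states) >= -1e-10  # observer positivity
        assert worst <= 1e-6

    def test_observer_positivity_with_nonnegative_signal(self, interval3_no_tenside):
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback")
        y = pb.MeasuredSignal(
            pb.SampleSeries(np.arange(7.0), np.array([0, 0.9, 1.1, 1.0, 0.95, 0.63, 0.68]))
        )
        obs = pb.run_observers(interval3_no_tenside, gain, y, horizon=12, step=0.01)
        assert np.min(obs.lower.states) >= -1e-10
        assert np.min(obs.upper.states) >= -1e-10


class TestObserveFromSamples:
    def test_reference_amounts_bracket_nominal_central_compartment(
        self, interval3_no_tenside, three_cpt_no_tenside, reference
    ):
        samples = reference["table1_no_tenside_mg"]
        gain = pb.synthesize_gain(interval3_no_tenside, "zero")
        bounds = pb.observe_from_samples(interval3_no_tenside, gain, samples, horizon=6, step=0.01)
        nominal = pb.simulate(three_cpt_no_tenside, horizon=6, step=0.01)
        assert np.all(bounds.lower.compartment(2) <= nominal.compartment(2) + 1e-9)
        assert np.all(nominal.compartment(2) <= bounds.upper.compartment(2) + 1e-9)

    def test_sampled_signal_containment_of_perturbed_systems(self, interval3_no_tenside):
        # samples taken densely from a random in-interval system; tolerance reflects
        # the piecewise-linear reconstruction of the output between grid points
        gain = pb.synthesize_gain(interval3_no_tenside, "max_feedback", l_max=2.0)
        rng = np.random.default_rng(5)
        for _ in range(20):
            system = pb.sample_interval_system(interval3_no_tenside, rng)
            traj = pb.simulate(system, horizon=12, step=0.01)
            samples = pb.SampleSeries(traj.times, np.maximum(traj.output, 0.0), unit="mg")
            bounds = pb.observe_from_samples(
                interval3_no_tenside, gain, samples, horizon=12, step=0.01
            )
            assert np.max(traj.states - bounds.upper.states) <= 1e-4
            assert np.max(bounds.lower.states - traj.states) <= 1e-4

    def test_rejects_concentration_series(self, interval3_no_tenside):
        gain = pb.synthesize_gain(interval3_no_tenside, "zero")
        conc = pb.SampleSeries([0.0, 1.0], [0.0, 0.07], unit="mg_per_ml")
        with pytest.raises(ValueError, match="mg"):
            pb.observe_from_samples(interval3_no_tenside, gain, conc)

    def test_malformed_samples_name_the_row(self):
        with pytest.raises(ValueError, match="row 3"):
            pb.SampleSeries([0.0, 2.0, 1.0], [0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="row 2"):
            pb.SampleSeries([0.0, 1.0], [0.0, -0.5])


class TestMeasuredSignal:
    def test_exact_at_samples_and_holds_last_value(self):
        series = pb.SampleSeries([0.0, 1.0, 2.0], [0.0, 1.0, 0.5])
        lin = pb.MeasuredSignal(series, interp="linear")
        np.testing.assert_array_equal(lin(series.times), series.values)
        assert lin(1.5) == pytest.approx(0.75)
        assert lin(10.0) == pytest.approx(0.5)  # extrapolation holds the last sample
        zoh = pb.MeasuredSignal(series, interp="zoh")
        assert zoh(1.5) == pytest.approx(1.0)
        assert zoh(0.2) == pytest.approx(0.0)
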