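"""ISI recursion, extrema expansions, spike counts, and sequence assembly."""

import math

import numpy as np
import pytest

from thetagamma import (
    ApplicabilityError,
    ModelParams,
    RegimeError,
    check_inhibition_dominance,
    isi,
    isi_extrema,
    isi_intrinsic,
    predict_spike_sequence,
    second_spike_excitable,
    simulate,
    snic_phase,
    special_constant_omega0,
    spike_count,
    spikes_per_theta_cycle,
)


def mk(IE, lam, gIE=6.0, epsI=0.1, epsTheta=0.01, omega=4.0):
    return ModelParams(IE=IE, lam=lam, gIE=gIE, epsI=epsI, epsTheta=epsTheta, omega=omega)


class TestDominance:
    def test_reference_sets(self):
        assert check_inhibition_dominance(mk(0.5, 0.8, gIE=6.0))
        assert not check_inhibition_dominance(mk(0.5, 0.8, gIE=2.1))  # boundary exact
        assert not check_inhibition_dominance(mk(0.5, 1.0, gIE=2.0))

    def test_downstream_applicability_error(self):
        weak = mk(0.5, 0.8, gIE=1.0)
        with pytest.raises(ApplicabilityError):
            isi(weak, 0.0)
        with pytest.raises(ApplicabilityError):
            spike_count(weak)


class TestIsi:
    def test_reduces_to_intrinsic_at_trough_or_uncoupled(self):
        """At the theta trough the drive equals IE, so the modulated ISI
        collapses to the intrinsic PING period."""
        p = mk(0.5, 0.8)
        assert isi(p, -math.pi) == pytest.approx(isi_intrinsic(p), rel=1e-12)
        p0 = mk(0.5, 0.0)
        assert isi(p0, 0.7) == pytest.approx(isi_intrinsic(p0), rel=1e-12)

    def test_intrinsic_reference_value(self):
        """IE=0.5, gIE=6, eps=0.1: 10*ln 12 + |Omega0|/(0.1^{1/3} 0.5^{1/3})."""
        val = isi_intrinsic(mk(0.5, 0.0))
        expected = 10 * math.log(12.0) + 2.33811 / (0.1 ** (1 / 3) * 0.5 ** (1 / 3))
        assert val == pytest.approx(expected, abs=1e-3)

    def test_both_terms_positive_and_phase_extremal(self):
        p = mk(0.5, 0.8)
        vals = [isi(p, T) for T in np.linspace(-math.pi, math.pi, 41)]
        assert min(vals) == pytest.approx(isi(p, 0.0))
        assert max(vals) == pytest.approx(isi(p, -math.pi))
        assert all(v > 0 for v in vals)

    def test_intrinsic_decreasing_in_IE(self):
        vals = [isi_intrinsic(mk(IE, 0.0)) for IE in (0.1, 0.3, 0.5, 1.0)]
        assert np.all(np.diff(vals) < 0)

    def test_outside_active_window_rejected(self):
        with pytest.raises(ApplicabilityError):
            isi(mk(-0.5, 1.0), -math.pi)  # drive negative at the trough


class TestIsiExtrema:
    def test_limits_recover_global_extrema(self):
        p = mk(0.5, 0.8)
        dT_max, dT_min = isi_extrema(p)
        assert dT_max == pytest.approx(isi_intrinsic(p), rel=1e-12)
        assert dT_min == pytest.approx(isi(p, 0.0), rel=1e-12)

    @pytest.mark.parametrize("delta", [0.05, 0.1, 0.2])
    def test_second_order_agreement_with_recursion(self, delta):
        """The quadratic expansions agree with the full ISI formula to
        O(delta^3) near their expansion points — the discriminating check
        for the expansion coefficients."""
        p = mk(0.5, 0.8)
        dT_max, _ = isi_extrema(p, Theta_prev=-math.pi + delta)
        _, dT_min = isi_extrema(p, Theta_prev=delta)
        err_trough = abs(dT_max - isi(p, -math.pi + delta))
        err_peak = abs(dT_min - isi(p, delta))
        # quartic-order remainder: shrink delta by 2, error by ~16
        assert err_trough < 20.0 * delta**4
        assert err_peak < 20.0 * delta**4

    def test_bracketing_of_simulated_isis(self):
        p = mk(0.5, 0.8)
        _, train = simulate(p, t_end=p.theta_period)
        dT_max, dT_min = isi_extrema(p)
        isis = np.diff(train.times)
        assert np.all(isis > 0.9 * dT_min)
        assert np.all(isis < 1.1 * dT_max)


class TestSpikeCount:
    @pytest.mark.parametrize(
        "IE, lam",
        [(0.5, 0.8), (0.1, 0.5), (-0.5, 1.0)],
    )
    def test_matches_simulation_on_reference_sets(self, IE, lam):
        p = mk(IE, lam)
        assert spike_count(p) == spikes_per_theta_cycle(p)

    def test_excitable_lambda_sweep_matches_simulation(self):
        """Burst size vs coupling for a strongly inhibited excitable cell."""
        for lam in (0.3, 0.6, 1.0, 1.5):
            p = mk(-0.5, lam)
            assert spike_count(p) == spikes_per_theta_cycle(p)

    def test_vanishing_active_window_gives_zero(self):
        """As 2*lam + IE -> 0+ the supra-threshold window closes faster than
        the slow-passage delay: no spike fits."""
        assert spike_count(mk(-0.5, 0.2505)) == 0

    def test_silent_regime_counts_zero(self):
        assert spike_count(mk(-3.0, 1.0)) == 0


class TestSecondSpike:
    def test_leading_gap_arithmetic(self, excitable_params):
        est = second_spike_excitable(excitable_params, T1=0.0)
        assert est.T2_leading == pytest.approx(-math.log(0.1) / 0.1)
        assert est.T2_leading == pytest.approx(23.026, abs=1e-3)

    def test_log_amplitude_constant(self, excitable_params):
        est = second_spike_excitable(excitable_params)
        expected = math.log(6.0 / (1.0 * 4.0 * math.sin(2 * math.pi / 3)))
        assert est.A == pytest.approx(expected, rel=1e-12)

    def test_refinement_wins_deep_in_the_asymptotic_regime(self):
        """For small enough synaptic eps the ln(-ln eps) refinement beats the
        leading-order estimate of the simulated second spike (at eps=0.1 the
        two are not yet ordered; see the methods note)."""
        p = mk(-0.5, 1.0, epsI=0.02, epsTheta=0.0004)
        _, train = simulate(p, t_end=0.6 * p.theta_period)
        assert train.count >= 2
        est = second_spike_excitable(p, T1=float(train.times[0]))
        err_lead = abs(est.T2_leading - train.times[1])
        err_ref = abs(est.T2_refined - train.times[1])
        assert err_ref < err_lead

    def test_regime_and_eps_guards(self):
        with pytest.raises(RegimeError):
            second_spike_excitable(mk(0.5, 0.8))
        with pytest.raises(ApplicabilityError):
            second_spike_excitable(mk(-0.5, 1.0, epsI=1.5, epsTheta=2.25))


class TestPredictSequence:
    def test_uncoupled_oscillator_is_equally_spaced(self):
        p = mk(0.5, 0.0)
        pred = predict_spike_sequence(p)
        assert pred.regime.value == "oscillator"
        assert np.allclose(pred.isis, isi_intrinsic(p), rtol=1e-12)

    def test_oscillator_times_near_simulation(self):
        """Predicted spike times track the simulated train: away from the
        cycle edges (where the frozen-phase assumption behind the recursion
        is weakest) each prediction falls within half a mean simulated ISI
        of its counterpart."""
        p = mk(0.5, 0.8)
        pred = predict_spike_sequence(p)
        _, train = simulate(p, t_end=p.theta_period)
        n = min(len(pred.times), train.count)
        assert n >= 6
        half_isi = 0.5 * np.diff(train.times).mean()
        for t_pred, t_sim in zip(pred.times[: n - 1], train.times[: n - 1]):
            assert abs(t_pred - t_sim) < half_isi

    def test_excitable_burst_confined_to_active_window(self):
        p = mk(-0.1, 1.0)
        pred = predict_spike_sequence(p)
        T0 = snic_phase(p)
        assert all(T0 < phase < -T0 for phase in pred.phases)
        assert pred.isis[0] == pytest.approx(
            second_spike_excitable(p).T2_refined - pred.T1
        )

    def test_times_strictly_increasing_and_within_period(self):
        for IE, lam in [(0.5, 0.8), (-0.5, 1.0)]:
            p = mk(IE, lam)
            pred = predict_spike_sequence(p)
            assert np.all(np.diff(pred.times) > 0)
            assert pred.times[-1] < p.theta_period
            assert pred.T1 == pred.times[0]


def test_count_term_magnitudes_respect_time_budget():
    """M complete mean intervals plus the opening spike never exceed the
    available active time by construction of the largest-integer rule."""
    p = mk(0.5, 0.8)
    M = spike_count(p)
    Om0 = special_constant_omega0()

    from scipy.integrate import quad

    I1, _ = quad(lambda T: math.log(p.gIE / p.drive(T)), -math.pi, math.pi)
    I2, _ = quad(lambda T: -Om0 * p.drive(T) ** (-1 / 3), -math.pi, math.pi)
    mean_isi_scaled = (p.epsI * I1 + p.epsI ** (5 / 3) * I2) / (2 * math.pi)
    assert (M - 1) * mean_isi_scaled < 2 * math.pi / p.omega
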