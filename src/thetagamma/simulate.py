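"""Direct numerical integration of the theta-modulated gamma model.

This is the ground truth against which all analytic spike-time predictions
are tested.  The model is integrated in the compact θ-coordinates (no
blow-up at spikes); an upward crossing of θE through π is a spike, at which
θE wraps to −π and the inhibitory synaptic variable sI jumps by one (the
δ-kick of the enslaved interneuron).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, Regime, RegimeError, classify_regime, rest_fixed_point


class SolverError(RuntimeError):
    """Integration failed (step-size collapse or non-finite state)."""


@dataclass(frozen=True)
class Trajectory:
    """Time course of the model state.

    t        ordered time grid
    thetaE   gamma-cell phase in [−π, π)
    sI       synaptic activation (≥ 0, decays as exp(−εI·t) between spikes)
    Theta    theta phase, unwrapped (slope εΘ·ω)
    """

    t: np.ndarray
    thetaE: np.ndarray
    sI: np.ndarray
    Theta: np.ndarray

    @property
    def VE(self) -> np.ndarray:
        """Membrane voltage VE = tan(θE/2) (diverges at spikes)."""
        return np.tan(self.thetaE / 2.0)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times with the theta phase at each spike."""

    times: np.ndarray
    phases: np.ndarray

    @property
    def count(self) -> int:
        return len(self.times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def _rhs(t, y, p: ModelParams):
    thetaE, sI, Theta = y
    drive = p.IE + p.lam * (1.0 + math.cos(Theta)) - p.gIE * sI
    return (
        (1.0 - math.cos(thetaE)) + drive * (1.0 + math.cos(thetaE)),
        -p.epsI * sI,
        p.epsTheta * p.omega,
    )


def simulate(
    params: ModelParams,
    t_end: float,
    init: tuple[float, float, float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    max_spikes: int = 100_000,
    dense_points: int = 0,
) -> tuple[Trajectory, SpikeTrain]:
    """Integrate the model and detect spikes.

    Parameters
    ----------
    params : ModelParams
    t_end : float
        End of the integration window (start is t = 0).
    init : (thetaE0, sI0, Theta0), optional
        Initial state.  Default follows the regime convention: θE(0) = −π
        for an oscillator (voltage at −∞ after a reset), θE(0) = θ0 (the
        resting fixed point) for an excitable cell; Θ(0) = −π; sI(0) = 0.
    rtol, atol : float
        Solver tolerances.  The vector field is smooth but nearly stalls at
        the SNIC, so tight tolerances matter for spike-time accuracy.
    dense_points : int
        If > 0, the trajectory is sampled on a uniform grid of this many
        points; otherwise only the solver's natural steps are stored.

    Returns
    -------
    (Trajectory, SpikeTrain)
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        regime = classify_regime(params)
        thetaE0 = rest_fixed_point(params) if regime is not Regime.OSCILLATOR else -math.pi
        init = (thetaE0, 0.0, -math.pi)
    thetaE0, sI0, Theta0 = init
    if not -math.pi <= thetaE0 < math.pi:
        raise ValueError(f"thetaE0 must lie in [-pi, pi), got {thetaE0}")

    def spike_event(t, y, p):
        return y[0] - math.pi

    spike_event.terminal = True
    spike_event.direction = 1

    t0 = 0.0
    state = np.array([thetaE0, sI0, Theta0], dtype=float)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    spike_times: list[float] = []

    while t0 < t_end:
        t_eval = None
        if dense_points:
            t_eval = np.linspace(t0, t_end, max(2, int(dense_points * (t_end - t0) / t_end)))
        sol = solve_ivp(
            _rhs,
            (t0, t_end),
            state,
            args=(params,),
            events=spike_event,
            rtol=rtol,
            atol=atol,
            dense_output=False,
            t_eval=t_eval,
            method="LSODA",
        )
        if not sol.success:
            raise SolverError(f"solver failed at t={sol.t[-1] if len(sol.t) else t0}: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SolverError("non-finite state encountered during integration")
        ts.append(sol.t)
        ys.append(sol.y)
        if sol.status == 1:  # spike event
            t_spk = float(sol.t_events[0][0])
            y_spk = sol.y_events[0][0]
            spike_times.append(t_spk)
            if len(spike_times) >= max_spikes:
                raise SolverError(f"exceeded max_spikes={max_spikes}")
            # reset: θE wraps π → −π, synapse receives a unit kick
            state = np.array([-math.pi, y_spk[1] + 1.0, y_spk[2]])
            t0 = t_spk
        else:
            break

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    thetaE = np.mod(y[0] + math.pi, 2.0 * math.pi) - math.pi
    traj = Trajectory(t=t, thetaE=thetaE, sI=y[1], Theta=y[2])
    times = np.asarray(spike_times)
    phases = Theta0 + params.epsTheta * params.omega * times
    return traj, SpikeTrain(times=times, phases=phases)


def spikes_per_theta_cycle(
    params: ModelParams,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> int:
    """Number of spikes over one theta period [0, 2π/(εΘω)).

    Uses the regime's default initial conditions (theta trough, no residual
    inhibition).
    """
    _, train = simulate(params, t_end=params.theta_period, rtol=rtol, atol=atol)
    return int(np.sum(train.times < params.theta_period))


def simulate_qif_nofeedback(
    params: ModelParams,
    t_end: float | None = None,
    v_cap: float = 1e3,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """First spike time of the theta-driven QIF cell without inhibition.

    Integrates dV/dt = V² + IE + λ(1 + cos(εΘωt − π)) from V(0) = −v_cap
    to V = +v_cap and adds the analytic tail 2/v_cap (the time a pure V²
    flow spends beyond ±v_cap, accounting for the reset from +∞ to −∞).
    This is the voltage-coordinate cross-check for the Mathieu-equation
    first-spike route and is restricted to the oscillator regime.
    """
    if classify_regime(params) is not Regime.OSCILLATOR:
        raise RegimeError("QIF first-spike simulation requires the oscillator regime")
    if t_end is None:
        t_end = params.theta_period

    def rhs(t, y):
        return [y[0] ** 2 + params.IE + params.lam * (1.0 + math.cos(params.epsTheta * params.omega * t - math.pi))]

    def blowup(t, y):
        return y[0] - v_cap

    blowup.terminal = True
    blowup.direction = 1

    sol = solve_ivp(rhs, (0.0, t_end), [-v_cap], events=blowup, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise SolverError(f"QIF integration failed: {sol.message}")
    if sol.status != 1:
        raise SolverError(f"no spike detected within t_end={t_end}")
    return float(sol.t_events[0][0]) + 2.0 / v_cap
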