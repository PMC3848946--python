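"""Analytic prediction of spike sequences within a theta cycle.

After the first spike the recruited inhibition dominates the dynamics:
each spike kicks the synaptic variable, the net drive turns negative, and
the next spike happens once inhibition has decayed back to the drive level
plus a slow-passage delay.  This yields a recursion for interspike
intervals (ISIs),

    ΔT(Θ) = (1/ε)·ln(gIE / F(Θ)) − Ω0 / (ε^{1/3}·F(Θ)^{1/3}),

with F(Θ) = IE + λ(1 + cos Θ) the instantaneous drive at the phase of the
previous spike and ε the synaptic decay rate.  Averaging the recursion
over the theta cycle gives a sharp integer estimate of the number of
spikes per cycle; expanding it around the theta trough/peak gives the
extreme ISIs, i.e. the instantaneous gamma frequency range.

All formulas here require *inhibition dominance*, gIE > IE + 2λ: a single
spike's inhibition must push the cell below the SNIC bifurcation at every
theta phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .firstspike import (
    first_spike_excitable,
    first_spike_oscillator,
    special_constant_omega0,
)
from .params import (
    ModelParams,
    Regime,
    RegimeError,
    classify_regime,
    snic_phase,
)


class ApplicabilityError(ValueError):
    """The recursion's validity conditions do not hold for these parameters."""


@dataclass(frozen=True)
class SecondSpikeEstimate:
    """Excitable second-spike estimates at two orders of accuracy.

    The second spike is anomalous: inhibition must decay from its full
    post-spike value while the drive is still barely positive, giving a
    gap of order −ln(ε)/ε rather than the mid-burst ISI.
    """

    T2_leading: float   # T1 − ln(ε)/ε
    T2_refined: float   # T1 + (−ln ε − ln(−ln ε) + A)/ε
    Theta2: float       # predicted theta phase of the second spike
    A: float            # log-amplitude constant ln(gIE/(−λω·sin Θ0))


@dataclass(frozen=True)
class SpikePrediction:
    """Assembled analytic prediction of a theta cycle's spike sequence."""

    T1: float
    times: tuple[float, ...]
    isis: tuple[float, ...]
    phases: tuple[float, ...]
    M: int
    isi_intrinsic: float | None
    isi_min: float | None
    isi_max: float | None
    regime: Regime


def check_inhibition_dominance(params: ModelParams) -> bool:
    """True iff gIE > IE + 2λ, so one spike's inhibition silences the cell
    at any theta phase (the drive maximum is IE + 2λ)."""
    return params.gIE > params.IE + 2.0 * params.lam


def _require_dominance(params: ModelParams) -> None:
    if not check_inhibition_dominance(params):
        raise ApplicabilityError(
            f"inhibition dominance gIE > IE + 2*lam fails "
            f"(gIE={params.gIE}, IE + 2*lam={params.IE + 2 * params.lam}); "
            "the ISI recursion does not apply"
        )


def isi(params: ModelParams, Theta_prev: float) -> float:
    """ISI following a spike at theta phase ``Theta_prev``.

    (1/ε)·ln(gIE/F) is the time for inhibition to decay back to the drive
    level F = IE + λ(1+cos Θ_prev); −Ω0/(ε^{1/3}F^{1/3}) is the slow-passage
    delay through the re-crossed SNIC.  Both terms are positive.
    """
    _require_dominance(params)
    F = params.drive(Theta_prev)
    if F <= 0:
        raise ApplicabilityError(
            f"drive F={F:.4g} at Theta={Theta_prev:.4g} is not positive; "
            "phase is outside the active window"
        )
    eps = params.epsI
    Om0 = special_constant_omega0()
    return math.log(params.gIE / F) / eps - Om0 / (eps ** (1.0 / 3.0) * F ** (1.0 / 3.0))


def isi_intrinsic(params: ModelParams) -> float:
    """Intrinsic (unmodulated, λ=0) PING period ΔT^IN = (1/ε)ln(gIE/IE) − Ω0/(ε^{1/3}IE^{1/3})."""
    if classify_regime(params) is not Regime.OSCILLATOR:
        raise RegimeError("intrinsic period requires the oscillator regime (IE > 0)")
    _require_dominance(params)
    eps = params.epsI
    Om0 = special_constant_omega0()
    return math.log(params.gIE / params.IE) / eps - Om0 / (
        eps ** (1.0 / 3.0) * params.IE ** (1.0 / 3.0)
    )


def isi_extrema(params: ModelParams, Theta_prev: float = None) -> tuple[float, float]:
    """Quadratic-in-phase ISI expansions around the theta trough and peak.

    Returns ``(dT_max, dT_min)``: the second-order expansion of the ISI
    recursion about Θ = −π (where the drive is minimal, ISI maximal)
    evaluated at ``Theta_prev`` measured from −π, and about Θ = 0 (drive
    maximal, ISI minimal) evaluated at ``Theta_prev`` directly.  With
    ``Theta_prev=None`` the global extremes (ΔT^IN, ΔT(0)) are returned.

    Expanding ΔT(F) with dΔT/dF = −1/(εF) + Ω0/(3ε^{1/3}F^{4/3}) and
    F ≈ IE + (λ/2)(Θ+π)² near the trough (resp. IE + 2λ − (λ/2)Θ² near the
    peak) gives quadratic corrections that are negative at the trough and
    positive at the peak, so the two expansions bracket every mid-cycle ISI.
    """
    if classify_regime(params) is not Regime.OSCILLATOR:
        raise RegimeError("ISI extrema expansions require the oscillator regime")
    _require_dominance(params)
    eps = params.epsI
    e13 = eps ** (1.0 / 3.0)
    Om0 = special_constant_omega0()
    IE, lam = params.IE, params.lam
    dTin = isi_intrinsic(params)

    d_trough = 0.0 if Theta_prev is None else Theta_prev + math.pi
    d_peak = 0.0 if Theta_prev is None else Theta_prev

    dT_max = dTin + (d_trough ** 2) * (
        -lam / (2.0 * eps * IE) + Om0 * lam / (6.0 * e13 * IE ** (4.0 / 3.0))
    )

    Fp = IE + 2.0 * lam
    dT_at_peak = (
        dTin
        - math.log(Fp / IE) / eps
        - (Om0 / e13) * (Fp ** (-1.0 / 3.0) - IE ** (-1.0 / 3.0))
    )
    dT_min = dT_at_peak + (d_peak ** 2) * (lam / 2.0) * (
        1.0 / (eps * Fp) - Om0 / (3.0 * e13 * Fp ** (4.0 / 3.0))
    )
    return dT_max, dT_min


def _count_integrals(params: ModelParams, lo: float, hi: float) -> tuple[float, float]:
    """∫ ln(gIE/F(Θ)) dΘ and ∫ (−Ω0)·F(Θ)^{−1/3} dΘ over [lo, hi].

    In the excitable case F vanishes at the window edges; both integrands
    have integrable endpoint singularities, handled by adaptive quadrature.
    """
    Om0 = special_constant_omega0()

    def log_term(Theta):
        return math.log(params.gIE / params.drive(Theta))

    def passage_term(Theta):
        return -Om0 * params.drive(Theta) ** (-1.0 / 3.0)

    I1, _ = quad(log_term, lo, hi, epsabs=1e-10, limit=200)
    I2, _ = quad(passage_term, lo, hi, epsabs=1e-10, limit=200)
    return I1, I2


def spike_count(params: ModelParams) -> int:
    """Predicted number of gamma spikes per theta cycle.

    The per-spike time averaged over the spiking phases is
    (1/L)·[ε·∫_W ln(gIE/F) dΘ + ε^{5/3}·∫_W (−Ω0)·F^{−1/3} dΘ],
    where W is the phase window with positive drive and L its length:
    the full cycle (L = 2π) for an oscillator, the supra-threshold window
    between the two SNIC crossings (L = 2|Θ0|) for an excitable cell.
    The averaged recursion bounds the number of *complete interspike
    intervals* k: k is the largest integer whose total predicted interval
    time k·⟨ΔT⟩ stays strictly inside the available time L/ω (rescaled by
    εΘ = ε²; an exact boundary is broken downward).  A window holding k
    complete intervals contains k + 1 spikes — each interval ends in a
    spike and the chain is opened by the first spike, which is paid for by
    the first-spike drift/passage rather than by an interval — so
    M = k + 1.  In the excitable regime, if even the predicted first spike
    falls beyond the closing SNIC crossing (a window too short for the
    slow-passage delay, e.g. 2λ + IE → 0⁺), no spike fits and M = 0.
    """
    _require_dominance(params)
    regime = classify_regime(params)
    eps = params.epsI
    if regime is Regime.OSCILLATOR:
        lo, hi = -math.pi, math.pi
    elif regime is Regime.EXCITABLE:
        Theta0 = snic_phase(params)
        lo, hi = Theta0, -Theta0
        t_close = (math.pi - Theta0) / (params.epsTheta * params.omega)
        if first_spike_excitable(params).T1 >= t_close:
            return 0
    else:
        return 0
    L = hi - lo
    I1, I2 = _count_integrals(params, lo, hi)
    per_interval = (eps * I1 + eps ** (5.0 / 3.0) * I2) / L
    x = (L / params.omega) / per_interval
    # strict inequality: an exact boundary is broken downward
    k = math.floor(x)
    if x - k < 1e-9:
        k -= 1
    return max(k, 0) + 1


def second_spike_excitable(params: ModelParams, T1: float | None = None) -> SecondSpikeEstimate:
    """Second-spike estimates in the excitable regime.

    Right after the first spike the drive is only marginally positive
    (the phase has just passed the SNIC), so the second spike waits for
    inhibition to decay almost completely: the gap is −ln(ε)/ε to leading
    order.  The refined estimate keeps the next order,
    ε·T2* = −ln ε − ln(−ln ε) + A with A = ln(gIE/(−λω·sin Θ0)),
    which accounts for the linear growth of the drive past the bifurcation.
    """
    if classify_regime(params) is not Regime.EXCITABLE:
        raise RegimeError("second-spike asymptotics require the excitable regime")
    _require_dominance(params)
    eps = params.epsI
    if eps >= 1.0:
        raise ApplicabilityError("asymptotics in -ln(eps) require eps < 1")
    if T1 is None:
        T1 = first_spike_excitable(params).T1
    Theta0 = snic_phase(params)
    A = math.log(params.gIE / (-params.lam * params.omega * math.sin(Theta0)))
    gap_leading = -math.log(eps) / eps
    gap_refined = (-math.log(eps) - math.log(-math.log(eps)) + A) / eps
    # phase advance uses the slow clock: ΔΘ = εΘ·ω·ΔT with ΔT ≈ −ln ε/ε
    Theta1 = -math.pi + params.epsTheta * params.omega * T1
    Theta2 = Theta1 + params.epsTheta * params.omega * gap_leading
    return SecondSpikeEstimate(
        T2_leading=T1 + gap_leading,
        T2_refined=T1 + gap_refined,
        Theta2=Theta2,
        A=A,
    )


def predict_spike_sequence(params: ModelParams, max_spikes: int = 10_000) -> SpikePrediction:
    """Assemble the full analytic spike sequence for one theta cycle.

    T1 comes from the matching first-spike branch; subsequent spikes follow
    the ISI recursion with the phase advanced by εΘ·ω·ΔT each step.  For an
    oscillator the sequence runs until one theta period has elapsed; for an
    excitable cell the second spike uses the dedicated asymptotics and the
    burst ends when the predicted phase leaves the supra-threshold window.
    """
    _require_dominance(params)
    regime = classify_regime(params)
    epsw = params.epsTheta * params.omega
    period = params.theta_period

    if regime is Regime.OSCILLATOR:
        T1 = first_spike_oscillator(params)
        times = [T1]
        Theta = -math.pi + epsw * T1
        while len(times) < max_spikes:
            dT = isi(params, Theta)
            t_next = times[-1] + dT
            if t_next >= period:
                break
            times.append(t_next)
            Theta += epsw * dT
        dTin = isi_intrinsic(params)
        dT_max, dT_min = isi_extrema(params)
    elif regime is Regime.EXCITABLE:
        Theta0 = snic_phase(params)
        T1 = first_spike_excitable(params).T1
        times = [T1]
        second = second_spike_excitable(params, T1)
        Theta = -math.pi + epsw * second.T2_refined
        if Theta < -Theta0 and second.T2_refined < period:
            times.append(second.T2_refined)
            while len(times) < max_spikes:
                if params.drive(Theta) <= 0:
                    break
                dT = isi(params, Theta)
                t_next = times[-1] + dT
                Theta_next = Theta + epsw * dT
                if Theta_next >= -Theta0 or t_next >= period:
                    break
                times.append(t_next)
                Theta = Theta_next
        # intrinsic period and trough expansion need IE > 0; only the
        # peak-phase minimum ISI is defined for an excitable cell
        dTin = dT_max = None
        dT_min = isi(params, 0.0)
    else:
        raise RegimeError("a silent cell produces no spikes")

    M = spike_count(params)
    if M != len(times):
        warnings.warn(
            f"integer spike-count estimate M={M} differs from assembled "
            f"sequence length {len(times)}",
            stacklevel=2,
        )
    times_arr = tuple(times)
    phases = tuple(-math.pi + epsw * t for t in times)
    return SpikePrediction(
        T1=T1,
        times=times_arr,
        isis=tuple(np.diff(times)),
        phases=phases,
        M=M,
        isi_intrinsic=dTin,
        isi_min=dT_min,
        isi_max=dT_max,
        regime=regime,
    )
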