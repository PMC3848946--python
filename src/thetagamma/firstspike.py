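"""Semi-analytic time to the first gamma spike.

Two regimes, two routes:

* **Oscillator** (IE > 0).  Before the first spike no inhibition has been
  recruited, so the voltage obeys the scalar QIF equation
  dV/dt = V² + IE + λ(1 + cos(εΘωt − π)).  The Riccati substitution
  V = −u′/u turns this into a Mathieu equation
  u″(z) = −(a − 2q·cos 2z)·u with z = εΘωt/2, a = 4(IE+λ)/(εΘω)²,
  q = 2λ/(εΘω)², and the spike times are the zeros of u.  The first zero
  of the solution with u(0) = 0, u′(0) = 1 (which encodes V(0) = −∞)
  gives T1.

* **Excitable** (IE < 0 < 2λ + IE).  The cell sits at rest until the theta
  phase sweeps the net drive through zero — a slow passage through a SNIC
  bifurcation at phase Θ0.  The passage time splits into a drift term
  (Θ0 + π)/(εΘω) (theta travelling from the trough to the bifurcation) and
  a slow-passage delay C0·εΘ^{−1/3} governed by the universal constant
  Ω0 ≈ −2.33811 (the first zero of Ai(−y)); the logarithmic and O(1)
  corrections vanish for this vector field, so the remainder is O(εΘ^{1/3}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import ai_zeros, jv

from .params import (
    ModelParams,
    Regime,
    RegimeError,
    classify_regime,
    critical_quantities,
)


@dataclass(frozen=True)
class MathieuCoeffs:
    """Rescaled Mathieu parameters: a, q, and the t→z mapping factor.

    z = z_scale · t with z_scale = εΘω/2; in z the theta forcing has
    period π.
    """

    a_m: float
    q: float
    z_scale: float


@dataclass(frozen=True)
class FirstSpikeExcitable:
    """Excitable first-spike prediction, with its two terms split out."""

    T1: float
    drift: float       # (Θ0 + π)/(εΘ·ω): theta trough → SNIC phase
    correction: float  # C0·εΘ^{−1/3}: slow-passage delay through the SNIC


def mathieu_coeffs(params: ModelParams) -> MathieuCoeffs:
    """Mathieu parameters a = 4(IE+λ)/(εΘω)², q = 2λ/(εΘω)²."""
    if classify_regime(params) is not Regime.OSCILLATOR:
        raise RegimeError("Mathieu reduction requires the oscillator regime (IE > 0)")
    s2 = (params.epsTheta * params.omega) ** 2
    return MathieuCoeffs(
        a_m=4.0 * (params.IE + params.lam) / s2,
        q=2.0 * params.lam / s2,
        z_scale=params.epsTheta * params.omega / 2.0,
    )


def _first_zero_of_u(a_m: float, q: float, z_max: float, rtol: float = 1e-11) -> float:
    """First positive zero of u″ = −(a − 2q cos 2z)u, u(0)=0, u′(0)=1.

    Integrated directly as an ODE (general-(a,q) Mathieu functions are not
    a library special function); the zero is located by the event finder
    and refined with brentq on the dense output.
    """

    def rhs(z, y):
        return [y[1], -(a_m - 2.0 * q * math.cos(2.0 * z)) * y[0]]

    def downcross(z, y):
        return y[0]

    # u ~ z near 0 (u' > 0): the first zero is a downward crossing, which
    # conveniently excludes the z = 0 root from event detection.
    downcross.terminal = True
    downcross.direction = -1

    sol = solve_ivp(rhs, (0.0, z_max), [0.0, 1.0], events=downcross,
                    rtol=rtol, atol=1e-14, dense_output=True, method="DOP853")
    if sol.status != 1:
        raise RuntimeError(
            f"Mathieu solution has no zero in (0, {z_max}]; a={a_m}, q={q}"
        )
    z1 = float(sol.t_events[0][0])
    # refine on the dense output around the event
    lo, hi = 0.9 * z1, min(z_max, 1.1 * z1)
    u = lambda z: sol.sol(z)[0]
    if u(lo) > 0 > u(hi):
        z1 = brentq(u, lo, hi, xtol=1e-13)
    return z1


def first_spike_oscillator(params: ModelParams) -> float:
    """Time to the first spike in the oscillator regime via the Mathieu zero.

    Valid from theta-trough initial conditions (Θ(0) = −π, V(0) = −∞) with
    the inhibitory synapse still silent.  In the uncoupled limit λ = 0 the
    equation is harmonic and T1 reduces to the QIF closed form π/√IE.
    """
    mc = mathieu_coeffs(params)
    z_max = math.pi  # one theta period in the z variable
    z1 = _first_zero_of_u(mc.a_m, mc.q, z_max)
    return z1 / mc.z_scale


@lru_cache(maxsize=1)
def special_constant_omega0() -> float:
    """Universal slow-passage constant Ω0 ≈ −2.33811.

    −Ω0 is the smallest positive root y* of
    J_{−1/3}(2y^{3/2}/3) + J_{1/3}(2y^{3/2}/3),
    the denominator of the Riccati/Bessel solution of the saddle-node
    normal form dx/dy = (y + x²)/ε.  The same combination is (up to a
    positive factor) the Airy function Ai(−y), so the root is cross-checked
    against the first Airy zero.  Stored negative: the passage-delay
    formulas use Ω0 < 0 so corrections come out positive.
    """

    def bessel_comb(y: float) -> float:
        arg = 2.0 * y ** 1.5 / 3.0
        return jv(-1.0 / 3.0, arg) + jv(1.0 / 3.0, arg)

    y_star = brentq(bessel_comb, 2.0, 3.0, xtol=1e-14)
    airy_zero = -float(ai_zeros(1)[0][0])  # first zero of Ai is at −2.338...
    if abs(y_star - airy_zero) > 1e-8:
        raise RuntimeError(
            f"Bessel-route root {y_star!r} disagrees with Airy zero {airy_zero!r}"
        )
    return -y_star


def first_spike_excitable(params: ModelParams) -> FirstSpikeExcitable:
    """Time to the first spike in the excitable regime (slow-passage asymptotics).

    T1 = (Θ0 + π)/(εΘω) + C0·εΘ^{−1/3},
    C0 = −2^{1/3}·Ω0/(ω·a)^{1/3},  a = 2·sqrt(−IE(2λ+IE)).

    Valid from rest (θE = θ0, Θ = −π, sI = 0); the remainder is O(εΘ^{1/3})
    because the ln εΘ and O(1) coefficients vanish for this model.
    """
    if classify_regime(params) is not Regime.EXCITABLE:
        raise RegimeError("excitable first-spike formula requires the excitable regime")
    cq = critical_quantities(params)
    drift = (cq.Theta0 + math.pi) / (params.epsTheta * params.omega)
    correction = cq.C0 * params.epsTheta ** (-1.0 / 3.0)
    return FirstSpikeExcitable(T1=drift + correction, drift=drift, correction=correction)


def first_spike(params: ModelParams) -> float:
    """Branch-dispatching first-spike time (oscillator → Mathieu, excitable → SNIC)."""
    regime = classify_regime(params)
    if regime is Regime.OSCILLATOR:
        return first_spike_oscillator(params)
    if regime is Regime.EXCITABLE:
        return first_spike_excitable(params).T1
    raise RegimeError("a silent cell never spikes")
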