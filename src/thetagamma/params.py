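"""Model parameters, regime classification, and SNIC-related critical quantities.

The model is a single excitatory gamma-band theta neuron driven by a slow
sinusoidal theta-phase input and self-inhibited through an enslaved
interneuron synapse:

    dθE/dt = (1 − cos θE) + (IE + λ(1 + cos Θ) − gIE·sI)(1 + cos θE)
    dsI/dt = −εI·sI + δ(θE − π)
    dΘ/dt  = εΘ·ω

Spikes occur at θE = π.  Depending on the constant drive ``IE`` the gamma
cell is an intrinsic oscillator (IE > 0), excitable (IE < 0 < 2λ + IE,
spiking gated by the theta phase through a SNIC bifurcation), or silent
(IE ≤ −2λ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum


class RegimeError(ValueError):
    """Raised when an operation is called outside its regime of validity."""


class DegenerateParameterError(ValueError):
    """Raised for parameter sets on a regime boundary (IE == 0)."""


class Regime(str, Enum):
    OSCILLATOR = "oscillator"
    EXCITABLE = "excitable"
    SILENT = "silent"


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the theta-modulated gamma model.

    Parameters
    ----------
    IE : float
        Constant drive to the excitatory gamma cell (dimensionless).
    lam : float
        Theta-gamma coupling strength λ ≥ 0.
    gIE : float
        Inhibitory synaptic strength ≥ 0 (the weight multiplying sI).
    epsI : float
        Inverse synaptic time scale ε > 0 (synaptic decay rate).
    epsTheta : float
        Slow time-scale parameter εΘ > 0; the theta angular frequency is
        ``epsTheta * omega``.  Modelling convention: εΘ ≈ ε².
    omega : float
        Theta frequency factor ω > 0.
    """

    IE: float
    lam: float = 0.0
    gIE: float = 0.0
    epsI: float = 0.1
    epsTheta: float = 0.01
    omega: float = 4.0
    timescale_warning: bool = field(init=False, default=False, compare=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.gIE < 0:
            raise ValueError(f"gIE must be >= 0, got {self.gIE}")
        for name in ("epsI", "epsTheta", "omega"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        # εΘ ~ ε² is a modelling assumption, not a hard constraint: warn only.
        mismatch = abs(self.epsTheta - self.epsI**2) / self.epsI**2
        if mismatch > 0.5:
            object.__setattr__(self, "timescale_warning", True)
            warnings.warn(
                f"epsTheta={self.epsTheta} deviates from epsI^2={self.epsI**2:.4g} "
                f"by {mismatch:.0%}; the slow/fast time-scale separation "
                "underlying the asymptotics assumes epsTheta ~ epsI^2",
                stacklevel=3,
            )

    @property
    def theta_period(self) -> float:
        """Duration of one full theta cycle, 2π/(εΘ·ω)."""
        return 2.0 * math.pi / (self.epsTheta * self.omega)

    def drive(self, Theta: float) -> float:
        """Net feedforward drive F(Θ) = IE + λ(1 + cos Θ) (no inhibition)."""
        return self.IE + self.lam * (1.0 + math.cos(Theta))


@dataclass(frozen=True)
class CriticalQuantities:
    """SNIC-related quantities of an excitable parameter set.

    theta0   resting fixed point of the gamma cell, in (−π, 0)
    Theta0   theta phase where the SNIC bifurcation is crossed, in (−π, 0)
    a_snic   local expansion coefficient 2·sqrt(−IE·(2λ+IE)) of the
             saddle-node normal form
    Omega0   universal slow-passage constant ≈ −2.33811 (first zero of
             Ai(−y), stored with negative sign)
    C0       first-spike delay coefficient −2^{1/3}·Ω0/(ω·a)^{1/3}
    """

    theta0: float
    Theta0: float
    a_snic: float
    Omega0: float
    C0: float


_CONFIG_KEYS = {
    "IE": "IE",
    "ie": "IE",
    "lambda": "lam",
    "lam": "lam",
    "gIE": "gIE",
    "gie": "gIE",
    "epsI": "epsI",
    "eps_i": "epsI",
    "epsTheta": "epsTheta",
    "eps_theta": "epsTheta",
    "omega": "omega",
}


def params_from_mapping(mapping: dict) -> ModelParams:
    """Build ModelParams from a flat key–value mapping (config-file schema).

    Accepts the keys IE, lambda, gIE, epsI, epsTheta, omega (plus snake_case
    aliases); unknown keys are ignored so simulator-level settings can share
    the same file.
    """
    kwargs = {}
    for key, value in mapping.items():
        field_name = _CONFIG_KEYS.get(key)
        if field_name is not None:
            kwargs[field_name] = float(value)
    if "IE" not in kwargs:
        raise ValueError("config must provide IE")
    return ModelParams(**kwargs)


def classify_regime(params: ModelParams) -> Regime:
    """Classify the parameter set as oscillator, excitable, or silent.

    Oscillator: IE > 0 (intrinsic firing at every theta phase).
    Excitable: IE < 0 < 2λ + IE (theta phase gates firing through a SNIC).
    Silent: IE ≤ −2λ (net drive never positive).

    IE == 0 sits exactly on the SNIC at the theta trough and is rejected:
    both analytic branches are singular there.
    """
    if params.IE == 0:
        raise DegenerateParameterError(
            "IE == 0 is on the bifurcation boundary; no regime assigned"
        )
    if params.IE > 0:
        return Regime.OSCILLATOR
    if 2.0 * params.lam + params.IE > 0:
        return Regime.EXCITABLE
    return Regime.SILENT


def rest_fixed_point(params: ModelParams) -> float:
    """Resting fixed point θ0 ∈ (−π, 0) of the gamma cell at the theta trough.

    Solves (1 − IE)·cos θ0 = 1 + IE, i.e. the stable root of
    (1 − cos θ) + IE(1 + cos θ) = 0.  Defined only for IE < 0.
    """
    if params.IE >= 0:
        raise RegimeError(f"rest fixed point requires IE < 0, got IE={params.IE}")
    return -math.acos((1.0 + params.IE) / (1.0 - params.IE))


def snic_phase(params: ModelParams) -> float:
    """Theta phase Θ0 ∈ (−π, 0) where the net drive crosses zero.

    cos Θ0 = −(λ + IE)/λ.  The symmetric exit crossing on the descending
    half of the theta cycle is −Θ0.  Requires the excitable regime: for an
    oscillator the drive never vanishes, for a silent cell it never turns
    positive.
    """
    regime = classify_regime(params)
    if regime is not Regime.EXCITABLE:
        raise RegimeError(
            f"SNIC crossing phase requires the excitable regime, got {regime.value}"
        )
    return -math.acos(-(params.lam + params.IE) / params.lam)


#: Universal slow-passage constant: −(first zero of Ai(−y)) ≈ −2.33811.
#: Recomputed from scratch in :func:`thetagamma.firstspike.special_constant_omega0`;
#: this copy avoids circular imports for formula evaluation.
OMEGA0 = -2.3381074104597674


def critical_quantities(params: ModelParams) -> CriticalQuantities:
    """Assemble the SNIC critical quantities for an excitable parameter set."""
    theta0 = rest_fixed_point(params)
    Theta0 = snic_phase(params)
    a = 2.0 * math.sqrt(-params.IE * (2.0 * params.lam + params.IE))
    from .firstspike import special_constant_omega0

    Omega0 = special_constant_omega0()
    C0 = -(2.0 ** (1.0 / 3.0)) * Omega0 / (params.omega * a) ** (1.0 / 3.0)
    return CriticalQuantities(theta0=theta0, Theta0=Theta0, a_snic=a, Omega0=Omega0, C0=C0)


def verify_log_term_vanishes(params: ModelParams) -> tuple[bool, dict[str, float]]:
    """Certify that the logarithmic slow-passage correction is absent.

    The first-spike expansion through the SNIC has a candidate O(ln εΘ)
    coefficient built from derivatives of the frozen-theta vector field
    φ(x, y) = (1 − cos x) + (IE + λ(1 + cos y))(1 + cos x) and of
    ψ(x, y) = ω at the singular point S = (0, Θ0).  That coefficient
    vanishes whenever the odd x-derivatives of φ and ψ_x vanish at S.
    Here they are evaluated from the exact trigonometric derivatives:

        φ_x   = (1 − IE − λ(1 + cos y))·sin x
        φ_xxx = −(1 − IE − λ(1 + cos y))·sin x
        ψ_x   = 0 identically

    all of which are exactly zero at x = 0.

    Returns ``(ok, diagnostics)`` with the evaluated derivative magnitudes.
    """
    regime = classify_regime(params)
    if regime is not Regime.EXCITABLE:
        raise RegimeError(f"requires the excitable regime, got {regime.value}")
    Theta0 = snic_phase(params)
    x = 0.0
    coef = 1.0 - params.IE - params.lam * (1.0 + math.cos(Theta0))
    phi_x = coef * math.sin(x)
    phi_xxx = -coef * math.sin(x)
    psi_x = 0.0
    diag = {
        "phi_x_at_S": phi_x,
        "phi_xxx_at_S": phi_xxx,
        "psi_x_at_S": psi_x,
        "Theta0": Theta0,
    }
    tol = 1e-12
    ok = abs(phi_x) < tol and abs(phi_xxx) < tol and abs(psi_x) < tol
    return ok, diag
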