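"""Closed-form stationary statistics of the free membrane potential.

With the threshold removed, the recursion v_{j+1} = beta*v_j + alpha*I_j
driven by i.i.d. currents is an AR(1) process whose stationary mean and
variance follow from the geometric sums

    <v>      = alpha * mu / (1 - beta),
    <dv^2>   = alpha^2 * sigma^2 / (1 - beta^2).

For the exact scheme the mean reduces to (tau/C)*mu regardless of step
size; the forward-Euler variance is strictly larger at any h in (0, tau),
which is the root of the firing-rate bias the package quantifies.

This module also inverts the coefficient relations: given any (alpha,
beta) -- in particular the exact-propagator pair -- it solves the
forward-Euler formulas for the effective (tau, C) that a forward-Euler
integrator would have to be configured with to produce those
coefficients.  The exact scheme at (tau=10, C=1, h=1) corresponds to an
Euler model with tau ~ 10.5 ms and C ~ 1.05 pF: the scheme silently
changes the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import NoiseParameters, SchemeCoefficients

__all__ = ["FreeMoments", "EffectiveParameters", "free_moments", "effective_euler_parameters"]


@dataclass(frozen=True)
class FreeMoments:
    """Stationary mean and standard deviation of the free potential, mV."""

    mean_v: float
    std_v: float


@dataclass(frozen=True)
class EffectiveParameters:
    """The (tau, C) a forward-Euler integrator implicitly simulates."""

    tau_eff: float
    c_eff: float


def free_moments(coeffs: SchemeCoefficients, noise: NoiseParameters) -> FreeMoments:
    """Stationary mean and std of v_{j+1} = beta*v_j + alpha*I_j.

    mean = alpha*mu/(1-beta); std = alpha*sigma/sqrt((1-beta)(1+beta)),
    the factored form avoiding cancellation in 1-beta^2 at small h/tau.
    """
    if coeffs.beta >= 1.0:
        raise ValueError(f"stationary moments diverge for beta >= 1 (beta={coeffs.beta})")
    mean_v = coeffs.alpha * noise.mu / (1.0 - coeffs.beta)
    std_v = coeffs.alpha * noise.sigma / math.sqrt((1.0 - coeffs.beta) * (1.0 + coeffs.beta))
    return FreeMoments(mean_v=mean_v, std_v=std_v)


def effective_euler_parameters(coeffs: SchemeCoefficients, h: float) -> EffectiveParameters:
    """Solve alpha = h/C, beta = 1 - h/tau for (tau, C) given (alpha, beta).

    tau_eff = h/(1-beta), c_eff = h/alpha.  A forward-Euler integrator
    configured with these parameters reproduces the given coefficients
    exactly; feeding it the exact-propagator pair reveals which model
    forward Euler actually solves.
    """
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    if coeffs.beta >= 1.0:
        raise ValueError(f"no finite tau_eff for beta >= 1 (beta={coeffs.beta})")
    if coeffs.alpha <= 0:
        raise ValueError(f"alpha must be positive, got {coeffs.alpha}")
    return EffectiveParameters(tau_eff=h / (1.0 - coeffs.beta), c_eff=h / coeffs.alpha)
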