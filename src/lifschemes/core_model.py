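"""Model definition and one-step update rules.

The membrane potential of a leaky integrate-and-fire (LIF) neuron obeys

    dv/dt = -v/tau + (I_ext + I_syn)/C,

with membrane time constant ``tau`` (ms) and capacitance ``C`` (pF); the
potential is reset to ``v_reset`` when it reaches the threshold ``theta``
and there is no refractory period.  The external current is piecewise
constant: every ``h`` milliseconds a fresh amplitude is drawn from the
half-open uniform distribution U[i_min, i_max).

Because the input is constant over each interval ``h``, the dynamics on the
time grid t_j = j*h reduce exactly to the scalar affine recursion

    v_{j+1} = beta * v_j + alpha * I_j,

where the coefficients (alpha, beta) encode the integration scheme:

* exact propagator (equivalently, exponential integration for
  piecewise-constant input): alpha = (tau/C)(1 - exp(-h/tau)),
  beta = exp(-h/tau) -- error-free for this model;
* forward Euler: alpha = h/C, beta = 1 - h/tau -- a first-order
  approximation that effectively simulates a *different* (tau, C).

Units are fixed throughout the package as mV / ms / pA / pF, which makes
ms/pF identical to mV/pA so the recursion is dimensionally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "NeuronParameters",
    "NoiseParameters",
    "NetworkParameters",
    "SchemeCoefficients",
    "TrajectoryState",
    "exact_coefficients",
    "euler_coefficients",
    "step",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Physical constants of a single LIF neuron.

    Attributes
    ----------
    tau : float
        Membrane time constant in ms. Must be positive.
    capacitance : float
        Membrane capacitance in pF. Must be positive.
    theta : float
        Spike threshold in mV. Must exceed ``v_reset``.
    v_reset : float
        Reset potential in mV (0 in the reference model).
    """

    tau: float = 10.0
    capacitance: float = 1.0
    theta: float = 6.0
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.capacitance <= 0:
            raise ValueError(f"capacitance must be positive, got {self.capacitance}")
        if self.theta <= self.v_reset:
            raise ValueError(
                f"theta ({self.theta}) must exceed v_reset ({self.v_reset})"
            )


@dataclass(frozen=True)
class NoiseParameters:
    """Piecewise-constant uniform external current.

    A fresh amplitude is drawn from U[i_min, i_max) pA every ``h`` ms and
    held constant in between; ``h`` doubles as the integration step.
    """

    i_min: float = 0.0
    i_max: float = 1.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.i_max < self.i_min:
            raise ValueError(f"i_max ({self.i_max}) must be >= i_min ({self.i_min})")
        if self.h <= 0:
            raise ValueError(f"h must be positive, got {self.h}")

    @property
    def mu(self) -> float:
        """Mean current (i_min + i_max)/2 in pA."""
        return 0.5 * (self.i_min + self.i_max)

    @property
    def sigma2(self) -> float:
        """Current variance (i_max - i_min)^2 / 12 in pA^2."""
        return (self.i_max - self.i_min) ** 2 / 12.0

    @property
    def sigma(self) -> float:
        """Current standard deviation in pA."""
        return math.sqrt(self.sigma2)


@dataclass(frozen=True)
class NetworkParameters:
    """All-to-all delta-synapse network of ``k`` excitatory neurons.

    Synaptic weights are drawn once from U[0, w_max) mV with
    w_max = 1/k, so the mean weight is 1/(2k) mV and the summed
    recurrent drive per presynaptic spike stays O(1) as k grows.
    Spikes are delivered after a fixed delay (a multiple of ``h``).
    """

    k: int = 1000
    delay: float = 1.0
    self_connections: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.delay <= 0:
            raise ValueError(f"delay must be positive, got {self.delay}")

    @property
    def w_max(self) -> float:
        """Upper synaptic-weight bound 1/k in mV."""
        return 1.0 / self.k


@dataclass(frozen=True)
class SchemeCoefficients:
    """The (alpha, beta) pair defining one discretized update rule.

    ``alpha`` is the per-step current-to-voltage gain (mV/pA) and
    ``beta`` the per-step decay factor (dimensionless); the update is
    v_{j+1} = beta*v_j + alpha*I_j.
    """

    alpha: float
    beta: float
    scheme_label: str

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass
class TrajectoryState:
    """Mutable per-neuron state during simulation.

    ``pending_spikes`` maps a future step index to the summed synaptic
    increment (mV) due for delivery at that step.
    """

    v: float = 0.0
    pending_spikes: dict[int, float] = field(default_factory=dict)


def exact_coefficients(neuron: NeuronParameters, h: float) -> SchemeCoefficients:
    """Propagator coefficients: the error-free update for this model.

    alpha = (tau/C)(1 - exp(-h/tau)),  beta = exp(-h/tau).

    For piecewise-constant input the resulting recursion reproduces the
    continuous-time solution exactly at the grid points, for any step size.
    """
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    decay = math.exp(-h / neuron.tau)
    alpha = (neuron.tau / neuron.capacitance) * (1.0 - decay)
    return SchemeCoefficients(alpha=alpha, beta=decay, scheme_label="exact")


def euler_coefficients(neuron: NeuronParameters, h: float) -> SchemeCoefficients:
    """Forward-Euler coefficients: alpha = h/C, beta = 1 - h/tau.

    Requires h < tau; at h >= tau the decay factor is non-positive and the
    scheme leaves the physically meaningful regime.
    """
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    if h >= neuron.tau:
        raise ValueError(
            f"forward Euler requires h < tau for stability "
            f"(got h={h} ms, tau={neuron.tau} ms: beta = 1 - h/tau <= 0)"
        )
    return SchemeCoefficients(
        alpha=h / neuron.capacitance, beta=1.0 - h / neuron.tau, scheme_label="forward_euler"
    )


def step(v: float, i: float, coeffs: SchemeCoefficients) -> float:
    """One linear update v -> beta*v + alpha*i.  No threshold logic."""
    return coeffs.beta * v + coeffs.alpha * i
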