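"""Seeded Monte-Carlo simulation of single neurons and the delta-synapse network.

Everything runs on the fixed time grid t_j = j*h at which the external
current switches, using the per-step update v -> beta*v + alpha*I for the
chosen scheme.  Within one step of the network simulation the event order
is: (1) linear update with the external current, (2) delivery of synaptic
deltas from spikes emitted one delay earlier (each adds its weight, in
mV, instantaneously), (3) threshold test and reset.  Delta synapses act
at the moment of delivery and may trigger a spike in the same step, which
is why delivery precedes the threshold test.

Randomness is organised so that results are reproducible and networks are
decomposable: a root ``SeedSequence`` spawns one child stream for the
synaptic weights and one independent child stream per neuron for its
external currents.  A zero-weight network is therefore bitwise identical
to the corresponding set of independent single-neuron runs when they are
fed the same per-neuron streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core_model import (
    NetworkParameters,
    NeuronParameters,
    NoiseParameters,
    SchemeCoefficients,
)
from .markov_analysis import VoltageGrid

__all__ = [
    "SpikeRaster",
    "RateEstimate",
    "VoltageHistogram",
    "neuron_streams",
    "simulate_neuron",
    "simulate_network",
    "estimate_rate",
    "voltage_histogram",
    "population_activity",
]

#: weight matrices above this many entries are refused unless the caller
#: raises the cap explicitly (k^2 doubles; 1e8 entries is 800 MB)
DEFAULT_WEIGHT_CAP = 200_000_000


@dataclass(frozen=True)
class SpikeRaster:
    """Spike events as parallel (time, neuron id) arrays.

    Times are in ms and are always multiples of the step h; a spike
    detected during the step ending at t_{j+1} is stamped t_{j+1}.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.neuron_ids):
            raise ValueError("times and neuron_ids must have equal length")

    @property
    def n_spikes(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RateEstimate:
    """Firing-rate estimate in spikes/s with its standard error."""

    rate: float
    stderr: float
    window: tuple[float, float]
    n_neurons: int


@dataclass(frozen=True)
class VoltageHistogram:
    """Histogram of grid-time voltage samples.

    ``mass`` is normalized over in-grid samples and sums to 1; samples
    falling outside the grid are never silently dropped -- they are
    counted in ``n_below``/``n_above``.
    """

    grid: VoltageGrid
    counts: np.ndarray
    mass: np.ndarray
    n_below: int
    n_above: int


def neuron_streams(seed, k: int) -> tuple[np.random.Generator, list[np.random.Generator]]:
    """Root seed -> (weight stream, one current stream per neuron).

    The spawn layout is part of the reproducibility contract: network and
    single-neuron simulations that share it produce identical currents.
    ``seed`` may be an int or a ``SeedSequence``.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(k + 1)
    weight_rng = np.random.default_rng(children[0])
    current_rngs = [np.random.default_rng(c) for c in children[1:]]
    return weight_rng, current_rngs


def _n_steps(duration: float, h: float) -> int:
    n = round(duration / h)
    if abs(n * h - duration) > 1e-9 * max(1.0, duration):
        raise ValueError(f"duration {duration} ms is not a multiple of h = {h} ms")
    if n < 1:
        raise ValueError("duration must cover at least one step")
    return n


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_neuron(
    neuron: NeuronParameters,
    noise: NoiseParameters,
    coeffs: SchemeCoefficients,
    duration: float,
    seed,
    thresholded: bool = True,
    v0: float = 0.0,
) -> tuple[SpikeRaster, np.ndarray]:
    """Simulate one neuron driven by external noise only.

    Returns the spike raster (empty when ``thresholded`` is False) and the
    voltage trace sampled at grid times, ``trace[j] = v(t_j)`` with
    ``trace[0] = v0``.  ``seed`` may be an int, a ``SeedSequence`` or a
    ``Generator`` (the latter allows sharing streams with a network run).
    """
    rng = _resolve_rng(seed)
    h = noise.h
    n = _n_steps(duration, h)
    currents = rng.uniform(noise.i_min, noise.i_max, size=n)
    trace = np.empty(n + 1)
    trace[0] = v0

    if not thresholded:
        # free run is a linear AR(1) filter of the current sequence
        trace[1:], _ = lfilter(
            [coeffs.alpha], [1.0, -coeffs.beta], currents, zi=[coeffs.beta * v0]
        )
        return (
            SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), duration, 1),
            trace,
        )

    alpha, beta, theta, v_reset = coeffs.alpha, coeffs.beta, neuron.theta, neuron.v_reset
    spike_steps: list[int] = []
    v = float(v0)
    for j in range(n):
        v = beta * v + alpha * currents[j]
        if v >= theta:
            spike_steps.append(j + 1)
            v = v_reset
        trace[j + 1] = v
    times = np.asarray(spike_steps, dtype=float) * h
    ids = np.zeros(len(spike_steps), dtype=np.int64)
    return SpikeRaster(times, ids, duration, 1), trace


def simulate_network(
    netparams: NetworkParameters,
    neuron: NeuronParameters,
    noise: NoiseParameters,
    coeffs: SchemeCoefficients,
    duration: float,
    seed,
    weights: np.ndarray | float | None = None,
    record_v: bool = False,
    weight_cap: int = DEFAULT_WEIGHT_CAP,
) -> tuple[SpikeRaster, np.ndarray | None]:
    """Simulate the all-to-all network of ``k`` neurons with delta synapses.

    ``weights[l, m]`` is the increment (mV) added to neuron m when neuron
    l's spike is delivered; by default all k^2 entries are drawn once from
    U[0, 1/k) mV (diagonal zeroed if self-connections are disabled).  Pass
    an explicit matrix to override, or the scalar ``0.0`` for an
    unconnected run without materialising k^2 zeros.  With ``record_v``
    the full (n_steps+1, k) voltage array is returned as well.
    """
    k = netparams.k
    h = noise.h
    n = _n_steps(duration, h)
    d_steps = round(netparams.delay / h)
    if abs(d_steps * h - netparams.delay) > 1e-9 or d_steps < 1:
        raise ValueError(f"delay {netparams.delay} ms must be a positive multiple of h={h}")
    weight_rng, current_rngs = neuron_streams(seed, k)
    if weights is None:
        if k * k > weight_cap:
            raise MemoryError(
                f"k^2 = {k * k} weights exceeds the cap of {weight_cap}; "
                "raise weight_cap explicitly to proceed"
            )
        weights = weight_rng.uniform(0.0, netparams.w_max, size=(k, k))
        if not netparams.self_connections:
            np.fill_diagonal(weights, 0.0)
        coupled = True
    elif np.isscalar(weights):
        if weights != 0.0:
            raise ValueError("scalar weights must be 0.0 (unconnected shortcut)")
        coupled = False
        weights = None
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (k, k):
            raise ValueError(f"weights shape {weights.shape} != ({k}, {k})")
        coupled = bool(np.any(weights))

    currents = np.empty((k, n))
    for idx, rng in enumerate(current_rngs):
        currents[idx] = rng.uniform(noise.i_min, noise.i_max, size=n)

    alpha, beta, theta, v_reset = coeffs.alpha, coeffs.beta, neuron.theta, neuron.v_reset
    v = np.zeros(k)
    spike_history = np.zeros((n, k), dtype=bool)
    spike_steps: list[int] = []
    spike_ids: list[np.ndarray] = []
    trace = np.zeros((n + 1, k)) if record_v else None

    for j in range(n):
        v = beta * v + alpha * currents[:, j]
        if coupled and j >= d_steps:
            arrivals = spike_history[j - d_steps]
            if arrivals.any():
                v += arrivals.astype(float) @ weights
        spiked = v >= theta
        if spiked.any():
            v[spiked] = v_reset
            spike_history[j] = spiked
            ids = np.flatnonzero(spiked)
            spike_steps.append(j + 1)
            spike_ids.append(ids)
        if record_v:
            trace[j + 1] = v

    if spike_steps:
        times = np.concatenate(
            [np.full(len(ids), s * h) for s, ids in zip(spike_steps, spike_ids)]
        )
        neuron_ids = np.concatenate(spike_ids)
    else:
        times = np.empty(0)
        neuron_ids = np.empty(0, dtype=np.int64)
    return SpikeRaster(times, neuron_ids, duration, k), trace


def estimate_rate(raster: SpikeRaster, window: tuple[float, float]) -> RateEstimate:
    """Population-average firing rate over a time window, in spikes/s.

    Spikes with t in (t_start, t_end] count; a spike stamped exactly at
    the window start belongs to the preceding interval.  The standard
    error comes from across-neuron dispersion of per-neuron rates; for a
    single neuron a Poisson approximation sqrt(N)/T is used.
    """
    t_start, t_end = window
    if not (0.0 <= t_start < t_end <= raster.duration):
        raise ValueError(f"window {window} not within [0, {raster.duration}] ms")
    in_window = (raster.times > t_start) & (raster.times <= t_end)
    length_s = (t_end - t_start) / 1000.0
    counts = np.bincount(
        raster.neuron_ids[in_window].astype(np.int64), minlength=raster.n_neurons
    )
    per_neuron = counts / length_s
    rate = float(per_neuron.mean())
    if raster.n_neurons > 1:
        stderr = float(per_neuron.std(ddof=1) / np.sqrt(raster.n_neurons))
    else:
        stderr = float(np.sqrt(counts.sum()) / length_s) if counts.sum() else 0.0
    return RateEstimate(rate=rate, stderr=stderr, window=window, n_neurons=raster.n_neurons)


def voltage_histogram(trace: np.ndarray, grid: VoltageGrid) -> VoltageHistogram:
    """Bin grid-time voltage samples on a voltage grid.

    Accepts a single trace or a (time, neuron) array; all samples are
    pooled.  Out-of-grid samples are tallied separately, never dropped.
    """
    samples = np.asarray(trace, dtype=float).ravel()
    below = int((samples < grid.v_lo).sum())
    above = int((samples >= grid.v_hi).sum())
    counts, _ = np.histogram(samples, bins=grid.edges)
    # np.histogram closes the last bin on the right; keep bins half-open
    at_top = int((samples == grid.v_hi).sum())
    if at_top:
        counts[-1] -= at_top
    total = counts.sum()
    mass = counts / total if total else np.zeros_like(counts, dtype=float)
    return VoltageHistogram(
        grid=grid, counts=counts, mass=mass, n_below=below, n_above=above
    )


def population_activity(raster: SpikeRaster, bin_ms: float, h: float = 1.0) -> np.ndarray:
    """Spike counts of all neurons in fixed time bins covering (0, duration].

    ``bin_ms`` must be a multiple of the step h so every spike time falls
    unambiguously into one bin; bins are right-inclusive to match the
    spike-time stamping at step ends.
    """
    ratio = bin_ms / h
    if abs(ratio - round(ratio)) > 1e-9 or bin_ms <= 0:
        raise ValueError(f"bin ({bin_ms} ms) must be a positive multiple of h ({h} ms)")
    n_bins = int(np.ceil(raster.duration / bin_ms - 1e-12))
    counts = np.zeros(n_bins, dtype=np.int64)
    if raster.n_spikes:
        idx = np.ceil(raster.times / bin_ms - 1e-12).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return counts
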