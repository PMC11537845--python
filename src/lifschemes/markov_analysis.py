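"""Markov-operator analysis of the discretized membrane potential.

Observed only at the grid times where the piecewise-constant current
switches, the membrane potential is a Markov chain: given v, the next
value beta*v + alpha*I is uniform on [beta*v + alpha*i_min,
beta*v + alpha*i_max), so the free transition density is the constant
1/(alpha*(i_max - i_min)) on that interval and 0 outside.  The spiking
threshold theta modifies the kernel by removing all superthreshold mass
and re-inserting it as a point mass at the reset potential -- each unit
of re-inserted mass is one spike.

Discretizing the kernel on a voltage grid yields a row-stochastic matrix
M (rows indexed by the source bin).  Its left eigenvector at eigenvalue 1
is the stationary membrane-potential distribution; contracting the
per-bin spike probability against it gives the per-step spike
probability, and dividing by the step length the steady-state firing
rate.  The same machinery without the threshold recovers the free
stationary distribution, whose moments must (and do) match the
closed-form AR(1) results -- a built-in consistency check.

Conventions fixed here: rows of M are source-indexed, so distributions
propagate by left multiplication q <- q @ M.  Bins are half-open
[edge_d, edge_{d+1}); transported mass is integrated exactly over
destination bins from the source-bin midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .closed_form import FreeMoments
from .core_model import NeuronParameters, NoiseParameters, SchemeCoefficients

__all__ = [
    "VoltageGrid",
    "DiscretizedDistribution",
    "MarkovOperator",
    "StationaryResult",
    "free_kernel_density",
    "thresholded_kernel",
    "build_markov_matrix",
    "build_free_markov_matrix",
    "stationary_distribution",
    "firing_rate",
    "free_stationary_distribution",
    "tail_mass_excess",
    "gaussian_tail_excess",
    "default_free_grid",
    "default_thresholded_grid",
]


@dataclass(frozen=True)
class VoltageGrid:
    """Uniform voltage grid of half-open bins on [v_lo, v_hi), in mV."""

    v_lo: float
    v_hi: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.v_lo >= self.v_hi:
            raise ValueError(f"require v_lo < v_hi, got [{self.v_lo}, {self.v_hi}]")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def bin_width(self) -> float:
        return (self.v_hi - self.v_lo) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.v_lo, self.v_hi, self.n_bins + 1)

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def bin_of(self, v: float) -> int:
        """Index of the half-open bin containing v."""
        if not (self.v_lo <= v < self.v_hi):
            raise ValueError(f"{v} mV outside grid [{self.v_lo}, {self.v_hi})")
        return min(int((v - self.v_lo) / self.bin_width), self.n_bins - 1)


@dataclass(frozen=True)
class DiscretizedDistribution:
    """Probability mass per grid bin (dimensionless, sums to 1)."""

    grid: VoltageGrid
    mass: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.shape != (self.grid.n_bins,):
            raise ValueError(f"mass shape {m.shape} != ({self.grid.n_bins},)")
        if np.any(m < -1e-12):
            raise ValueError("negative probability mass")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass sums to {m.sum()}, expected 1")

    def mean(self) -> float:
        """Mean voltage under the midpoint rule, mV."""
        return float(self.mass @ self.grid.midpoints)

    def std(self) -> float:
        """Standard deviation under the midpoint rule, mV."""
        mids = self.grid.midpoints
        mu = self.mass @ mids
        return float(np.sqrt(self.mass @ (mids - mu) ** 2))

    def tail_mass(self, threshold: float) -> float:
        """P(v > threshold), counting partial bins as uniformly filled."""
        e = self.grid.edges
        frac = np.clip((e[1:] - threshold) / self.grid.bin_width, 0.0, 1.0)
        return float(self.mass @ frac)


@dataclass(frozen=True)
class MarkovOperator:
    """Row-stochastic transition matrix on a voltage grid.

    ``matrix[from, to]`` is the one-step probability of moving from bin
    ``from`` to bin ``to``; ``spike_prob[from]`` is the probability that
    the step from bin ``from`` crosses threshold (0 everywhere for a free
    operator).  Reset mass is already folded into the matrix.
    """

    grid: VoltageGrid
    matrix: np.ndarray
    spike_prob: np.ndarray

    def __post_init__(self) -> None:
        row_sums = self.matrix.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > 1e-9:
            raise ValueError(
                f"rows must be stochastic; worst |row sum - 1| = "
                f"{np.max(np.abs(row_sums - 1.0)):.3e}"
            )
        if np.any(self.matrix < -1e-15):
            raise ValueError("negative transition probability")
        if np.any((self.spike_prob < -1e-15) | (self.spike_prob > 1 + 1e-12)):
            raise ValueError("spike_prob outside [0, 1]")


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution, per-step spike probability, and rate (sp/s)."""

    distribution: DiscretizedDistribution
    rate: float
    per_step_spike_prob: float


def free_kernel_density(
    v_to: float, v_from: float, coeffs: SchemeCoefficients, noise: NoiseParameters
) -> float:
    """Free transition density p(v_to | v_from) in 1/mV.

    Uniform with height 1/(alpha*(i_max - i_min)) on the image interval
    [beta*v_from + alpha*i_min, beta*v_from + alpha*i_max); this height is
    what makes the density integrate to 1 over v_to for every v_from.
    """
    if noise.i_max == noise.i_min:
        raise ValueError(
            "degenerate kernel: i_max == i_min gives a deterministic map, not a density"
        )
    lo = coeffs.beta * v_from + coeffs.alpha * noise.i_min
    hi = coeffs.beta * v_from + coeffs.alpha * noise.i_max
    if lo <= v_to < hi:
        return 1.0 / (coeffs.alpha * (noise.i_max - noise.i_min))
    return 0.0


def thresholded_kernel(
    v_to: float,
    v_from: float,
    coeffs: SchemeCoefficients,
    noise: NoiseParameters,
    neuron: NeuronParameters,
) -> tuple[float, float]:
    """Thresholded kernel: (density at v_to, point mass at the reset potential).

    The density vanishes above theta; the removed mass, plus whatever free
    density already sat at the reset potential, reappears as a point mass
    there, so total outgoing mass per source stays exactly 1.
    """
    if v_from >= neuron.theta:
        raise ValueError(f"source potential {v_from} must lie below theta={neuron.theta}")
    lo = coeffs.beta * v_from + coeffs.alpha * noise.i_min
    hi = coeffs.beta * v_from + coeffs.alpha * noise.i_max
    super_mass = max(0.0, (hi - max(lo, neuron.theta))) / (hi - lo)
    density = 0.0 if v_to > neuron.theta else free_kernel_density(v_to, v_from, coeffs, noise)
    return density, super_mass


def _image_bounds(
    v_from: np.ndarray, coeffs: SchemeCoefficients, noise: NoiseParameters
) -> tuple[np.ndarray, np.ndarray]:
    lo = coeffs.beta * v_from + coeffs.alpha * noise.i_min
    hi = coeffs.beta * v_from + coeffs.alpha * noise.i_max
    return lo, hi


def _bin_overlap_matrix(
    grid: VoltageGrid, lo: np.ndarray, hi: np.ndarray, width: np.ndarray
) -> np.ndarray:
    """Mass of U over ``width`` restricted to [lo_s, hi_s), binned on the grid.

    ``width`` is the full image-interval width alpha*(i_max - i_min); it
    stays the normalizer even when [lo, hi) has been clipped at threshold.
    """
    e = grid.edges
    overlap = np.minimum(hi[:, None], e[None, 1:]) - np.maximum(lo[:, None], e[None, :-1])
    return np.clip(overlap, 0.0, None) / width[:, None]


def build_free_markov_matrix(
    grid: VoltageGrid, coeffs: SchemeCoefficients, noise: NoiseParameters
) -> MarkovOperator:
    """Discretize the free (threshold-less) kernel on ``grid``.

    The grid must contain the image of every source-bin midpoint;
    otherwise probability would leak and the rows could not be stochastic.
    """
    if noise.i_max == noise.i_min:
        raise ValueError("degenerate kernel: i_max == i_min; use the deterministic map")
    lo, hi = _image_bounds(grid.midpoints, coeffs, noise)
    if lo.min() < grid.v_lo - 1e-12 or hi.max() > grid.v_hi + 1e-12:
        raise ValueError(
            f"grid [{grid.v_lo}, {grid.v_hi}] does not cover the kernel image "
            f"[{lo.min():.4g}, {hi.max():.4g}]"
        )
    matrix = _bin_overlap_matrix(grid, lo, hi, hi - lo)
    return MarkovOperator(grid=grid, matrix=matrix, spike_prob=np.zeros(grid.n_bins))


def build_markov_matrix(
    grid: VoltageGrid,
    coeffs: SchemeCoefficients,
    noise: NoiseParameters,
    neuron: NeuronParameters,
) -> MarkovOperator:
    """Discretize the thresholded kernel: superthreshold mass -> reset bin.

    The grid must cover [v_reset, theta].  ``spike_prob[from]`` records the
    probability of crossing theta in one step from bin ``from``; that mass
    is added to the bin containing the reset potential so each row still
    sums to 1.
    """
    if noise.i_max == noise.i_min:
        raise ValueError("degenerate kernel: i_max == i_min; use the deterministic map")
    if grid.v_lo > neuron.v_reset + 1e-12 or grid.v_hi < neuron.theta - 1e-12:
        raise ValueError(
            f"grid [{grid.v_lo}, {grid.v_hi}] must cover "
            f"[{neuron.v_reset}, {neuron.theta}]"
        )
    lo, hi = _image_bounds(grid.midpoints, coeffs, noise)
    width = hi - lo
    spike_prob = np.clip(hi - np.maximum(lo, neuron.theta), 0.0, None) / width
    # subthreshold part: clip the image interval at theta before binning
    matrix = _bin_overlap_matrix(grid, lo, np.minimum(hi, neuron.theta), width)
    # mass that would land below theta but outside the grid would be a bug
    reset_bin = grid.bin_of(neuron.v_reset)
    matrix[:, reset_bin] += spike_prob
    row_sums = matrix.sum(axis=1)
    if np.max(np.abs(row_sums - 1.0)) > 1e-9:
        raise ValueError(
            "probability leaked outside the grid; extend v_lo "
            f"(worst row sum {row_sums.min():.12f})"
        )
    return MarkovOperator(grid=grid, matrix=matrix, spike_prob=spike_prob)


def stationary_distribution(
    op: MarkovOperator,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> DiscretizedDistribution:
    """Stationary distribution q with q = q @ M, by power iteration.

    Starts from the uniform vector and iterates until the L1 residual
    ||qM - q||_1 drops below ``tol`` (default 1e-12).  A direct
    eigensolve is deliberately not the default: power iteration is
    robust on large grids and its residual is an explicit certificate.
    """
    q = np.full(op.grid.n_bins, 1.0 / op.grid.n_bins)
    for _ in range(max_iter):
        q_next = q @ op.matrix
        q_next /= q_next.sum()
        residual = np.abs(q_next - q).sum()
        q = q_next
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} steps "
            f"(last L1 residual {residual:.3e})"
        )
    q = np.clip(q, 0.0, None)
    q /= q.sum()
    return DiscretizedDistribution(grid=op.grid, mass=q)


def firing_rate(
    op: MarkovOperator, q: DiscretizedDistribution, h: float
) -> StationaryResult:
    """Steady-state firing rate in spikes/s.

    The per-step spike probability is the stationary average of the
    per-bin threshold-crossing probability; dividing by the step length h
    (ms) and converting to seconds gives the rate.
    """
    per_step = float(q.mass @ op.spike_prob)
    return StationaryResult(
        distribution=q, rate=per_step / h * 1000.0, per_step_spike_prob=per_step
    )


def free_stationary_distribution(
    coeffs: SchemeCoefficients,
    noise: NoiseParameters,
    grid: VoltageGrid,
    tol: float = 1e-12,
) -> DiscretizedDistribution:
    """Stationary distribution of the free (threshold-less) chain on ``grid``."""
    op = build_free_markov_matrix(grid, coeffs, noise)
    return stationary_distribution(op, tol=tol)


def tail_mass_excess(
    dist_a: DiscretizedDistribution, dist_b: DiscretizedDistribution, theta: float
) -> float:
    """Percent excess tail mass of a over b above ``theta``.

    Returns 100*(P_a(v > theta)/P_b(v > theta) - 1).  With a = forward
    Euler and b = exact, this is the "how much more superthreshold mass"
    number that anticipates the firing-rate ordering.
    """
    tail_a = dist_a.tail_mass(theta)
    tail_b = dist_b.tail_mass(theta)
    if tail_b == 0.0:
        raise ZeroDivisionError(f"reference distribution has no mass above {theta} mV")
    return 100.0 * (tail_a / tail_b - 1.0)


def gaussian_tail_excess(moments_a: FreeMoments, moments_b: FreeMoments, theta: float) -> float:
    """Tail-mass excess under Gaussian approximations with the given moments.

    The stationary free distribution is a sum of many independent scaled
    uniforms and is close to (but not exactly) normal; this approximation
    quantifies how much of the tail ratio survives collapsing each
    distribution to its first two moments.
    """
    tail_a = stats.norm.sf(theta, loc=moments_a.mean_v, scale=moments_a.std_v)
    tail_b = stats.norm.sf(theta, loc=moments_b.mean_v, scale=moments_b.std_v)
    if tail_b == 0.0:
        raise ZeroDivisionError("reference Gaussian tail is zero")
    return 100.0 * (tail_a / tail_b - 1.0)


def default_thresholded_grid(
    neuron: NeuronParameters, bin_width: float = 0.01
) -> VoltageGrid:
    """Grid on the reachable set [v_reset, theta] of the thresholded chain."""
    n = round((neuron.theta - neuron.v_reset) / bin_width)
    return VoltageGrid(v_lo=neuron.v_reset, v_hi=neuron.theta, n_bins=n)


def default_free_grid(
    coeffs: SchemeCoefficients, noise: NoiseParameters, bin_width: float = 0.01
) -> VoltageGrid:
    """Grid covering the reachable set [lo*, hi*] of the free chain.

    The affine map contracts toward the fixed points of the extreme
    currents, so from v0 = 0 with i_min >= 0 all mass stays inside
    [alpha*i_min/(1-beta), alpha*i_max/(1-beta)] -- [0, 10] mV at the
    default parameters.
    """
    lo_star = min(0.0, coeffs.alpha * noise.i_min / (1.0 - coeffs.beta))
    hi_star = coeffs.alpha * noise.i_max / (1.0 - coeffs.beta)
    n = int(np.ceil((hi_star - lo_star) / bin_width))
    return VoltageGrid(v_lo=lo_star, v_hi=lo_star + n * bin_width, n_bins=n)
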