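# Methods

## Model

A leaky integrate-and-fire neuron with membrane time constant τ and
capacitance C, threshold θ, reset potential 0 and **no refractory
period**. The external drive is piecewise constant: a current amplitude
is drawn from the half-open uniform U[I_min, I_max) pA at every grid
time t_j = jh and held for h ms, so the mean drive is μ = (I_min+I_max)/2
and its variance σ² = (I_max−I_min)²/12. In the recurrent variant, K
neurons are coupled all-to-all by delta synapses: when neuron l spikes,
every neuron receives an instantaneous potential increment w_lk mV after
a delay d, with weights drawn once at setup from U[0, 1/K) mV.

Units are fixed as mV / ms / pA / pF throughout (ms/pF ≡ mV/pA, so the
recursion below is dimensionally closed).

Defaults, used everywhere unless overridden: τ = 10 ms, C = 1 pF,
h = 1 ms, I ~ U[0, 1) pA, θ = 6 mV, d = 1 ms, K = 1000. The first five
are pinned by the reference values they must reproduce (α ≈ 0.952,
β ≈ 0.905, ⟨v⟩ = 5 mV); θ and d are benchmark parameters taken from the
model this package analyses, and are validated a posteriori: with θ = 6 mV
the Markov analysis lands on the reference rates (9.93/10.92 sp/s) at
printed precision. K = 1000 is the package's default study scale for the
network; weights U[0, 1/K) keep the mean recurrent drive K·w̄·r = r/2
mV/s invariant in K, and a single K = 10,000 run confirms the rate is
K-independent to within sampling error.

## Discretized update

Because the input is constant over each step, the per-step map is exactly
affine, v_{j+1} = βv_j + αI_j. The exact propagator uses
α = (τ/C)(1−e^(−h/τ)), β = e^(−h/τ) and is error-free for this input
class at any h; forward Euler uses α = h/C, β = 1−h/τ and is accepted
only for h < τ (beyond that β ≤ 0 and the scheme leaves the physically
meaningful regime — the constructor refuses it). Threshold crossing is
detected as v ≥ θ: with continuous noise, exact equality has probability
zero, so ≥ is the measure-consistent reading of "reset when v = θ".
Spikes are stamped at the end of the step in which they occur.

Inverting the Euler formulas at given (α, β) — τ_eff = h/(1−β),
C_eff = h/α — identifies the model forward Euler actually solves; for the
exact coefficients at defaults this is τ ≈ 10.5 ms, C ≈ 1.05 pF.

## Free-potential moments

Without a threshold the recursion is an AR(1) process; iterating from
v₀ = 0 gives a geometric sum whose stationary limits are
⟨v⟩ = αμ/(1−β) and std ασ/√(1−β²). The variance denominator is computed
as (1−β)(1+β) to avoid cancellation at small h/τ. Both schemes share the
mean (5 mV at defaults); Euler's std (0.662 mV) exceeds the exact one
(0.645 mV) for every stable h, which is the mechanism behind its excess
firing.

## Markov analysis

Observed at the noise-switching times, the membrane potential is a
Markov chain. Given v, the next value is uniform on
[βv + αI_min, βv + αI_max), so the free transition density is the
constant 1/(α(I_max−I_min)) on that interval — the unique height that
normalizes it. The threshold modifies the kernel by zeroing the density
above θ and returning the removed mass as a point mass at the reset
potential; each unit of returned mass is one spike, so the stationary
firing rate is the stationary per-step spike probability divided by h
(×1000 for spikes/s).

Numerical choices:

* **Grids.** Thresholded chain on [0, θ] (the reachable set, since
  I ≥ 0 and reset = 0), free chain on [0, αI_max/(1−β)] ([0, 10] mV at
  defaults). Default bin width 0.01 mV — 600 and 1000 bins — matching the
  histogram resolution used for simulation comparisons. Grid-refinement
  tests show the rate moves < 0.1% on halving the bin width (converged
  values 9.923/10.917 sp/s at 0.001 mV bins).
* **Discretization.** Rows of M are source-indexed; distributions
  propagate as q ← qM. Transported mass is integrated exactly over
  destination bins from each source-bin midpoint (the kernel is piecewise
  constant, so only the source-midpoint rule, not the destination
  integral, is approximate). Superthreshold mass is added to the bin
  containing the reset potential, keeping every row stochastic to 1e−9
  (enforced, not assumed). Degenerate noise (I_min = I_max) is rejected:
  the kernel is then a deterministic map, not a density.
* **Stationary solve.** Power iteration from the uniform vector with L1
  residual tolerance 1e−12 and an iteration cap of 10⁶; the residual is
  an explicit convergence certificate. A dense left-eigenvector solve is
  the cross-check (tested to 1e−8 L∞ agreement on a 30-bin instance), not
  the default, for robustness on large grids.
* **Tail excess.** P(v > θ) is computed from the free stationary
  distributions with partial-bin interpolation. The exact-distribution
  computation gives 8.37% Euler-over-exact excess at defaults; collapsing
  each distribution to its first two moments and using normal tails gives
  8.15%. Both are exposed (`tail_mass_excess`, `gaussian_tail_excess`);
  the reference figure of ≈8% evidently corresponds to the Gaussian
  reading, and the two agree within half a percentage point.

Two conventions in the source material are dimensionally inconsistent as
printed and are corrected here, loudly rather than silently: the free
kernel's normalizing prefactor must be 1/(α(I_max−I_min)) (a τ in place
of α does not integrate to 1), and the rate must be the per-step spike
probability *divided* by h (multiplying by h has the wrong units). Both
corrections are confirmed by reproducing the reference rates.

## Simulation

Single neurons and networks are simulated with the same per-step map.
Free (threshold-less) traces use `scipy.signal.lfilter`, which applies
the AR(1) recursion exactly. Within each network step the order is:
(1) linear update with the external current, (2) delivery of synaptic
deltas from spikes emitted d earlier, (3) threshold test and reset —
delta synapses act instantaneously at delivery and may trigger a
same-step spike, which is why delivery precedes the test. Self-connections
are included by default (the coupling sum has no self-exclusion; at mean
weight 1/(2K) mV their effect is negligible) and can be disabled. Initial
condition is v₀ = 0 for all neurons; rate windows start at 100 ms, an
order of magnitude longer than the 10-ms relaxation time, to skip the
transient.

RNG streams: a root `SeedSequence` spawns one child for the weights and
one per neuron for its currents. This makes a zero-weight network
bitwise identical to the corresponding independent single-neuron runs
(tested), and makes every result reproducible from (parameters, seed)
alone with numpy's PCG64.

Study sizes: Monte-Carlo rate checks use 100 neurons × 60 s = 6000 s of
simulated time per scheme (SE ≈ 0.03 sp/s); histogram comparisons use
1000 s of stationary samples at 0.01 mV bins, for which the sampling
L1 distance to the Markov distribution is ≈0.018; the connected network
is averaged over 20 seeds of 295 ms at K = 1000.

## What the generator emulates — and what it does not

The synthetic drive reproduces the benchmark's study conditions exactly:
uniform piecewise-constant currents, uniform static weights, fixed
delay. It does not model the benchmark's plasticity rule
(potentiation-only STDP), refractoriness, conductance or exponential-PSC
synapses, or off-grid spike timing. Consequently the static-weight
connected network settles at 11.04 ± 0.02 sp/s in the 100–295 ms window,
below the ≈11.6 sp/s reported for the full benchmark with plasticity
active; the unconnected rate (9.9 sp/s) and all single-neuron quantities
are unaffected. Passing tests therefore validate the scheme analysis and
the static-weight network, not plasticity dynamics.

## Known limitations

* The Markov operator assumes uniform noise; other input families would
  need their own kernel.
* The source-midpoint rule makes the matrix first-order accurate in bin
  width; at the 0.01 mV default this contributes < 0.02% to the rate, but
  very coarse grids (kernel support spanning < 10 bins) should not be
  trusted.
* Dense matrices: memory grows as (θ/Δv)², fine below ~10⁴ bins, and the
  network weight matrix grows as K² (guarded by a configurable cap).
* All dynamics are observed at the noise-switching grid; sub-step
  threshold crossings between grid points are not modelled (consistent
  with the discretized model definition, but a difference from
  continuous-time first-passage treatments).
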