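"""Markov-operator discretization, stationary distributions, and firing rates."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from lifschemes import (
    NeuronParameters,
    NoiseParameters,
    VoltageGrid,
    build_free_markov_matrix,
    build_markov_matrix,
    default_free_grid,
    default_thresholded_grid,
    firing_rate,
    free_kernel_density,
    free_moments,
    free_stationary_distribution,
    gaussian_tail_excess,
    stationary_distribution,
    tail_mass_excess,
    thresholded_kernel,
)


def _stationary(neuron, noise, coeffs, bin_width=0.01):
    grid = default_thresholded_grid(neuron, bin_width)
    op = build_markov_matrix(grid, coeffs, noise, neuron)
    q = stationary_distribution(op)
    return op, q


class TestFreeKernel:
    def test_in_support_height(self, exact, noise):
        """Uniform image of U[0,1) pA: height 1/(alpha*(i_max-i_min)) ~ 1.0508/mV."""
        v_from = 3.0
        mid = exact.beta * v_from + exact.alpha * 0.5
        assert free_kernel_density(mid, v_from, exact, noise) == pytest.approx(
            1.0 / exact.alpha, rel=1e-12
        )

    def test_zero_outside_support(self, exact, noise):
        v_from = 3.0
        lo = exact.beta * v_from + exact.alpha * noise.i_min
        hi = exact.beta * v_from + exact.alpha * noise.i_max
        assert free_kernel_density(lo - 1e-9, v_from, exact, noise) == 0.0
        assert free_kernel_density(hi, v_from, exact, noise) == 0.0

    @settings(derandomize=True, max_examples=15)
    @given(v_from=st.floats(-2.0, 8.0))
    def test_density_integrates_to_one(self, v_from, exact, noise):
        lo = exact.beta * v_from + exact.alpha * noise.i_min
        hi = exact.beta * v_from + exact.alpha * noise.i_max
        v_to = np.linspace(lo - 0.1, hi + 0.1, 4001)
        dens = [free_kernel_density(v, v_from, exact, noise) for v in v_to]
        assert np.trapezoid(dens, v_to) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_noise_rejected(self, exact):
        with pytest.raises(ValueError, match="degenerate"):
            free_kernel_density(1.0, 1.0, exact, NoiseParameters(i_min=1.0, i_max=1.0))


class TestThresholdedKernel:
    @settings(derandomize=True, max_examples=30)
    @given(v_from=st.floats(0.0, 5.999))
    def test_total_outgoing_mass_is_one(self, v_from, exact, noise, neuron):
        """Subthreshold density plus reset point mass always sums to 1."""
        _, reset_mass = thresholded_kernel(0.0, v_from, exact, noise, neuron)
        lo = exact.beta * v_from + exact.alpha * noise.i_min
        hi = exact.beta * v_from + exact.alpha * noise.i_max
        sub = (min(hi, neuron.theta) - min(lo, neuron.theta)) / (hi - lo)
        assert sub + reset_mass == pytest.approx(1.0, abs=1e-12)

    def test_vanishes_above_threshold(self, exact, noise, neuron):
        dens, _ = thresholded_kernel(6.5, 5.9, exact, noise, neuron)
        assert dens == 0.0

    def test_no_crossing_equals_free_kernel(self, exact, noise, neuron):
        """Sources that cannot reach theta keep the free kernel and zero reset mass."""
        v_from = 1.0  # image tops out near 1.86 mV << 6 mV
        dens, reset_mass = thresholded_kernel(1.2, v_from, exact, noise, neuron)
        assert reset_mass == 0.0
        assert dens == free_kernel_density(1.2, v_from, exact, noise)


class TestOperatorBuild:
    def test_rows_stochastic(self, exact, noise, neuron):
        op, _ = _stationary(neuron, noise, exact, bin_width=0.02)
        assert np.max(np.abs(op.matrix.sum(axis=1) - 1.0)) < 1e-9
        assert op.matrix.min() >= 0.0
        assert np.all((op.spike_prob >= 0) & (op.spike_prob <= 1))

    def test_degenerate_noise_rejected(self, exact, neuron):
        grid = default_thresholded_grid(neuron, 0.05)
        with pytest.raises(ValueError, match="degenerate"):
            build_markov_matrix(grid, exact, NoiseParameters(i_min=1.0, i_max=1.0), neuron)

    def test_coverage_errors(self, exact, noise, neuron):
        with pytest.raises(ValueError, match="cover"):
            build_markov_matrix(VoltageGrid(0.0, 4.0, 100), exact, noise, neuron)
        with pytest.raises(ValueError, match="cover"):
            build_free_markov_matrix(VoltageGrid(0.0, 4.0, 100), exact, noise)

    def test_grid_refinement_converges(self, exact, noise, neuron):
        """Halving the bin width moves the stationary rate by < 0.5%."""
        rates = []
        for bw in (0.01, 0.005):
            op, q = _stationary(neuron, noise, exact, bw)
            rates.append(firing_rate(op, q, noise.h).rate)
        assert abs(rates[1] - rates[0]) / rates[0] < 0.005


class TestStationary:
    def test_fixed_point_and_normalization(self, exact, noise, neuron):
        op, q = _stationary(neuron, noise, exact, bin_width=0.02)
        assert q.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(q.mass @ op.matrix - q.mass).sum() < 1e-10
        assert q.mass.min() >= 0.0

    def test_power_iteration_matches_eigensolver(self, exact, noise, neuron):
        """On a coarse grid the power-iteration fixed point equals the
        eigenvalue-1 left eigenvector from a direct dense eigensolve."""
        grid = default_thresholded_grid(neuron, 0.2)  # 30 bins
        op = build_markov_matrix(grid, exact, noise, neuron)
        q = stationary_distribution(op)
        w, vl = scipy.linalg.eig(op.matrix, left=True, right=False)
        idx = np.argmin(np.abs(w - 1.0))
        assert w[idx].real == pytest.approx(1.0, abs=1e-12)
        ref = np.abs(vl[:, idx].real)
        ref /= ref.sum()
        assert np.max(np.abs(ref - q.mass)) < 1e-8

    def test_schemes_give_distinct_distributions(self, exact, euler, noise, neuron):
        _, q_ex = _stationary(neuron, noise, exact, 0.02)
        _, q_eu = _stationary(neuron, noise, euler, 0.02)
        diff = q_eu.mass - q_ex.mass
        assert np.abs(diff).sum() > 0.01  # visibly distinct
        assert diff.sum() == pytest.approx(0.0, abs=1e-9)  # both normalized


class TestFiringRate:
    def test_printed_rates(self, exact, euler, noise, neuron):
        """600-bin Markov analysis reproduces 9.93 / 10.92 spikes/s."""
        op, q = _stationary(neuron, noise, exact)
        assert firing_rate(op, q, noise.h).rate == pytest.approx(9.93, abs=0.01)
        op, q = _stationary(neuron, noise, euler)
        assert firing_rate(op, q, noise.h).rate == pytest.approx(10.92, abs=0.01)

    def test_rate_identity(self, exact, noise, neuron):
        op, q = _stationary(neuron, noise, exact, 0.02)
        res = firing_rate(op, q, noise.h)
        assert res.rate == pytest.approx(res.per_step_spike_prob / noise.h * 1000.0)

    def test_unreachable_threshold_gives_zero_rate(self, exact, noise):
        """theta above the maximal reachable potential alpha*i_max/(1-beta)."""
        tall = NeuronParameters(theta=12.0)
        grid = default_thresholded_grid(tall, 0.02)
        op = build_markov_matrix(grid, exact, noise, tall)
        q = stationary_distribution(op)
        assert firing_rate(op, q, noise.h).rate == 0.0

    def test_rate_decreases_with_threshold(self, exact, euler, noise):
        for coeffs in (exact, euler):
            rates = []
            for theta in np.linspace(5.5, 9.0, 8):
                neuron = NeuronParameters(theta=theta)
                grid = default_thresholded_grid(neuron, 0.02)
                op = build_markov_matrix(grid, exact if coeffs is exact else euler, noise, neuron)
                q = stationary_distribution(op)
                rates.append(firing_rate(op, q, noise.h).rate)
            assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_euler_exceeds_exact_and_gap_shrinks_with_h(self, noise):
        """The scheme bias is positive and vanishes as h -> 0."""
        from lifschemes import euler_coefficients, exact_coefficients

        neuron = NeuronParameters()
        gaps = []
        for h in (1.0, 0.5):
            nz = NoiseParameters(h=h)
            r = {}
            for maker in (exact_coefficients, euler_coefficients):
                c = maker(neuron, h)
                grid = default_thresholded_grid(neuron, 0.01)
                op = build_markov_matrix(grid, c, nz, neuron)
                q = stationary_distribution(op)
                r[c.scheme_label] = firing_rate(op, q, h).rate
            gaps.append(r["forward_euler"] - r["exact"])
        assert gaps[0] > gaps[1] > 0


class TestFreeDistribution:
    def test_moments_match_closed_form(self, exact, euler, noise):
        for coeffs in (exact, euler):
            grid = default_free_grid(coeffs, noise, 0.01)
            q = free_stationary_distribution(coeffs, noise, grid)
            m = free_moments(coeffs, noise)
            assert q.mean() == pytest.approx(m.mean_v, rel=2e-3)
            assert q.std() == pytest.approx(m.std_v, rel=2e-3)

    def test_support_is_reachable_set(self, exact, noise):
        """At defaults all free stationary mass lies inside [0, 10] mV."""
        grid = default_free_grid(exact, noise, 0.01)
        assert grid.v_lo == 0.0
        assert grid.v_hi == pytest.approx(10.0, abs=0.02)
        q = free_stationary_distribution(exact, noise, grid)
        assert q.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tail_excess_printed_value(self, exact, euler, noise, neuron):
        grid = VoltageGrid(0.0, 10.0, 1000)
        q_ex = free_stationary_distribution(exact, noise, grid)
        q_eu = free_stationary_distribution(euler, noise, grid)
        excess = tail_mass_excess(q_eu, q_ex, neuron.theta)
        assert excess == pytest.approx(8.1, abs=0.5)

    def test_tail_excess_of_identical_distributions_is_zero(self, exact, noise, neuron):
        grid = default_free_grid(exact, noise, 0.02)
        q = free_stationary_distribution(exact, noise, grid)
        assert tail_mass_excess(q, q, neuron.theta) == 0.0

    def test_gaussian_cross_check(self, exact, euler, noise, neuron):
        """Normal-tail approximation agrees with the exact computation to 0.5 pp."""
        grid = VoltageGrid(0.0, 10.0, 1000)
        q_ex = free_stationary_distribution(exact, noise, grid)
        q_eu = free_stationary_distribution(euler, noise, grid)
        exact_excess = tail_mass_excess(q_eu, q_ex, neuron.theta)
        gauss = gaussian_tail_excess(
            free_moments(euler, noise), free_moments(exact, noise), neuron.theta
        )
        assert abs(gauss - exact_excess) < 0.5
        # independent oracle for the Gaussian branch itself
        from scipy.stats import norm

        m_eu, m_ex = free_moments(euler, noise), free_moments(exact, noise)
        ref = 100.0 * (
            norm.sf(6.0, m_eu.mean_v, m_eu.std_v) / norm.sf(6.0, m_ex.mean_v, m_ex.std_v) - 1.0
        )
        assert gauss == pytest.approx(ref, rel=1e-12)
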