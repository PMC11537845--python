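"""Which model does forward Euler actually solve?

Takes the exact-propagator coefficients of the default model and inverts
the forward-Euler coefficient formulas: the resulting (tau, C) is the
model a forward-Euler integrator would have to be given to reproduce the
exact update -- equivalently, Euler applied to the nominal model silently
simulates a neuron with these shifted parameters.
"""

from lifschemes import (
    NeuronParameters,
    NoiseParameters,
    effective_euler_parameters,
    exact_coefficients,
)

neuron = NeuronParameters()
noise = NoiseParameters()
exact = exact_coefficients(neuron, noise.h)
eff = effective_euler_parameters(exact, noise.h)

print(f"nominal model:    tau = {neuron.tau:.1f} ms, C = {neuron.capacitance:.2f} pF")
print(f"effective (Euler) tau = {eff.tau_eff:.3f} ms, C = {eff.c_eff:.4f} pF")
# A ~5% shift in both parameters: integration-scheme choice is a model
# change, not just a numerical error.
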