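"""Determine k_on, k_off and K_i from one simulated titration experiment.

Simulates a pre-equilibrium titration of a potent bicyclic-peptide
protease inhibitor (k_on = 3.5e6 M^-1 s^-1, k_off = 1.92e-4 s^-1, so
K_i = 55 pM) at 1 nM enzyme: 11 twofold dilutions from 8 nM plus a
no-inhibitor control, read after 5, 15, 45 and 120 minutes of incubation,
with 2% rate noise.  A global fit of the integrated binding law with
shared k_on/k_off then recovers both rate constants — and hence the
residence time 1/k_off and K_i = k_off/k_on — from this single dataset.
"""

from preqfit import (
    AssayConditions,
    BindingParameters,
    SimulationSpec,
    fit_preequilibrium,
    simulate_titration,
)

truth = BindingParameters(k_on=3.5e6, k_off=1.92e-4)
conditions = AssayConditions(E_0=1e-9, timepoints=(300.0, 900.0, 2700.0, 7200.0))
spec = SimulationSpec(
    params=truth, conditions=conditions, top_I0=8e-9, seed=42, noise_sd=0.02
)

dataset = simulate_titration(spec)
result = fit_preequilibrium(dataset)

print(f"simulated wells: {result.n_points}  (4 timepoints x 12 concentrations)")
print(f"true   k_on = {truth.k_on:.3g} M^-1 s^-1   k_off = {truth.k_off:.3g} s^-1")
print(
    f"fitted k_on = {result.params.k_on:.3g} M^-1 s^-1 "
    f"(CV {result.cv_percent['k_on']:.1f}%)"
)
print(
    f"fitted k_off = {result.params.k_off:.3g} s^-1 "
    f"(CV {result.cv_percent['k_off']:.1f}%)"
)
print(f"K_i = k_off/k_on = {result.K_i / 1e-9:.3f} nM (true {truth.K_i / 1e-9:.3f} nM)")
print(f"residence time 1/k_off = {1 / result.params.k_off / 60:.0f} min")
# The CVs are the asymptotic standard errors of the global fit expressed as
# a percentage of the estimate; with 2% rate noise they land in the range
# reported for replicate plate experiments (roughly 15-20%).
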