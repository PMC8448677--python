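# Methods

## Model

The package treats reversible 1:1 enzyme–inhibitor binding,
E + I ⇌ EI, written in total concentrations E₀ and I₀ (no free≈total
simplification, so the model remains valid for tight binders with
I₀ ~ E₀). Occupancy starts at zero when enzyme and inhibitor are mixed and
relaxes toward the equilibrium value at rate b:

    d[EI]/dt = k_on (E₀−[EI])(I₀−[EI]) − k_off [EI]

    [EI]_t = ( a(1−c) − b(1+c) ) / ( 2 k_on (1−c) ),
    a = k_on(E₀+I₀)+k_off,  b = √(a²−4k_on²E₀I₀),  c = ((a−b)/(a+b)) e^(−bt)

Assumptions: one binding step (no induced fit), inactive complex, substrate
addition ends the binding incubation (the readout is fast relative to
binding), and negligible substrate depletion during the readout window —
the last enforced upstream by the 10%-hydrolysis guard rather than
modelled. Residual activity is proportional to free enzyme,
vᵢ = v₀(E₀−[EI]_t)/E₀. At t→∞ the expression collapses to the Morrison
tight-binding curve with K_i,app = k_off/k_on. Under competitive
inhibition, apparent constants measured at substrate concentration S relate
to true ones by K_i,app = K_i(1+S/K_m), k_on,app = k_on/(1+S/K_m),
k_off,app = k_off; the package defaults to reporting apparent values (i.e.
treats S/K_m as 0, the S ≪ K_m regime) and applies the conversion only when
both S and K_m are supplied.

## Numerics

All computation is SI (mol/L, s); only report writers convert to nM.

The textbook form of [EI]_t is 0/0 at t = 0 and ill-conditioned where
b → 0. Instead of branch-switching on series expansions we evaluate the
algebraically identical form

    [EI]_t = 2 k_on E₀ I₀ u / ( a u + b (2−u) ),   u = 1 − e^(−bt) (expm1),

which is exact at t = 0 (u = 0), cannot overflow (the exponent is never
positive), and tends smoothly to the b→0 limit a²t/(2k_on(2+at)); only at
b = 0 exactly (k_off = 0 and E₀ = I₀) is that limit substituted
explicitly. The radicand of b is expanded as
k_on²(E₀−I₀)² + k_off² + 2k_off·k_on(E₀+I₀), a sum of nonnegative terms,
eliminating the catastrophic cancellation of a² − 4k_on²E₀I₀ near
stoichiometric equivalence with slow dissociation; no clamping is needed,
though the equilibrium quadratic keeps a clamp-and-warn guard. The
equilibrium root uses the co-root form 2E₀I₀/(s+√(s²−4E₀I₀)) for the same
reason. Results are clipped to [0, min(E₀, I₀)] against last-bit round-off.
A brute-force reference (`ei_ode_oracle`, stiff Radau integration of the
ODE at rtol 1e-10) validates the closed form in the tests; a 100-point
random sweep over E₀, I₀ ∈ [1e-11, 1e-7] M, k_on ∈ [1e4, 1e8] M⁻¹s⁻¹,
k_off ∈ [1e-6, 1e-1] s⁻¹, t ∈ [1, 1e5] s agrees to well under 1e-6
relative (scaled by min(E₀, I₀)).

## Fitting

The global objective is the unweighted sum of squared rate residuals over
every (timepoint, concentration) record — equal weighting, the only mode.
k_on and k_off are optimized as log10 values (positivity is structural and
the scales span decades), bounded to [1e2, 1e10] M⁻¹s⁻¹ and
[1e-8, 1e2] s⁻¹; v₀ is shared (default) or per-timepoint, started at the
mean of the no-inhibitor control rates it governs; E₀ is fixed at its known
value by default or estimated as one shared parameter within ±2 decades.
Minimization uses bounded trust-region least squares (lmfit/SciPy,
xtol = ftol = gtol = 1e-12) from a 4×4 log-spaced multistart grid
(k_on ∈ {1e4…1e7}, k_off ∈ {1e-5…1e-2}): families of nearly equilibrated
curves make the objective multimodal along the k_off/k_on ridge. Best RSS
wins; ties (ΔRSS < 1e-12·RSS) break toward smaller k_off. Standard errors
come from the Jacobian at the optimum (asymptotic, no bootstrap — reported
CV% = 100·SE/estimate); SE of K_i uses the delta method on
log10 k_off − log10 k_on including their covariance.

Identifiability: when every well is effectively equilibrated, the data
determine only the ratio k_off/k_on. The fit flags "ratio-only" when
|corr(log10 k_on, log10 k_off)| > 0.999 or when the slowest-relaxing well
has b·t ≥ 10 at the fitted constants (occupancy within e⁻¹⁰ of
equilibrium); singular covariances additionally flag "no-covariance", and
estimates within 1e-6 decades of a bound flag "bound-hit". The equilibrium
(Morrison) fit of a single curve returns a "no-inhibition" diagnostic
instead of an estimate when the rate drop across the titration is below
0.1% of v₀ — K_i,app is unbounded above on such data.

The equilibration-bias report chains the two fitting routes: simulate a
noiseless pre-equilibrium curve at incubation time t, fit it with the
equilibrium model, and compare the fitted K_i,app against k_off/k_on. Its
default concentration grid is an 11-point twofold dilution from 8·E₀ plus
the control; the reference comparison in the tests uses 16 nM top at
E₀ = 2 nM. The fitted bias depends mildly on the grid, which is why the
grid is part of the report's provenance.

## Rate extraction

Initial rates are ordinary least-squares slopes of the fluorescence trace
over a window (default: the first 60 s, within the 30–60 s range typical
for keeping traces linear). Two guards mark a well for exclusion rather
than silently dropping it: windowed r² < 0.98 (the package's own linearity
bar; a constant trace is treated as an exact zero-slope fit), and more
than 10% of the substrate hydrolyzed over the trace, computed as
Δsignal/(signal_per_product·[S]) when the calibration factor is supplied
and reported "unknown" otherwise (the boundary value 0.10 passes). An
optional no-enzyme blank trace is subtracted pointwise when given.

## Simulator

The generator emulates the plate assay's structure: a serial dilution
(twofold by default, 11 points bracketing E₀) plus a no-inhibitor control,
one enzyme concentration in the 0.25–2 nM range, several incubation
timepoints (default {300, 900, 2700, 7200} s, spanning pre-equilibrium
through near-equilibrium for nanomolar binders), one well per point, and
additive Gaussian noise on initial rates with SD equal to 2% of v₀ by
default — the simplest noise model consistent with the equal-weighted fit,
chosen because replicate plate experiments report parameter-level CVs of
roughly 15–20% rather than a rate-level noise law. Seeds are mandatory.
What it does not emulate: substrate-depletion curvature, inner-filter
effects, enzyme inactivation over long incubations, pipetting error
correlated across a dilution series, or plate-position effects — so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to those real-world artifacts. Progress traces
are simulated as exactly linear signals plus point noise, which is what
the rate extractor assumes; they exercise the plumbing, not curvature QC.

## Problem sizes

The test suite and acceptance script use the dataset geometry above
(12 concentrations × 3–4 timepoints, ~36–48 wells per fit); the stochastic
recovery check runs 100 seeded replicates at 2% noise and the
closed-form/ODE equivalence sweep uses 100 random parameter draws.

## Known limitations

One-step binding only (no induced-fit/two-step discrimination); only the
competitive apparent↔true correction is provided; fits model initial rates,
not full progress curves; asymptotic standard errors can understate
uncertainty near identifiability boundaries — consult the diagnostics
flags before trusting them.
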