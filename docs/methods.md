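# Methods

## Model

The state is (P, N): proliferating and quiescent (G0) hematopoietic stem
cells, in cells per 10,000 peripheral blood leukocytes; time is in days.
Quiescent cells re-enter the cycle at rate β(N) = β₀θⁿ/(θⁿ+Nⁿ) per day;
re-entrants complete one cycle of fixed duration τ and return as two
daughters attenuated by in-cycle apoptosis, the term
2e^(−γτ)β(N_τ)N_τ with N_τ = N(t−τ). Quiescent cells are additionally
lost to the periphery at rate δ. Two treatment terms transfer cells
between the pools without creating or destroying any:
β_HIA(P) = β₀,HIA θ₁^m/(θ₁^m+P^m) · g_HIA(t) (pro-mitotic, strongest at
low P) and β_C(P) = β₀,C P^w/(θ₂^w+P^w) · g_C(t) (anti-mitotic,
strongest at high P). Their decay clocks run on time since the
respective administration: g_HIA is 1 up to τ₁ then decays at rate s₁;
g_C is 1 up to τ₂, decays at s₂ on (τ₂, τ₃], then freezes at the
residual e^(−s₂(τ₃−τ₂)), representing the tail effect of a single dose.

δ appears in dN/dt as a loss term, −δN. That sign is forced jointly by
δ's meaning (loss to the periphery) and by the closed-form equilibrium,
which only balances as a loss; the implementation offers no toggle.

Assumptions inherited from this model family: fixed oxygen
concentration; no pharmacokinetic absorption/clearance compartments for
either drug (the g-factors are pure effect-decay envelopes); a single
constant delay (no distributed cycle durations); a single administration
of each agent (no multi-cycle protocols).

## Parameters

Defaults are the baseline calibration; all rates per day, populations in
cells/10,000 leukocytes.

| symbol | field | default | meaning |
|---|---|---|---|
| β₀ | `beta0` | 1.4 (4 in `with_cta`) | maximal G0→S transit rate |
| θ | `theta` | 60 | half-activation N for β(N) |
| n | `n` | 2.7 (2 in `with_cta`) | re-entry Hill sensitivity |
| δ | `delta` | 0.09 | quiescent loss to periphery |
| γ | `gamma` | 0.15 | in-cycle apoptosis rate |
| τ | `tau` | 2.22 d | proliferation-cycle duration |
| β₀,HIA | `beta0_HIA` | 0.08 | maximal HIA transition rate |
| θ₁, m | `theta1`, `m` | 100, 0.1 | HIA Hill half-activation, sensitivity |
| β₀,C | `beta0_C` | 0.206 | maximal CTA transition rate |
| θ₂, w | `theta2`, `w` | 100, 1 | CTA Hill half-activation, sensitivity |
| s₁, s₂ | `s1`, `s2` | 0.2 | effect decay rates |
| τ₁, τ₂ | `tau1`, `tau2` | 5 d | decay-onset times (HIA, CTA) |
| τ₃ | `tau3` | 18 d | CTA decay freeze time |

τ₁, τ₂, τ₃ are calibrated defaults of this package (no published values
exist for them): τ₂ = 5 d places the chemotherapy nadir about five days
after administration and τ₃ = 18 d sets the residual
e^(−0.2·13) ≈ 0.074, which puts the post-chemotherapy plateau near 80
cells; τ₁ mirrors τ₂. They are ordinary parameters, overridable in any
config or preset.

The `with_cta` preset raises β₀ to 4 and lowers n to 2 so the untreated
plateau of P is 100 — the elevated count typical of patients entering
chemotherapy — and starts from P₀ = 100, N₀ = 70. HIA dose-sweep levels
are 0.04 / 0.08 / 0.16 per day (low / moderate / high): calibrated here
so that, against chemotherapy at the default dose, the low dose
under-rescues the nadir, the moderate (default) dose lands it at the
healthy control plateau ≈ 45, and the high dose overshoots it.

## Numerical integration

Method of steps: with a single constant delay, every window of length
≤ τ is an ordinary IVP whose delayed lookup lies in already-computed
history. Windows are integrated with scipy's adaptive RK45
(rtol = atol = 1e−8, max step 0.1 d) and its quartic dense output is
retained, serving both as the delayed lookup of later windows and as the
public dense-evaluation interface of the returned trajectory.

Discontinuity handling: constant history generically leaves a
derivative jump at t = 0, and each treatment contributes jumps or kinks
at its onset and at onset + τ₁/τ₂/τ₃. Every such point gains one order
of smoothness per delay generation, so its images at +kτ are tracked for
3 generations and no integration window straddles any of them; deeper
images are below the integration tolerances. Defaults were chosen so the
reported metrics are tolerance-independent at their printed precision;
the suite verifies self-convergence (10× tighter tolerances move a 60-d
endpoint by < 1e−4 relative) and agreement with R deSolve's `dede` to
1e−4 on the control run.

Degenerate inputs: the model preserves positivity analytically, but
floating-point undershoot near 0 would poison fractional-power Hills, so
states in [−1e−9, 0) are clamped to 0 inside rate evaluations only,
while anything below −1e−9 aborts with the failure time. Hill functions
are evaluated in log space from whichever side keeps the ratio ≤ 1, so
neither deep saturation nor depletion loses precision; the exact limits
at zero population are returned directly. τ = 0 is accepted by the
generic solver (the lag collapses onto the present state), which the
suite uses to check delay handling against a plain ODE integration.

## Protocols

Every scenario burns in the untreated system from constant history
(P₀, N₀) until the trailing 50-day window varies by less than 1e−6
relative (cap 1000 d; the presets settle near 145–151 d), switches the
scenario's treatments on at the detected settling time, and continues
for 300 days — enough for both decay clocks to run out and the final
plateau to settle. The nadir is the global minimum of the densely
evaluated P after onset (grid scan plus bounded local refinement);
plateaus are trailing 50-day means. There is no randomness anywhere, so
identical configurations produce bit-identical outputs (trajectory CSVs
are written with 17 significant digits for exact round-trip).

## Equilibria

Writing E = e^(−γτ) and D = δ + b_HIA − b_C for constant treatment rates,
the quiescent equation decouples: β(N*) = D/(2E−1), invertible in closed
form, and P* follows linearly. The positive state exists iff
0 < γτ < ln[2β₀/(D+β₀)]; note a positive b_C *widens* the admissible γτ
range. Two equilibrium modes are deliberately exposed, because the
printed algebra of this model family uses bare constants β₀,HIA, β₀,C
while the simulated dynamics use Hill-weighted, decaying rates:
`constants` mode reproduces the algebra at caller-supplied rates;
`late_time_limits` mode solves the coupled system with g_HIA → 0 and
g_C at its frozen residual, which is what a simulation actually
plateaus at after one administration. Which one the original authors
intended is not asserted; both are tested. The numeric solver brackets
the monotone scalar N-equation (Brent) and polishes with damped Newton
using the analytic Jacobian; in the late-time mode a fixed-point loop
over the CTA Hill seeds Newton if the initial guess stalls. Converged
roots satisfy both residuals below 1e−10. With b_C large the algebra can
produce P* ≤ 0 while N* > 0; the closed form reports the root as the
equations give it, and the randomized cross-check test covers that
regime.

## Stability

At equilibrium the N-perturbation obeys n′ = −A·n − B·n(t−τ) with
F = θⁿ(θⁿ+(1−n)N*ⁿ)/(θⁿ+N*ⁿ)² (so β₀F is d[β(N)N]/dN at N*),
A = δ + β₀F + b_HIA, B = −2β₀e^(−γτ)F − b_C. The published form of the
stability inequality for this model is typographically damaged; it is
implemented as the classical Hayes criterion for
λ + A + B e^(−λτ) = 0 — stable iff A + B > 0 and either |B| ≤ A or
τ√(B²−A²) < arccos(−A/B) — which is the unique standard result matching
the surviving fragments. The arccos-domain restriction (|A/B| ≤ 1) is
reported as a separate flag rather than silently resolved. As an
independent arbiter, the rightmost characteristic root is computed
exactly: substituting z = (λ+A)τ gives z·e^z = −Bτe^(Aτ), so the roots
are λ_k = −A + W_k(−Bτe^(Aτ))/τ over Lambert-W branches; real parts
decrease with |k|, so scanning branches |k| ≤ 8 with Newton polish
(residual < 1e−10) yields the rightmost root. This replaces a
winding-count search: for a scalar characteristic function the W-branch
enumeration is exact and cannot miss roots. The suite checks
criterion-vs-root agreement over a (B, τ) grid (excluding a 1e−3 band at
the boundary), that the root is purely imaginary on the boundary curve
itself, and that simulated perturbations decay or grow as the verdict
says (τ = 3.4 d gives an existing but unstable equilibrium used for the
growth case).

## What the tests do and do not show

All quantitative checks run on the two shipped presets and parameter
draws around them; the model is a deliberately coarse description of
real hematopoiesis. Passing tests demonstrate internal consistency
(integrator ↔ algebra ↔ stability theory agree to tight tolerances) and
reproduction of this model family's published behaviors — they do not
validate the model against patient data, which enters only through the
calibrated plateau levels (45–150 CD34+ cells per 10,000 leukocytes).
Known limitations: single dose per agent (no multi-cycle chemotherapy),
no drug pharmacokinetics, fixed oxygen tension, one constant delay, and
figure-level curve shapes from interactive DDE sessions are reproduced
only at the level of their quantitative claims (settling values, nadirs,
timing), not pixel-for-pixel.

One deliberate metric choice: "slower effect decay gives slower
recovery" is tested as a later nadir, pointwise-lower P throughout
recovery, and a lower final plateau — not as a longer time to reach a
fixed fraction of the run's own plateau, because halving s₁, s₂ also
lowers that plateau (84.3 → 52.3), which makes the fractional-recovery
time shorter even though the drug demonstrably wears off more slowly.
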