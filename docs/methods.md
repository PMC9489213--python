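# Methods

## Model

A readily releasable vesicle (RRP vesicle) carries `n_syts` copies of
synaptotagmin.  Each C2B domain binds two Ca²⁺ ions in one effective step
(rate `[Ca²⁺]^c α` with stoichiometry `c = 2` by default; the exponent is
a configuration integer so a one-ion variant can be run) and one
PI(4,5)P₂ (rate `[PI(4,5)P₂] γ`).  Dissociation rate constants are tied
to the in-vitro affinities, `β = K_D,2Ca · α` and `δ = K_D,PIP2 · γ`, so
the free kinetic parameters are the association rate constants only.  At
most `M_slots` syts per vesicle may hold PI(4,5)P₂ simultaneously
(membrane slots); every PI(4,5)P₂ association rate carries the factor
(free slots).  A syt bound to both ligands (a *dual binding*) is
allosterically stabilised: both of its dissociation rates are multiplied
by `A = (3.3/221)² ≈ 2.2·10⁻⁴`.  The factor must appear on both legs for
the cycle products of forward and backward rates to stay equal
(microscopic reversibility); the test suite checks this Kolmogorov
criterion explicitly on all elementary four-cycles.  Fusion is an
absorbing step with rate `L₊ f^n` for `n` dual bindings, i.e. each
engaged syt lowers the fusion barrier by `ln f` (in kBT).

Because syts are exchangeable, the aggregated state `(n, m, k)` (dual,
Ca²⁺-only, PI(4,5)P₂-only counts, with `n+m+k ≤ n_syts`, `n+k ≤ M_slots`)
is sufficient for the vesicle-level chain; states are ordered
lexicographically with the fused state last (141 states for 15 syts and
3 slots).  Matrices are dense — even six slots give only ~400 states.

Internal units are seconds and micromolar; milliseconds appear only at
I/O boundaries (datasets, traces, the latency delay `d`).

## Steady state

At rest (0.05 µM Ca²⁺; for stimuli below rest, the stimulus concentration
itself) fusion is neglected and the chain is reversible, so the
equilibrium follows from detailed balance: walking the lexicographic
order, each state's weight is the previous weight times the
forward/backward rate ratio.  The `n`-increment has no single connecting
reaction; it is computed along the two-step path
`(n−1,0,0) → (n−1,1,0) → (n,0,0)` (bind Ca²⁺, then convert to dual),
which is path-independent by reversibility.  Zero ligand concentrations
make states unreachable; they receive zero weight rather than raising.
The result is validated entrywise (1e−10) against a null-space solve of
the fusion-free generator over randomised parameter sets.

The RRP size is gamma distributed (mean 4000, sd 2000, i.e. shape 4 and
scale 1000), rounded to integers; wherever the release latency (the time
of the fifth fusion) is evaluated, sizes below five are redrawn — this is
the same truncation that the constant `K` normalises in the likelihood.

## Constant-Ca²⁺ (uncaging) solution

With constant Ca²⁺ the chain is homogeneous and
`p(t) = φ exp(Q t)`; the fused component gives the single-vesicle
cumulative fusion probability `G(t)` and `G'(t) = (φ Q e^{Qt})_F` the
fusion-rate density.  The default grid is 0–100 ms in 0.01 ms steps and
extends by doubling (capped at 10 s) when a required quantile of G lies
beyond it; beyond 2·10⁶ points the step coarsens so memory stays bounded.
Numerically the propagator is evaluated through the spectral
decomposition of Q (`G(t) = Σ cᵢ e^{λᵢ t}`), which makes arbitrary-time
evaluation cheap inside searches and the fitting loop; the decomposition
is accepted only if it reproduces the exact identities `G(0) = 0` and
`G'(0) = (φQ)_F` to 1e−4 relative, otherwise the code falls back to
scaling-and-squaring stepping on the uniform grid.  Modes whose
exponential has underflown are dropped per evaluation chunk.

Peak release rates use the unimodality of `G'`: a horizon where 75–90%
of vesicles have fused is located by doubling and bisection, a coarse
grid brackets the interior maximum, and golden-section search narrows it
to 0.01 ms.  If the maximum is not interior (sub-threshold Ca²⁺, where
release decays from t = 0) the dense-grid maximum is returned with a
warning.  Release latencies are sampled by drawing one uniform variate
per vesicle, taking the fifth smallest, and inverting G by
piecewise-linear interpolation; the fitted delay `d` is added.  Mean
fusion times come from the exact first-passage solve `Q₀ h = −1` on the
non-fused states.

## Latency likelihood

Mapping fusion times through `u = G(t)` turns the pool into i.i.d.
uniforms, so with fixed pool size the fifth order statistic is
Beta(5, n−4) and the latency density is `G'(t)` times the Beta density at
`u`.  Binomial coefficients are evaluated with log-gamma (pools of ~4000
overflow naive factorials).  With a gamma pool the marginal density has a
closed form: completing the exponential family gives a rescaled scale
`θ̃ = θ/(1 − θ log(1−u))`, and the falling factorial
`x(x−1)…(x−4) = x⁵ − 10x⁴ + 35x³ − 50x² + 24x` reduces the integral to
five upper incomplete-gamma terms `Iₙ`, normalised by
`K = P(pool ≥ 5) ≈ 1`.  Upper tails use the complementary regularised
incomplete gamma directly — forming `1 − P(a,x)` loses all precision when
the tail is ~1e−11 and was the only numerically delicate point.  The
closed form is validated to 1e−6 relative against quadrature of the
unreduced integral (with the integrand rescaled by its maximum, since the
raw magnitudes reach e⁻⁵⁰) and against histograms of sampled fifth-fusion
times.  Densities are per second internally; the fitting cost converts to
per-millisecond (a constant `ln 1000` shift per observation) so cost
magnitudes are comparable across unit conventions.  The order `k = 5` of
the defining fusion event is a named constant; the gamma closed form is
specific to it (the falling-factorial expansion), so other orders are
rejected rather than silently approximated.

## Fitting

The objective is `2 Σᵢ (r_model − r_data)²` over peak rates (in
(vesicles/ms)²; the weight 2 is a configuration constant) minus the
summed latency log-likelihood.  The model peak rate is the mean pool size
(4000) times the single-vesicle peak; prediction intervals are a plotting
concern, not part of the cost.  Minimisation is Nelder–Mead on
transformed coordinates — log for `α, γ, [PI(4,5)P₂], f` (positive,
upper bound 10¹⁰) and a logit for `d` within its bounds
[0.3, 0.405] ms — which respects all bounds smoothly without modifying
the optimizer.  Iteration and evaluation caps default to 5000.
Multistart uses log-uniform perturbations around the supplied centre.
Grid exploration re-optimises only `d` per grid point; since `d` is a
pure output shift, the per-point time courses and peak rates are computed
once and reused by the 1-D bounded search.

## Gillespie engine

The per-syt simulator tracks an `n_syts × n_ves` matrix of codes
(unbound / PI(4,5)P₂ / Ca²⁺ / dual; −1 marks absent syts when copy
numbers vary).  Events draw four uniforms in a fixed order — waiting
time, vesicle, syt-or-fusion row, reaction — with cumulative-sum
selection ("smallest index reaching r × total"), so trajectories are
bit-reproducible given a seed.  Initial states are drawn from the
aggregated steady state by inverse CDF and written into columns duals
first, then Ca²⁺-only, then PI(4,5)P₂-only.  With a time-varying
stimulus, concentrations are linearly interpolated and refreshed after
every event, and waiting times are capped at 0.8 ms — a longer draw
advances time with no reaction.  With constant stimuli no cap is applied;
the tests confirm the cap is statistically transparent by comparing a
constant trace against the scalar fast path.  Vesicle propensities are
maintained from per-class code counts (O(classes) per refresh); because a
trace-driven run refreshes all vesicles every event, such runs are
chunked into batches of 100 independent vesicles, which keeps total work
linear in pool size.  The event loop is compiled with numba.

Heterozygous vesicles (wild type + mutant syts) use the joint equilibrium
over per-class triplets with shared slots; by detailed balance its weight
is the product of per-class multinomial binding weights times a single
falling-factorial slot-availability factor `M(M−1)…(M−used+1)`.  A
null-space solve of the explicitly assembled joint generator verifies
this closed form in the tests.  Mutants are parameter overrides: the
low-affinity Ca²⁺ mutant multiplies `β` by 10; the "no Ca²⁺ binding,
allosteric-on" mutant sets `α = 0` and fixes its PI(4,5)P₂ dissociation
at `A δ` (permanently mimicking the Ca²⁺-bound state), so it occupies
slots avidly without ever promoting fusion; the "allosteric-off" variant
keeps the normal `δ`.  Dual-binding episode lifetimes are recorded as
completed intervals only; episodes censored by fusion or the end of the
run are discarded, which biases recorded lifetimes short — the average
lifetime of a dual binding is therefore reported by the census tooling
but not treated as a validation quantity.

## EPSC synthesis

Fusion times are rounded up to the next 0.02 ms bin (50 kHz) and the
counts convolved with the quantal kernel
`A((1−ρ)e^{−t/τ₁} + ρ e^{−t/τ₂} − e^{−t/τ₀})`, `τ₀ = τ₁ = 0.12 ms`,
`τ₂ = 13 ms`, `ρ = 10⁻⁵`, normalised numerically to a 60 pA peak.  With
`τ₀ = τ₁` the fast decay cancels the rise term exactly and the kernel
degenerates to `Aρ(e^{−t/τ₂} − e^{−t/τ₁})` — a 13 ms-decay event.  The
constants are used exactly as tabulated (the degeneracy is deliberate in
this parameterisation); consequently paired responses overlap and the
paired-pulse ratio is measured from the current level immediately before
the second onset.  Traces are negative-going (inward currents);
amplitudes are magnitudes.  The variability score sums the across-trace
standard deviation over [0, 6) ms — exactly 300 samples at 50 kHz with
the endpoint-exclusive window.

## Synthetic data

No experimental traces ship with the package; generators stand in for
them and are pure functions of parameters and seed.

* **Uncaging datasets** — per concentration of the standard 31-point grid
  (0.001, 0.1–0.9, 1, 1.25, 1.5, 1.75, 2, 2.5, 3–9, 10–80 µM): one
  latency (a stochastic fifth-fusion draw under the gamma pool, plus
  `d`) and one peak rate (model mean × lognormal noise, CV 0.1 by
  default), mirroring the single-measurement structure of uncaging
  experiments.
* **AP-like transient** — the microdomain Ca²⁺ wave a docked vesicle
  experiences is emulated as a Gaussian pulse on the 0.05 µM baseline,
  default peak 40 µM and 0.5 ms full width at half maximum, sampled at
  0.02 ms.  The published transient shape is not reproduced; peak and
  width are free configuration, and no validated quantity depends on
  them.
* **Paired pulse** — two transients 10 ms apart plus a residual Ca²⁺ tail
  (amplitude 0.4 µM).  The residual "decay time constant 0.154 s⁻¹" has
  rate units despite its name; the default follows the stated unit,
  `exp(−t · 0.154 s⁻¹)`, with a flag to reinterpret it as
  `exp(−t/0.154 s)`.  The membrane-binding-mutant scenario lowers the
  initial PI(4,5)P₂ to a fraction (default 0.25) of the wild-type level
  and relaxes it back with a 5 ms time constant after the first pulse —
  the rise is parameterised because only the qualitative ordering
  (reduced first response, facilitation) is constrained.

Synthetic data reproduce the statistical *structure* the methods assume —
independent vesicles, gamma pool sizes, single noisy measurements — not
the biological scatter of a real synapse; passing tests therefore
demonstrate correctness of the machinery and internal consistency, not
fidelity to any particular dataset.

## Problem sizes and numerical choices

Stochastic checks are sized to their statistical job: distributional
equivalences (Gillespie vs analytic) use 4000–10⁴ vesicles
(Kolmogorov–Smirnov at α = 0.01), Monte Carlo cross-checks of exact
means use ~4000 draws and assert agreement within three standard errors,
and AP-evoked qualitative comparisons use pools of 100–400 vesicles where
only orderings (amplitude ladders, paired-pulse ratios, mutant severity)
are asserted.  The parameter-recovery check fits the full 31-point
synthetic dataset with a single Nelder–Mead start (cap 800 iterations)
from a centre perturbed away from the truth; the factor-two recovery
band reflects the genuine flatness of the objective along correlated
directions (notably γ with `f` and [PI(4,5)P₂]) when only one latency
draw per concentration is available.

Known limitations: no spatial Ca²⁺ buffering or diffusion (concentration
is an externally supplied scalar or trace); no receptor saturation or
desensitisation in EPSC synthesis (strict linear summation); no
sequential two-step Ca²⁺ binding; the macroscopic non-integer
stoichiometry variant is out of scope (the integer exponent is exposed
instead).
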