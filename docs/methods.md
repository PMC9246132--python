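# Methods

## Model

A structure of integer size `n` (subunit counts) grows from a shared pool by
single-subunit steps with propensities

    K_on(n)  = k+ · N_av · (1 + n)^(−α) / V
    K_off(n) = k− · n^β ,  K_off(0) = 0

where `N_av = N − Σᵢ nᵢ` is the free pool in limiting-pool mode, or
`K_on = k+ ρ (1+n)^(−α)` when the cell buffers the free concentration at
`ρ`.  The exponents are dimensionless model constants; `k+` carries units of
volume/time and `k−` of 1/time, so `κ = k+/k−` has units of volume and the
distributions depend on volume only through `κ/V`.  The `(1+n)` form keeps
the assembly law finite at `n = 0`; the hard rule `K_off(0) = 0` regularizes
the `n^β` divergence for `β < 0` and guarantees non-negative sizes.  (The
`β < 0` quadrant is accepted with a warning: no known biological process
realizes positive feedback through size-dependent *disassembly*.)

Assumptions: the pool is well mixed (no explicit diffusion), structures
exchange subunits only through the pool, and rates follow pure power laws.
Spatially resolved transport, multi-state subunits and motor microscopics
are out of scope; where such mechanisms matter they enter only through
their effective `(α, β)`.

## Exact stationary solutions

The single-structure chain is a birth–death process satisfying detailed
balance, giving

    P(n) ∝ (κ/V)^n · N! / [ (N−n)! · (n!)^(α+β) ] ,

and two structures sharing one pool (and one `(α, β)`) have

    P(n₁, n₂) ∝ κ₁^{n₁} κ₂^{n₂} N! / [ (n₁!)^{α+β} (n₂!)^{α+β} (N−n₁−n₂)! ]

on the simplex `n₁ + n₂ ≤ N`.  Distinct per-structure exponents are accepted
by the implementation but flagged in metadata as an extension of the shared-
exponent closed form.  Under a buffered concentration the joint law
factorizes into independent weights `(κρ)^n / (n!)^{α+β}`; normalizability
fails exactly when the weight ratio `κρ/(n+1)^{α+β}` does not eventually
drop below one (`α+β < 0`, or `α+β = 0` with `κρ ≥ 1`), which the code
certifies analytically before attempting truncation; otherwise the support
is doubled until the appended tail mass is below 1e−10.

All weights are evaluated as log-gamma expressions and normalized by
log-sum-exp: `N!/(N−n)!` overflows double precision near `N = 171`, while
log space is stable for every parameter set used here.  Mode counting
merges equal-probability plateaus and requires a strict rise and fall; no
smoothing is applied because the input is an exact probability vector.

Two derived thresholds characterize a structure's growth rate: `κ₀`, where
the stationary CV crosses 1 (located by a log-spaced scan plus Brent
bisection to |CV−1| < 1e−6; below it the structure barely grows), and the
bimodality window `[κ*, κ^c]` for `α + β < 0`, found by scanning 600
log-spaced growth rates and bisecting each edge to 1e−6 relative precision.

## Stochastic simulation

The simulator is an exact Gillespie algorithm: each step draws two uniforms
in fixed order — `r₁` for the waiting time `τ = log(1/r₁)/ΣR`, `r₂` for
channel selection by cumulative-propensity inversion over the `2M`
assembly/disassembly channels plus up to two optional channels.  The inner
loop is a numba kernel seeded per run, making trajectories bit-for-bit
reproducible.  Recording is either per event (bounded by `max_events`) or
thinned on a fixed time grid; stationary statistics always weight states by
their holding times, because event-count histograms are biased toward
fast-switching states.

Two optional channels extend the model:

* **Subunit production** at propensity `r_p (Δ_N − δN)`, where `δN` counts
  subunits produced since activation.  The produced count then follows
  `Δ_N (1 − e^{−r_p t})` in the mean, with a hard cap at `Δ_N`.
* **Linear cell growth** as a unit-Poisson channel of constant rate `g`:
  each firing adds one subunit to the pool and `δV` to the volume, so
  `E[N(t)] = N₀ + g t` and `E[V(t)] = V₀ + g δV t`.  The growth law is
  stochasticized as a jump channel rather than a deterministic drift between
  reactions; this keeps the propensities time-homogeneous and the algorithm
  exact, and the package verifies the ensemble means against the linear law.

## Deterministic dynamics

The continuum rate equations `ṅᵢ = K_on(nᵢ) − K_off(nᵢ)` are treated as an
approximate deterministic model (for general exponents the true moment
equations do not close).  Integration uses LSODA with tight tolerances and
clips sizes at zero.  Fixed points are found by dense grid seeding (200
points per axis for one structure, 60² for two) followed by Newton polishing
with the analytic Jacobian; convergence is accepted on the residual
(‖ṅ‖ < 1e−8), not on the optimizer's progress flag.  Eigenvalues of the
analytic Jacobian classify each point (stable/unstable node, saddle), with
|Re λ| ≤ 1e−9 reported as marginal rather than forced into a class.  For
`β < 0` the ODE domain is restricted to `n ≥ 1e−9` and the origin is
examined separately under the `K_off(0) = 0` rule: it is reported as a
`boundary_regularized` equilibrium when the flow just inside the boundary
points toward it.  For more than two structures the search is restricted to
the symmetric subspace.

Closed-form steady sizes for the two canonical negative-feedback motifs,
with `ρ₀ = N/V` held fixed:

    (α,β) = (0,1):  n* = κρ₀V / (κM + V)
    (α,β) = (1,0):  n* = (κρ₀ − 1)V / (κM + V)   (0, flagged, if κρ₀ ≤ 1)

`κM ≫ V` gives linear scaling with cell size (`n* ≈ ρ₀V/M`); `κM ≪ V` gives
a size independent of `V` and `M`.  The scaling sweeps tag each grid point
by the side of the `κM = V` crossover it falls on.  Note that at a fixed
finite ratio `r = κM/V` the steady size is exactly `n* = ρ₀V·r/(M(r+1))`:
the linear-regime slope approaches `ρ₀/M` with a relative deficit of
`1/(r+1)`, which is why the scaling checks hold the ratio fixed across the
volume grid rather than the rate.

## Organelle models and parameter sets

Concentrations are converted to counts through one routine:
`N = conc[µM] · 602.214 · V[µm³]`, or `conc · V` for number densities.

**Flagella** `(α, β) = (1, 0)`: intraflagellar transport makes assembly
inversely proportional to length; M flagella share one tubulin pool.
Defaults: tubulin 5 µM, 10 nm per subunit, `k+ = 120 µm³/min`,
`k− = 100/min`, severing at `t₀ = 1000 min`, production `r_p = 0.0016/min`.
The accessible cytoplasmic volume is not part of that set; it defaults to
2 µm³, which places the system in the pool-limited regime where the
regrowth experiment is informative (steady length ≈ 16 µm, the two flagella
holding a sizable fraction of the tubulin): with a much larger accessible
volume the free pool dwarfs the flagella, severing one barely perturbs the
other, and recovery is not production-limited.  The amputation protocol
runs to steady state, sets one length to zero, removes that amount from the
total pool, and arms the production channel with target `Δ_N` equal to the
lost amount.  A one-parameter least-squares fit of `r_p` against a
user-supplied length-vs-time table is provided; no experimental dataset is
bundled.

**Centrosome** `(α, β) = (0, 1)`: assembly localized at the centriole,
disassembly distributed through the porous PCM volume.  Closed forms
exposed: single-centrosome steady size `k+N/(k+ + k−V)`, relaxation time
`(k+/V + k−)^{−1}`, multi-centrosome size `κN/(κM+V)`.  Defaults: subunits
1.67 µM, block volume 5.8e−7 µm³, `k+ = 10³ µm³/min`, `k− = 10⁻³/min`,
`V_cell = 5000 µm³`.

**LLPS droplet**: with spontaneous condensation off (`k_AB = 0`) and a
constant internal volume fraction `ψ₋`, droplet growth reduces to
`ṅ_B = (C0 + C1 n_B)(N_av/V_c) − C2 n_B` with `C0 = (1−ψ₋)Q`,
`C1 = (1−ψ₋)kδ_v`, `C2 = k_BA`.  `C1 ≳ C0` lies on the degenerate
limiting-pool line (effective `(α,β) = (−1,1)`); at `C1 = 0` the law *is*
the kinetic centrosome model with `k+ = C0`, `k− = C2`, and the package
verifies that identity by running both parameterizations on the same seed.

**Nucleus + aster**: nuclear envelope (NE) or nucleoplasm (NP) subunits are
delivered at rate `K+ = k+ (4π/3)((L̄+R_n)³ − R_n³) · (N−n)/V` —
proportional to the shell volume spanned by the microtubule aster — and
removed at `k− n`; each filament obeys the antenna law (assembly
`k_m+ N_av,m/V`, disassembly `k_m− L`).  Whether the aster prefactor also
carries `1/V` is exposed as a config flag (`normalize_by_V`, default on).
Geometry maps counts to radius: `4πR_n² = n δ_A` (NE, `R ∝ n^{1/2}`) or
`(4π/3)R_n³ = n δ_V` (NP, `R ∝ n^{1/3}`); the early-phase positive feedback
of NE growth emerges from the geometry with no separate switch.
Confinement at radius `R_sys` zeroes filament assembly when `L̄ + R_n ≥
R_sys` (hard wall; an exponential soft-decay option is exposed).  Defaults
follow the in vitro set — NE subunits 8 µm⁻³, `δ_A = 0.215 µm²`,
`k+ = 5·10⁻³ µm³/min`, `k− = 0.1/min`; NP subunits 0.75 µm⁻³,
`δ_V = 0.1 µm³`, `k+ = 2 µm³/min`, `k− = 10⁻³/min`; tubulin 0.67 µM,
`δ_L = 5 nm`, `k_m+ = 2 µm³/min`, `k_m− = 10⁻²/min` — with a 100 µm³ system
and 20 filaments per nucleus (not part of the printed set; chosen to keep
the aster near 10 µm and the nucleus near 3 µm).  The cell-size scaling
exponent of nuclear volume is *measured* from a log–log fit across a volume
sweep at fixed concentrations rather than hard-coded: the NP mode comes out
linear (`V_n ∝ V_cell`) and the NE mode strongly superlinear (≈ 2 in the
default regime).

## Ensemble statistics

**Residence times** use two-threshold hysteresis on the occupied fraction
`n/N_current`: high entered at ≥ 0.75, low at ≤ 0.25, intermediate samples
keep the previous state.  The thresholds are implementation-defined (the
state boundary has no canonical definition) and recorded with the result;
hysteresis suppresses spurious switch counts.  Completed dwells are stored
with their state; the ongoing final stay is reported as a censored lower
bound and never dropped — at large pools the selected state may outlive any
feasible run.  The pool-size trend is measured as survival of the *large*
state: each run starts with the structure holding the whole pool and the
first high-state dwell (censored at `t_max`) is recorded; this matches the
observation that the stochastically selected large structure persists for
times growing exponentially with `N`, and it remains well defined at pool
sizes where the stationary law is not yet bimodal.

**State diagram**: labels are a deterministic function of the exact
single-structure distribution.  Two or more modes → `bistable`; a single
mode at `n ≤ 2` with more than 1% of probability beyond 3× the mean →
`shoulder`; a single small mode with CV ≥ 1 and no such tail →
`no_growth`; anything else → `monostable_large`.  The tail-mass test runs
before the CV test: near-exponential bodies acquire the long tail (the
shoulder) while the CV is still above 1, so ordering the CV test first
would leave the shoulder class empty.  All thresholds are surfaced in the
returned criteria record.

**Coexistence** evaluates both marginal means from the exact joint law on
an `(α+β, κ₁)` grid with `κ₂` fixed; a cell coexists when both means exceed
one subunit.  **Anticorrelation** is the holding-time-weighted Pearson
correlation of the two sizes; in a growing cell the shared upward trend is
removed by correlating inside fixed-duration windows (short against the
growth timescale, long against the structure dynamics) and averaging.
**Polarity selection** runs one seeded simulation per seed with M identical
autocatalytic structures; a structure is dominant when it holds more than
half the consumed pool, and the module reports the final winner, its
persistence over the last 10% of the run, the number of distinct dominants
(flickering), and a chi-square test of winner uniformity.

## Reproducibility and problem sizes

Every stochastic run is driven by a single integer seed; the CLI emits a
manifest (config echo, version, seed, output digests) and identical seeds
reproduce outputs byte for byte.  `scripts/acceptance.py` derives one
sub-seed per stage from `--seed` so stages stay independent.

Problem sizes used by the test suite and the acceptance script: pools of
`N = 10–60` for exact-law cross-checks (dense generator oracle up to 61
states); 10⁶-event simulations for distribution comparisons, except the
degenerate `α+β = 0` pair, which mixes slowly along the simplex diagonal
and uses 4×10⁶ events with the two identical structures' histograms pooled;
20 seeds per pool size for residence-time medians (observation window
3×10⁵); 50 seeds for polarity selection at `N = 2000, M = 20`; organelle
sweeps over 3–7 parameter values at the defaults above.  The whole suite
runs in about half a minute on one CPU after numba compilation; the
acceptance script in well under a minute.

## Known limitations

- The mean-field module is an approximate description; it is expected to
  disagree with stochastic means on the degenerate line and in bistable
  regimes (that disagreement is part of the science, not an error).
- The two-structure closed form assumes a shared `(α, β)`; per-structure
  exponents are an implementation extension, labelled as such in metadata.
- The synthetic organelle runs emulate kinetics only: no spatial gradients,
  no sigmoidal centrosome growth, no IFT/motor microscopics, no nuclear
  pore transport.  Passing tests demonstrate internal consistency of the
  kinetic theory and its closed forms, not agreement with any particular
  experimental dataset.
- Simulation is plain SSA; no tau-leaping, so regimes with event rates many
  orders of magnitude above the recording timescale are slow by design.
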