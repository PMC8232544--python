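# Methods

## Model definition

The automaton lives on a periodic 1D or 2D square lattice.  Each node
carries, per phenotype, `b` velocity channels (`b = 2` in 1D, `4` in 2D)
and `a` rest channels, `K = a + b` in total, each occupied by at most one
cell (exclusion principle).  Channel ordering is normative: velocity
channels first, in angular order (1D: `+1, −1`; 2D: `+x, +y, −x, −y`,
i.e. `c_p = (cos 2π(p−1)/b, sin 2π(p−1)/b)`), then rest channels.  The
angular order matters because the nematic alignment vector
`N(s) = ½ Σ_p c_{[2(p−1) mod b]+1} s_p` doubles channel angles by index
arithmetic; with this order opposite channels fold onto the same nematic
direction, as they must.  Multi-phenotype states are stored as concatenated
per-phenotype channel blocks; exclusion applies per phenotype per channel.

One step applies reorientation (O), then birth/death (R), then phenotype
switching (S), then deterministic propagation (P); the time counter
increments with P.  Reorientation is synchronous: every node's outcome
distribution is built from the *pre-update* neighbourhood, then all nodes
are replaced at once.  Mass is conserved exactly by O and P; with zero
demographic rates the total cell number is invariant for all time, and
propagation conserves total momentum exactly (it merely permutes channel
contents across nodes).

### Reorientation

For a node with per-phenotype counts `n_σ`, all `Π_σ C(K, n_σ)`
mass-conserving outcomes are enumerated exactly (no Monte-Carlo estimate of
the partition function); `K` is capped at 16 to bound the enumeration.
Outcome weights are `exp(E(s^O, s_N))`; probabilities are normalised by a
shifted (log-space) softmax so sensitivities as large as β = 100 (used in
the aggregation study) cannot overflow.  With all sensitivities zero every
rule reduces to the uniform random walk.

The built-in energies depend on the outcome only through its flux `J(s^O)`,
nematic vector `N(s^O)` and resting count, and on the neighbourhood through
a small set of fields (density gradient, neighbour momentum, signal
gradient, logistic density gradient, neighbourhood flux, neighbourhood
resting count).  The density-gradient and signal-gradient sums run over the
`b` lattice neighbours; rest channels carry zero velocity vectors, so this
is equivalent to summing over all `K` channels.  Environment fields (scalar
signal, vector field **E**) are static during a run; coupled signal
dynamics is out of scope.  The neighbourhood passed to rules is the von
Neumann template excluding the central node; in particular the invasion
rule's neighbourhood flux `g_align` sums neighbour fluxes only.
`n_crit` in the logistic density gradient accepts non-integer values and
`g_agg` is not normalised by `K`.

### Demographics

The model family does not pin down functional forms for birth, death and
switching, so the defaults here are deliberately the simplest
exclusion-respecting choices and are pluggable: each cell dies
independently with probability `r_d`; each survivor attempts one birth with
probability `r_b` into a uniformly chosen free channel of its node (no free
channel → the birth fails); a switching cell keeps its channel index and
moves to the target phenotype's block only if that channel is free.  These
defaults should be treated as placeholders when quantitative demographic
effects matter.

### Randomness and reproducibility

A single seeded `numpy` generator drives a run.  Reorientation draws one
uniform variate per node in canonical row-major order *before* any update;
outcome selection is a deterministic transform of those draws, so runs are
bit-reproducible for a given seed independent of the internal
vectorisation.  Birth/death and switching consume vectorised draws from the
same generator (deterministic given the seed).  Output files embed the seed
and a configuration hash.

## Rule derivation

**From potentials.** Overdamped self-propelled-particle models give the
orientation θ a Langevin dynamics in a potential `U`; assuming fast angular
relaxation, the stationary Fokker–Planck solution `P(θ) ∝ exp(−βU(θ))`
(β = γ/D_θ) is taken as the single-cell orientation distribution.  Only
this stationary solution is used; the Langevin/Fokker–Planck dynamics are
never integrated.  Discretising orientations onto the lattice directions
and assuming independent channel occupations yields outcome weights
`exp(−β Σ_j U(c_j) s_j^O)` over mass-conserving configurations.  Rest
channels receive zero potential unless values are supplied (the derivation
covers only moving directions); the integration constant is absorbed into
the normalisation.  For the cosine family `U = −C cosⁿ(θ − φ)` the energy
is `β J·G` (n = 1) or `β N·G` (n = 2) with `‖G‖ = C`, `arg G = φ`.

**From data (maximum caliber).** Given per-channel observable values
`Ũ(s_i | s_N)` and a measured expectation `E_j` per time step, the
maximum-path-entropy distribution is `P ∝ exp(β(j) Ũ)` with β(j) fixed by
`⟨Ũ⟩ = E_j`.  The forward map β ↦ ⟨Ũ⟩ is strictly increasing (its
derivative is the observable's variance), so β is found by geometric
bracket expansion plus Brent's method to 1e−10; targets outside the open
range of the observable raise an error naming the feasible interval.
Time-independent targets give a constant multiplier.  Independence of cells
within a node is assumed when factorising multi-cell outcomes — an
approximation, stated as such.  All weights are computed in log-space.

The two routes agree exactly (tested to 1e−10) when the observable is
`s_i c_i·G`, both reducing to the director-field form.

## Mean-field analysis

Both analytical tracks assume the low-density single-particle regime (at
most one cell per node, weak coupling) and translation invariance; their
predictions are quantitative near onset and indicative deep in the
nonlinear regime.

**Adhesion model (1D).** Linearising the adhesion transition probability
and closing on the mean node density gives a five-point finite-difference
equation; its Fourier modes grow per step by `1 + g(κ)` with
`g(κ) = (2/K)[2βρ̄ − 1 + cos κ − 2βρ̄ cos²κ]` (implemented in the
algebraically equivalent form `(2/K)[(cos κ − 1) + 2βρ̄ sin²κ]` so that
`g(0) = 0` holds exactly in floating point).  Setting `dg/dκ = 0` and
discarding the trivial solutions κ = 0, π yields
`cos κ_c = 1/(4βρ̄)`: instability requires `βρ̄ > 1/4`, the critical
wavelength `λ_c = 2π/κ_c` diverges at threshold and decreases towards 4
lattice sites as βρ̄ → ∞.  The growth sign convention follows the bracket:
positive bracket ⇒ growing perturbation (the printed derivation is
ambiguous about whether the increment on the left-hand side refers to step
k or k+1; the stability conclusions are unaffected).  Criticality treats κ
as quasi-continuous (infinite-lattice limit); finite-lattice modes
`q = 2πm/L` are used only when comparing with simulations.

**Simulation–theory comparison.** The aggregation study runs the full
automaton at β = 100, ρ̄ = 1, a = 2, L = 100 for 500 steps and compares the
spectral peak of late-time density with λ_c ≈ 4.01.  The initial state
matters here: the pattern emerges *from a homogeneous state*, so the
generator places exactly ⌊ρ̄⌋ cells at every node (fractional parts by
Bernoulli) in random channels (`initialize_homogeneous`) — the only
disorder is in the channel assignment.  Under per-channel Bernoulli
initial conditions (`initialize_random`) the O(1) density noise locks the
strongly-coupled dynamics into irregular cluster spacings (≈ 5 sites on
average) within a few steps, and the late-time spectral peak then reflects
the initial noise basins rather than the linear mode selection; with the
density-homogeneous start the κ_c mode dominates and the measured period
agrees with λ_c to about one lattice site in ≥ 8/10 seeds.  Both
initialisers are first-class API.

**Invasion model (1D).** The mean-field dynamics of the combined rule is
the lattice-Boltzmann equation `f_j(r+c_j, k+1) = ρ(r,k) T_j` with
single-particle probabilities built from the rule energies.  Its
homogeneous steady state solves `f_r = ρ̄ Π_r/(2 + a Π_r)`,
`Π_r = exp(2β_rest a f_r)`, by damped fixed-point iteration (damping 0.5)
with a bracketed-bisection fallback; the right-hand side is evaluated in an
overflow-safe form and the returned state satisfies both steady-state
relations to 1e−12.  The Boltzmann propagator
`Γ_{m,n}(q) = e^{−ic_m q}[T_m + Σ_{ℓ=±1} e^{ic_ℓ q} ρ̄ ∂T_m/∂f_n(r+c_ℓ)]`
uses analytic derivatives; a built-in oracle cross-checks them against
central finite differences of the real-space LBE map (step 1e−6, tolerance
1e−5) and raises on disagreement.  At q = 0 one eigenvalue equals 1
(mass conservation); spectra at q and 2π − q are complex conjugates.

**Phase classification.** Over a wavenumber grid of ≥ 256 points in
(0, 2π), the dominant eigenvalue decides the phase.  Stable spectra
(max |Λ| ≤ 1 + 1e−9): *jammed* if the steady-state resting fraction
`a f_r/ρ̄ ≥ 0.75`, else *diffusive*.  Unstable spectra: *collective* if the
dominant mode travels (|arg Λ| > 1e−6) **or** is a homogeneous-drift mode —
the flux instability whose maximum sits at the edge of the q grid (κ → 0,
or its staggered-momentum aliases at q = π and 2π − κ, the automaton's
trivial wavenumbers); otherwise the unstable mode is a stationary
finite-wavelength pattern: *aggregation*.  The drift clause is needed
because in 1D the onset of collective motion is a pitchfork (real
eigenvalue) at κ → 0, not a Hopf bifurcation; the arg criterion alone
captures only travelling waves at finite κ.  The resting-fraction and
argument thresholds are classification conventions, exposed as
configuration.

**Phase-diagram study conditions.** Sweep ranges are not dictated by the
model; the package's reference study uses ρ̄ = 0.4, a = 4, n_crit = 4,
β_agg, β_align ∈ [0, 4] (20×20 grid) at β_rest ∈ {0, 1}.  These values
were chosen once so that all four regimes are reachable: the collective
threshold is ≈ 1/(mobile density) ≈ 3.8, the aggregation threshold ≈ 1,
and at β_rest = 1 the steady state is both stable and rest-dominated
(resting fraction ≈ 0.79 ≥ 0.75), giving a jammed region; higher β_rest
values excite a weak rest-condensation instability (max |Λ| ≲ 1.02) and
would be classified as aggregation.  Labels are invariant under refining
the q grid from 256 to 1024 points.

## Synthetic data and what the tests show

All inputs are generated programmatically: seeded Bernoulli or
density-homogeneous lattice states, tiled lattices that realise many
identical neighbourhoods for sampling/enumeration comparisons, and channel
choices drawn from a known Boltzmann distribution for the
parameter-recovery study.  These fixtures emulate the model's own
statistical structure, not real microscopy data: there is no measurement
noise, no tracking error, no spatial heterogeneity beyond what the rules
generate.  Passing tests therefore demonstrate internal correctness
(operators match their enumerated distributions, analytics match
simulations in their regime of validity, fits invert their forward models)
— not that any particular biological system follows these rules.

## Numerical choices

* Boltzmann weights: log-space softmax everywhere; `Z` reported via
  log-sum-exp.
* Outcome selection: inverse-CDF on the cumulative probabilities with one
  uniform per node; ties broken towards the lower index; selection index
  clamped to the last outcome against rounding.
* Max-caliber root solve: bracket `[−1, 1]` doubled until sign change,
  Brent to xtol 1e−10.
* Steady-state solver: damped fixed point, residual target 1e−12, 1e4
  iteration cap, bisection fallback; non-convergence raises with the
  residual.
* Propagator validation: central differences with step 1e−6 on an L = 16
  periodic lattice; phase-diagram scans validate once per parameter set
  (at one q) rather than at every grid point, for cost.
* Degenerate inputs: empty nodes and full nodes have a single outcome and
  consume their per-node draw without branching; `g_agg` vanishes
  identically when both neighbour densities equal `n_crit`.

## Problem sizes

The reference studies are sized for interactive use: aggregation runs use
L = 100 for 500 steps × 10 seeds (seconds); the phase diagram evaluates
2 × 400 parameter points × 255 wavenumbers (seconds); sampling/enumeration
comparisons draw 1e5 outcomes per rule through the full update path;
diffusion checks track 1000 independent walkers on one lattice.  All sizes
are set in the tests/examples and scale linearly if enlarged.

## Known limitations

* Mean-field predictions ignore pair correlations; measured growth rates
  of the stochastic automaton are systematically smaller than the
  Boltzmann values away from onset, and deep in the nonlinear regime only
  the selected wavelength (not the growth rate) is comparable.
* Demographic operators are placeholder forms (see above).
* Hexagonal and 3D lattices, non-periodic boundaries, dynamic environment
  fields, off-lattice dynamics and boson-type (non-exclusion) variants are
  out of scope.
* The phase labels inherit the single-particle approximation; near phase
  boundaries the automaton's finite-size behaviour may differ from the
  mean-field label.
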