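# Methods

## Model

Each node of a simple undirected graph carries a binary state
`s_i ∈ {0, 1}` (inactive/active gene). The energy of a configuration is

    H = -(1/2) Σ_ij J A_ij s_i s_j - h Σ_i s_i

with the ordered double sum de-duplicated by the 1/2. Units: `k_B = 1`,
`β = 1/T`, and `J`, `h`, `T` share one energy scale, so only their
ratios matter. `T = 0` is treated as the deterministic `β → ∞` limit
(heat-bath ties resolved by a fair coin; Metropolis rejects ties).

Because only pairs of *active* genes contribute to the coupling term,
the model is asymmetric: unlike the ±1 Ising model at `h = 0`, it has no
global spin-flip symmetry. The exact substitution `s'_i = 2(s_i − 1/2)`
makes this explicit — it maps the model onto a classical ±1 system with

    J' = J/4,   h'_i = h/2 + (J/4) k_i,   E0 = -(J/4)|E| - N h/2,
    H_{0,1}(s) = H_{-1,+1}(s') + E0,   Z_{0,1} = e^{-βE0} Z_{-1,+1}.

The degree-dependent intrinsic field `(J/4) k_i` survives at `h = 0` and
is what drives hubs to order first. These constants are not taken on
trust: `exact_oracle.verify_mapping` enumerates all `2^N` configurations
of both conventions and requires the energy identity and the partition
relation to hold to a relative 1e-8 (they hold to machine precision).

## Networks

Barabási–Albert generation follows linear growth with preferential
attachment: `m0` initially unconnected seed nodes (default `m0 = m`),
then each new node attaches `m` distinct edges with probability
proportional to current degree. Since all seed degrees are zero, any
attachment step whose candidate degrees are all zero falls back to
uniform sampling without replacement; this is the minimal rule that
makes the stated construction executable. Consequences used in tests:
`|E| = m(N − m0)` exactly, mean degree `≈ 2m`, and a power-law degree
tail whose continuous maximum-likelihood exponent (fitted above
`k_min = m`) lands near 3 for large N. If `m < m0`, seed nodes that
never receive an edge remain isolated — degree-proportional attachment
cannot reach them.

The annealed adjacency `⟨A_ij⟩ = k_i k_j / (2mN)` is exposed (clipped to
[0, 1]; the clip is only active between hubs) and is consistent with the
degree normalisation: its row sums reproduce `k_i` up to the finite-size
factor `(N − m0)/N`.

## Monte Carlo

Single-site updates at uniformly random nodes (no sweeps; the
literature's step arithmetic — 5e4 steps on 5e3 nodes = 10 attempted
flips per spin — only holds under this reading). The heat-bath kernel
resamples the chosen node from its conditional Boltzmann distribution
`P(s_i = 1) = logistic(β(h + J Σ_j A_ij s_j))`; it is the default
because its annealed average is exactly the mean-field self-consistency
map, making the MC/mean-field comparison self-consistent. Metropolis is
provided as an alternative and the two are statistically
indistinguishable in equilibrium (tested at 3σ). Default initial state:
all-active for `J > 0`, all-inactive otherwise.

Error bars on chain means use 20 batch means (50 in the long
oracle-equivalence chains) to blunt autocorrelation, which is otherwise
not modelled. Samples are recorded at the end of every sampling step by
default; thinning is available but off, matching the stated protocol.

Seeding: ensembles derive a network seed `master_seed XOR r` and
per-realization chain-seed streams from `SeedSequence((master_seed, r))`;
identical inputs reproduce results bit for bit. The chain inner loop is
JIT-compiled with numba and uses numba's own seeded RNG.

## Mean-field solver

`M ← (1 − λ)M + λ f(M)` with `f(M) = Σ_k P(k) logistic(β(h + J M k))`
evaluated over the *actual* degree sequence (compressed to unique
degrees with weights), not an idealised continuum distribution — this is
the form that can be compared against MC on the same graph. Defaults:
`λ = 0.5`, tolerance 1e-10 on `|f(M) − M|`, cap 1e5 iterations. At very
large β the map slope at the fixed point can exceed 1 in magnitude and
the λ = 0.5 iteration 2-cycles; the solver halves λ whenever successive
residuals change sign, which restores local stability without moving the
fixed point. `β = 0` short-circuits to the exact value `M = 1/2` (every
logistic term is exactly 1/2). Iterates are asserted to remain in
[0, 1], which `f` guarantees.

Branch analysis runs the solver from `M = 0` and `M = 1` at every field
value; a point is *bistable* when the branches differ by more than 0.5,
and each branch's discontinuity is reported as the midpoint of its
largest adjacent-grid jump. The high-temperature closed form
`M ≈ (1/2)(2 + βh)/(2 − βJm)` uses the minus sign for ferromagnetic
coupling (the sign that makes M increase with J and M at fixed large T)
and plus for antiferromagnetic; it is singular at `βJm = 2` and the
solver, not the closed form, is authoritative there.

## Protocols

Temperature and field sweeps run an independent equilibrium chain per
(realization, control value) — no state is carried — over an ensemble of
fresh BA realizations (default n = 20 per the study conditions; reduced
sizes used in tests are stated below). The hysteresis protocol is the
deliberate exception: the final configuration at each field seeds the
next, first 10 → −10 then back (grid widths configurable), and the loop
area is the trapezoidal `|∮ M dh|`.

The measured critical field is read from an ascending field sweep
started all-inactive with antiferromagnetic coupling (the activation
transition): `h_c_hat` is the linearly interpolated first crossing of
`M = 0.5`, ties resolved toward lower h. Pinning the protocol to one
branch is essential in a first-order system; the deactivation transition
of the ferromagnetic active branch sits instead near `−J·k_min = −Jm`
and is what the hysteresis loop exposes.

## What the synthetic conditions do and do not show

The generator's defaults are the study conditions: `N = 5000`, `m = 5`,
`|J| = 1`, schedule 2e4 + 3e4 steps, 20 realizations. Reduced problem
sizes are used where the check is statistical rather than quantitative:
oracle-equivalence chains use N ≤ 12 (where exact enumeration is
possible) with 1e6-step chains; phenomenology checks use N = 500 with
5 realizations; critical-field scaling uses N = 400 with 3 realizations.
These sizes were chosen so each property is measured far above its noise
floor.

BA graphs emulate the heavy-tailed connectivity of real regulatory
networks but none of their directedness, signed/weighted interactions,
modularity, or logic; a uniform `J` and `h` is the strongest
simplification. Passing tests therefore demonstrate correctness of the
simulator and of the theory *for this model class*, not biological
validity on any particular dataset. Imported edge lists are treated
identically to generated graphs except that annealed-adjacency
operations require the attachment parameter `m` as metadata.

Two deliberate deviations from naive mean-field expectations are worth
recording. First, at `h = 0` and low T the antiferromagnetic model does
**not** empty out: every independent set has zero energy, so the
equilibrium is the hard-core lattice gas at unit fugacity with density
≈ 0.2 on BA(m = 5) graphs. Mean-field theory (which predicts M → 0)
misses this entropic effect, so MC/mean-field overlays for `J < 0` are
only asserted at `T ≥ 2`; for `J > 0` they agree within 0.1 at all
temperatures. A field `h ≲ −0.5` suppresses the hard-core density to
zero, which is why field-sweep anchors are placed at `h = −2`. Second,
the measured activation `h_c` lies below the mean-field line `J m`
(crossing `M = 1/2` near `0.4 Jm` on these graphs): real
anti-correlations let half the network activate earlier than the
decoupled theory predicts. The linear growth of `h_c` with `J` and `m`
survives; the mean-field slope over-estimates it. Full saturation
(`M ≥ 0.99`) under antiferromagnetic coupling requires fields of the
order of the *hub* degree, since a hub stays suppressed until
`h ≳ |J| k_i`; field grids for saturation checks therefore extend to
h = 80 at N = 500.

## Known limitations

- No cluster updates or parallel tempering; at `T ≪ 1` single-flip
  dynamics are metastable by design (that is what the hysteresis
  protocol measures), so "equilibrium" sweeps at very low T report the
  branch selected by the initial state.
- The exact oracle is capped at N = 20 (≈ 1e6 configurations).
- Degree-exponent estimation uses the continuous MLE above `k_min = m`;
  it is a summary diagnostic, not a rigorous discrete power-law fit.
- Directed, weighted, bipartite networks and per-node external fields as
  *inputs* are out of scope (per-node fields arise only internally
  through the ±1 mapping).
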