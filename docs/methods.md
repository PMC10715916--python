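# Methods

## Model

Opinions are probability mass functions on a fixed grid of 200 belief
values, the bin centres −1 + Δb·(i + ½) with Δb = 0.01, i.e.
{−0.995, …, 0.995}.  Storing masses (not densities) makes normalisation,
moments and the multiplicative update simplest; the perception mixture and
the Bayesian product are invariant to this choice after renormalisation.

**Social update.**  A listener observes a messenger through the perception
filter α·x_j + (1−α)·U and multiplies it into its own opinion, then
renormalises.  α is capped at 0.99 so the posterior mass cannot vanish when
prior and likelihood have disjoint support; α = 0 transmits no information
(the update is exactly the identity).  Only the listener changes.  Two
forces compete: assimilation toward the messenger where the distributions
overlap, and conservatism (the prior zeroes out beliefs it does not hold).
Repeated mutual confirmation contracts an opinion toward a single bin;
repulsive (negative-α) influence is out of scope.

**Non-interaction.**  One implicit (backward-time, centred-space) step of
the heat equation with diffusivity κ and Δt = 1 simulation step.  Zero
Dirichlet values are imposed at ghost points one spacing outside the
outermost grid points (±1.005) — the plain BTCS matrix with no wrap-around
or flux correction, which is the simplest reading of "zero boundaries at
the edges of the belief space".  Dirichlet edges drain mass, so the result
is renormalised each step; distributions then remain probability
distributions and moments stay defined, and the subsequent multiplicative
update is unaffected (it renormalises anyway).  No artificial mass floor is
applied: double precision plus per-step renormalisation is sufficient for
α ≤ 0.99.  Note the renormalised iteration converges to the principal
eigenmode of the solve (a broad sine-like profile), which is flat only in
the interior; we implement the stated equations rather than any idealised
"perfectly uniform" long-run limit.  The solve uses the Thomas tridiagonal
algorithm (the library path via LAPACK's banded solver, the simulation
kernel via precomputed sweep coefficients, since the matrix is constant
within a run); both agree with a dense solve to 1e−10.

**Network.**  Two ring lattices (one per identity group), k_in nearest
in-group neighbours each; red agent i also links to blue agents at
circulant offsets i, …, i+k_out−1 (mod n/2).  A ring lattice cannot give
every node an odd degree by symmetric offsets alone, so odd k_in adds a
perfect matching at the diametric offset — the p=0 network stays regular
(needed e.g. for the homophily sweep point k_in=9, k_out=1).  Rewiring with
probability p per link: in-group links follow the Watts–Strogatz sweep
(offset-major over each node's forward lattice edges), re-targeting to a
uniform same-group non-neighbour; out-group links keep the red endpoint
(the constructor that "owns" the link) and re-target the blue endpoint to a
uniform out-group non-neighbour of the owner.  A draw with no legal target
leaves the link in place (vanishingly rare at n = 100).  Counts of in- and
out-group links are conserved exactly, so homophily is a construction
invariant.  Nodes are 0-based internally.

**Scheduling.**  Per step, all n agents are visited in a fresh uniform
permutation; updates apply immediately, so later listeners see earlier
same-step updates (the standard meaning of asynchronous random-sequential
updating; whether the messenger's opinion is pre- or post-update this step
is a convention — we fix the immediate-update one and keep it identical in
both execution paths).  The messenger is chosen uniformly over all
neighbours; homophily enters only through the network composition.  An
isolated agent selected for interaction diffuses instead.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| n | agents | 100 | — |
| k_in, k_out | mean in-/out-group degree | 8, 2 | links |
| p | link rewiring probability | 1.0 | — |
| q | interaction probability per agent-step | 0.2 | — |
| κ | opinion decay speed | 0.0002 | belief²/step |
| σ0 | SD of initial Gaussian opinions | 0.2 | belief |
| δ | identity predisposition of initial means | 0 | — |
| α_in, α_out | perception filter transparencies | 0.5, 0.5 | — |
| t_max | simulation length | 5000 | steps |
| σ_cons | consensus threshold on σ | 0.01 | belief |

σ0 is the *standard deviation* of the initial Gaussian (the initialisation
literature sometimes writes the spread parameter loosely as a "variance");
with σ0 = 0.2 and means uniform on [−1, 1] the initial disagreement is
σ(0) ≈ 0.5–0.6.  Initial means under predisposition: red agents draw a
negative mean (uniform magnitude) with probability 0.5 + δ/2, blue agents
with 0.5 − δ/2; δ = 0 recovers Uniform[−1, 1] independent of identity.
Named scenarios: U1 (α_in = α_out = 0.25, skeptical), U2 (0.5, neutral),
U3 (0.75, credulous), B (α_in = 0.75, α_out = 0.25, biased).

## Consensus accounting

Disagreement σ is the population SD (ddof = 0) of the n mean opinions,
recorded every step including t = 0.  Consensus is first passage strictly
below σ_cons ("below a threshold" read strictly); C_t counts runs with
first passage ≤ t and is therefore non-decreasing in t.  Because influence
is purely assimilative, consensus is empirically absorbing, so ensembles
may stop a run at first passage without changing C_t — the ensemble driver
does this for speed.

## Randomness and reproducibility

One integer seed per run feeds a `SeedSequence` split into an
initialisation stream (network rewiring first, then initial opinions) and
an update stream — changing t_max never changes the topology or the start.
Each step draws one permutation, n interaction uniforms and n
neighbour-choice uniforms, in that order, regardless of which branch each
agent takes; the compiled kernel and the pure-Python reference step
therefore consume identical streams.  Ensemble run i uses the seed derived
from `SeedSequence([base_seed, i])` (masked below 2³¹): counter-based, so
ensembles are extensible and order-independent.  Sweeps reuse the same
base seed at every grid point (common random numbers), making a
single-point sweep exactly equal to a plain ensemble.

## Numerical and performance choices

The asynchronous loop is inherently sequential, so the hot path is a
numba-compiled scalar kernel; a pure-Python path implements the same step
from the same library operations and the two agree to ~1e−8 over a
100-step trajectory (bit identity is not expected across different float
summation orders; within one engine, reruns are bit-identical).  One
5000-step run of the default society costs roughly 0.2–0.8 s on one CPU.
Ensembles of 200 replicates put the binomial SE of a consensus frequency
at ≤ 3.5 percentage points, which resolves all qualitative contrasts of
interest; the reference study scale of 1000 replicates is available by
passing `reps=1000`.

Degenerate inputs: κ = 0 and α = 0 are exact identities; an empty
neighbour list falls back to diffusion; a single-agent society has σ = 0
from t = 0 and counts as immediate consensus.  n = 1 is the only odd n
accepted (identity groups must otherwise be equal).

## What the simulator does and does not show

All experiment data is generated by the model itself under the stated
conditions; there is no external data.  The synthetic society emulates the
mechanism — Bayesian assimilation, perception bias, homophilic small-world
structure — not any measured population: real opinion networks have
heterogeneous degrees, correlated identities and opinions, multi-topic
belief spaces and time-varying ties, none of which are modelled.  Passing
tests show the mechanism's consequences (bias–topology interaction,
echo-chamber formation), not quantitative predictions about real societies.

## Known limitations

- Consensus frequencies at 200 replicates carry ±3.5-point Monte-Carlo
  error; contrasts between scenarios are far larger than this, point
  estimates are not exact.
- The t → ∞ behaviour (e.g. saturation of C_t on random networks) requires
  ~10⁶-step runs and is outside the default experiment scale, though t_max
  is unrestricted.
- Exactly two identity groups, global α_in/α_out, fixed network, no
  repulsion, no zealots or media forcing.
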