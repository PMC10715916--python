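# opinionet

Agent-based simulation of opinion dynamics under social identity, in-group
bias and network clustering — for computational social scientists studying
when societies of socially influenced agents reach consensus and when they
fracture into echo chambers.

## Model

A society of *n* agents debates one issue.  Agent *i* holds an opinion as a
probability distribution *x_i(b)* over a belief space *b ∈ [−1, 1]*,
discretised to 200 equally spaced values {−0.995, −0.985, …, 0.995}, and
carries a fixed binary social identity (red/blue, groups of equal size).
Agents sit on a fixed undirected network built from two coupled ring
lattices: each agent links to its *k_in* nearest in-group neighbours and to
the *k_out* circularly closest out-group agents; every link is then rewired
with probability *p* (Watts–Strogatz style in-group, endpoint re-targeting
out-group), which preserves the in-/out-group link counts.  *p → 0* gives a
highly clustered, regular topology; *p → 1* a highly random one.

Each time step visits all agents in random order.  With probability *q* a
visited agent (listener *i*) observes a random neighbour (messenger *j*)
through a perception filter

    p_i(x_j) = α · x_j + (1 − α) · U,        α = α_in or α_out,

where *U* is the uniform distribution and *α* is the filter transparency —
higher for in-group messengers when agents are biased (α_in > α_out).  The
listener's opinion becomes the Bayesian posterior

    x_i ← x_i · p_i(x_j) / Σ_b x_i · p_i(x_j).

With probability 1 − *q* the agent does not interact and its opinion
broadens by one implicit (backward-Euler) step of the heat equation
∂x/∂t = κ ∂²x/∂b² with zero Dirichlet boundaries, modelling fading
conviction.  Disagreement is measured by σ, the population standard
deviation of the agents' mean opinions; a run reaches consensus when
σ < σ_cons = 0.01, and the consensus frequency C_t is the fraction of
ensemble runs reaching consensus by step *t*.

The headline phenomenon: in-group bias *impedes* consensus on highly random
networks (it stabilises identity-aligned echo chambers) but *fosters*
consensus on highly clustered networks (it aligns dispersed in-group agents
before isolated local clusters can solidify).

## Worked example

```python
from opinionet import SCENARIOS, SimulationConfig, run_ensemble, run_simulation

# one biased society on a highly random network
cfg = SCENARIOS["B"].apply(SimulationConfig(p=1.0, seed=7))
res = run_simulation(cfg)
print(res.sigma[0], res.consensus_step)
# 0.5026...  None     <- this seed keeps two echo chambers through t=5000

# consensus frequency over 50 replicates
summary = run_ensemble(cfg, reps=50, base_seed=42)
print(summary.consensus_frequency)
# 0.62   <- biased agents reach consensus far less often than unbiased
#           ones on the same random topology (compare scenario "U2": 0.94)
```

`res.sigma[0] ≈ 0.51` is the initial disagreement of a society whose opinion
means are spread uniformly over the belief space; `consensus_step=None`
means σ never fell below 0.01 within 5000 steps.  The ensemble frequency
0.62 (±0.07 binomial SE at 50 reps) is the model's central quantity C_5000.

The same experiments run from the shell:

```sh
opinionet simulate --scenario B --p 1 --seed 7 --out run/
opinionet ensemble --scenario U2 --p 0 --reps 200 --out ens/
opinionet network --n 100 --k-in 8 --k-out 2 --p 0 --out net/
opinionet sweep --grid grid.yaml --reps 200 --out sweep/
```

Every invocation writes a `manifest.json` (config, seed, code version,
SHA-256 of each output) from which the run reproduces bit-identically.

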