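"""Society initialisation and the asynchronous opinion-update loop.

One simulation step visits all ``n`` agents in a fresh uniform random
permutation.  With probability ``q`` a visited agent (the listener)
interacts: it picks one of its network neighbours uniformly (the messenger)
and performs the Bayesian social update through the in-group or out-group
perception filter, reading the messenger's *current* opinion — later
listeners in the permutation see earlier updates.  Otherwise the agent's
opinion broadens by one implicit diffusion step.  Identities and the network
are fixed for the whole run.

Randomness contract
-------------------
Per step, exactly one permutation of size ``n`` plus ``n`` interaction
uniforms plus ``n`` neighbour-choice uniforms are drawn, in that order,
regardless of which branch each agent takes.  The pure-Python ``step`` path
and the compiled kernel used by ``run_simulation`` therefore consume the
same stream and produce the same trajectory (up to float summation order).

Seeding: ``SeedSequence(config.seed)`` is split into an initialisation
stream (network rewiring, then initial opinions) and an update stream, so
changing ``t_max`` never changes the network or the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import opinions as op
from ._kernel import simulate_kernel, thomas_coefficients
from .network import SocialNetwork, build_homophilic_lattice, rewire

__all__ = [
    "SimulationConfig",
    "SocietyState",
    "SimulationResult",
    "sample_initial_means",
    "init_society",
    "step",
    "run_simulation",
]


class SimulationConfig(BaseModel):
    """Every model parameter plus the RNG seed; single source of truth.

    Defaults are the standard study conditions: a society of 100 agents on a
    moderately homophilic network (k_in=8, k_out=2), interaction probability
    q=0.2, diffusion speed kappa=0.0002, initial opinion spread sigma0=0.2,
    no predisposition, 5000 steps, consensus threshold 0.01.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n: int = Field(default=100, ge=1)
    k_in: int = Field(default=8, ge=0)
    k_out: int = Field(default=2, ge=0)
    p: float = Field(default=1.0, ge=0.0, le=1.0)
    q: float = Field(default=0.2, ge=0.0, le=1.0)
    kappa: float = Field(default=0.0002, ge=0.0)
    sigma0: float = Field(default=0.2, gt=0.0)
    delta: float = Field(default=0.0, ge=0.0, le=1.0)
    alpha_in: float = Field(default=0.5, ge=0.0, le=op.ALPHA_MAX)
    alpha_out: float = Field(default=0.5, ge=0.0, le=op.ALPHA_MAX)
    t_max: int = Field(default=5000, ge=0)
    sigma_cons: float = Field(default=0.01, gt=0.0)
    seed: int = Field(default=0, ge=0)
    record_stride: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _check_degrees(self) -> "SimulationConfig":
        if self.n == 1:
            if self.k_in or self.k_out:
                raise ValueError("n=1 requires k_in=k_out=0")
            return self
        if self.n % 2 != 0:
            raise ValueError("n must be even (two equal identity groups)")
        if self.k_in >= self.n // 2:
            raise ValueError("k_in must be smaller than the group size n/2")
        if self.k_out > self.n // 2:
            raise ValueError("k_out cannot exceed the group size n/2")
        return self

    @property
    def biased(self) -> bool:
        return self.alpha_in > self.alpha_out


@dataclass
class SocietyState:
    """Mutable state of a running simulation."""

    time: int
    network: SocialNetwork
    opinions: np.ndarray  # (n, 200) row-normalised masses
    identities: np.ndarray  # (n,) int8
    grid: op.BeliefGrid = field(default_factory=op.make_belief_grid)

    @property
    def n(self) -> int:
        return self.opinions.shape[0]

    def mean_opinions(self) -> np.ndarray:
        return self.opinions @ self.grid.points


@dataclass
class SimulationResult:
    """Trajectory of one run.

    ``sigma`` holds the disagreement (population SD of mean opinions) at
    steps 0..steps_run; ``mean_trajectory`` holds per-agent mean opinions at
    the steps in ``record_steps`` (thinned by ``config.record_stride``).
    ``consensus_step`` is the first step with sigma < sigma_cons, or None.
    """

    config: SimulationConfig
    sigma: np.ndarray
    record_steps: np.ndarray
    mean_trajectory: np.ndarray
    consensus_step: int | None
    steps_run: int
    final_state: SocietyState | None = None


def sample_initial_means(
    n: int,
    identities: np.ndarray,
    delta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial opinion means, optionally predisposed by identity.

    With predisposition ``delta``, a red agent draws a negative mean (from
    Uniform[-1, 0)) with probability 0.5 + delta/2 and a positive one (from
    Uniform[0, 1]) otherwise; blue agents are symmetric (negative with
    probability 0.5 - delta/2).  delta = 0 recovers Uniform[-1, 1]
    independent of identity.  Two uniforms are drawn per agent regardless of
    delta, keeping the stream layout fixed.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    identities = np.asarray(identities)
    p_negative = np.where(identities == 0, 0.5 + delta / 2.0, 0.5 - delta / 2.0)
    u_sign = rng.random(n)
    magnitude = rng.random(n)
    return np.where(u_sign < p_negative, -magnitude, magnitude)


def init_society(
    config: SimulationConfig, rng: np.random.Generator
) -> SocietyState:
    """Build the network and initial truncated-Gaussian opinions.

    Consumes the stream in a fixed order: network rewiring first, then
    initial means — so two configs differing only in opinion parameters
    share the same topology for the same stream.
    """
    grid = op.make_belief_grid()
    lattice = build_homophilic_lattice(config.n, config.k_in, config.k_out)
    net = rewire(lattice, config.p, rng)
    mus = sample_initial_means(config.n, net.identity, config.delta, rng)
    x = np.empty((config.n, grid.n_points))
    for i in range(config.n):
        x[i] = op.truncated_gaussian_opinion(float(mus[i]), config.sigma0, grid)
    return SocietyState(
        time=0,
        network=net,
        opinions=x,
        identities=net.identity.copy(),
        grid=grid,
    )


def draw_step_randomness(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one step's randomness: (visit order, interaction u, neighbour u)."""
    perm = rng.permutation(n).astype(np.int32)
    u_interact = rng.random(n)
    u_neighbor = rng.random(n)
    return perm, u_interact, u_neighbor


def _apply_step_python(
    state: SocietyState,
    config: SimulationConfig,
    perm: np.ndarray,
    u_interact: np.ndarray,
    u_neighbor: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
) -> None:
    """Reference implementation of one asynchronous step (in place)."""
    x = state.opinions
    grid = state.grid
    for pos, i in enumerate(perm):
        i = int(i)
        deg = int(indptr[i + 1] - indptr[i])
        if u_interact[pos] < config.q and deg > 0:
            j = int(indices[indptr[i] + int(u_neighbor[pos] * deg)])
            alpha = (
                config.alpha_in
                if state.identities[i] == state.identities[j]
                else config.alpha_out
            )
            x[i] = op.social_update(x[i], x[j], alpha, grid)
        else:
            x[i] = op.diffuse_step(x[i], config.kappa, grid)
    state.time += 1


def step(
    state: SocietyState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SocietyState:
    """Advance the society by one step (mutates and returns ``state``)."""
    perm, u_i, u_n = draw_step_randomness(rng, state.n)
    indptr, indices = state.network.adjacency_csr()
    _apply_step_python(state, config, perm, u_i, u_n, indptr, indices)
    return state


def _population_sd(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def run_simulation(
    config: SimulationConfig,
    *,
    engine: str = "numba",
    stop_at_consensus: bool = False,
    record_means: bool = True,
    keep_final_state: bool = False,
) -> SimulationResult:
    """Run one full simulation of ``config.t_max`` steps.

    Reproducible: one seed drives network topology, initial opinions and
    update order.  ``engine='numba'`` uses the compiled kernel (default);
    ``engine='python'`` uses the reference step loop.  With
    ``stop_at_consensus`` the run halts at the first step where the
    disagreement sigma drops below ``config.sigma_cons`` (first passage is
    what the consensus frequency counts, so this does not change it).
    """
    if engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    root = np.random.SeedSequence(config.seed)
    ss_init, ss_update = root.spawn(2)
    state = init_society(config, np.random.default_rng(ss_init))
    rng_upd = np.random.default_rng(ss_update)
    indptr, indices = state.network.adjacency_csr()
    n, t_max, stride = config.n, config.t_max, config.record_stride

    n_records = t_max // stride + 1 if record_means else 0
    means_out = np.empty((n_records, n))
    sigma_out = np.empty(t_max + 1)

    if engine == "numba":
        perms = np.empty((t_max, n), dtype=np.int32)
        u_int = np.empty((t_max, n))
        u_nb = np.empty((t_max, n))
        for t in range(t_max):
            perms[t], u_int[t], u_nb[t] = draw_step_randomness(rng_upd, n)
        r = config.kappa / state.grid.spacing**2
        cp, inv_denom = thomas_coefficients(r, state.grid.n_points)
        steps_run, cons = simulate_kernel(
            state.opinions,
            np.asarray(state.grid.points),
            state.identities,
            indptr,
            indices,
            config.alpha_in,
            config.alpha_out,
            config.q,
            r,
            cp,
            inv_denom,
            perms,
            u_int,
            u_nb,
            config.sigma_cons,
            stop_at_consensus,
            sigma_out,
            means_out,
            stride,
        )
        state.time = steps_run
    else:
        means = state.mean_opinions()
        sigma_out[0] = _population_sd(means)
        if record_means:
            means_out[0] = means
        cons = 0 if sigma_out[0] < config.sigma_cons else -1
        steps_run = 0
        if not (stop_at_consensus and cons == 0):
            for t in range(t_max):
                perm, u_i, u_n = draw_step_randomness(rng_upd, n)
                _apply_step_python(
                    state, config, perm, u_i, u_n, indptr, indices
                )
                means = state.mean_opinions()
                sigma_out[t + 1] = _population_sd(means)
                if record_means and (t + 1) % stride == 0:
                    means_out[(t + 1) // stride] = means
                steps_run = t + 1
                if cons < 0 and sigma_out[t + 1] < config.sigma_cons:
                    cons = t + 1
                    if stop_at_consensus:
                        break

    sigma = sigma_out[: steps_run + 1].copy()
    if record_means:
        last_row = steps_run // stride
        record_steps = np.arange(0, (last_row + 1) * stride, stride)
        means_traj = means_out[: last_row + 1].copy()
    else:
        record_steps = np.empty(0, dtype=int)
        means_traj = np.empty((0, n))
    return SimulationResult(
        config=config,
        sigma=sigma,
        record_steps=record_steps,
        mean_trajectory=means_traj,
        consensus_step=None if cons < 0 else int(cons),
        steps_run=int(steps_run),
        final_state=state if keep_final_state else None,
    )
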