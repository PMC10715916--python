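"""Consensus metrics, ensembles, named scenarios and parameter sweeps.

Disagreement is the population standard deviation sigma of all agents' mean
opinions; a run reaches consensus at the first step where sigma drops
strictly below the threshold sigma_cons.  The consensus frequency C_t is the
fraction of ensemble runs whose first passage is at or before step t.

Four named perception scenarios are compared throughout: societies of
unbiased agents that are skeptical (U1), neutral (U2) or credulous (U3)
towards everyone, and a biased society (B) that is credulous towards the
in-group and skeptical towards the out-group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, SocietyState, run_simulation

__all__ = [
    "Scenario",
    "SCENARIOS",
    "EnsembleSummary",
    "disagreement",
    "detect_consensus",
    "derive_run_seed",
    "run_ensemble",
    "sweep",
]


@dataclass(frozen=True)
class Scenario:
    """A named (alpha_in, alpha_out) perception setting."""

    name: str
    alpha_in: float
    alpha_out: float

    @property
    def biased(self) -> bool:
        return self.alpha_in > self.alpha_out

    def apply(self, config: SimulationConfig) -> SimulationConfig:
        return config.model_copy(
            update={"alpha_in": self.alpha_in, "alpha_out": self.alpha_out}
        )


SCENARIOS: dict[str, Scenario] = {
    "U1": Scenario("U1", 0.25, 0.25),  # unbiased, skeptical
    "U2": Scenario("U2", 0.50, 0.50),  # unbiased, neutral
    "U3": Scenario("U3", 0.75, 0.75),  # unbiased, credulous
    "B": Scenario("B", 0.75, 0.25),  # in-group credulous, out-group skeptical
}


def disagreement(state: SocietyState) -> float:
    """Population SD of the per-agent mean opinions."""
    means = state.mean_opinions()
    return float(np.sqrt(np.mean((means - means.mean()) ** 2)))


def detect_consensus(sigma_series, sigma_cons: float) -> int | None:
    """First index with sigma strictly below the threshold, or None."""
    if sigma_cons <= 0:
        raise ValueError(f"sigma_cons must be positive, got {sigma_cons}")
    below = np.asarray(sigma_series) < sigma_cons
    idx = np.flatnonzero(below)
    return int(idx[0]) if idx.size else None


def derive_run_seed(base_seed: int, run_index: int) -> int:
    """Counter-based per-run seed: hash of (base_seed, run_index), < 2^31.

    Order-independent and extensible: adding replicates never changes the
    seeds of existing ones.
    """
    ss = np.random.SeedSequence([int(base_seed), int(run_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class EnsembleSummary:
    """Per-run consensus times and the consensus frequency of an ensemble.

    ``consensus_times[i]`` is the first-passage step of run i, or None if
    the run never reached consensus within t_max.
    """

    reps: int
    consensus_times: list[int | None]
    config: SimulationConfig
    base_seed: int

    @property
    def consensus_count(self) -> int:
        return sum(t is not None for t in self.consensus_times)

    @property
    def consensus_frequency(self) -> float:
        """C_{t_max}: fraction of runs reaching consensus within the run."""
        return self.consensus_count / self.reps

    def frequency_at(self, t: int) -> float:
        """C_t for t <= t_max; non-decreasing in t."""
        hits = sum(ct is not None and ct <= t for ct in self.consensus_times)
        return hits / self.reps


def run_ensemble(
    config: SimulationConfig,
    reps: int,
    base_seed: int,
    *,
    engine: str = "numba",
) -> EnsembleSummary:
    """Run ``reps`` independent realisations and collect consensus times.

    Run i uses the seed ``derive_run_seed(base_seed, i)``; results are
    identical however the runs are scheduled.  Runs halt at first passage
    (consensus is near-absorbing under purely assimilative influence, and
    C_t counts first passage), which only saves time.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    times: list[int | None] = []
    for i in range(reps):
        cfg = config.model_copy(update={"seed": derive_run_seed(base_seed, i)})
        result = run_simulation(
            cfg,
            engine=engine,
            stop_at_consensus=True,
            record_means=False,
        )
        times.append(result.consensus_step)
    return EnsembleSummary(
        reps=reps, consensus_times=times, config=config, base_seed=base_seed
    )


_SWEEP_COLUMNS = [
    "p",
    "alpha_in",
    "alpha_out",
    "k_in",
    "k_out",
    "delta",
    "n",
    "q",
    "kappa",
    "sigma0",
    "t",
    "reps",
    "consensus_count",
    "C_t",
]


def sweep(
    grid: list[dict],
    reps: int,
    base_seed: int,
    *,
    base_config: SimulationConfig | None = None,
    engine: str = "numba",
) -> pd.DataFrame:
    """Run one ensemble per grid point and tabulate consensus frequencies.

    Each grid point is a dict of :class:`SimulationConfig` overrides (a
    ``scenario`` key expands to the named alpha pair).  Every point uses the
    same ``base_seed`` (common random numbers across points), so a
    single-point sweep reproduces ``run_ensemble`` exactly.
    """
    base = base_config or SimulationConfig()
    rows = []
    for point in grid:
        point = dict(point)
        scenario = point.pop("scenario", None)
        cfg = base.model_copy(update=point) if point else base
        if scenario is not None:
            cfg = SCENARIOS[str(scenario)].apply(cfg)
        summary = run_ensemble(cfg, reps, base_seed, engine=engine)
        rows.append(
            {
                "p": cfg.p,
                "alpha_in": cfg.alpha_in,
                "alpha_out": cfg.alpha_out,
                "k_in": cfg.k_in,
                "k_out": cfg.k_out,
                "delta": cfg.delta,
                "n": cfg.n,
                "q": cfg.q,
                "kappa": cfg.kappa,
                "sigma0": cfg.sigma0,
                "t": cfg.t_max,
                "reps": reps,
                "consensus_count": summary.consensus_count,
                "C_t": summary.consensus_frequency,
            }
        )
    return pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
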