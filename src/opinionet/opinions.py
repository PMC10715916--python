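"""Belief-space discretisation and opinion-distribution operations.

An agent's opinion is a probability mass function on a fixed grid of 200
belief values in (-1, 1).  Social influence multiplies the listener's opinion
pointwise with a filtered ("perceived") version of the messenger's opinion and
renormalises — a Bayesian update with the listener's opinion as prior and the
perceived opinion as likelihood.  Non-interaction broadens an opinion by one
implicit (backward-Euler) step of the heat equation with zero Dirichlet
boundaries just outside the grid.

Distributions are plain 1-D numpy arrays of masses summing to 1; the module
functions validate and preserve that invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "N_POINTS",
    "NORM_TOL",
    "ALPHA_MAX",
    "BeliefGrid",
    "make_belief_grid",
    "truncated_gaussian_opinion",
    "opinion_moments",
    "perceive",
    "social_update",
    "diffuse_step",
]

#: number of discrete belief values
N_POINTS = 200

#: tolerance to which masses must sum to 1 after every public operation
NORM_TOL = 1e-12

#: upper cap on the perception parameter; alpha = 1 would allow the posterior
#: mass to vanish when prior and likelihood have disjoint support
ALPHA_MAX = 0.99

_BELIEF_MIN = -1.0
_BELIEF_MAX = 1.0


@dataclass(frozen=True)
class BeliefGrid:
    """The discretised belief space shared by all opinion distributions.

    Attributes
    ----------
    points
        Grid of belief values, strictly increasing, symmetric about 0:
        {-0.995, -0.985, ..., 0.995}.
    spacing
        Distance between adjacent points (0.01).
    uniform_reference
        The uniform distribution U on the grid (mass 1/200 per point).
    """

    points: np.ndarray
    spacing: float
    uniform_reference: np.ndarray

    @property
    def n_points(self) -> int:
        return self.points.size


def make_belief_grid() -> BeliefGrid:
    """Return the canonical 200-point belief grid on (-1, 1).

    Points are bin centres -1 + Δb·(i + 1/2) with Δb = 0.01, i.e.
    {-0.995, -0.985, ..., 0.995}.
    """
    spacing = (_BELIEF_MAX - _BELIEF_MIN) / N_POINTS
    points = _BELIEF_MIN + spacing * (np.arange(N_POINTS) + 0.5)
    uniform = np.full(N_POINTS, 1.0 / N_POINTS)
    points.setflags(write=False)
    uniform.setflags(write=False)
    return BeliefGrid(points=points, spacing=spacing, uniform_reference=uniform)


def _validate_distribution(x: np.ndarray, grid: BeliefGrid) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape != grid.points.shape:
        raise ValueError(
            f"distribution has shape {x.shape}, expected {grid.points.shape}"
        )
    return x


def truncated_gaussian_opinion(
    mu: float, sigma: float, grid: BeliefGrid
) -> np.ndarray:
    """Gaussian opinion N(mu, sigma) truncated to the belief grid.

    Masses are proportional to the normal density at the grid points and
    renormalised, so near the boundaries the realised mean is pulled inward
    relative to ``mu``.

    Parameters
    ----------
    mu
        Centre of the Gaussian, in [-1, 1].
    sigma
        Standard deviation of the Gaussian (> 0).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (_BELIEF_MIN <= mu <= _BELIEF_MAX):
        raise ValueError(f"mu must lie in [-1, 1], got {mu}")
    z = (grid.points - mu) / sigma
    mass = np.exp(-0.5 * z * z)
    return mass / mass.sum()


def opinion_moments(x: np.ndarray, grid: BeliefGrid) -> tuple[float, float]:
    """Mean and variance of an opinion distribution on the grid."""
    x = _validate_distribution(x, grid)
    mean = float(x @ grid.points)
    var = float(x @ (grid.points - mean) ** 2)
    return mean, var


def perceive(x_j: np.ndarray, alpha: float, grid: BeliefGrid) -> np.ndarray:
    """Filtered view of a messenger's opinion: alpha·x_j + (1-alpha)·U.

    ``alpha`` is the transparency of the perception filter: 0 yields the
    uniform reference (fully opaque — no information transmitted), values
    near 1 pass the messenger's opinion through nearly unchanged.
    """
    if not (0.0 <= alpha <= ALPHA_MAX):
        raise ValueError(f"alpha must lie in [0, {ALPHA_MAX}], got {alpha}")
    x_j = _validate_distribution(x_j, grid)
    return alpha * x_j + (1.0 - alpha) * grid.uniform_reference


def social_update(
    x_i: np.ndarray, x_j: np.ndarray, alpha: float, grid: BeliefGrid
) -> np.ndarray:
    """Bayesian update of listener ``x_i`` after observing messenger ``x_j``.

    The posterior is the pointwise product of the listener's prior with the
    perceived messenger opinion, renormalised.  Only the listener changes;
    ``x_j`` is not modified.
    """
    x_i = _validate_distribution(x_i, grid)
    posterior = x_i * perceive(x_j, alpha, grid)
    total = posterior.sum()
    if total < 1e-300:
        # cannot occur for alpha <= 0.99 with normalised inputs
        raise FloatingPointError("posterior mass underflow in social_update")
    return posterior / total


def diffuse_step(x: np.ndarray, kappa: float, grid: BeliefGrid) -> np.ndarray:
    """One implicit diffusion step broadening an opinion distribution.

    Solves ``(I - r·L)·x_new = x`` with ``r = kappa·Δt/Δb²`` (Δt = 1 step) and
    L the second-difference operator with zero Dirichlet values at ghost
    points one spacing outside the grid.  Dirichlet boundaries leak mass, so
    the solution is renormalised to remain a probability distribution.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    x = _validate_distribution(x, grid)
    if kappa == 0:
        return x.copy()
    m = grid.n_points
    r = kappa / grid.spacing**2
    ab = np.zeros((3, m))
    ab[0, 1:] = -r
    ab[1, :] = 1.0 + 2.0 * r
    ab[2, :-1] = -r
    y = solve_banded((1, 1), ab, x)
    return y / y.sum()
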