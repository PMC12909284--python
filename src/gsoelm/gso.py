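"""Glowworm swarm optimization over a continuous search space.

Each agent carries a position s in R^d, a luciferin level l (a decayed
running combination of past brightness and current fitness) and an adaptive
neighborhood radius r.  Per iteration every agent's objective is evaluated
once, luciferin is updated as

    l(t+1) = (1 - rho) l(t) + gamma J(t),

agents probabilistically follow a strictly brighter neighbor within their
radius (probability proportional to luciferin excess), take a step of length
beta toward it plus small uniform noise, and adapt their radius toward a
desired neighbor count n_t.  An agent with no brighter neighbor takes a pure
noise step.  Convergence practice: the best positions are retained across
iterations (elitism), the step size anneals linearly from beta to beta/3
over the iteration budget, and the search stops early after ``patience``
iterations without improvement of the best objective.

For feature selection, positions decode to binary masks by a sigmoid
transfer with a strict threshold: mask_j = 1 iff sigma(s_j) > tau.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .elm import sigmoid

logger = logging.getLogger("gsoelm.gso")


@dataclass
class SwarmConfig:
    """All swarm constants, with practitioner-range defaults.

    G agents for T_max iterations; luciferin decay rho in (0,1) and gain
    gamma; movement step beta_step annealed to a third of itself; radius
    dynamics (r0, r_s, alpha_r, desired neighbor count n_t); uniform noise
    amplitude eps_scale; mask threshold tau; early-stopping patience; number
    of elite positions retained.  r0 defaults to 0.1*sqrt(d) (the diagonal
    of the normalized search space scales with sqrt(d)).
    """

    G: int = 20
    T_max: int = 50
    rho: float = 0.4
    gamma: float = 0.6
    beta_step: float = 0.1
    r0: float | None = None
    r_s: float = 1.0
    alpha_r: float = 0.05
    n_t: int = 5
    eps_scale: float = 0.01
    tau: float = 0.5
    patience: int | None = 20
    elite_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if self.gamma <= 0 or self.beta_step <= 0:
            raise ValueError("gamma and beta_step must be positive")
        if self.r0 is not None and not 0 <= self.r0 <= self.r_s:
            raise ValueError("r0 must lie in [0, r_s]")
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")


def position_to_mask(s: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binary mask m_j = 1 iff sigma(s_j) > tau (strict, as defined)."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return (sigmoid(np.asarray(s, dtype=float)) > tau).astype(int)


def luciferin_update(l: float | np.ndarray, J: float | np.ndarray,
                     rho: float, gamma: float) -> float | np.ndarray:
    """l' = (1 - rho) l + gamma J; fixed point gamma J / rho under constant J."""
    return (1.0 - rho) * l + gamma * J


def neighbors(i: int, positions: np.ndarray, luciferins: np.ndarray,
              r_i: float) -> np.ndarray:
    """Indices j != i within Euclidean distance r_i that are strictly brighter."""
    d = np.linalg.norm(positions - positions[i], axis=1)
    mask = (d <= r_i) & (luciferins > luciferins[i])
    mask[i] = False
    return np.nonzero(mask)[0]


def move_probabilities(i: int, neighbor_idx: Sequence[int],
                       luciferins: np.ndarray) -> np.ndarray:
    """p_ij proportional to luciferin excess l_j - l_i over the neighbor set."""
    neighbor_idx = np.asarray(neighbor_idx, dtype=int)
    if neighbor_idx.size == 0:
        raise ValueError("neighbor set is empty")
    excess = luciferins[neighbor_idx] - luciferins[i]
    return excess / excess.sum()


def move(s_i: np.ndarray, s_j: np.ndarray, beta_step: float,
         eps: np.ndarray | None = None) -> np.ndarray:
    """Step of length beta_step toward s_j plus additive noise eps.

    Coincident positions skip the directed step and apply noise only.
    """
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if eps is None:
        eps = np.zeros_like(s_i)
    delta = s_j - s_i
    dist = np.linalg.norm(delta)
    if dist == 0:
        return s_i + eps
    return s_i + beta_step * delta / dist + eps


def radius_update(r_i: float, neighbor_count: int, n_t: int,
                  alpha_r: float, r_s: float) -> float:
    """Clamped linear radius adaptation toward the desired neighbor count."""
    return min(r_s, max(0.0, r_i + alpha_r * (n_t - neighbor_count)))


@dataclass
class SwarmTrace:
    """Per-iteration summary of a swarm run."""

    iterations: list[int]
    best_J: list[float]          # best-so-far (non-decreasing under elitism)
    mean_J: list[float]
    mean_neighbors: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": self.iterations,
            "best_J": self.best_J,
            "mean_J": self.mean_J,
            "mean_neighbors": self.mean_neighbors,
        })


def gso_optimize(
    objective: Callable[[np.ndarray], float],
    d: int,
    config: SwarmConfig,
) -> tuple[np.ndarray, float, SwarmTrace]:
    """Maximize ``objective`` over R^d with a glowworm swarm.

    Positions initialize uniformly on [-1, 1]^d (so sigmoid-decoded masks
    start diverse), luciferin at zero.  The objective is evaluated once per
    agent per iteration; non-finite values are treated as -inf fitness with
    a warning.  Returns the best position ever evaluated, its objective, and
    the iteration trace.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    G, T = config.G, config.T_max
    positions = rng.uniform(-1.0, 1.0, size=(G, d))
    lucif = np.zeros(G)
    r0 = config.r0 if config.r0 is not None else min(config.r_s, 0.1 * math.sqrt(d))
    radii = np.full(G, r0)

    # elite archive: list of (J, counter, position) kept to elite_count entries
    elite: list[tuple[float, int, np.ndarray]] = []
    counter = 0
    best_J = -np.inf
    best_pos = positions[0].copy()
    stagnant = 0
    trace = SwarmTrace([], [], [], [])

    for t in range(T):
        frac = t / max(T - 1, 1)
        beta_t = config.beta_step * (1.0 - (2.0 / 3.0) * frac)  # beta -> beta/3

        J = np.empty(G)
        for i in range(G):
            val = objective(positions[i])
            if not np.isfinite(val):
                logger.warning("non-finite objective at iteration %d, agent %d; using -inf", t, i)
                val = -np.inf
            J[i] = val

        improved = False
        for i in range(G):
            if J[i] > best_J:
                best_J = J[i]
                best_pos = positions[i].copy()
                improved = True
            counter += 1
            heapq.heappush(elite, (J[i], counter, positions[i].copy()))
            if len(elite) > max(config.elite_count, 1):
                heapq.heappop(elite)

        lucif = luciferin_update(lucif, np.where(np.isfinite(J), J, 0.0), config.rho, config.gamma)

        new_positions = positions.copy()
        counts = np.zeros(G, dtype=int)
        for i in range(G):
            nbrs = neighbors(i, positions, lucif, radii[i])
            counts[i] = len(nbrs)
            eps = rng.uniform(-config.eps_scale, config.eps_scale, size=d)
            if len(nbrs) == 0:
                new_positions[i] = positions[i] + eps  # pure noise step
            else:
                probs = move_probabilities(i, nbrs, lucif)
                j = nbrs[rng.choice(len(nbrs), p=probs)]
                new_positions[i] = move(positions[i], positions[j], beta_t, eps)
            radii[i] = radius_update(radii[i], counts[i], config.n_t,
                                     config.alpha_r, config.r_s)
        positions = new_positions

        trace.iterations.append(t)
        trace.best_J.append(best_J)
        trace.mean_J.append(float(np.mean(np.where(np.isfinite(J), J, np.nan))))
        trace.mean_neighbors.append(float(counts.mean()))

        stagnant = 0 if improved else stagnant + 1
        if config.patience is not None and stagnant >= config.patience:
            logger.info("early stop at iteration %d after %d stagnant iterations", t, stagnant)
            break

    return best_pos, float(best_J), trace
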