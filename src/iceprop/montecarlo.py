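"""Stochastic simulation of ice formation and propagation on tissues.

Two samplers draw freeze-time trajectories of the non-dimensional model
(unfrozen cell j freezes at rate 1 + k_j*alpha):

* ``run_fixed_step`` — synchronous discrete-tau chain with per-step freeze
  probability (1 + k_j alpha) dtau and the step-size rule
  dtau = epsilon / ((1 + n alpha) N), which bounds the probability of any
  IIF event per step by epsilon;
* ``run_gillespie`` — exact event-driven sampling via exponential waiting
  times, statistically equivalent to the fixed-step chain as epsilon -> 0
  and to the master equation of :mod:`iceprop.markov`.

Replicates use independent, order-independent RNG streams derived from
(rng_seed, replicate index), so runs are reproducible bit-for-bit and
trivially parallelizable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ContactGraph, Tissue
from .markov import StateClass

__all__ = [
    "MCConfig",
    "FreezeLog",
    "FreezeEnsemble",
    "compute_dtau",
    "n_steps",
    "step_probability",
    "run_fixed_step",
    "run_gillespie",
    "run",
    "aggregate",
    "class_probabilities",
    "all_frozen_curve",
]


class MonteCarloError(ValueError):
    """Invalid Monte Carlo configuration or state."""


class StepSizeError(MonteCarloError):
    """The discretized per-step freeze probability reached 1."""


@dataclass(frozen=True)
class MCConfig:
    """Stochastic-simulation configuration.

    ``n_max`` overrides the maximum neighbour count n of the step-size rule;
    by default n is the maximum degree of the supplied contact graph.
    """

    alpha: float
    epsilon: float = 0.05
    n_max: int | None = None
    tau_max: float = 1.0
    replicates: int = 1
    rng_seed: int = 0
    method: str = "gillespie"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise MonteCarloError("alpha must be nonnegative")
        if not 0 < self.epsilon <= 0.1:
            raise MonteCarloError("epsilon must lie in (0, 0.1]")
        if self.replicates < 1:
            raise MonteCarloError("replicates must be >= 1")
        if self.tau_max <= 0:
            raise MonteCarloError("tau_max must be positive")
        if self.method not in ("fixed_step", "gillespie"):
            raise MonteCarloError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class FreezeLog:
    """Ordered freeze events (cell id, tau) of one replicate.

    Pre-frozen seed cells are not events; a cell appears at most once.
    """

    events: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        taus = [tau for _c, tau in self.events]
        if any(b < a for a, b in zip(taus, taus[1:])):
            raise MonteCarloError("freeze times must be nondecreasing")
        cells = [c for c, _t in self.events]
        if len(set(cells)) != len(cells):
            raise MonteCarloError("a cell may freeze at most once")


@dataclass
class FreezeEnsemble:
    """Freeze times of all replicates: shape (replicates, N), inf = never froze.

    Seed cells carry tau = 0.  ``logs()`` reconstructs the per-replicate
    event lists.
    """

    freeze_tau: np.ndarray
    seeds: np.ndarray            # (N,) bool
    config: MCConfig
    graph: ContactGraph

    @property
    def replicates(self) -> int:
        return self.freeze_tau.shape[0]

    @property
    def n_cells(self) -> int:
        return self.freeze_tau.shape[1]

    def logs(self) -> list[FreezeLog]:
        out = []
        for row in self.freeze_tau:
            ev = [
                (int(c), float(row[c]))
                for c in np.argsort(row, kind="stable")
                if np.isfinite(row[c]) and not self.seeds[c]
            ]
            ev.sort(key=lambda e: e[1])
            out.append(FreezeLog(tuple(ev)))
        return out

    def frozen_at(self, tau: float) -> np.ndarray:
        """(replicates, N) boolean frozen state at clock value tau."""
        return self.freeze_tau <= tau

    def to_frame(self, tau_map=None) -> pd.DataFrame:
        """Event table (replicate, cell_id, tau, t, T); t/T blank in pure-tau runs."""
        rows = []
        for rep in range(self.replicates):
            row = self.freeze_tau[rep]
            for c in np.nonzero(np.isfinite(row) & ~self.seeds)[0]:
                rows.append((rep, int(c), float(row[c])))
        df = pd.DataFrame(rows, columns=["replicate", "cell_id", "tau"])
        if tau_map is not None:
            df["t"] = tau_map.t_at_tau(df["tau"].to_numpy())
            df["T"] = tau_map.T_at_tau(df["tau"].to_numpy())
        else:
            df["t"] = np.nan
            df["T"] = np.nan
        return df


def _graph_of(tissue: Tissue | ContactGraph) -> tuple[ContactGraph, np.ndarray]:
    if isinstance(tissue, ContactGraph):
        return tissue, np.zeros(tissue.N, dtype=bool)
    if tissue.graph is None:
        raise MonteCarloError("tissue has no contact graph; call Tissue.with_graph first")
    return tissue.graph, tissue.frozen0


def compute_dtau(config: MCConfig, N: int, n: int | None = None) -> float:
    """Step size dtau = epsilon / ((1 + n alpha) N).

    ``n`` is the maximum neighbour count; ``config.n_max`` takes precedence.
    """
    if N < 1:
        raise MonteCarloError("N must be >= 1")
    if config.n_max is not None:
        n = config.n_max
    if n is None:
        raise MonteCarloError("maximum neighbour count n is required (set n_max or pass n)")
    return config.epsilon / ((1.0 + n * config.alpha) * N)


def n_steps(config: MCConfig, N: int, n: int | None = None) -> int:
    """Number of fixed steps covering [0, tau_max] at the dtau of Eq. dtau-rule.

    ceil(tau_max/dtau) with a small tolerance so exact ratios (e.g. the
    1744-step 2x2 validation) are not perturbed by floating point.
    """
    dtau = compute_dtau(config, N, n=n)
    return int(math.ceil(config.tau_max / dtau - 1e-9))


def step_probability(k_frozen_neighbours: int, alpha: float, dtau: float) -> float:
    """Per-step freeze probability (1 + k alpha) dtau, clamped to [0, 1]."""
    p = (1.0 + k_frozen_neighbours * alpha) * dtau
    if p >= 1.0:
        raise StepSizeError(
            f"per-step probability {p:.3g} >= 1; decrease epsilon (dtau={dtau:.3g})"
        )
    return max(p, 0.0)


def run_fixed_step(tissue: Tissue | ContactGraph, config: MCConfig) -> FreezeEnsemble:
    """Synchronous fixed-step Monte Carlo.

    Each step, every unfrozen cell freezes independently with probability
    (1 + k alpha) dtau computed from the start-of-step neighbour counts, so
    several cells may freeze in one step but freezes do not cascade within
    it.  Frozen is absorbing.  Freeze times are recorded at the end of the
    step in which the event occurred.
    """
    graph, seeds = _graph_of(tissue)
    N = graph.N
    dtau = compute_dtau(config, N, n=graph.max_degree)
    # fail fast if the worst-case per-step probability could reach 1
    step_probability(graph.max_degree, config.alpha, dtau)
    steps_total = n_steps(config, N, n=graph.max_degree)
    adj = graph.adjacency()
    R = config.replicates
    freeze_step = np.full((R, N), -1, dtype=np.int64)  # -1 = never; seeds stay -1

    # replicate-major chunks bound memory; each replicate consumes its own stream
    block = 512
    max_doubles = int(2e7)
    chunk = max(1, min(R, max_doubles // max(1, block * N)))
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        gens = [np.random.default_rng([config.rng_seed, rep]) for rep in range(lo, hi)]
        frozen = np.broadcast_to(seeds, (hi - lo, N)).copy()
        fstep = freeze_step[lo:hi]
        step = 0
        while step < steps_total and not frozen.all():
            nb = min(block, steps_total - step)
            U = np.stack([g.random((nb, N)) for g in gens])  # (chunk, nb, N)
            for b in range(nb):
                k = frozen @ adj
                p = (1.0 + k * config.alpha) * dtau
                new = (~frozen) & (U[:, b, :] < p)
                if new.any():
                    rr, cc = np.nonzero(new)
                    fstep[rr, cc] = step + 1
                    frozen[rr, cc] = True
                step += 1
                if frozen.all():
                    break

    freeze_tau = np.where(freeze_step >= 0, (freeze_step) * dtau, np.inf)
    freeze_tau[:, seeds] = 0.0
    return FreezeEnsemble(freeze_tau=freeze_tau, seeds=seeds.copy(), config=config, graph=graph)


def run_gillespie(tissue: Tissue | ContactGraph, config: MCConfig) -> FreezeEnsemble:
    """Exact event-driven (Gillespie) sampling of the freeze process.

    The total rate is Lambda = sum over unfrozen cells of (1 + k_j alpha);
    waiting times are Exponential(Lambda) and the freezing cell is chosen
    proportionally to its rate.
    """
    graph, seeds = _graph_of(tissue)
    N = graph.N
    nbrs = [np.fromiter(s, dtype=np.int64) for s in graph.neighbour_sets()]
    R = config.replicates
    freeze_tau = np.full((R, N), np.inf)
    freeze_tau[:, seeds] = 0.0

    for rep in range(R):
        rng = np.random.default_rng([config.rng_seed, rep])
        frozen = seeds.copy()
        k = np.zeros(N)
        for c in np.nonzero(seeds)[0]:
            k[nbrs[c]] += 1.0
        rates = np.where(frozen, 0.0, 1.0 + k * config.alpha)
        total = rates.sum()
        tau = 0.0
        while total > 0.0:
            tau += rng.exponential(1.0 / total)
            if tau > config.tau_max:
                break
            j = rng.choice(N, p=rates / total)
            frozen[j] = True
            freeze_tau[rep, j] = tau
            rates[j] = 0.0
            for m in nbrs[j]:
                if not frozen[m]:
                    rates[m] += config.alpha
            total = rates.sum()
    return FreezeEnsemble(freeze_tau=freeze_tau, seeds=seeds.copy(), config=config, graph=graph)


def run(tissue: Tissue | ContactGraph, config: MCConfig) -> FreezeEnsemble:
    """Dispatch on ``config.method``."""
    fn = run_fixed_step if config.method == "fixed_step" else run_gillespie
    return fn(tissue, config)


def aggregate(ensemble: FreezeEnsemble, tau_grid: np.ndarray) -> pd.DataFrame:
    """Per-cell freeze-probability map over a tau grid.

    Returns a long-format table (tau, cell_id, p_frozen, stderr) where
    p_frozen is the fraction of replicates frozen by tau and stderr its
    binomial standard error sqrt(p(1-p)/R).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    R = ensemble.replicates
    rows = []
    for tau in tau_grid:
        p = ensemble.frozen_at(tau).mean(axis=0)
        se = np.sqrt(p * (1.0 - p) / R)
        for c in range(ensemble.n_cells):
            rows.append((tau, c, p[c], se[c]))
    return pd.DataFrame(rows, columns=["tau", "cell_id", "p_frozen", "stderr"])


def per_cell_probability(ensemble: FreezeEnsemble, tau_grid: np.ndarray) -> np.ndarray:
    """(len(tau_grid), N) matrix of per-cell freeze probabilities."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    return (ensemble.freeze_tau[None, :, :] <= tau_grid[:, None, None]).mean(axis=1)


def class_probabilities(
    ensemble: FreezeEnsemble, tau_grid: np.ndarray, classes: list[StateClass]
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical state-class probabilities and their binomial standard errors.

    Each replicate's frozen subset at tau is mapped to its symmetry class;
    returns (P, SE) of shape (len(tau_grid), n_classes).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    class_of = {m: c.index for c in classes for m in c.members}
    R = ensemble.replicates
    C = len(classes)
    P = np.zeros((len(tau_grid), C))
    for gi, tau in enumerate(tau_grid):
        frozen = ensemble.frozen_at(tau)
        for rep in range(R):
            subset = tuple(np.nonzero(frozen[rep])[0].tolist())
            P[gi, class_of[subset]] += 1.0
    P /= R
    SE = np.sqrt(P * (1.0 - P) / R)
    return P, SE


def all_frozen_curve(ensemble: FreezeEnsemble, tau_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(all cells frozen by tau) with binomial standard errors."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    last = ensemble.freeze_tau.max(axis=1)          # tau at which the last cell froze
    p = (last[None, :] <= tau_grid[:, None]).mean(axis=1)
    se = np.sqrt(p * (1.0 - p) / ensemble.replicates)
    return p, se
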