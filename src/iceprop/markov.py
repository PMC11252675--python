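"""Exact continuous-time Markov chain for ice propagation in small constructs.

The tissue state is the set of frozen cells; an unfrozen cell j freezes at
non-dimensional rate 1 + k_j*alpha, where k_j counts its frozen neighbours
and alpha = J_p/J_i is the propagation-to-nucleation rate ratio.  The raw
state space has 2^N states; graph symmetries partition it into orbit classes
on which the chain lumps exactly, and the master equation

    dP/dtau = P Q

is solved on the reduced space.  This module is the gold-standard oracle for
the Monte Carlo samplers in :mod:`iceprop.montecarlo`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .geometry import ContactGraph

__all__ = [
    "StateClass",
    "MarkovSystem",
    "enumerate_reduced_states",
    "build_generator",
    "build_markov_system",
    "solve_master_equation",
    "two_by_two_graph",
]

_ENUMERATION_LIMIT = 20
_EXPM_LIMIT_CELLS = 12


class MarkovError(ValueError):
    """Invalid Markov-system construction input."""


@dataclass(frozen=True)
class StateClass:
    """Orbit of frozen-cell subsets under the graph symmetry group."""

    index: int
    representative: tuple[int, ...]   # canonical (minimal sorted) member
    members: tuple[tuple[int, ...], ...]
    n_frozen: int

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class MarkovSystem:
    """Symmetry-reduced generator and initial condition for one construct."""

    graph: ContactGraph
    alpha: float
    classes: list[StateClass]
    Q: np.ndarray                 # (C, C) generator, rows sum to zero
    P0: np.ndarray                # (C,) initial probability over classes
    class_of: dict[frozenset, int]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def all_frozen_index(self) -> int:
        return self.class_of[frozenset(range(self.graph.N))]


def two_by_two_graph() -> ContactGraph:
    """The packaged 2x2 validation construct.

    Cells 0-1-2-3 sit on a square (cycle order); all pairs, including the
    diagonals, are neighbours, and the symmetry group is the dihedral group
    of the square (order 8).
    """
    edges = tuple((i, j) for i in range(4) for j in range(i + 1, 4))
    # dihedral-4 acting on the cycle 0-1-2-3
    rot = (1, 2, 3, 0)
    ref = (1, 0, 3, 2)
    group = set()
    perm = tuple(range(4))
    for _ in range(4):
        group.add(perm)
        group.add(tuple(ref[p] for p in perm))
        perm = tuple(rot[p] for p in perm)
    return ContactGraph(4, edges, tuple(sorted(group)))


def enumerate_reduced_states(graph: ContactGraph) -> list[StateClass]:
    """Partition the 2^N frozen-cell subsets into symmetry orbits.

    Classes are ordered by the number of frozen cells, then by canonical
    representative.  With an empty symmetry group every subset is its own
    class (no reduction).
    """
    n = graph.N
    if n > _ENUMERATION_LIMIT:
        raise MarkovError(f"full state enumeration limited to N <= {_ENUMERATION_LIMIT}")
    group = graph.symmetry_group or (tuple(range(n)),)
    seen: set[frozenset] = set()
    orbits: list[tuple[tuple[int, ...], list[frozenset]]] = []
    for bits in range(2**n):
        subset = frozenset(i for i in range(n) if bits >> i & 1)
        if subset in seen:
            continue
        orbit = {frozenset(perm[i] for i in subset) for perm in group}
        seen |= orbit
        members = sorted(tuple(sorted(s)) for s in orbit)
        orbits.append((members[0], [frozenset(m) for m in orbit]))
    orbits.sort(key=lambda o: (len(o[0]), o[0]))
    return [
        StateClass(
            index=idx,
            representative=rep,
            members=tuple(sorted(tuple(sorted(s)) for s in members)),
            n_frozen=len(rep),
        )
        for idx, (rep, members) in enumerate(orbits)
    ]


def build_generator(
    graph: ContactGraph, classes: list[StateClass], alpha: float
) -> np.ndarray:
    """Generator of the lumped chain in non-dimensional time.

    The off-diagonal rate from class C to class D is, for any representative
    subset S of C, the sum over unfrozen cells j with S u {j} in D of
    (1 + k_j(S) alpha); symmetry guarantees the sum is representative-
    independent (strong lumpability).  Diagonals make rows sum to zero.
    """
    if alpha < 0:
        raise MarkovError("alpha must be nonnegative")
    class_of = {frozenset(m): c.index for c in classes for m in c.members}
    nbrs = graph.neighbour_sets()
    C = len(classes)
    Q = np.zeros((C, C))
    for c in classes:
        S = frozenset(c.representative)
        for j in range(graph.N):
            if j in S:
                continue
            k = len(nbrs[j] & S)
            rate = 1.0 + k * alpha
            Q[c.index, class_of[S | {j}]] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def build_markov_system(
    graph: ContactGraph,
    alpha: float,
    initial_frozen: frozenset | set | tuple = (),
) -> MarkovSystem:
    """Assemble classes, generator and initial condition for one construct."""
    classes = enumerate_reduced_states(graph)
    Q = build_generator(graph, classes, alpha)
    class_of = {frozenset(m): c.index for c in classes for m in c.members}
    P0 = np.zeros(len(classes))
    P0[class_of[frozenset(initial_frozen)]] = 1.0
    return MarkovSystem(graph=graph, alpha=alpha, classes=classes, Q=Q, P0=P0, class_of=class_of)


def solve_master_equation(system: MarkovSystem, tau_grid: np.ndarray) -> np.ndarray:
    """Solve dP/dtau = P Q on the reduced space.

    Returns an array of shape (len(tau_grid), n_classes).  For constructs up
    to 12 cells the solution is the exact matrix exponential stepped between
    grid points; larger systems fall back to an adaptive ODE solver.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.ndim != 1 or np.any(np.diff(tau_grid) < 0) or np.any(tau_grid < 0):
        raise MarkovError("tau_grid must be 1-D, nonnegative and nondecreasing")
    Q = system.Q
    if system.graph.N <= _EXPM_LIMIT_CELLS:
        out = np.empty((len(tau_grid), system.n_classes))
        p = system.P0.copy()
        prev = 0.0
        for idx, tau in enumerate(tau_grid):
            dtau = tau - prev
            if dtau > 0:
                p = p @ expm(Q * dtau)
            prev = tau
            out[idx] = p
    else:
        sol = solve_ivp(
            lambda _t, p: p @ Q,
            (0.0, float(tau_grid[-1]) if len(tau_grid) else 0.0),
            system.P0,
            t_eval=tau_grid,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"master-equation integration failed: {sol.message}")
        out = sol.y.T
    out = np.clip(out, 0.0, 1.0)
    sums = out.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise RuntimeError("probability conservation violated beyond 1e-9")
    return out / sums[:, None]
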