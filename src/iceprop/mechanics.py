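"""Center-based intercellular mechanics with water-to-ice expansion.

Cells are spheres interacting along their centre line with a quadratic-ramp
repulsion inside membrane contact and a quadratic-ramp adhesion out to a
maximum adhesive reach, the standard center-based formulation.  Motion is
overdamped: velocity = net force / drag.  When a cell freezes, its residual
liquid water turns to ice with a 9% volume expansion and its volume is fixed
thereafter; the resulting pushes can sever adhesive contacts ("fissures"),
which :func:`detect_detachment` reports.

Default strengths: adhesion 30 pN, repulsion 750 pN, maximum adhesive reach
1.25 x the sum of radii (interpreted as the standard relative reach — an
absolute 1.25 um reach would be unreachable for non-overlapping 21 um
cells; an absolute mode is provided for sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MechParams",
    "MechState",
    "FissureReport",
    "freeze_expand",
    "pair_force",
    "net_forces",
    "step_positions",
    "detect_detachment",
    "radius_of_volume",
]

logger = logging.getLogger(__name__)


class MechanicsError(ValueError):
    """Invalid mechanics input or state."""


class StabilityError(RuntimeError):
    """Per-step displacement too large for the chosen time step."""


@dataclass(frozen=True)
class MechParams:
    """Center-based force-model parameters.

    c_adh/c_rep in pN; adh_reach is relative to the sum of radii (or an
    absolute reach in um when ``adh_mode="absolute"``); dt_mech in s; drag
    in pN s/um; expansion is the water-to-ice volume factor.
    """

    c_adh: float = 30.0
    c_rep: float = 750.0
    adh_reach: float = 1.25
    dt_mech: float = 1e-3
    drag: float = 1.0
    expansion: float = 1.09
    adh_mode: str = "relative"
    frozen_mobile: bool = True

    def __post_init__(self) -> None:
        for name in ("c_adh", "c_rep", "adh_reach", "dt_mech", "drag", "expansion"):
            if not getattr(self, name) > 0:
                raise MechanicsError(f"{name} must be positive")
        if self.adh_mode == "relative" and self.adh_reach < 1.0:
            raise MechanicsError("relative adhesive reach must be >= 1")
        if self.adh_mode not in ("relative", "absolute"):
            raise MechanicsError(f"unknown adh_mode {self.adh_mode!r}")

    def reach(self, sum_radii: float | np.ndarray) -> float | np.ndarray:
        """Maximum adhesion distance for a pair with the given radius sum."""
        if self.adh_mode == "relative":
            return self.adh_reach * sum_radii
        return sum_radii + self.adh_reach


def radius_of_volume(V: float | np.ndarray) -> float | np.ndarray:
    """Sphere radius from volume, r = (3V / 4 pi)^(1/3)."""
    return (3.0 * np.asarray(V) / (4.0 * np.pi)) ** (1.0 / 3.0)


def freeze_expand(V: float, V_w: float, expansion: float = 1.09) -> float:
    """Volume after solidification: solids unchanged, water expanded.

    (V - V_w) + expansion * V_w; the frozen volume is fixed thereafter.
    """
    if not 0.0 <= V_w <= V:
        raise MechanicsError(f"water volume V_w={V_w} outside [0, V={V}]")
    return (V - V_w) + expansion * V_w


@dataclass
class MechState:
    """Mutable mechanical state of all agents."""

    positions: np.ndarray           # (N, 3) [um]
    volumes: np.ndarray             # (N,) [um^3]
    frozen: np.ndarray              # (N,) bool
    velocities: np.ndarray | None = None
    attachments: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.volumes = np.asarray(self.volumes, dtype=float).reshape(n)
        self.frozen = np.asarray(self.frozen, dtype=bool).reshape(n)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        self.attachments = {(min(i, j), max(i, j)) for i, j in self.attachments}

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def radii(self) -> np.ndarray:
        return radius_of_volume(self.volumes)


def pair_force(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    r_i: float,
    r_j: float,
    params: MechParams,
) -> np.ndarray:
    """Force on cell i from cell j [pN].

    Repulsion c_rep (1 - d/s)^2 for d < s = r_i + r_j; adhesion
    c_adh (1 - d/reach)^2 for d < reach; zero beyond the adhesive reach.
    Antisymmetric between the pair.  Coincident centres repel along a fixed
    fallback axis (+x) with a diagnostic.
    """
    dvec = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    d = float(np.linalg.norm(dvec))
    s = r_i + r_j
    reach = params.reach(s)
    if d >= reach:
        return np.zeros(3)
    if d == 0.0:
        logger.warning("coincident cell centres; repelling along +x fallback axis")
        return np.array([params.c_rep, 0.0, 0.0])
    u = dvec / d
    mag = 0.0
    if d < s:
        mag += params.c_rep * (1.0 - d / s) ** 2
    mag -= params.c_adh * (1.0 - d / reach) ** 2
    return mag * u


def net_forces(state: MechState, params: MechParams) -> np.ndarray:
    """(N, 3) net pairwise forces; all-pairs evaluation."""
    n = state.n_cells
    pos = state.positions
    r = state.radii
    F = np.zeros((n, 3))
    if n <= 1:
        return F
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    s = r[:, None] + r[None, :]
    reach = params.reach(s)
    np.fill_diagonal(d, np.inf)
    active = d < reach
    if not active.any():
        return F
    coincident = active & (d == 0.0)
    if coincident.any():
        logger.warning("coincident cell centres; repelling along +x fallback axis")
        ii, jj = np.nonzero(np.triu(coincident, 1))
        for i, j in zip(ii, jj):
            F[i, 0] += params.c_rep
            F[j, 0] -= params.c_rep
        active &= d > 0.0
    dd = np.where(active, d, 1.0)
    mag = np.where(active & (d < s), params.c_rep * (1.0 - dd / s) ** 2, 0.0)
    mag -= np.where(active, params.c_adh * (1.0 - dd / reach) ** 2, 0.0)
    with np.errstate(invalid="ignore"):
        unit = diff / dd[:, :, None]
    F += (np.where(active, mag, 0.0)[:, :, None] * unit).sum(axis=1)
    return F


def step_positions(state: MechState, params: MechParams) -> MechState:
    """One overdamped step: v = F/drag, x += v dt.  Mutates and returns state.

    Frozen cells participate in forces identically (solid but interacting);
    with ``frozen_mobile=False`` they are pinned instead.  A displacement
    exceeding half the smallest radius raises :class:`StabilityError`.
    """
    F = net_forces(state, params)
    v = F / params.drag
    if not params.frozen_mobile:
        v[state.frozen] = 0.0
    dx = v * params.dt_mech
    max_disp = float(np.linalg.norm(dx, axis=1).max()) if state.n_cells else 0.0
    if max_disp > 0.5 * float(state.radii.min()):
        raise StabilityError(
            f"displacement {max_disp:.3g} um exceeds half the smallest radius; "
            "reduce dt_mech"
        )
    state.velocities = v
    state.positions = state.positions + dx
    return state


@dataclass(frozen=True)
class FissureReport:
    """Severed adhesive contacts of a construct."""

    severed: tuple[tuple[int, int], ...]
    lost_contacts: dict[int, int]
    components: tuple[tuple[int, ...], ...]

    @property
    def n_severed(self) -> int:
        return len(self.severed)

    def to_dict(self) -> dict:
        return {
            "severed": [list(p) for p in self.severed],
            "lost_contacts": {int(k): int(v) for k, v in self.lost_contacts.items()},
            "components": [list(c) for c in self.components],
        }


def detect_detachment(state: MechState, params: MechParams) -> FissureReport:
    """Report attachment pairs separated beyond the adhesive reach.

    A pair is severed when its centre distance exceeds the maximum adhesion
    distance.  Severed pairs are removed from ``state.attachments`` (so the
    report is idempotent in the absence of further motion) and the surviving
    attachment graph's connected components are listed.
    """
    r = state.radii
    severed = []
    for i, j in sorted(state.attachments):
        d = float(np.linalg.norm(state.positions[i] - state.positions[j]))
        if d > params.reach(r[i] + r[j]):
            severed.append((i, j))
    for pair in severed:
        state.attachments.discard(pair)
    lost: dict[int, int] = {}
    for i, j in severed:
        lost[i] = lost.get(i, 0) + 1
        lost[j] = lost.get(j, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(range(state.n_cells))
    g.add_edges_from(state.attachments)
    comps = tuple(tuple(sorted(c)) for c in sorted(nx.connected_components(g), key=min))
    return FissureReport(severed=tuple(severed), lost_contacts=lost, components=comps)


def snapshot_frame(state: MechState, t: float) -> pd.DataFrame:
    """One trajectory snapshot as a (t, cell_id, x, y, z, radius, frozen) table."""
    n = state.n_cells
    return pd.DataFrame(
        {
            "t": np.full(n, t),
            "cell_id": np.arange(n),
            "x": state.positions[:, 0],
            "y": state.positions[:, 1],
            "z": state.positions[:, 2],
            "radius": state.radii,
            "frozen": state.frozen.astype(int),
        }
    )
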