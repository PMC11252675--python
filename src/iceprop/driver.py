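"""Experiment orchestration: dehydration -> tau map -> freeze sampling ->
ice expansion -> mechanics relaxation.

A full freezing experiment couples the deterministic single-cell biophysics
(all cells share one dehydration trajectory: identical parameters, no
thermal gradients) with the stochastic propagation model and, optionally,
center-based mechanics in dimensional time.  Every run writes a provenance
block (config hash, seed, package version) alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import (
    CellParams,
    CoolingProtocol,
    DehydrationTrajectory,
    TauMap,
    integrate_dehydration,
)
from .geometry import (
    NeighbourRule,
    Tissue,
    build_disc_monolayer,
    build_slab,
    build_spheroid,
)
from .mechanics import (
    FissureReport,
    MechParams,
    MechState,
    detect_detachment,
    freeze_expand,
    snapshot_frame,
    step_positions,
)
from .montecarlo import FreezeEnsemble, MCConfig, aggregate
from .montecarlo import run as run_mc

__all__ = [
    "ExperimentConfig",
    "SimResult",
    "run_experiment",
    "freeze_time_matching",
    "single_cell_iif_curve",
    "iif_convergence_rate",
    "build_tissue",
]

logger = logging.getLogger(__name__)

#: Default stop temperature of the packaged protocols [K]: -15 C, the
#: endpoint by which hepatocyte cryomicroscopy IIF assays are complete.
DEFAULT_T_END = 258.15


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class TissueSpec:
    """Geometry-kind plus build parameters for a construct."""

    kind: str                           # disc | spheroid | slab
    n_cells: int | None = None
    cell_diameter: float = 21.0
    spacing_factor: float = 0.85
    packing: str = "hex"
    spheroid_diameter: float = 100.0
    nx: int | None = None
    ny: int | None = None
    nz: int | None = None
    seed_cells: tuple[int, ...] = ()


def build_tissue(spec: TissueSpec, rule: NeighbourRule) -> Tissue:
    """Construct and wire a tissue from its spec."""
    if spec.kind == "disc":
        t = build_disc_monolayer(
            spec.n_cells, spec.cell_diameter, spec.spacing_factor, spec.packing
        )
    elif spec.kind == "spheroid":
        t = build_spheroid(
            spec.n_cells, spec.spheroid_diameter, spec.cell_diameter, spec.spacing_factor
        )
    elif spec.kind == "slab":
        t = build_slab(spec.nx, spec.ny, spec.nz, spec.cell_diameter)
    else:
        raise ConfigError(f"unknown tissue kind {spec.kind!r}")
    t = t.with_graph(rule)
    if spec.seed_cells:
        t = t.seed(spec.seed_cells)
    return t


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one freezing experiment."""

    tissue: TissueSpec
    protocol: CoolingProtocol
    mc: MCConfig
    rule: NeighbourRule = NeighbourRule()
    cell_params: CellParams = field(default_factory=CellParams.rat_hepatocyte)
    mech: MechParams = MechParams()
    stages: tuple[str, ...] = ("propagation",)
    mech_replicate: int = 0
    snapshot_every: int = 100
    outputs: str | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigError("stage set must be non-empty")
        for s in self.stages:
            if s not in ("propagation", "mechanics"):
                raise ConfigError(f"unknown stage {s!r}")

    # ---- flat key-value (YAML) round trip -------------------------------
    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {
            "tissue": clean(self.tissue),
            "protocol": clean(self.protocol),
            "mc": clean(self.mc),
            "rule": clean(self.rule),
            "cell_params": clean(self.cell_params),
            "mech": clean(self.mech),
            "stages": list(self.stages),
            "mech_replicate": self.mech_replicate,
            "snapshot_every": self.snapshot_every,
            "outputs": self.outputs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        tissue = d.pop("tissue")
        tissue["seed_cells"] = tuple(tissue.get("seed_cells", ()))
        cp = d.pop("cell_params", None)
        if isinstance(cp, str):
            if cp != "rat_hepatocyte":
                raise ConfigError(f"unknown parameter set {cp!r}")
            cell_params = CellParams.rat_hepatocyte()
        elif cp is None:
            cell_params = CellParams.rat_hepatocyte()
        else:
            cell_params = CellParams(**cp)
        return cls(
            tissue=TissueSpec(**tissue),
            protocol=CoolingProtocol(**d.pop("protocol")),
            mc=MCConfig(**d.pop("mc")),
            rule=NeighbourRule(**d.pop("rule", {})),
            cell_params=cell_params,
            mech=MechParams(**d.pop("mech", {})),
            stages=tuple(d.pop("stages", ("propagation",))),
            mech_replicate=d.pop("mech_replicate", 0),
            snapshot_every=d.pop("snapshot_every", 100),
            outputs=d.pop("outputs", None),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimResult:
    """Everything a full experiment produced."""

    config: ExperimentConfig
    tissue: Tissue
    trajectory: DehydrationTrajectory
    tau_map: TauMap
    ensemble: FreezeEnsemble
    probability_map: pd.DataFrame
    mech_trajectory: pd.DataFrame | None = None
    fissures: FissureReport | None = None

    def provenance(self) -> dict:
        return {
            "config_digest": self.config.digest(),
            "rng_seed": self.config.mc.rng_seed,
            "version": __version__,
        }

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_frame().to_csv(out / "dehydration.csv", index=False)
        self.tissue.save(out / "tissue.csv", out / "contacts.edgelist")
        self.ensemble.to_frame(self.tau_map).to_csv(out / "freeze_events.csv", index=False)
        self.probability_map.to_csv(out / "probability_map.csv", index=False)
        if self.mech_trajectory is not None:
            self.mech_trajectory.to_csv(out / "mechanics.csv", index=False)
        if self.fissures is not None:
            (out / "fissures.json").write_text(json.dumps(self.fissures.to_dict(), indent=1))
        (out / "provenance.json").write_text(json.dumps(self.provenance(), indent=1))
        self.config.to_yaml(out / "config.yaml")


def freeze_time_matching(
    freeze_tau: np.ndarray, tau_map: TauMap, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map stochastic freeze clocks to the dimensional time grid.

    Each tau_j maps to the first grid point t = m*dt with tau(t) >= tau_j.
    Returns (t_events, scheduled_mask); events beyond the protocol's final
    tau are unscheduled ("never froze in protocol", t = +inf).
    """
    if np.any(np.diff(tau_map.tau) < 0):
        raise ConfigError("tau map must be nondecreasing")
    freeze_tau = np.asarray(freeze_tau, dtype=float)
    t_cont = tau_map.t_at_tau(freeze_tau)
    scheduled = np.isfinite(t_cont)
    t_grid = np.where(scheduled, np.ceil(t_cont / dt - 1e-12) * dt, np.inf)
    return t_grid, scheduled


def run_experiment(config: ExperimentConfig) -> SimResult:
    """Run a full freezing experiment.

    1. integrate the shared dehydration trajectory; 2. build the tau(t)
    map; 3. sample freeze logs up to tau(T_end); 4. replay one replicate in
    dimensional time, firing the 1.09x water-to-ice expansion at each
    cell's freeze time; 5. step mechanics at dt_mech throughout.
    """
    logger.info("stage: dehydration (B=%.0f K/min)", config.protocol.B)
    try:
        trajectory = integrate_dehydration(config.cell_params, config.protocol)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage dehydration failed: {err}") from err
    tau_map = trajectory.tau_map()

    tissue = build_tissue(config.tissue, config.rule)

    logger.info("stage: propagation (%s, %d replicates)", config.mc.method, config.mc.replicates)
    mc_cfg = dataclasses.replace(config.mc, tau_max=max(tau_map.tau_final, 1e-12))
    try:
        ensemble = run_mc(tissue, mc_cfg)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage propagation failed: {err}") from err

    tau_grid = np.linspace(0.0, mc_cfg.tau_max, 51)
    probability_map = aggregate(ensemble, tau_grid)

    mech_traj = None
    fissures = None
    if "mechanics" in config.stages:
        logger.info("stage: mechanics (replicate %d)", config.mech_replicate)
        try:
            mech_traj, fissures = _replay_mechanics(config, tissue, trajectory, tau_map, ensemble)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage mechanics failed: {err}") from err

    result = SimResult(
        config=config, tissue=tissue, trajectory=trajectory, tau_map=tau_map,
        ensemble=ensemble, probability_map=probability_map,
        mech_trajectory=mech_traj, fissures=fissures,
    )
    if config.outputs:
        result.save(config.outputs)
    return result


def _replay_mechanics(
    config: ExperimentConfig,
    tissue: Tissue,
    trajectory: DehydrationTrajectory,
    tau_map: TauMap,
    ensemble: FreezeEnsemble,
) -> tuple[pd.DataFrame, FissureReport]:
    """Dimensional-time replay of one replicate with expansion and forces."""
    params = config.cell_params
    mech = config.mech
    dt = mech.dt_mech
    rep = config.mech_replicate
    freeze_tau = ensemble.freeze_tau[rep]
    t_events, scheduled = freeze_time_matching(freeze_tau, tau_map, dt)

    n = tissue.n_cells
    duration = config.protocol.duration
    n_steps = int(np.floor(duration / dt))
    state = MechState(
        positions=tissue.positions.copy(),
        volumes=np.full(n, params.V_iso),
        frozen=tissue.frozen0.copy(),
        attachments=set(tissue.graph.edges) if tissue.graph else set(),
    )
    # seed cells freeze at t=0 with full isotonic water
    for c in np.nonzero(tissue.frozen0)[0]:
        state.volumes[c] = freeze_expand(params.V_iso, params.V_w_iso, mech.expansion)

    snapshots = [snapshot_frame(state, 0.0)]
    for step in range(1, n_steps + 1):
        t = step * dt
        V_t = float(trajectory.volume_at_time(t))
        Vw_t = float(trajectory.water_at_time(t))
        unfrozen = ~state.frozen
        state.volumes[unfrozen] = V_t
        firing = unfrozen & (t_events <= t)
        for c in np.nonzero(firing)[0]:
            state.volumes[c] = freeze_expand(V_t, Vw_t, mech.expansion)
            state.frozen[c] = True
        step_positions(state, mech)
        if step % config.snapshot_every == 0 or step == n_steps:
            snapshots.append(snapshot_frame(state, t))
    report = detect_detachment(state, mech)
    return pd.concat(snapshots, ignore_index=True), report


def single_cell_iif_curve(
    params: CellParams, protocol: CoolingProtocol, grid_step: float = 0.05
) -> pd.DataFrame:
    """Cumulative IIF probability of an isolated cell versus temperature.

    P_IIF(T) = 1 - exp(-tau(T)); nondecreasing as the temperature falls.
    """
    tr = integrate_dehydration(params, protocol, grid_step=grid_step)
    return pd.DataFrame({"T": tr.T, "t": tr.t, "tau": tr.tau, "p_iif": 1.0 - np.exp(-tr.tau)})


def iif_convergence_rate(
    params: CellParams,
    B_grid: np.ndarray,
    T0: float = 272.15,
    T_end: float = DEFAULT_T_END,
    threshold: float = 0.995,
) -> tuple[float | None, pd.DataFrame]:
    """Scan cooling rates for convergence of the asymptotic IIF probability.

    Returns the smallest B whose asymptotic P_IIF reaches ``threshold``
    (None if none does) plus the full (B, tau_final, p_iif) table.
    """
    rows = []
    for B in np.asarray(B_grid, dtype=float):
        tr = integrate_dehydration(params, CoolingProtocol(T0=T0, B=float(B), T_end=T_end))
        rows.append((float(B), tr.tau[-1], 1.0 - np.exp(-tr.tau[-1])))
    table = pd.DataFrame(rows, columns=["B", "tau_final", "p_iif"])
    hit = table[table["p_iif"] >= threshold]
    return (float(hit["B"].iloc[0]) if len(hit) else None), table
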