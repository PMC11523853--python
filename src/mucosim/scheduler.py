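"""Two-phase time loop coupling the agent model to the substrate solver.

Phase 1 (colonization, 1-s steps) seeds the substratum; phase 2 advances
in 15-min growth steps.  Each growth step: bin frozen biomass onto the
grid, solve the pseudo-steady concentration fields, grow every cell from
its block's concentrations, divide cells past their thresholds, relax
overlaps by shoving, remove biomass above the niche height cap, and
record totals.  Scheduled newcomer injections land at the start of the
first step at or after their time.  The run ends when every species'
biomass has been flat over a trailing window (steady state) with all
events applied, or at max_time_h.

All randomness flows from one seeded generator, so a (config, seed) pair
maps to one bitwise-reproducible trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .colonization import run_colonization
from .core_types import (
    AgentPopulation,
    InjectionEvent,
    ScenarioConfig,
    Trajectory,
    radius_of,
    validate_scenario,
)
from .growth_division import divide_population, draw_division_threshold, draw_newborn_mass, grow_population
from .mechanics import enforce_height_cap, growth_advection, relax
from .metrics_io import species_biomass
from .reaction_diffusion import DiffusionSolver, accumulate_block_biomass

logger = logging.getLogger(__name__)

__all__ = ["SimulationState", "growth_step", "apply_injection", "steady_state_reached", "run_simulation"]


@dataclass
class SimulationState:
    config: ScenarioConfig
    pop: AgentPopulation
    rng: np.random.Generator
    solver: DiffusionSolver
    time_h: float = 0.0
    fields: np.ndarray | None = None  # (n_substrates, ny, nx), warm start between steps
    events_applied: set = field(default_factory=set)
    removed_last_step: np.ndarray | None = None
    grown_last_step: np.ndarray | None = None


def apply_injection(state: SimulationState, event: InjectionEvent, rng: np.random.Generator) -> SimulationState:
    """Drop ``count`` newcomer cells at the niche mid-height, frozen in place."""
    key = (event.time_h, event.species_id, event.count)
    if key in state.events_applied:
        raise RuntimeError(f"injection event {key} applied twice")
    state.events_applied.add(key)
    cfg = state.config
    if event.species_id not in cfg.species_ids():
        raise KeyError(f"unknown species {event.species_id!r}")
    if event.count == 0:
        return state
    k = cfg.species_ids().index(event.species_id)
    n = event.count
    state.pop.add(
        species=np.full(n, k),
        mass=draw_newborn_mass(rng, size=n),
        x=rng.uniform(0.0, cfg.domain.width, size=n),
        y=np.full(n, cfg.domain.biofilm_height_cap / 2.0),
        frozen=True,
        heading=0.0,
        div_threshold=draw_division_threshold(cfg.division, rng, size=n),
    )
    return state


def growth_step(state: SimulationState, trajectory: Trajectory | None = None) -> SimulationState:
    """Advance one growth step of ``growth_dt_min`` minutes."""
    cfg = state.config
    dt = cfg.growth_dt_h
    # pending events land before the step's physics
    for ev in cfg.events:
        key = (ev.time_h, ev.species_id, ev.count)
        if state.time_h >= ev.time_h and key not in state.events_applied:
            apply_injection(state, ev, state.rng)

    grown = np.zeros(len(cfg.species))
    if state.pop.n > 0:
        dens = accumulate_block_biomass(state.pop, cfg.domain)
        state.fields = state.solver.solve(dens, S_init=state.fields)
        dm, row, col = grow_population(
            state.pop, state.fields, state.solver.kin,
            np.array([s.maintenance_m for s in cfg.species]),
            cfg.domain, dt,
        )
        np.add.at(grown, state.pop.view("species"), dm)
        growth_advection(state.pop, dm, row, col, cfg.domain)
        divide_population(state.pop, cfg.division, cfg.domain, state.rng, cfg.radius_law)
        relax(
            state.pop, cfg.domain, radius_law=cfg.radius_law, rng=state.rng,
            max_iter=cfg.relax_max_iter, sweeps_per_iter=cfg.relax_sweeps_per_iter,
        )
        removed = enforce_height_cap(state.pop, cfg.domain.biofilm_height_cap)
    else:
        removed = np.zeros(len(cfg.species))
    state.removed_last_step = removed
    state.grown_last_step = grown
    state.time_h += dt
    if trajectory is not None:
        trajectory.record(state.time_h, species_biomass(state.pop), removed)
    return state


def steady_state_reached(
    trajectory: Trajectory,
    window_h: float,
    rel_tol: float,
    abs_floor: float = 0.5,
) -> bool:
    """True when every species' biomass is flat across the trailing window.

    A species whose biomass stays below ``abs_floor`` mass units (absent or
    extinct) never blocks the verdict.  Flat means (max - min) within the
    window is below rel_tol times the window mean.
    """
    times = np.asarray(trajectory.times)
    if len(times) < 2 or times[-1] - times[0] < window_h:
        return False
    in_window = times >= times[-1] - window_h
    B = trajectory.biomass_array()[in_window]
    for s in range(B.shape[1]):
        b = B[:, s]
        if b.max() < abs_floor:
            continue
        mean = b.mean()
        if (b.max() - b.min()) > rel_tol * mean:
            return False
    return True


def run_simulation(config: ScenarioConfig, progress: bool = False) -> Trajectory:
    """Full experiment: colonization, then growth to steady state or max_time_h."""
    violations = validate_scenario(config)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))
    rng = np.random.default_rng(config.rng_seed)
    pop = run_colonization(config, rng)
    state = SimulationState(
        config=config, pop=pop, rng=rng, solver=DiffusionSolver(config)
    )
    traj = Trajectory(species_ids=config.species_ids())
    traj.record(0.0, species_biomass(pop), np.zeros(len(config.species)))
    traj.snapshots.append((0.0, pop.copy()))

    next_snapshot = config.snapshot_every_h
    next_log = 10.0
    ss = config.steady_state
    last_event = max((ev.time_h for ev in config.events), default=0.0)
    while state.time_h < config.max_time_h - 1e-9:
        growth_step(state, traj)
        if state.time_h >= next_snapshot - 1e-9:
            traj.snapshots.append((state.time_h, state.pop.copy()))
            next_snapshot += config.snapshot_every_h
        if progress and state.time_h >= next_log:
            logger.info(
                "t=%.1f h, %d agents, biomass %.1f",
                state.time_h, state.pop.n, float(state.pop.view("mass").sum()),
            )
            next_log += 10.0
        if (
            state.time_h > last_event + ss.window_h
            and steady_state_reached(traj, ss.window_h, ss.rel_tol, ss.abs_floor)
        ):
            break
    if not traj.snapshots or traj.snapshots[-1][0] != state.time_h:
        traj.snapshots.append((state.time_h, state.pop.copy()))
    return traj
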