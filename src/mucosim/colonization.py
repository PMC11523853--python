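"""Phase 1: planktonic random walk and substratum attachment.

Planktonic cells are injected at uniformly random positions, swim a
persistent random walk (fixed speed, heading perturbed by a uniform turn
each second), wrap around the periodic x boundary, reflect off the top
boundary and freeze the moment their path touches the substratum.  The
phase produces the seeding layer: exactly ``seed_count`` attached cells,
with species sampled from the initial abundance mix.  Remaining swimmers
are discarded at phase end.

The injected population size needed to reach the target attachment count
is not prescribed; cells are injected in batches and walked until the
target is met, which makes the attached count deterministic while
positions stay random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import Agent, AgentPopulation, DomainSpec, ScenarioConfig, radius_of
from .growth_division import draw_division_threshold, draw_newborn_mass

__all__ = ["WalkParams", "inject_planktonic", "walk_step", "resolve_substratum_contact", "run_colonization"]


@dataclass
class WalkParams:
    speed: float = 10.0  # um/s
    turn_deg: float = 45.0  # heading perturbation drawn from +-turn_deg
    dt: float = 1.0  # s


class ColonizationTimeout(RuntimeError):
    pass


def inject_planktonic(
    pop: AgentPopulation,
    species_mix: np.ndarray,
    n: int,
    domain: DomainSpec,
    rng: np.random.Generator,
    config: ScenarioConfig | None = None,
) -> AgentPopulation:
    """Add n planktonic swimmers with uniform random positions and headings."""
    if n <= 0:
        raise ValueError("n must be positive")
    division = config.division if config is not None else None
    species = rng.choice(len(species_mix), size=n, p=species_mix)
    thresholds = (
        draw_division_threshold(division, rng, size=n)
        if division is not None
        else np.full(n, 2.0)
    )
    pop.add(
        species=species,
        mass=draw_newborn_mass(rng, size=n),
        x=rng.uniform(0.0, domain.width, size=n),
        y=rng.uniform(0.0, domain.height, size=n),
        frozen=False,
        heading=rng.uniform(0.0, 2.0 * np.pi, size=n),
        div_threshold=thresholds,
    )
    return pop


def resolve_substratum_contact(
    x0: float, y0: float, x1: float, y1: float, radius: float
) -> tuple[float, float, bool]:
    """Stop a displacement at first substratum contact.

    The cell touches the wall when its center reaches y = radius.  If the
    segment (x0,y0)->(x1,y1) crosses that line, the move is shortened to
    the crossing point and the cell freezes; otherwise the move stands.
    Returns (x, y, attached).
    """
    if y1 >= radius:
        return x1, y1, False
    if y0 <= radius:  # started at/below contact height: attach in place
        return x0, radius, True
    t = (y0 - radius) / (y0 - y1)
    return x0 + t * (x1 - x0), radius, True


def walk_step(
    agent: Agent, params: WalkParams, domain: DomainSpec, rng: np.random.Generator,
    radius_law: str = "area",
) -> Agent:
    """One random-walk step for a single planktonic agent (reference path)."""
    if agent.frozen:
        raise ValueError("frozen agents do not walk")
    agent.heading = (agent.heading + np.deg2rad(rng.uniform(-params.turn_deg, params.turn_deg))) % (2 * np.pi)
    step = params.speed * params.dt
    x1 = agent.x + step * np.cos(agent.heading)
    y1 = agent.y + step * np.sin(agent.heading)
    if y1 > domain.height:  # reflective top
        y1 = 2.0 * domain.height - y1
    x, y, attached = resolve_substratum_contact(
        agent.x, agent.y, x1, y1, radius_of(agent.mass, radius_law)
    )
    agent.x = float(np.mod(x, domain.width))
    agent.y = float(y)
    if attached:
        agent.frozen = True
    return agent


def _walk_all(
    pop: AgentPopulation,
    params: WalkParams,
    domain: DomainSpec,
    rng: np.random.Generator,
    radius_law: str,
) -> np.ndarray:
    """Vectorized walk for all planktonic agents; returns newly-attached rows."""
    live = ~pop.view("frozen")
    idx = np.flatnonzero(live)
    if len(idx) == 0:
        return idx
    turn = np.deg2rad(rng.uniform(-params.turn_deg, params.turn_deg, size=len(idx)))
    heading = np.mod(pop.heading[idx] + turn, 2 * np.pi)
    pop.heading[idx] = heading
    step = params.speed * params.dt
    x0, y0 = pop.x[idx], pop.y[idx]
    x1 = x0 + step * np.cos(heading)
    y1 = y0 + step * np.sin(heading)
    over = y1 > domain.height
    y1[over] = 2.0 * domain.height - y1[over]
    radii = radius_of(pop.mass[idx], radius_law)

    hit = y1 < radii
    x_new, y_new = x1.copy(), y1.copy()
    if hit.any():
        started_low = y0 <= radii
        shorten = hit & ~started_low
        t = np.zeros_like(y0)
        t[shorten] = (y0[shorten] - radii[shorten]) / (y0[shorten] - y1[shorten])
        x_new[shorten] = x0[shorten] + t[shorten] * (x1[shorten] - x0[shorten])
        y_new[hit] = radii[hit]
        x_new[hit & started_low] = x0[hit & started_low]
    pop.x[idx] = np.mod(x_new, domain.width)
    pop.y[idx] = y_new
    attached = idx[hit]
    pop.frozen[attached] = True
    return attached


def run_colonization(
    config: ScenarioConfig, rng: np.random.Generator, batch_size: int | None = None
) -> AgentPopulation:
    """Run phase 1 until exactly ``seed_count`` cells sit frozen on the substratum.

    Swimmers are injected in batches and walked with 1-s steps; attachment
    beyond the target within a step is trimmed deterministically (lowest
    row indices keep their attachment, the rest are discarded with the
    other swimmers).  A step cap guards against a pathological scenario.
    """
    mix = np.array([config.initial_abundance.get(sid, 0.0) for sid in config.species_ids()])
    if mix.sum() <= 0:
        raise ValueError("initial_abundance assigns no seeding species")
    mix = mix / mix.sum()
    params = WalkParams(dt=config.colonization_dt)
    pop = AgentPopulation(config.species_ids())
    target = config.seed_count
    batch = batch_size or max(4 * target, 100)
    duration_steps = max(int(round(config.colonization_duration / params.dt)), 1)
    max_steps = 10**6

    inject_planktonic(pop, mix, batch, config.domain, rng, config)
    attached_total = 0
    steps = 0
    while attached_total < target:
        newly = _walk_all(pop, params, config.domain, rng, config.radius_law)
        attached_total += len(newly)
        if attached_total >= target:
            surplus = attached_total - target
            if surplus:
                pop.frozen[newly[len(newly) - surplus :]] = False
                attached_total = target
            break
        steps += 1
        if steps % duration_steps == 0:  # top up each nominal 2-min window
            inject_planktonic(pop, mix, batch, config.domain, rng, config)
        if steps >= max_steps:
            raise ColonizationTimeout(
                f"colonization reached {attached_total}/{target} attachments "
                f"within the {max_steps}-step cap"
            )
    pop.keep(pop.view("frozen"))
    return pop
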