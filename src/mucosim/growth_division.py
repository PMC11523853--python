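"""Biomass accumulation and binary fission of frozen cells.

Each cell grows at the summed Monod rate over the substrates its species
consumes, minus a maintenance rate m:

    dx/dt = (sum_i mu_max_i * S_i/(S_i+Ks_i) - m) * x

integrated with an exponential Euler step (exact for concentrations held
constant over the step, and positivity-preserving).  Concentrations are
taken from the block the cell sits in, frozen at the start of the step.

A cell divides once its mass reaches its individual division threshold,
drawn at birth from a Gaussian with mean 2 mass units and 10% CV,
truncated at two standard deviations.  Division splits the mass exactly
in half and drops the daughter tangentially in a uniformly random
direction; the shoving relaxation untangles any overlap afterwards.
"""

from __future__ import annotations

import numpy as np

from .core_types import (
    Agent,
    AgentPopulation,
    DivisionParams,
    DomainSpec,
    ScenarioConfig,
    SpeciesSpec,
    radius_of,
)
from .reaction_diffusion import monod_factor

__all__ = [
    "grow_agent",
    "grow_population",
    "draw_division_threshold",
    "draw_newborn_mass",
    "divide",
    "divide_population",
]


def specific_growth_rate(spec: SpeciesSpec, local_S: dict[str, float]) -> float:
    """Summed Monod growth rate (1/h) minus maintenance for one species."""
    mu = 0.0
    for entry in spec.kinetics:
        mu += entry.mu_max * monod_factor(local_S[entry.substrate_id], entry.Ks)
    return mu - spec.maintenance_m


def grow_agent(agent: Agent, local_S: dict[str, float], spec: SpeciesSpec, dt: float) -> Agent:
    """Exponential-Euler mass update over dt hours; returns the updated agent."""
    if not agent.frozen:
        raise ValueError("only frozen agents grow")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = specific_growth_rate(spec, local_S)
    agent.mass = agent.mass * float(np.exp(rate * dt))
    return agent


def growth_rate_grid(fields: np.ndarray, kin, maintenance: np.ndarray) -> np.ndarray:
    """Per-species specific growth rate on the grid, shape (n_species, ny, nx).

    ``fields`` is the (n_substrates, ny, nx) concentration stack; ``kin``
    the solver's kinetic table (mu, Ks indexed (substrate, species)).
    """
    n_sub, ny, nx = fields.shape
    n_sp = kin.mu.shape[1]
    f = fields[:, None, :, :] / (fields[:, None, :, :] + kin.Ks[:, :, None, None])
    rate = (kin.mu[:, :, None, None] * f).sum(axis=0)
    return rate - maintenance[:, None, None]


def grow_population(
    pop: AgentPopulation,
    fields: np.ndarray,
    kin,
    maintenance: np.ndarray,
    domain: DomainSpec,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow every frozen agent in place.

    Returns (dm, row, col): per-agent mass added and the grid block each
    agent occupied, which downstream mechanics reuse for the growth
    advection field.
    """
    if pop.n == 0:
        empty = np.zeros(0)
        return empty, empty.astype(int), empty.astype(int)
    rates = growth_rate_grid(fields, kin, maintenance)
    row, col = domain.block_of(pop.view("x"), pop.view("y"))
    r = rates[pop.view("species"), row, col]
    mass = pop.view("mass")
    dm = mass * (np.exp(r * dt) - 1.0)
    mass += dm
    return dm, row, col


def _truncated_normal(
    mean: float, cv: float, trunc_sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sampled Gaussian confined to mean +- trunc_sd standard deviations."""
    if cv == 0:
        return np.full(size, mean)
    sd = cv * mean
    lo, hi = mean - trunc_sd * sd, mean + trunc_sd * sd
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def draw_division_threshold(
    params: DivisionParams, rng: np.random.Generator, size: int | None = None
):
    """Division mass threshold(s): N(2, 0.2) truncated to [1.6, 2.4] by default."""
    out = _truncated_normal(
        params.threshold_mean, params.cv, params.truncation_sd, size or 1, rng
    )
    return float(out[0]) if size is None else out


def draw_newborn_mass(rng: np.random.Generator, size: int | None = None):
    """Initial cell mass: mean 1, 10% CV, truncated at 2 SD (so [0.8, 1.2])."""
    out = _truncated_normal(1.0, 0.10, 2.0, size or 1, rng)
    return float(out[0]) if size is None else out


def divide(
    agent: Agent,
    rng: np.random.Generator,
    radius_law: str = "area",
    params: DivisionParams | None = None,
) -> tuple[Agent, Agent]:
    """Split one cell into two of exactly half the mass each.

    The daughter is placed tangentially: center-to-center distance equals
    the sum of the two post-division radii, along a uniformly random
    direction.  Mass is conserved to the bit.
    """
    if not agent.frozen:
        raise ValueError("planktonic agents do not divide")
    params = params or DivisionParams()
    frac = 0.5
    if params.split_cv > 0:
        frac = float(
            _truncated_normal(0.5, params.split_cv, params.truncation_sd, 1, rng)[0]
        )
    total = agent.mass
    daughter_mass = total * frac
    parent_mass = total - daughter_mass  # conserves mass to the bit
    r = radius_of(parent_mass, radius_law) + radius_of(daughter_mass, radius_law)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    daughter = Agent(
        uid=-1,
        species_id=agent.species_id,
        mass=daughter_mass,
        x=agent.x + r * np.cos(theta),
        y=agent.y + r * np.sin(theta),
        frozen=True,
        division_threshold=draw_division_threshold(params, rng),
    )
    agent.mass = parent_mass
    agent.division_threshold = draw_division_threshold(params, rng)
    return agent, daughter


def divide_population(
    pop: AgentPopulation,
    params: DivisionParams,
    domain: DomainSpec,
    rng: np.random.Generator,
    radius_law: str = "area",
) -> int:
    """Divide every frozen agent at or past its threshold; returns divisions done."""
    if pop.n == 0:
        return 0
    ready = (pop.view("mass") >= pop.view("div_threshold")) & pop.view("frozen")
    idx = np.flatnonzero(ready)
    if len(idx) == 0:
        return 0
    total = pop.mass[idx].copy()
    if params.split_cv > 0:
        frac = _truncated_normal(0.5, params.split_cv, params.truncation_sd, len(idx), rng)
    else:
        frac = 0.5
    d_mass = total * frac
    p_mass = total - d_mass
    pop.mass[idx] = p_mass
    r = radius_of(d_mass, radius_law)
    sep = radius_of(p_mass, radius_law) + r
    theta = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
    dx, dy = sep * np.cos(theta), sep * np.sin(theta)
    new_y = np.clip(pop.y[idx] + dy, r, domain.height)
    pop.div_threshold[idx] = draw_division_threshold(params, rng, size=len(idx))
    pop.add(
        species=pop.species[idx],
        mass=d_mass,
        x=np.mod(pop.x[idx] + dx, domain.width),
        y=new_y,
        frozen=True,
        heading=0.0,
        div_threshold=draw_division_threshold(params, rng, size=len(idx)),
    )
    return len(idx)
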