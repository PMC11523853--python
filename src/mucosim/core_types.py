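"""Domain types shared by every module of the simulator.

The model world is a 2-D box of liquid above a flat substratum.  Bacteria
are circular agents with continuous positions and individual masses; one
mass unit corresponds to a cell of 1 um diameter.  Dissolved substances
live on a rectangular finite-volume grid.  A :class:`ScenarioConfig`
gathers everything needed to reproduce one in-silico experiment, including
the RNG seed, and round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SubstrateSpec",
    "KineticEntry",
    "ByproductRule",
    "SpeciesSpec",
    "DomainSpec",
    "DivisionParams",
    "InjectionEvent",
    "SteadyStateParams",
    "ScenarioConfig",
    "Agent",
    "AgentPopulation",
    "Trajectory",
    "radius_of",
    "validate_scenario",
    "load_scenario",
    "save_scenario",
]


class InvalidAgentError(ValueError):
    pass


@dataclass
class SubstrateSpec:
    """One dissolved chemical species.

    Concentrations are normalized: a bulk nutrient's top-boundary value
    defaults to 1.  Metabolic byproducts are produced in situ and carry a
    zero top-boundary concentration (the top face acts as a sink for them).
    """

    id: str
    diffusion_coefficient: float = 2.5e3  # um^2 / h
    top_boundary_concentration: float = 1.0
    is_bulk: bool = True

    def __post_init__(self) -> None:
        if not self.is_bulk:
            self.top_boundary_concentration = 0.0


@dataclass
class KineticEntry:
    """Monod parameters of one species on one substrate.

    mu_max in 1/h; Ks in normalized concentration units; Y is the yield,
    biomass produced per unit substrate consumed (dimensionless).
    """

    substrate_id: str
    mu_max: float
    Ks: float = 0.1
    Y: float = 0.15


@dataclass
class ByproductRule:
    """Excretion wiring: consuming `consumed` releases `produced`.

    ``gamma`` is the excreted fraction of consumed substrate mass; the
    default ``None`` resolves to 1 - Y of the matching kinetic entry
    (mass balance: what is not built into biomass leaves as byproduct).
    """

    consumed: str
    produced: str
    gamma: float | None = None


@dataclass
class SpeciesSpec:
    id: str
    label: str = ""
    kinetics: list[KineticEntry] = field(default_factory=list)
    byproducts: list[ByproductRule] = field(default_factory=list)
    maintenance_m: float = 0.0  # 1/h

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id

    def kinetic_for(self, substrate_id: str) -> KineticEntry | None:
        for k in self.kinetics:
            if k.substrate_id == substrate_id:
                return k
        return None

    def gamma_for(self, rule: ByproductRule) -> float:
        if rule.gamma is not None:
            return rule.gamma
        entry = self.kinetic_for(rule.consumed)
        if entry is None:
            raise KeyError(
                f"species {self.id}: byproduct rule consumes {rule.consumed} "
                "but no kinetic entry exists for it"
            )
        return 1.0 - entry.Y


@dataclass
class DomainSpec:
    """Simulation box and FVM grid geometry (all lengths in um)."""

    width: float = 500.0
    height: float = 500.0
    grid_dx: float = 10.0
    biofilm_height_cap: float = 60.0

    @property
    def nx(self) -> int:
        return int(round(self.width / self.grid_dx))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.grid_dx))

    def block_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices (row, col) of positions; row 0 touches the substratum."""
        col = np.clip((np.asarray(x) / self.grid_dx).astype(int), 0, self.nx - 1)
        row = np.clip((np.asarray(y) / self.grid_dx).astype(int), 0, self.ny - 1)
        return row, col


@dataclass
class DivisionParams:
    """Division-threshold distribution: truncated Gaussian around 2 mass units.

    ``split_cv`` = 0 gives the default exact 50/50 split; a positive value
    instead draws the daughter's mass fraction from N(0.5, split_cv*0.5)
    truncated at two standard deviations (mass still conserved exactly).
    """

    threshold_mean: float = 2.0
    cv: float = 0.10
    truncation_sd: float = 2.0
    split_cv: float = 0.0


@dataclass
class InjectionEvent:
    """Scheduled introduction of newcomer cells at the niche mid-height."""

    time_h: float
    species_id: str = ""
    count: int = 5


@dataclass
class SteadyStateParams:
    window_h: float = 50.0
    rel_tol: float = 0.01
    abs_floor: float = 0.5  # mass units; species below this never block steady state


@dataclass
class ScenarioConfig:
    """Complete description of one simulated experiment."""

    domain: DomainSpec = field(default_factory=DomainSpec)
    substrates: list[SubstrateSpec] = field(default_factory=list)
    species: list[SpeciesSpec] = field(default_factory=list)
    initial_abundance: dict[str, float] = field(default_factory=dict)
    seed_count: int = 50
    colonization_dt: float = 1.0  # s
    colonization_duration: float = 120.0  # s
    growth_dt_min: float = 15.0  # min
    max_time_h: float = 500.0
    events: list[InjectionEvent] = field(default_factory=list)
    steady_state: SteadyStateParams = field(default_factory=SteadyStateParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    rng_seed: int = 0
    radius_law: str = "area"  # "area": r = 0.5*sqrt(m); "volume": r = 0.5*m^(1/3)
    literal_yield_form: bool = False  # multiply consumption by Y instead of dividing
    snapshot_every_h: float = 10.0
    relax_max_iter: int = 10  # pair-list rebuilds per growth step
    relax_sweeps_per_iter: int = 10  # shoving sweeps per rebuild

    # -- lookups ---------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def substrate_ids(self) -> list[str]:
        return [s.id for s in self.substrates]

    def species_by_id(self, sid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species {sid!r}")

    @property
    def growth_dt_h(self) -> float:
        return self.growth_dt_min / 60.0

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["domain"] = DomainSpec(**d.get("domain", {}))
        d["substrates"] = [SubstrateSpec(**s) for s in d.get("substrates", [])]
        d["species"] = [
            SpeciesSpec(
                id=s["id"],
                label=s.get("label", ""),
                kinetics=[KineticEntry(**k) for k in s.get("kinetics", [])],
                byproducts=[ByproductRule(**b) for b in s.get("byproducts", [])],
                maintenance_m=s.get("maintenance_m", 0.0),
            )
            for s in d.get("species", [])
        ]
        d["events"] = [InjectionEvent(**e) for e in d.get("events", [])]
        d["steady_state"] = SteadyStateParams(**d.get("steady_state", {}))
        d["division"] = DivisionParams(**d.get("division", {}))
        return cls(**d)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

@dataclass
class Agent:
    """A single bacterium (convenience record; bulk state lives in arrays)."""

    uid: int
    species_id: str
    mass: float
    x: float
    y: float
    frozen: bool = True
    heading: float = 0.0
    division_threshold: float = 2.0


def radius_of(agent_or_mass, law: str = "area"):
    """Cell radius in um from mass.

    ``area`` (default): radius = 0.5 * sqrt(mass), so the circle's area is
    proportional to mass — consistent 2-D packing density.  ``volume``:
    radius = 0.5 * mass**(1/3), a sphere-equivalent alternative.  Both pin
    the anchor mass 1 <-> diameter 1 um.
    """
    mass = getattr(agent_or_mass, "mass", agent_or_mass)
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise InvalidAgentError("agent mass must be positive")
    if law == "area":
        r = 0.5 * np.sqrt(mass)
    elif law == "volume":
        r = 0.5 * np.cbrt(mass)
    else:
        raise ValueError(f"unknown radius law {law!r}")
    return float(r) if r.ndim == 0 else r


class AgentPopulation:
    """Struct-of-arrays store for agents, the unit the vectorized code runs on.

    Rows 0..n-1 are live agents.  ``species`` holds integer indices into
    ``species_ids``.  Planktonic agents have ``frozen == False`` and a
    heading angle; frozen agents ignore the heading.
    """

    _FIELDS = ("uid", "species", "mass", "x", "y", "frozen", "heading", "div_threshold")

    def __init__(self, species_ids: Sequence[str], capacity: int = 256):
        self.species_ids = list(species_ids)
        self.n = 0
        self._next_uid = 0
        cap = max(capacity, 16)
        self.uid = np.zeros(cap, dtype=np.int64)
        self.species = np.zeros(cap, dtype=np.int32)
        self.mass = np.zeros(cap, dtype=float)
        self.x = np.zeros(cap, dtype=float)
        self.y = np.zeros(cap, dtype=float)
        self.frozen = np.zeros(cap, dtype=bool)
        self.heading = np.zeros(cap, dtype=float)
        self.div_threshold = np.full(cap, 2.0, dtype=float)

    # -- internals -------------------------------------------------------
    def _grow_to(self, need: int) -> None:
        cap = len(self.uid)
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        for name in self._FIELDS:
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def view(self, name: str) -> np.ndarray:
        return getattr(self, name)[: self.n]

    # -- mutation --------------------------------------------------------
    def add(
        self,
        species: np.ndarray,
        mass: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        frozen: bool | np.ndarray,
        heading: np.ndarray | float = 0.0,
        div_threshold: np.ndarray | float = 2.0,
    ) -> np.ndarray:
        """Append agents; returns the new row indices."""
        k = len(np.atleast_1d(mass))
        self._grow_to(self.n + k)
        sl = slice(self.n, self.n + k)
        self.uid[sl] = np.arange(self._next_uid, self._next_uid + k)
        self._next_uid += k
        self.species[sl] = species
        self.mass[sl] = mass
        self.x[sl] = x
        self.y[sl] = y
        self.frozen[sl] = frozen
        self.heading[sl] = heading
        self.div_threshold[sl] = div_threshold
        self.n += k
        return np.arange(sl.start, sl.stop)

    def keep(self, mask: np.ndarray) -> None:
        """Compact the population to rows where mask is True."""
        idx = np.flatnonzero(mask)
        for name in self._FIELDS:
            arr = getattr(self, name)
            arr[: len(idx)] = arr[: self.n][idx]
        self.n = len(idx)

    def copy(self) -> "AgentPopulation":
        out = AgentPopulation(self.species_ids, capacity=max(self.n, 16))
        for name in self._FIELDS:
            getattr(out, name)[: self.n] = self.view(name)
        out.n = self.n
        out._next_uid = self._next_uid
        return out

    # -- conversion ------------------------------------------------------
    def to_agents(self) -> list[Agent]:
        return [
            Agent(
                uid=int(self.uid[i]),
                species_id=self.species_ids[self.species[i]],
                mass=float(self.mass[i]),
                x=float(self.x[i]),
                y=float(self.y[i]),
                frozen=bool(self.frozen[i]),
                heading=float(self.heading[i]),
                division_threshold=float(self.div_threshold[i]),
            )
            for i in range(self.n)
        ]

    @classmethod
    def from_agents(cls, agents: Iterable[Agent], species_ids: Sequence[str]) -> "AgentPopulation":
        agents = list(agents)
        pop = cls(species_ids, capacity=max(len(agents), 16))
        if agents:
            idx = {sid: i for i, sid in enumerate(species_ids)}
            pop.add(
                species=np.array([idx[a.species_id] for a in agents]),
                mass=np.array([a.mass for a in agents]),
                x=np.array([a.x for a in agents]),
                y=np.array([a.y for a in agents]),
                frozen=np.array([a.frozen for a in agents]),
                heading=np.array([a.heading for a in agents]),
                div_threshold=np.array([a.division_threshold for a in agents]),
            )
            pop.uid[: pop.n] = [a.uid for a in agents]
            pop._next_uid = int(pop.uid[: pop.n].max()) + 1 if pop.n else 0
        return pop

    def __len__(self) -> int:
        return self.n


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-step community time series plus periodic agent snapshots."""

    species_ids: list[str]
    times: list[float] = field(default_factory=list)
    biomass: list[np.ndarray] = field(default_factory=list)
    fractions: list[np.ndarray] = field(default_factory=list)
    removed: list[np.ndarray] = field(default_factory=list)  # mass removed by the cap this step
    snapshots: list[tuple[float, AgentPopulation]] = field(default_factory=list)

    def record(self, time_h: float, biomass: np.ndarray, removed: np.ndarray) -> None:
        total = biomass.sum()
        frac = biomass / total if total > 0 else np.zeros_like(biomass)
        self.times.append(float(time_h))
        self.biomass.append(np.asarray(biomass, dtype=float).copy())
        self.fractions.append(frac)
        self.removed.append(np.asarray(removed, dtype=float).copy())

    def biomass_array(self) -> np.ndarray:
        return np.array(self.biomass) if self.biomass else np.zeros((0, len(self.species_ids)))

    def fractions_array(self) -> np.ndarray:
        return np.array(self.fractions) if self.fractions else np.zeros((0, len(self.species_ids)))

    def removed_array(self) -> np.ndarray:
        return np.array(self.removed) if self.removed else np.zeros((0, len(self.species_ids)))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_scenario(config: ScenarioConfig) -> list[str]:
    """Check every structural invariant; returns human-readable violations."""
    v: list[str] = []
    dom = config.domain
    if dom.width <= 0 or dom.height <= 0 or dom.grid_dx <= 0:
        v.append("domain: width, height and grid_dx must be positive")
    else:
        for name, length in (("width", dom.width), ("height", dom.height)):
            if abs(length / dom.grid_dx - round(length / dom.grid_dx)) > 1e-9:
                v.append(f"domain.{name}: not an integer multiple of grid_dx")
    if not (0 < dom.biofilm_height_cap < dom.height):
        v.append("domain.biofilm_height_cap: must lie strictly between 0 and height")

    sub_ids = config.substrate_ids()
    if len(set(sub_ids)) != len(sub_ids):
        v.append("substrates: duplicate ids")
    for sub in config.substrates:
        if sub.diffusion_coefficient <= 0:
            v.append(f"substrate {sub.id}: diffusion_coefficient must be > 0")
        if sub.top_boundary_concentration < 0:
            v.append(f"substrate {sub.id}: top_boundary_concentration must be >= 0")
        if not sub.is_bulk and sub.top_boundary_concentration != 0:
            v.append(f"substrate {sub.id}: byproducts must have zero top concentration")

    sp_ids = config.species_ids()
    if len(set(sp_ids)) != len(sp_ids):
        v.append("species: duplicate ids")
    for sp in config.species:
        for k in sp.kinetics:
            if k.substrate_id not in sub_ids:
                v.append(f"species {sp.id}: kinetic entry references unknown substrate {k.substrate_id}")
            if k.mu_max < 0:
                v.append(f"species {sp.id}/{k.substrate_id}: mu_max must be >= 0")
            if k.Ks <= 0:
                v.append(f"species {sp.id}/{k.substrate_id}: Ks must be > 0")
            if not (0 < k.Y <= 1):
                v.append(f"species {sp.id}/{k.substrate_id}: Y must be in (0, 1]")
        for rule in sp.byproducts:
            if rule.consumed not in sub_ids or rule.produced not in sub_ids:
                v.append(f"species {sp.id}: byproduct rule references unknown substrate")
                continue
            entry = sp.kinetic_for(rule.consumed)
            if entry is None:
                v.append(f"species {sp.id}: byproduct rule consumes {rule.consumed} without a kinetic entry")
            elif rule.gamma is not None:
                if not (0 <= rule.gamma <= 1):
                    v.append(f"species {sp.id}: gamma must be in [0, 1]")
                elif rule.gamma + entry.Y > 1 + 1e-9:
                    v.append(f"species {sp.id}: gamma + Y > 1 for substrate {rule.consumed} (mass balance)")
        if sp.maintenance_m < 0:
            v.append(f"species {sp.id}: maintenance_m must be >= 0")

    fracs = config.initial_abundance
    for sid in fracs:
        if sid not in sp_ids:
            v.append(f"initial_abundance: unknown species {sid}")
    if fracs and abs(sum(fracs.values()) - 1.0) > 1e-9:
        v.append("initial_abundance: fractions sum != 1")
    if any(f < 0 for f in fracs.values()):
        v.append("initial_abundance: negative fraction")

    if config.seed_count < 1:
        v.append("seed_count: must be >= 1")
    for ev in config.events:
        if ev.species_id not in sp_ids:
            v.append(f"event at {ev.time_h} h: unknown species {ev.species_id}")
        if ev.count < 0:
            v.append(f"event at {ev.time_h} h: count must be >= 0")
        if not (0 <= ev.time_h <= config.max_time_h):
            v.append(f"event at {ev.time_h} h: outside the growth phase [0, {config.max_time_h}] h")
    if config.radius_law not in ("area", "volume"):
        v.append(f"radius_law: unknown law {config.radius_law!r}")
    return v
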