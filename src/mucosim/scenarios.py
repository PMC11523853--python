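"""Ready-to-run scenario builders for the study's community designs.

Species come in three kinetic strategies obeying the growth-yield
trade-off (mu_max * Y held constant): a baseline (N), a rate strategist
(G, doubled mu_max) and a yield strategist (E, doubled Y).  Two parameter
tables exist: the two-species table and the three-species table whose
baseline runs twice as fast.  Byproduct (cross-feeding) kinetics are ten
times faster than the corresponding bulk kinetics, with the same yield.

Interaction topologies wire species to substrates:

* competition  — both consume one shared bulk nutrient;
* neutralism   — each consumes its own bulk nutrient;
* commensalism — the provider consumes a bulk nutrient and excretes a
  byproduct which is the beneficiary's sole food;
* mutualism    — each consumes its own bulk nutrient and the byproduct
  excreted by the partner.

Three-species invasion panels (a-j) place a newcomer, injected at 300 h,
in every combination of resident interaction x invader relation; the
wiring of each panel is documented on its builder.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_types import (
    ByproductRule,
    DomainSpec,
    InjectionEvent,
    KineticEntry,
    ScenarioConfig,
    SpeciesSpec,
    SubstrateSpec,
)

__all__ = [
    "SpeciesTemplate",
    "table1_species",
    "table2_species",
    "make_interaction",
    "two_species_config",
    "succession_config",
    "three_species_scenario",
    "named_scenarios",
    "build_named",
]

INTERACTIONS = ("competition", "neutralism", "commensalism", "mutualism")
DEFAULT_KS = 0.1
INJECTION_TIME_H = 300.0
INJECTION_COUNT = 5
# Maintenance rate applied to every catalog species (1/h).  Small against
# the growth rates (<= 3% of mu_max) but decisive deep in the community:
# it zeroes net growth where nutrients are exhausted, so the interior of a
# mature biofilm is demographically frozen rather than a slow upward
# conveyor, allowing the stratified steady states and mid-height newcomer
# establishment the model is meant to study.
DEFAULT_MAINTENANCE = 0.01


@dataclass(frozen=True)
class SpeciesTemplate:
    """Kinetic strategy card: bulk and byproduct Monod parameters."""

    kind: str
    bulk_mu: float
    bulk_Y: float
    byproduct_mu: float
    byproduct_Y: float
    Ks: float = DEFAULT_KS


_TABLE1 = {
    "N": SpeciesTemplate("N", 0.3, 0.15, 3.0, 0.15),
    "G": SpeciesTemplate("G", 0.6, 0.15, 6.0, 0.15),
    "E": SpeciesTemplate("E", 0.3, 0.30, 3.0, 0.30),
}
_TABLE2 = {
    "N": SpeciesTemplate("N", 0.6, 0.15, 6.0, 0.15),
    "G": SpeciesTemplate("G", 1.2, 0.15, 12.0, 0.15),
    "E": SpeciesTemplate("E", 0.6, 0.30, 6.0, 0.30),
}


def table1_species(kind: str) -> SpeciesTemplate:
    """Two-species parameter card: N 0.3/0.15, G 0.6/0.15, E 0.3/0.3 (bulk)."""
    try:
        return _TABLE1[kind]
    except KeyError:
        raise KeyError(f"unknown species kind {kind!r} (expected N, G or E)") from None


def table2_species(kind: str) -> SpeciesTemplate:
    """Three-species parameter card: baseline doubled (N 0.6/0.15 bulk)."""
    try:
        return _TABLE2[kind]
    except KeyError:
        raise KeyError(f"unknown species kind {kind!r} (expected N, G or E)") from None


def _bulk(sid: str) -> SubstrateSpec:
    return SubstrateSpec(id=sid, is_bulk=True, top_boundary_concentration=1.0)


def _byp(sid: str) -> SubstrateSpec:
    return SubstrateSpec(id=sid, is_bulk=False)


def _bulk_entry(t: SpeciesTemplate, sid: str) -> KineticEntry:
    return KineticEntry(substrate_id=sid, mu_max=t.bulk_mu, Ks=t.Ks, Y=t.bulk_Y)


def _byp_entry(t: SpeciesTemplate, sid: str) -> KineticEntry:
    return KineticEntry(substrate_id=sid, mu_max=t.byproduct_mu, Ks=t.Ks, Y=t.byproduct_Y)


def make_interaction(
    pair_type: str,
    templates: tuple[SpeciesTemplate, SpeciesTemplate],
    ids: tuple[str, str] = ("A", "B"),
    beneficiary_bulk: bool = False,
) -> tuple[list[SubstrateSpec], list[SpeciesSpec]]:
    """Substrate list and fully wired species pair for one topology.

    For commensalism the first species is the provider; the beneficiary
    has no bulk food unless ``beneficiary_bulk`` is set.
    """
    tA, tB = templates
    a, b = ids
    if pair_type == "competition":
        subs = [_bulk("S1")]
        spA = SpeciesSpec(id=a, kinetics=[_bulk_entry(tA, "S1")])
        spB = SpeciesSpec(id=b, kinetics=[_bulk_entry(tB, "S1")])
    elif pair_type == "neutralism":
        subs = [_bulk("S1"), _bulk("S2")]
        spA = SpeciesSpec(id=a, kinetics=[_bulk_entry(tA, "S1")])
        spB = SpeciesSpec(id=b, kinetics=[_bulk_entry(tB, "S2")])
    elif pair_type == "commensalism":
        subs = [_bulk("S1"), _byp("P1")]
        spA = SpeciesSpec(
            id=a,
            kinetics=[_bulk_entry(tA, "S1")],
            byproducts=[ByproductRule(consumed="S1", produced="P1")],
        )
        kinB = [_byp_entry(tB, "P1")]
        if beneficiary_bulk:
            subs.insert(1, _bulk("S2"))
            kinB.insert(0, _bulk_entry(tB, "S2"))
        spB = SpeciesSpec(id=b, kinetics=kinB)
    elif pair_type == "mutualism":
        subs = [_bulk("S1"), _bulk("S2"), _byp("P1"), _byp("P2")]
        spA = SpeciesSpec(
            id=a,
            kinetics=[_bulk_entry(tA, "S1"), _byp_entry(tA, "P2")],
            byproducts=[ByproductRule(consumed="S1", produced="P1")],
        )
        spB = SpeciesSpec(
            id=b,
            kinetics=[_bulk_entry(tB, "S2"), _byp_entry(tB, "P1")],
            byproducts=[ByproductRule(consumed="S2", produced="P2")],
        )
    else:
        raise ValueError(f"unsupported interaction {pair_type!r}")
    spA.maintenance_m = DEFAULT_MAINTENANCE
    spB.maintenance_m = DEFAULT_MAINTENANCE
    return subs, [spA, spB]


def two_species_config(
    interaction: str,
    kinds: tuple[str, str] = ("N", "N"),
    abundance: tuple[float, float] = (0.5, 0.5),
    table: int = 1,
    rng_seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Co-colonization of a species pair under one interaction topology."""
    pick = table1_species if table == 1 else table2_species
    tA, tB = pick(kinds[0]), pick(kinds[1])
    ids = (f"{kinds[0]}1", f"{kinds[1]}2")
    subs, species = make_interaction(interaction, (tA, tB), ids=ids)
    cfg = ScenarioConfig(
        substrates=subs,
        species=species,
        initial_abundance={ids[0]: abundance[0], ids[1]: abundance[1]},
        rng_seed=rng_seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def succession_config(
    interaction: str,
    resident_kind: str = "E",
    newcomer_kind: str = "G",
    injection_time_h: float = INJECTION_TIME_H,
    count: int = INJECTION_COUNT,
    rng_seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """A mature single-species biofilm invaded by a delayed newcomer pair-partner."""
    cfg = two_species_config(
        interaction,
        kinds=(resident_kind, newcomer_kind),
        abundance=(1.0, 0.0),
        table=1,
        rng_seed=rng_seed,
    )
    newcomer = cfg.species[1].id
    cfg.events = [InjectionEvent(time_h=injection_time_h, species_id=newcomer, count=count)]
    cfg.max_time_h = max(cfg.max_time_h, injection_time_h + 300.0)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# Three-species invasion panels
# ---------------------------------------------------------------------------

_PANEL_DOC = {
    "a": "commensal residents (R1 provider S1 -> P1, R2 beneficiary); invader competes for the provider's bulk S1",
    "b": "neutral residents (S1, S2); invader competes for both bulk nutrients",
    "c": "commensal residents; invader competes for the byproduct P1",
    "d": "mutualistic residents; invader competes for resident R1's bulk S1",
    "e": "mutualistic residents; invader competes for the byproduct P1",
    "f": "competing residents (shared S1); R1 excretes P1; invader is commensal beneficiary on P1",
    "g": "neutral residents; R1 excretes P1; invader is commensal beneficiary on P1",
    "h": "competing residents (shared S1); invader is neutral with its own bulk S2",
    "i": "competing residents; invader mutualistic with R1 (invader bulk S2 -> P2 feeds R1; R1's P1 feeds invader)",
    "j": "neutral residents (S1, S2); invader mutualistic with R1 (invader bulk S3 -> P3 feeds R1; R1's P1 feeds invader)",
}


def three_species_scenario(
    panel: str,
    invader_kind: str = "G",
    rng_seed: int = 0,
    injection_time_h: float = INJECTION_TIME_H,
    **overrides,
) -> ScenarioConfig:
    """Resident pair (baseline kinetics) plus a newcomer injected at 300 h.

    Panels a-e: the invader competes with the residents (over a bulk
    nutrient or over the shared byproduct); panels f-j: the invader joins
    cooperatively (commensal, neutral or mutualistic).  See module doc and
    the per-panel wiring notes in ``_PANEL_DOC``.
    """
    if panel not in _PANEL_DOC:
        raise KeyError(f"unknown panel {panel!r} (expected a-j)")
    tN = table2_species("N")
    tV = table2_species(invader_kind)
    inv = f"{invader_kind}3"

    resident_interaction = {
        "a": "commensalism", "c": "commensalism", "f": "competition",
        "b": "neutralism", "g": "neutralism", "h": "competition",
        "d": "mutualism", "e": "mutualism", "i": "competition", "j": "neutralism",
    }[panel]
    subs, species = make_interaction(resident_interaction, (tN, tN), ids=("N1", "N2"))

    if panel == "a" or panel == "d":
        invader = SpeciesSpec(id=inv, kinetics=[_bulk_entry(tV, "S1")])
    elif panel == "b":
        invader = SpeciesSpec(id=inv, kinetics=[_bulk_entry(tV, "S1"), _bulk_entry(tV, "S2")])
    elif panel == "c" or panel == "e":
        invader = SpeciesSpec(id=inv, kinetics=[_byp_entry(tV, "P1")])
    elif panel in ("f", "g"):
        subs.append(_byp("P1"))
        species[0].byproducts = [ByproductRule(consumed="S1", produced="P1")]
        invader = SpeciesSpec(id=inv, kinetics=[_byp_entry(tV, "P1")])
    elif panel == "h":
        subs.append(_bulk("S2"))
        invader = SpeciesSpec(id=inv, kinetics=[_bulk_entry(tV, "S2")])
    else:  # i, j: mutualism between invader and resident N1
        own_bulk = "S2" if panel == "i" else "S3"
        own_byp = "P2" if panel == "i" else "P3"
        subs.extend([_bulk(own_bulk), _byp("P1"), _byp(own_byp)])
        species[0].byproducts = [ByproductRule(consumed="S1", produced="P1")]
        species[0].kinetics.append(_byp_entry(tN, own_byp))
        invader = SpeciesSpec(
            id=inv,
            kinetics=[_bulk_entry(tV, own_bulk), _byp_entry(tV, "P1")],
            byproducts=[ByproductRule(consumed=own_bulk, produced=own_byp)],
        )

    invader.maintenance_m = DEFAULT_MAINTENANCE
    species.append(invader)
    cfg = ScenarioConfig(
        substrates=subs,
        species=species,
        initial_abundance={"N1": 0.5, "N2": 0.5, inv: 0.0},
        events=[InjectionEvent(time_h=injection_time_h, species_id=inv, count=INJECTION_COUNT)],
        max_time_h=injection_time_h + 300.0,
        rng_seed=rng_seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# Named catalog (CLI surface)
# ---------------------------------------------------------------------------

def named_scenarios() -> dict[str, str]:
    """Name -> description of every built-in scenario."""
    names: dict[str, str] = {}
    for inter in INTERACTIONS:
        names[f"pair-{inter}-NN"] = f"{inter}, two baseline species, co-colonization"
        names[f"pair-{inter}-GE"] = f"{inter}, rate vs yield strategist, co-colonization"
        names[f"succession-{inter}-EG"] = f"{inter}, resident E invaded by G at 300 h"
        names[f"succession-{inter}-GE"] = f"{inter}, resident G invaded by E at 300 h"
    for panel, doc in _PANEL_DOC.items():
        for kind in ("N", "G", "E"):
            names[f"invasion-{panel}-{kind}"] = f"panel {panel} ({doc}); invader kind {kind}"
    return names


def build_named(name: str, abundance: tuple[float, float] | None = None, rng_seed: int = 0) -> ScenarioConfig:
    parts = name.split("-")
    if parts[0] == "pair" and len(parts) == 3:
        kinds = (parts[2][0], parts[2][1])
        ab = abundance or (0.5, 0.5)
        return two_species_config(parts[1], kinds=kinds, abundance=ab, rng_seed=rng_seed)
    if parts[0] == "succession" and len(parts) == 3:
        return succession_config(parts[1], resident_kind=parts[2][0], newcomer_kind=parts[2][1], rng_seed=rng_seed)
    if parts[0] == "invasion" and len(parts) == 3:
        return three_species_scenario(parts[1], invader_kind=parts[2], rng_seed=rng_seed)
    raise KeyError(f"unknown scenario name {name!r}; see `scenarios list`")
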