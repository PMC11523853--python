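"""Community summaries, artifact I/O and snapshot rendering.

All numeric artifacts are CSV (diff-able, language neutral): the time
series (biomass and abundance per species), agent snapshots, and
concentration-field matrices whose row 0 is the substratum-adjacent grid
row.  Run metadata (full config + seed) goes to JSON.  Snapshots render
as side views of the niche: filled circles colored by species, the
substratum at the bottom and the height cap drawn as a dashed line.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_types import AgentPopulation, DomainSpec, ScenarioConfig, Trajectory, radius_of

__all__ = [
    "species_biomass",
    "abundance_fraction",
    "intermixing_index",
    "write_outputs",
    "read_trajectory",
    "render_snapshot",
]


def species_biomass(pop: AgentPopulation) -> np.ndarray:
    """Total frozen biomass per species (mass units), in species order."""
    totals = np.zeros(len(pop.species_ids))
    if pop.n:
        frozen = pop.view("frozen")
        np.add.at(totals, pop.view("species")[frozen], pop.view("mass")[frozen])
    return totals


def abundance_fraction(totals: np.ndarray) -> np.ndarray:
    totals = np.asarray(totals, dtype=float)
    s = totals.sum()
    if s <= 0:
        raise ValueError("abundance fractions undefined for zero total biomass")
    return totals / s


def intermixing_index(pop: AgentPopulation, k: int = 6, domain: DomainSpec | None = None) -> float:
    """Mean heterospecific fraction among each cell's k nearest neighbours.

    0 for a fully segregated (or monospecific) community; approaches the
    overall heterospecific fraction when species are well mixed.  Distances
    use the periodic x axis when a domain is given.
    """
    if pop.n < k + 1:
        raise ValueError(f"need at least {k + 1} agents for k={k}")
    pts = np.column_stack([pop.view("x"), pop.view("y")])
    if domain is not None:
        pts = np.column_stack([np.mod(pts[:, 0], domain.width), pts[:, 1]])
        tree = cKDTree(pts, boxsize=(domain.width, 4.0 * max(domain.height, 1.0)))
    else:
        tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k + 1)
    nbr = nbr[:, 1:]  # drop self
    sp = pop.view("species")
    hetero = sp[nbr] != sp[:, None]
    return float(hetero.mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _timeseries_frame(traj: Trajectory) -> pd.DataFrame:
    cols = {"time_h": traj.times}
    B, F, R = traj.biomass_array(), traj.fractions_array(), traj.removed_array()
    for i, sid in enumerate(traj.species_ids):
        cols[f"biomass_{sid}"] = B[:, i]
    for i, sid in enumerate(traj.species_ids):
        cols[f"fraction_{sid}"] = F[:, i]
    for i, sid in enumerate(traj.species_ids):
        cols[f"removed_{sid}"] = R[:, i]
    return pd.DataFrame(cols)


def write_outputs(
    traj: Trajectory,
    out_dir,
    config: ScenarioConfig | None = None,
    fields: np.ndarray | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _timeseries_frame(traj).to_csv(out / "timeseries.csv", index=False)
    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for t, pop in traj.snapshots:
        df = pd.DataFrame(
            {
                "uid": pop.view("uid"),
                "species": [pop.species_ids[s] for s in pop.view("species")],
                "mass": pop.view("mass"),
                "x": pop.view("x"),
                "y": pop.view("y"),
                "state": np.where(pop.view("frozen"), "frozen", "planktonic"),
            }
        )
        df.to_csv(snap_dir / f"t{t:09.2f}.csv", index=False)
    if config is not None:
        meta = {"config": config.to_dict(), "seed": config.rng_seed, "format": "mucosim-run-v1"}
        (out / "run.json").write_text(json.dumps(meta, indent=2))
        if fields is not None:
            for i, sub in enumerate(config.substrates):
                np.savetxt(out / f"field_{sub.id}.csv", fields[i], delimiter=",")
    return out


def read_trajectory(out_dir) -> Trajectory:
    """Round-trip reader for :func:`write_outputs` artifacts."""
    out = Path(out_dir)
    try:
        df = pd.read_csv(out / "timeseries.csv", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed timeseries.csv: {exc}") from exc
    species_ids = [c[len("biomass_") :] for c in df.columns if c.startswith("biomass_")]
    traj = Trajectory(species_ids=species_ids)
    traj.times = df["time_h"].tolist()
    traj.biomass = [row for row in df[[f"biomass_{s}" for s in species_ids]].to_numpy()]
    traj.fractions = [row for row in df[[f"fraction_{s}" for s in species_ids]].to_numpy()]
    traj.removed = [row for row in df[[f"removed_{s}" for s in species_ids]].to_numpy()]
    snap_dir = out / "snapshots"
    if snap_dir.is_dir():
        for path in sorted(snap_dir.glob("t*.csv")):
            t = float(path.stem[1:])
            sdf = pd.read_csv(path, float_precision="round_trip")
            pop = AgentPopulation(species_ids, capacity=max(len(sdf), 16))
            if len(sdf):
                idx = {sid: i for i, sid in enumerate(species_ids)}
                pop.add(
                    species=np.array([idx[s] for s in sdf["species"]]),
                    mass=sdf["mass"].to_numpy(),
                    x=sdf["x"].to_numpy(),
                    y=sdf["y"].to_numpy(),
                    frozen=(sdf["state"] == "frozen").to_numpy(),
                )
                pop.uid[: pop.n] = sdf["uid"].to_numpy()
            traj.snapshots.append((t, pop))
    return traj


def render_snapshot(
    pop: AgentPopulation,
    domain: DomainSpec,
    ax: plt.Axes | None = None,
    radius_law: str = "area",
    dpi: int = 120,
):
    """Side view of the community: circles by species, cap line at h."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6 * domain.height / domain.width), dpi=dpi)
    else:
        fig = ax.figure
    cmap = plt.get_cmap("tab10")
    if pop.n:
        radii = radius_of(pop.view("mass"), radius_law)
        for i in range(pop.n):
            ax.add_patch(
                plt.Circle(
                    (pop.x[i], pop.y[i]), radii[i],
                    color=cmap(int(pop.species[i]) % 10), linewidth=0,
                )
            )
    ax.axhline(domain.biofilm_height_cap, ls="--", lw=0.8, color="0.4")
    ax.axhline(0.0, color="k", lw=1.5)
    ax.set_xlim(0, domain.width)
    ax.set_ylim(-1, domain.height)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("height (um)")
    ax.set_aspect("equal")
    return fig
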