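"""Overlap relaxation ("shoving"), wall constraints and the height cap.

After growth and division neighbouring cells overlap.  Each shove step
assigns every overlapping pair two displacement vectors of half the
overlap, directed apart along the line of centers, sums the contributions
per agent and applies them simultaneously; iterating this to a small
residual overlap reproduces close packing.  The x axis is periodic
(minimum-image convention) and the substratum is impenetrable: a cell's
center can never drop below its radius.  Biomass reaching above the fixed
niche height h is removed, emulating erosion by luminal flow.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core_types import Agent, AgentPopulation, DomainSpec, radius_of

__all__ = ["overlap", "shove_step", "relax", "enforce_height_cap", "overlap_pairs"]

# y coordinates stay within [0, height]; the fake periodic box in y must be
# tall enough that images never come closer than any real pair.
_Y_BOX_FACTOR = 4.0


def _min_image_dx(dx: np.ndarray, width: float) -> np.ndarray:
    return dx - width * np.round(dx / width)


def overlap(a: Agent, b: Agent, domain: DomainSpec, radius_law: str = "area") -> float:
    """(r_a + r_b) - center distance, minimum image in x; <= 0 means clear."""
    dx = _min_image_dx(np.asarray(a.x - b.x), domain.width)
    d = float(np.hypot(dx, a.y - b.y))
    return radius_of(a.mass, radius_law) + radius_of(b.mass, radius_law) - d


def overlap_pairs(
    x: np.ndarray,
    y: np.ndarray,
    radii: np.ndarray,
    domain: DomainSpec,
    extra: float = 0.0,
) -> np.ndarray:
    """Indices (i, j) of all candidate contact pairs, i < j.

    Uses a k-d tree with a periodic box in x (the y period is padded far
    beyond reach so it never wraps).  The candidate set is every pair
    within the maximum possible contact distance; callers filter by the
    actual per-pair radii.
    """
    n = len(x)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    r_max = float(radii.max())
    ybox = _Y_BOX_FACTOR * max(domain.height, 1.0)
    pts = np.column_stack([np.mod(x, domain.width), y])
    tree = cKDTree(pts, boxsize=(domain.width, ybox))
    pairs = tree.query_pairs(2.0 * r_max + extra, output_type="ndarray")
    return pairs


def shove_step(
    pop: AgentPopulation,
    domain: DomainSpec,
    radius_law: str = "area",
    rng: np.random.Generator | None = None,
    pairs: np.ndarray | None = None,
) -> float:
    """One simultaneous shoving sweep in place; returns the max overlap found."""
    n = pop.n
    if n < 2:
        return 0.0
    x, y = pop.view("x"), pop.view("y")
    radii = radius_of(pop.view("mass"), radius_law)
    if pairs is None:
        pairs = overlap_pairs(x, y, radii, domain)
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    dx = _min_image_dx(x[i] - x[j], domain.width)
    dy = y[i] - y[j]
    dist = np.hypot(dx, dy)
    ov = radii[i] + radii[j] - dist
    hit = ov > 0
    if not hit.any():
        return float(ov.max(initial=0.0))
    i, j, dx, dy, dist, ov = i[hit], j[hit], dx[hit], dy[hit], dist[hit], ov[hit]

    coincident = dist < 1e-9
    if coincident.any():
        if rng is None:
            rng = np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(coincident.sum()))
        dx[coincident] = np.cos(theta) * 1e-9
        dy[coincident] = np.sin(theta) * 1e-9
        dist[coincident] = 1e-9

    ux, uy = dx / dist, dy / dist
    half = 0.5 * ov
    disp = np.zeros((n, 2))
    np.add.at(disp[:, 0], i, half * ux)
    np.add.at(disp[:, 1], i, half * uy)
    np.add.at(disp[:, 0], j, -half * ux)
    np.add.at(disp[:, 1], j, -half * uy)

    x += disp[:, 0]
    y += disp[:, 1]
    np.mod(x, domain.width, out=x)
    np.maximum(y, radii, out=y)  # substratum is rigid
    np.minimum(y, domain.height, out=y)
    return float(ov.max())


try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _seq_sweep(x, y, r, pairs, width, height):  # pragma: no cover - jitted
        worst = 0.0
        total = 0.0
        half_w = 0.5 * width
        for p in range(pairs.shape[0]):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = x[i] - x[j]
            if dx > half_w:
                dx -= width
            elif dx < -half_w:
                dx += width
            dy = y[i] - y[j]
            d2 = dx * dx + dy * dy
            rsum = r[i] + r[j]
            if d2 >= rsum * rsum:
                continue
            d = np.sqrt(d2)
            ov = rsum - d
            total += ov
            if ov > worst:
                worst = ov
            if d > 1e-9:
                s = 0.5 * ov / d
                x[i] += s * dx
                y[i] += s * dy
                x[j] -= s * dx
                y[j] -= s * dy
                if y[i] < r[i]:
                    y[i] = r[i]
                elif y[i] > height:
                    y[i] = height
                if y[j] < r[j]:
                    y[j] = r[j]
                elif y[j] > height:
                    y[j] = height
        return worst, total

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


def relax(
    pop: AgentPopulation,
    domain: DomainSpec,
    tol: float = 0.05,
    max_iter: int = 50,
    radius_law: str = "area",
    rng: np.random.Generator | None = None,
    sweeps_per_iter: int = 10,
) -> float:
    """Drive the worst pairwise overlap down to <= tol (um).

    Each outer iteration rebuilds the neighbour-pair list (with a distance
    margin so it stays valid while cells move) and runs a block of
    Gauss-Seidel sweeps of the pairwise half-overlap displacement rule.
    Sequential (immediate-update) sweeps propagate expansion through a
    packed colony far faster than simultaneous sweeps, whose displacement
    waves travel one cell layer per sweep; the per-pair rule is identical
    to :func:`shove_step`, which remains the simultaneous reference.

    Under continuous interior turnover the worst pairwise overlap can sit
    somewhat above tol at the active growth front when the budget runs
    out; the packing stays physical as long as the budget is generous.
    Mutates positions in place and returns the final max overlap; the
    next growth step's relaxation continues the job.
    """
    worst = 0.0
    if not _HAVE_NUMBA:
        for _ in range(max_iter * sweeps_per_iter):
            worst = shove_step(pop, domain, radius_law=radius_law, rng=rng)
            if worst <= tol:
                break
        return worst

    n = pop.n
    if n < 2:
        return 0.0
    x, y = pop.view("x"), pop.view("y")
    radii = np.ascontiguousarray(radius_of(pop.view("mass"), radius_law))
    margin = max(2.0 * float(radii.max()), 1.0) * 0.5
    height = float(domain.height)
    width = float(domain.width)
    for _ in range(max_iter):
        np.mod(x, width, out=x)
        # separate coincident centers before the sweep so the kernel's
        # direction is defined; direction drawn from the step's RNG
        pairs = overlap_pairs(x, y, radii, domain, extra=margin)
        if len(pairs):
            dxp = _min_image_dx(x[pairs[:, 0]] - x[pairs[:, 1]], width)
            dyp = y[pairs[:, 0]] - y[pairs[:, 1]]
            coincident = np.flatnonzero(dxp * dxp + dyp * dyp < 1e-18)
            if len(coincident):
                gen = rng if rng is not None else np.random.default_rng(0)
                theta = gen.uniform(0.0, 2.0 * np.pi, size=len(coincident))
                ii = pairs[coincident, 0]
                x[ii] += 1e-6 * np.cos(theta)
                y[ii] = np.maximum(y[ii] + 1e-6 * np.sin(theta), radii[ii])
        p64 = np.ascontiguousarray(pairs.astype(np.int32))
        x0, y0 = x.copy(), y.copy()
        for _ in range(sweeps_per_iter):
            worst, total = _seq_sweep(x, y, radii, p64, width, height)
            if worst <= tol:
                np.mod(x, width, out=x)
                return worst
            if np.hypot(x - x0, y - y0).max() > margin / 2:
                break  # pair list stale; rebuild
    np.mod(x, width, out=x)
    return worst


# hexagonal close packing of discs: area fraction 0.9069, disc area pi/4 per
# unit mass => reference biomass density of a packed bed
PACKED_DENSITY = 0.9069 / (np.pi / 4.0)  # ~1.155 mass / um^2


def growth_advection(
    pop: AgentPopulation,
    dm: np.ndarray,
    row: np.ndarray,
    col: np.ndarray,
    domain: DomainSpec,
    rho_ref: float = PACKED_DENSITY,
) -> None:
    """Lift cells by the upward displacement a packed bed imposes on growth.

    In a close-packed, laterally confined bed, newly produced biomass can
    only be accommodated by displacing the material above it upward.  The
    per-column displacement at height y is the biomass produced below y
    this step, divided by (column width x packing density).  Applying that
    field before shoving removes the systematic expansion from the
    relaxation workload, leaving only local rearrangements; the shoving
    pass remains the authority on pairwise non-overlap.
    """
    if pop.n == 0 or len(dm) == 0:
        return
    added = np.zeros((domain.ny, domain.nx))
    np.add.at(added, (row, col), dm)
    below = np.vstack([np.zeros((1, domain.nx)), np.cumsum(added, axis=0)[:-1]])
    lift = (below + 0.5 * added) / (domain.grid_dx * rho_ref)
    y = pop.view("y")
    y += lift[row, col]
    np.clip(y, 0.0, domain.height, out=y)


def enforce_height_cap(pop: AgentPopulation, h: float) -> np.ndarray:
    """Remove frozen agents whose center lies strictly above h.

    Returns per-species removed mass (for the biomass ledger).  Center
    height is the criterion; a cell tangent above the line survives.
    """
    removed = np.zeros(len(pop.species_ids))
    if pop.n == 0:
        return removed
    above = pop.view("y") > h
    if above.any():
        np.add.at(removed, pop.view("species")[above], pop.view("mass")[above])
        pop.keep(~above)
    return removed
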