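"""Pseudo-steady-state substrate fields on the finite-volume grid.

Within each growth step the chemistry is assumed to relax instantly
relative to biomass change, so every substrate obeys

    div(D grad S) + R(S) = 0

on a rectangular grid of square blocks, with a fixed concentration at the
top face (the lumen supplies bulk nutrients; byproducts see a zero sink
there), zero flux through the substratum, and periodic side faces matching
the wrapped agent domain.

The reaction term couples substrates through the community:
consumption of substrate i is Monod uptake summed over species, scaled by
1/Y (a unit of new biomass costs 1/Y units of substrate); production of a
byproduct is a fraction gamma of the donor species' consumption of its
precursor.  A config flag (`literal_yield_form`) multiplies uptake by Y
instead, for comparison with the alternative convention.

The nonlinear system is solved by Picard iteration with the uptake term
linearized semi-implicitly: the Monod denominator is lagged, so the
consumption enters the matrix diagonal as a nonnegative coefficient.  The
resulting matrix is an M-matrix and iterates stay nonnegative.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_types import AgentPopulation, DomainSpec, ScenarioConfig

__all__ = [
    "monod_factor",
    "accumulate_block_biomass",
    "reaction_rate",
    "DiffusionSolver",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


def monod_factor(S, Ks):
    """Saturation factor S/(S+Ks) in [0, 1)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("negative concentration")
    if np.any(np.asarray(Ks) <= 0):
        raise ValueError("Ks must be positive")
    out = S / (S + Ks)
    return float(out) if out.ndim == 0 else out


def accumulate_block_biomass(pop: AgentPopulation, domain: DomainSpec) -> np.ndarray:
    """Per-species biomass density on the grid, shape (n_species, ny, nx).

    Each agent's full mass is credited to the block containing its center;
    densities are mass per block area (mass units / um^2).
    """
    n_sp = len(pop.species_ids)
    dens = np.zeros((n_sp, domain.ny, domain.nx))
    if pop.n == 0:
        return dens
    x, y = pop.view("x"), pop.view("y")
    if np.any((x < 0) | (x >= domain.width) | (y < 0) | (y > domain.height)):
        raise ValueError("agent outside the domain")
    row, col = domain.block_of(x, y)
    np.add.at(dens, (pop.view("species"), row, col), pop.view("mass"))
    dens /= domain.grid_dx**2
    return dens


class _Kinetics:
    """Dense per-(substrate, species) kinetic arrays derived from a config."""

    def __init__(self, config: ScenarioConfig):
        subs = config.substrate_ids()
        sps = config.species_ids()
        ns, nk = len(subs), len(sps)
        self.substrate_ids = subs
        self.mu = np.zeros((ns, nk))
        self.Ks = np.ones((ns, nk))
        self.Y = np.ones((ns, nk))
        # gamma[i, j, k]: fraction of species k's consumption of substrate j
        # excreted as substrate i
        self.gamma = np.zeros((ns, ns, nk))
        sub_idx = {s: i for i, s in enumerate(subs)}
        for k, spsp in enumerate(config.species):
            for entry in spsp.kinetics:
                i = sub_idx[entry.substrate_id]
                self.mu[i, k] = entry.mu_max
                self.Ks[i, k] = entry.Ks
                self.Y[i, k] = entry.Y
            for rule in spsp.byproducts:
                i = sub_idx[rule.produced]
                j = sub_idx[rule.consumed]
                self.gamma[i, j, k] = spsp.gamma_for(rule)
        self.literal_yield = config.literal_yield_form

    def uptake_per_biomass(self, S: np.ndarray) -> np.ndarray:
        """Specific consumption rate q[i, k, ...] at concentrations S[i, ...].

        q = mu * S/(S+Ks) / Y (or * Y in the literal form); units 1/h per
        unit biomass density, i.e. concentration/h once multiplied by x_k.
        """
        f = S[:, None] / (S[:, None] + self.Ks.reshape(self.Ks.shape + (1,) * (S.ndim - 1)))
        mu = self.mu.reshape(self.mu.shape + (1,) * (S.ndim - 1))
        Y = self.Y.reshape(self.Y.shape + (1,) * (S.ndim - 1))
        if self.literal_yield:
            return mu * f * Y
        return mu * f / Y


def reaction_rate(
    S_all: dict[str, float],
    biomass: dict[str, float] | np.ndarray,
    config: ScenarioConfig,
    substrate_id: str,
) -> float:
    """Net volumetric reaction rate R_i (concentration/h) at one block.

    Consumption by every species plus production as a gamma-fraction of
    donor consumption of precursor substrates.  A scalar reference path
    used by tests and by the solver oracle; the solver itself evaluates
    the same kinetics in array form.
    """
    kin = _Kinetics(config)
    subs = kin.substrate_ids
    if substrate_id not in subs:
        raise KeyError(f"unknown substrate {substrate_id!r}")
    S = np.array([S_all[s] for s in subs])
    if isinstance(biomass, dict):
        x = np.array([biomass.get(sid, 0.0) for sid in config.species_ids()])
    else:
        x = np.asarray(biomass, dtype=float)
    q = kin.uptake_per_biomass(S)  # (n_sub, n_species)
    i = subs.index(substrate_id)
    consumption = float(q[i] @ x)
    production = float(np.einsum("jk,jk,k->", kin.gamma[i], q, x))
    return -consumption + production


class DiffusionSolver:
    """Steady-state solver bound to one scenario's grid, substrates and species."""

    def __init__(self, config: ScenarioConfig, tol: float = 1e-6, max_iter: int = 200):
        self.config = config
        self.domain = config.domain
        self.kin = _Kinetics(config)
        self.tol = tol
        self.max_iter = max_iter
        self.S_top = np.array([s.top_boundary_concentration for s in config.substrates])
        self._assemble()

    def _assemble(self) -> None:
        dom = self.domain
        nx, ny = dom.nx, dom.ny
        N = nx * ny
        dx2 = dom.grid_dx**2
        rows, cols, vals = [], [], []
        diag = np.zeros(N)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for j in range(ny):
            for i in range(nx):
                p = j * nx + i
                # periodic x neighbours
                for ii in ((i - 1) % nx, (i + 1) % nx):
                    add(p, j * nx + ii, -1.0)
                    diag[p] += 1.0
                if j > 0:  # neighbour below; j == 0 face is no-flux
                    add(p, (j - 1) * nx + i, -1.0)
                    diag[p] += 1.0
                if j < ny - 1:
                    add(p, (j + 1) * nx + i, -1.0)
                    diag[p] += 1.0
                else:  # top face: half-cell Dirichlet ghost
                    diag[p] += 2.0
        lap = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
        lap += sp.diags(diag)
        # per-substrate operator: (D/dx^2) * lap ; rhs from the top Dirichlet face
        self._lap = lap
        self._a = np.array([s.diffusion_coefficient / dx2 for s in self.config.substrates])
        b_top = np.zeros(N)
        b_top[(ny - 1) * nx :] = 2.0
        self._b_top = b_top  # multiply by a_i * S_top_i per substrate

    def solve(
        self,
        biomass_density: np.ndarray,
        S_init: np.ndarray | None = None,
        tol: float | None = None,
        max_iter: int | None = None,
    ) -> np.ndarray:
        """Concentration stack (n_substrates, ny, nx) at pseudo-steady state."""
        tol = self.tol if tol is None else tol
        max_iter = self.max_iter if max_iter is None else max_iter
        dom = self.domain
        nx, ny = dom.nx, dom.ny
        n_sub = len(self.config.substrates)
        x_flat = biomass_density.reshape(biomass_density.shape[0], -1)
        if S_init is None:
            S = np.repeat(self.S_top[:, None], ny * nx, axis=1)
        else:
            S = S_init.reshape(n_sub, -1).copy()
        np.maximum(S, 0.0, out=S)

        no_biomass = not np.any(x_flat)
        for it in range(max_iter):
            S_old = S.copy()
            # production sources from the previous iterate (explicit)
            q = self.kin.uptake_per_biomass(S)  # (n_sub, n_sp, N)
            cons_flux = q * x_flat[None, :, :]  # consumption rate per substrate/species
            prod = np.einsum("ijk,jkn->in", self.kin.gamma, cons_flux)
            for i in range(n_sub):
                # semi-implicit uptake: mu*x/(Y*(S_prev+Ks)) multiplies S_new,
                # finite at S_prev = 0 and keeps the matrix an M-matrix
                den = S[i][None, :] + self.kin.Ks[i][:, None]  # (n_sp, N)
                if self.kin.literal_yield:
                    coef = self.kin.mu[i][:, None] * self.kin.Y[i][:, None] / den
                else:
                    coef = self.kin.mu[i][:, None] / (self.kin.Y[i][:, None] * den)
                c = (coef * x_flat).sum(axis=0)
                A = self._a[i] * self._lap + sp.diags(c)
                b = self._a[i] * self.S_top[i] * self._b_top + prod[i]
                S[i] = spla.spsolve(A.tocsr(), b)
            np.maximum(S, 0.0, out=S)
            scale = max(float(np.abs(S).max()), 1e-12)
            if no_biomass or float(np.abs(S - S_old).max()) <= tol * scale:
                return S.reshape(n_sub, ny, nx)
        resid = float(np.abs(S - S_old).max()) / scale
        raise SolverError(
            f"steady-state Picard iteration did not converge in {max_iter} sweeps "
            f"(relative change {resid:.3e} > tol {tol:.1e})"
        )

    def residual(self, S: np.ndarray, biomass_density: np.ndarray) -> np.ndarray:
        """Discrete nonlinear residual D*L(S) + R(S), shape (n_sub, ny, nx)."""
        n_sub = S.shape[0]
        Sf = S.reshape(n_sub, -1)
        x_flat = biomass_density.reshape(biomass_density.shape[0], -1)
        q = self.kin.uptake_per_biomass(Sf)
        cons_flux = q * x_flat[None, :, :]
        prod = np.einsum("ijk,jkn->in", self.kin.gamma, cons_flux)
        out = np.empty_like(Sf)
        for i in range(n_sub):
            out[i] = (
                -(self._a[i] * (self._lap @ Sf[i]) - self._a[i] * self.S_top[i] * self._b_top)
                - cons_flux[i].sum(axis=0)
                + prod[i]
            )
        return out.reshape(S.shape)

    def top_flux(self, S: np.ndarray) -> np.ndarray:
        """Diffusive influx through the top boundary per substrate (conc*um^2/h ... in block units).

        Positive = into the domain.  Units: concentration * um^2 / h summed
        over top-row blocks (consistent with R integrated over block areas).
        """
        dom = self.domain
        nx, ny = dom.nx, dom.ny
        top = S[:, ny - 1, :]
        per_block = 2.0 * self._a[:, None] * (self.S_top[:, None] - top) * dom.grid_dx**2
        return per_block.sum(axis=1)
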