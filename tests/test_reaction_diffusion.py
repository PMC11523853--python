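"""Steady-state substrate fields: kinetics, assembly, oracles, conservation."""

import numpy as np
import pytest

from mucosim.core_types import (
    ByproductRule,
    DomainSpec,
    KineticEntry,
    ScenarioConfig,
    SpeciesSpec,
    SubstrateSpec,
)
from mucosim.reaction_diffusion import (
    DiffusionSolver,
    accumulate_block_biomass,
    monod_factor,
    reaction_rate,
)
from tests.conftest import make_population


class TestMonodFactor:
    @pytest.mark.parametrize("S,Ks,expected", [(0.1, 0.1, 0.5), (0.0, 0.1, 0.0), (0.9, 0.1, 0.9)])
    def test_values(self, S, Ks, expected):
        assert monod_factor(S, Ks) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        S = np.linspace(0, 50, 200)
        f = monod_factor(S, 0.3)
        assert (np.diff(f) > 0).all()
        assert (f >= 0).all() and (f < 1).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            monod_factor(-0.1, 0.1)


class TestBlockBiomass:
    def test_mass_assigned_to_center_block(self):
        dom = DomainSpec(width=50, height=50, grid_dx=10, biofilm_height_cap=30)
        pop = make_population(["A"], [(0, 2.0, 5.0, 5.0)])
        dens = accumulate_block_biomass(pop, dom)
        assert dens[0, 0, 0] == pytest.approx(0.02)
        assert dens.sum() == pytest.approx(0.02)

    def test_empty_population_gives_zero_field(self, small_domain):
        dens = accumulate_block_biomass(make_population(["A"], []), small_domain)
        assert dens.shape == (1, 5, 5)
        assert not dens.any()

    def test_masses_sum_within_block(self, small_domain):
        pop = make_population(["A"], [(0, 1.0, 5.0, 5.0), (0, 1.0, 5.0, 6.0)])
        dens = accumulate_block_biomass(pop, small_domain)
        assert dens[0, 0, 0] == pytest.approx(0.02)

    def test_total_mass_recovered(self, small_domain, rng):
        rows = [(0, m, x, y) for m, x, y in zip(
            rng.uniform(0.5, 2, 40), rng.uniform(0, 50, 40), rng.uniform(0, 50, 40))]
        pop = make_population(["A"], rows)
        dens = accumulate_block_biomass(pop, small_domain)
        assert dens.sum() * 100.0 == pytest.approx(pop.view("mass").sum())

    def test_agent_outside_domain_rejected(self, small_domain):
        pop = make_population(["A"], [(0, 1.0, 60.0, 5.0)])
        with pytest.raises(ValueError):
            accumulate_block_biomass(pop, small_domain)


def _single_species_config(mu=0.3, Ks=0.1, Y=0.15, gamma=None, literal=False):
    return ScenarioConfig(
        domain=DomainSpec(width=50, height=50, grid_dx=10, biofilm_height_cap=30),
        substrates=[SubstrateSpec(id="S1"), SubstrateSpec(id="P1", is_bulk=False)],
        species=[
            SpeciesSpec(
                id="A",
                kinetics=[KineticEntry("S1", mu_max=mu, Ks=Ks, Y=Y)],
                byproducts=[ByproductRule("S1", "P1", gamma=gamma)],
            )
        ],
        initial_abundance={"A": 1.0},
        literal_yield_form=literal,
    )


class TestReactionRate:
    def test_zero_biomass_zero_rate(self):
        cfg = _single_species_config()
        assert reaction_rate({"S1": 0.5, "P1": 0.0}, {"A": 0.0}, cfg, "S1") == 0.0

    def test_consumption_scales_inversely_with_yield(self):
        cfg = _single_species_config(mu=0.3, Ks=0.1, Y=0.15)
        R = reaction_rate({"S1": 0.1, "P1": 0.0}, {"A": 0.02}, cfg, "S1")
        assert R == pytest.approx(-0.3 * 0.5 * 0.02 / 0.15)  # -0.02 / h

    def test_byproduct_source_is_gamma_fraction_of_consumption(self):
        cfg = _single_species_config(gamma=0.85)
        R = reaction_rate({"S1": 0.1, "P1": 0.0}, {"A": 0.02}, cfg, "P1")
        assert R == pytest.approx(0.85 * 0.02)  # +0.017 / h

    def test_default_gamma_is_one_minus_yield(self):
        cfg = _single_species_config(Y=0.15)
        cons = -reaction_rate({"S1": 0.1, "P1": 0.0}, {"A": 0.02}, cfg, "S1")
        prod = reaction_rate({"S1": 0.1, "P1": 0.0}, {"A": 0.02}, cfg, "P1")
        assert prod == pytest.approx(0.85 * cons)

    def test_literal_yield_form_multiplies_by_Y(self):
        cfg = _single_species_config(literal=True)
        R = reaction_rate({"S1": 0.1, "P1": 0.0}, {"A": 0.02}, cfg, "S1")
        assert R == pytest.approx(-0.3 * 0.5 * 0.02 * 0.15)

    def test_mass_balance_when_gamma_plus_Y_is_one(self):
        """biomass made + byproduct made = substrate consumed, per unit time."""
        cfg = _single_species_config(Y=0.25, gamma=0.75)
        S = {"S1": 0.37, "P1": 0.0}
        x = {"A": 0.04}
        consumed = -reaction_rate(S, x, cfg, "S1")
        produced = reaction_rate(S, x, cfg, "P1")
        growth = 0.3 * monod_factor(0.37, 0.1) * 0.04
        assert growth + produced == pytest.approx(consumed, rel=1e-12)


class TestSolveSteadyState:
    def test_zero_biomass_uniform_dirichlet(self):
        cfg = _single_species_config()
        solver = DiffusionSolver(cfg)
        S = solver.solve(np.zeros((1, 5, 5)))
        np.testing.assert_allclose(S[0], 1.0, atol=1e-10)  # bulk
        np.testing.assert_allclose(S[1], 0.0, atol=1e-10)  # byproduct

    def test_diffusivity_scale_invariance_without_reaction(self):
        cfg = _single_species_config()
        S1 = DiffusionSolver(cfg).solve(np.zeros((1, 5, 5)))
        for sub in cfg.substrates:
            sub.diffusion_coefficient *= 2
        S2 = DiffusionSolver(cfg).solve(np.zeros((1, 5, 5)))
        np.testing.assert_allclose(S1, S2, atol=1e-12)

    @staticmethod
    def _column_config(q, k_sink, n=50, D=2.5e3, dx=10.0):
        """1-D column (single x block): saturated sink q in the bottom k blocks."""
        mu, Y, Ks = 0.3, 0.15, 1e-9
        x_dens = q * Y / mu
        cfg = ScenarioConfig(
            domain=DomainSpec(width=dx, height=n * dx, grid_dx=dx, biofilm_height_cap=k_sink * dx),
            substrates=[SubstrateSpec(id="S1", diffusion_coefficient=D)],
            species=[SpeciesSpec(id="A", kinetics=[KineticEntry("S1", mu_max=mu, Ks=Ks, Y=Y)])],
            initial_abundance={"A": 1.0},
        )
        dens = np.zeros((1, n, 1))
        dens[0, :k_sink, 0] = x_dens
        return cfg, dens

    def test_two_layer_column_matches_discrete_closed_form(self):
        """Constant sink in the bottom 60 um of a 500 um column.

        The difference equations telescope: the face flux above i sink
        blocks carries i*q*dx, so S_{i+1}-S_i = (i+1)*q*dx^2/D in the sink
        layer and k*q*dx^2/D above it, anchored at the top half-cell
        Dirichlet face.  That closed form is evaluated here independently
        of the sparse solver.
        """
        n, k, D, dx = 50, 6, 2.5e3, 10.0
        a = D / dx**2
        q = 0.003 * a
        cfg, dens = self._column_config(q, k, n=n, D=D, dx=dx)
        S = DiffusionSolver(cfg, tol=1e-13, max_iter=500).solve(dens)[0, :, 0]

        F = np.where(np.arange(n - 1) < k, (np.arange(n - 1) + 1) * q / a, k * q / a)
        expected = np.empty(n)
        expected[n - 1] = 1.0 - F[n - 2] / 2
        for i in range(n - 2, -1, -1):
            expected[i] = expected[i + 1] - F[i]
        np.testing.assert_allclose(S, expected, rtol=1e-6)

    def test_column_converges_to_continuum_profile(self):
        """Refining dx approaches -D S'' = -q's piecewise quadratic/linear at O(dx^2)."""
        D, H, L = 2.5e3, 500.0, 60.0
        q = 0.075

        def continuum(z):
            S_L = 1.0 - q * L * (H - L) / D
            return np.where(z <= L, S_L - q * (L**2 - z**2) / (2 * D), S_L + q * L / D * (z - L))

        errs = []
        for dx in (10.0, 5.0):
            n = int(H / dx)
            k = int(L / dx)
            cfg, dens = self._column_config(q, k, n=n, D=D, dx=dx)
            S = DiffusionSolver(cfg, tol=1e-13, max_iter=500).solve(dens)[0, :, 0]
            z = (np.arange(n) + 0.5) * dx
            errs.append(np.abs(S - continuum(z)).max())
        # the sink edge coincides with a face, where the flux stencil is
        # first-order; the error must at least halve with dx
        assert errs[0] < 0.05
        assert errs[1] < 0.6 * errs[0]

    def test_monotone_with_height_for_single_sink(self):
        cfg, dens = self._column_config(q=0.05, k_sink=6)
        S = DiffusionSolver(cfg).solve(dens)[0, :, 0]
        assert (np.diff(S) >= -1e-12).all()

    def test_conservation_top_influx_equals_net_consumption(self):
        """Diffusive influx through the top face balances reaction, per substrate."""
        cfg = _single_species_config(gamma=0.85)
        rows = [(0, 1.5, 5.0, 5.0), (0, 2.5, 25.0, 15.0), (0, 1.0, 45.0, 5.0)]
        pop = make_population(["A"], rows)
        dens = accumulate_block_biomass(pop, cfg.domain)
        solver = DiffusionSolver(cfg, tol=1e-12)
        S = solver.solve(dens)
        influx = solver.top_flux(S)
        area = cfg.domain.grid_dx**2
        net = np.zeros(2)
        for i, sid in enumerate(("S1", "P1")):
            for r in range(cfg.domain.ny):
                for c in range(cfg.domain.nx):
                    net[i] -= reaction_rate(
                        {"S1": S[0, r, c], "P1": S[1, r, c]},
                        np.array([dens[0, r, c]]), cfg, sid,
                    ) * area
        np.testing.assert_allclose(influx, net, atol=1e-6 * max(abs(net[0]), 1.0))

    def test_nonlinear_solution_matches_dense_fixed_point_oracle(self):
        """5x5 grid, one occupied block: agree with a brute-force dense iteration."""
        cfg = _single_species_config(mu=0.3, Ks=0.1, Y=0.15, gamma=0.85)
        for sub in cfg.substrates:
            sub.diffusion_coefficient = 100.0  # make the reaction term bite
        dom = cfg.domain
        dens = np.zeros((1, 5, 5))
        dens[0, 1, 2] = 0.5
        S = DiffusionSolver(cfg, tol=1e-14, max_iter=2000).solve(dens)

        # independent dense discretization + fixed-point iteration
        n = 25
        a = 100.0 / dom.grid_dx**2
        A = np.zeros((n, n))
        b_top = np.zeros(n)
        for r in range(5):
            for c in range(5):
                p = r * 5 + c
                for cc in ((c - 1) % 5, (c + 1) % 5):
                    A[p, r * 5 + cc] -= a
                    A[p, p] += a
                if r > 0:
                    A[p, (r - 1) * 5 + c] -= a
                    A[p, p] += a
                if r < 4:
                    A[p, (r + 1) * 5 + c] -= a
                    A[p, p] += a
                else:
                    A[p, p] += 2 * a
                    b_top[p] = 2 * a
        x = dens[0].ravel()
        mu, Ks, Y, gamma = 0.3, 0.1, 0.15, 0.85
        S1 = np.full(n, 1.0)
        P1 = np.zeros(n)
        for _ in range(20000):
            cons = mu * S1 / (S1 + Ks) * x / Y
            S1_new = np.linalg.solve(A, b_top * 1.0 - cons)
            P1_new = np.linalg.solve(A, b_top * 0.0 + gamma * cons)
            if max(np.abs(S1_new - S1).max(), np.abs(P1_new - P1).max()) < 1e-14:
                S1, P1 = S1_new, P1_new
                break
            S1, P1 = S1_new, P1_new
        np.testing.assert_allclose(S[0].ravel(), S1, atol=1e-8)
        np.testing.assert_allclose(S[1].ravel(), P1, atol=1e-8)

    def test_nonnegative_concentrations_under_strong_sink(self):
        cfg, dens = self._column_config(q=10.0, k_sink=6)
        cfg.species[0].kinetics[0].Ks = 0.05
        S = DiffusionSolver(cfg).solve(dens)
        assert (S >= 0).all()
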