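"""Shoving, wall constraints, neighbour search, height cap, growth advection."""

import numpy as np
import pytest

from mucosim.core_types import Agent, AgentPopulation, DomainSpec, radius_of
from mucosim.mechanics import (
    enforce_height_cap,
    growth_advection,
    overlap,
    overlap_pairs,
    relax,
    shove_step,
)
from tests.conftest import make_population


def brute_force_pairs(x, y, radii, width, slack=0.0):
    """O(n^2) reference neighbour scan with periodic x (minimum image)."""
    out = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dx -= width * round(dx / width)
            if np.hypot(dx, y[i] - y[j]) < radii[i] + radii[j] + slack:
                out.append((i, j))
    return set(out)


def max_overlap(pop, domain):
    x, y = pop.view("x"), pop.view("y")
    r = radius_of(pop.view("mass"))
    worst = 0.0
    for i in range(pop.n):
        for j in range(i + 1, pop.n):
            dx = x[i] - x[j]
            dx -= domain.width * round(dx / domain.width)
            worst = max(worst, r[i] + r[j] - np.hypot(dx, y[i] - y[j]))
    return worst


class TestOverlap:
    def _agent(self, x, y, mass=1.0):
        return Agent(uid=0, species_id="A", mass=mass, x=x, y=y)

    def test_half_micron_gap(self):
        dom = DomainSpec()
        assert overlap(self._agent(0, 10), self._agent(0.5, 10), dom) == pytest.approx(0.5)

    def test_tangency_is_zero(self):
        dom = DomainSpec()
        assert overlap(self._agent(0, 10), self._agent(1.0, 10), dom) == pytest.approx(0.0)

    def test_minimum_image_across_periodic_seam(self):
        dom = DomainSpec(width=500)
        assert overlap(self._agent(0.2, 10), self._agent(499.8, 10), dom) == pytest.approx(0.6)


class TestShoveStep:
    def test_isolated_pair_separates_to_tangency(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 100.0, 10.0), (0, 1.0, 100.5, 10.0)])
        shove_step(pop, dom, rng=rng)
        d = abs(pop.x[0] - pop.x[1])
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_equal_and_opposite_displacements(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 100.0, 10.0), (0, 1.0, 100.6, 10.0)])
        x0 = pop.view("x").copy()
        shove_step(pop, dom, rng=rng)
        moved = pop.view("x") - x0
        assert moved[0] == pytest.approx(-moved[1])

    def test_clear_configuration_is_fixed_point(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 10.0, 10.0), (0, 1.0, 15.0, 10.0)])
        x0, y0 = pop.view("x").copy(), pop.view("y").copy()
        shove_step(pop, dom, rng=rng)
        np.testing.assert_array_equal(pop.view("x"), x0)
        np.testing.assert_array_equal(pop.view("y"), y0)

    def test_wall_clamp_keeps_center_above_radius(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 100.0, 0.5), (0, 1.0, 100.0, 1.2)])
        shove_step(pop, dom, rng=rng)
        assert (pop.view("y") >= radius_of(pop.view("mass")) - 1e-12).all()

    def test_conserves_mass_and_count(self, rng):
        dom = DomainSpec(width=50, height=50)
        pop = make_population(
            ["A", "B"],
            [(i % 2, 1.0 + 0.1 * i, 10 + 0.4 * i, 5.0) for i in range(20)],
        )
        masses0 = np.sort(pop.view("mass").copy())
        shove_step(pop, dom, rng=rng)
        assert pop.n == 20
        np.testing.assert_array_equal(np.sort(pop.view("mass")), masses0)


class TestRelax:
    def test_dense_cluster_reaches_tolerance(self, rng):
        dom = DomainSpec(width=100, height=200, biofilm_height_cap=60)
        n = 100
        pop = make_population(
            ["A"],
            [(0, 1.0, x, y) for x, y in zip(rng.uniform(40, 60, n), rng.uniform(1, 20, n))],
        )
        worst = relax(pop, dom, tol=0.05, max_iter=200, rng=rng)
        assert worst <= 0.05
        assert max_overlap(pop, dom) <= 0.05 + 1e-9

    def test_already_relaxed_unchanged(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 10.0, 10.0), (0, 1.0, 20.0, 10.0)])
        x0 = pop.view("x").copy()
        relax(pop, dom, rng=rng)
        np.testing.assert_array_equal(pop.view("x"), x0)

    def test_single_agent_noop(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 10.0, 10.0)])
        assert relax(pop, dom, rng=rng) == 0.0

    def test_coincident_centers_get_separated(self, rng):
        dom = DomainSpec()
        pop = make_population(["A"], [(0, 1.0, 50.0, 10.0), (0, 1.0, 50.0, 10.0)])
        worst = relax(pop, dom, tol=0.05, rng=rng)
        assert worst <= 0.05

    def test_biomass_conserved(self, rng):
        dom = DomainSpec(width=50, height=50)
        pop = make_population(
            ["A"], [(0, 1.2, 25 + 0.3 * i, 5.0) for i in range(30)]
        )
        total0 = pop.view("mass").sum()
        relax(pop, dom, rng=rng)
        assert pop.view("mass").sum() == total0


class TestNeighborSearch:
    def test_tree_pairs_match_all_pairs_scan(self, rng):
        """Spatial index finds exactly the pairs a brute-force scan finds."""
        dom = DomainSpec(width=100, height=200)
        n = 500
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0.5, 40, n)
        m = rng.uniform(0.8, 2.0, n)
        radii = radius_of(m)
        pairs = overlap_pairs(x, y, radii, dom)
        # tree returns candidates within 2*r_max; filter both sides identically
        got = set()
        for i, j in pairs:
            i, j = int(min(i, j)), int(max(i, j))
            dx = x[i] - x[j]
            dx -= 100 * round(dx / 100)
            if np.hypot(dx, y[i] - y[j]) < radii[i] + radii[j]:
                got.add((i, j))
        assert got == brute_force_pairs(x, y, radii, 100.0)


class TestHeightCap:
    def test_strictly_above_removed(self):
        pop = make_population(["A"], [(0, 1.0, 10, 59.0), (0, 1.0, 20, 60.0), (0, 1.0, 30, 61.0)])
        removed = enforce_height_cap(pop, 60.0)
        assert pop.n == 2
        assert removed[0] == pytest.approx(1.0)
        assert set(np.round(pop.view("y"))) == {59.0, 60.0}

    def test_empty_population(self):
        pop = make_population(["A"], [])
        removed = enforce_height_cap(pop, 60.0)
        assert pop.n == 0 and removed[0] == 0.0

    def test_no_removal_below_cap(self):
        pop = make_population(["A"], [(0, 1.0, 10, 5.0), (0, 2.0, 20, 30.0)])
        removed = enforce_height_cap(pop, 60.0)
        assert pop.n == 2 and removed[0] == 0.0

    def test_removed_ledger_split_by_species(self):
        pop = make_population(["A", "B"], [(0, 1.5, 10, 70.0), (1, 2.5, 20, 70.0), (0, 1.0, 30, 10.0)])
        removed = enforce_height_cap(pop, 60.0)
        np.testing.assert_allclose(removed, [1.5, 2.5])


class TestGrowthAdvection:
    def test_cell_above_growing_block_is_lifted(self):
        dom = DomainSpec(width=10, height=100, grid_dx=10, biofilm_height_cap=60)
        # grower in block row 0, passive rider in row 3
        pop = make_population(["A"], [(0, 1.0, 5.0, 5.0), (0, 1.0, 5.0, 35.0)])
        dm = np.array([2.0, 0.0])
        row, col = dom.block_of(pop.view("x"), pop.view("y"))
        y0 = pop.view("y").copy()
        rho = 1.155
        growth_advection(pop, dm, row, col, dom, rho_ref=rho)
        lift = pop.view("y") - y0
        assert lift[1] == pytest.approx(2.0 / (10.0 * rho))
        assert lift[0] == pytest.approx(0.5 * 2.0 / (10.0 * rho))  # half its own block's growth

    def test_no_growth_no_motion(self):
        dom = DomainSpec(width=10, height=100, grid_dx=10)
        pop = make_population(["A"], [(0, 1.0, 5.0, 5.0), (0, 1.0, 5.0, 35.0)])
        row, col = dom.block_of(pop.view("x"), pop.view("y"))
        y0 = pop.view("y").copy()
        growth_advection(pop, np.zeros(2), row, col, dom)
        np.testing.assert_array_equal(pop.view("y"), y0)

    def test_columns_are_independent(self):
        dom = DomainSpec(width=20, height=100, grid_dx=10)
        # grower in column 0; rider in column 1 must not move
        pop = make_population(["A"], [(0, 1.0, 5.0, 5.0), (0, 1.0, 15.0, 35.0)])
        dm = np.array([3.0, 0.0])
        row, col = dom.block_of(pop.view("x"), pop.view("y"))
        y0 = pop.view("y").copy()
        growth_advection(pop, dm, row, col, dom)
        assert pop.y[1] == y0[1]
        assert pop.y[0] > y0[0]
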