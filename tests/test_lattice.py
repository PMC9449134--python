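"""Unit tests of the elementary cellular-automaton events."""

import numpy as np
import pytest

from invabc.config import (InteractionMatrix, PhenotypeParams,
                           SimulationConfig)
from invabc.lattice import (collapse_to_2d, effective_motility,
                            enumerate_propensities, execute_death,
                            execute_division, execute_move,
                            initialize_spheroid, global_proportions)

from conftest import state_from_sites


def ball_site_count(radius: int) -> int:
    """Brute-force count of integer lattice points with |x|^2 <= r^2."""
    r = np.arange(-radius, radius + 1)
    d2 = (r[:, None, None] ** 2 + r[None, :, None] ** 2
          + r[None, None, :] ** 2)
    return int((d2 <= radius * radius).sum())


class TestInitializeSpheroid:
    def test_radius_five_pure_culture_seeds_515_sites(self):
        cfg = SimulationConfig(lattice_edge=30, seed_radius=5,
                               seeding_ratio=1.0, end_time=1.0, rng_seed=1)
        state = initialize_spheroid(cfg)
        assert state.count("A") == 515 == ball_site_count(5)
        assert state.count("B") == 0
        assert state.time == 0.0

    def test_seeded_sites_lie_within_radius(self):
        cfg = SimulationConfig(lattice_edge=30, seed_radius=5, end_time=1.0)
        state = initialize_spheroid(cfg)
        d = np.linalg.norm(state.positions("A") - np.array(cfg.center), axis=1)
        assert d.max() == pytest.approx(5.0)  # touches but never exceeds

    def test_radius_zero_single_cell_at_center(self):
        cfg = SimulationConfig(lattice_edge=9, seed_radius=0, end_time=1.0)
        state = initialize_spheroid(cfg)
        assert state.total_cells == 1
        assert tuple(state.positions("A")[0]) == cfg.center

    def test_mixed_seeding_partitions_the_ball(self):
        cfg = SimulationConfig(lattice_edge=30, seed_radius=5,
                               seeding_ratio=0.5, end_time=1.0, rng_seed=7)
        state = initialize_spheroid(cfg)
        assert state.count("A") + state.count("B") == 515
        assert 0 < state.count("A") < 515

    def test_seeding_is_reproducible(self):
        cfg = SimulationConfig(lattice_edge=30, seed_radius=5,
                               seeding_ratio=0.5, end_time=1.0, rng_seed=3)
        a = initialize_spheroid(cfg)
        b = initialize_spheroid(cfg)
        assert np.array_equal(a.grid, b.grid)


class TestEffectiveMotility:
    def test_paper_formula(self):
        model = InteractionMatrix.received(by_a=2.0)
        assert effective_motility("A", 1.0, {"B": 0.5}, model) == 2.0

    def test_zero_interaction_is_identity(self):
        model = InteractionMatrix.none()
        assert effective_motility("A", 1.3, {"B": 0.9}, model) == 1.3

    def test_monoculture_returns_base(self):
        model = InteractionMatrix.received(by_a=5.0)
        assert effective_motility("A", 1.0, {"B": 0.0}, model) == 1.0

    def test_negative_result_clamped_to_zero(self):
        model = InteractionMatrix.received(by_a=-20.0)
        assert effective_motility("A", 1.0, {"B": 0.5}, model) == 0.0

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            effective_motility("A", -1.0, {"B": 0.0}, InteractionMatrix.none())


class TestPropensities:
    def test_single_cell_total(self, single_cell_state):
        prop = enumerate_propensities(single_cell_state,
                                      PhenotypeParams(1.0, 5.0))
        assert prop["total"] == pytest.approx(6.1)

    def test_empty_lattice_total_zero(self):
        state = state_from_sites(5, {})
        prop = enumerate_propensities(state, PhenotypeParams(1.0, 5.0))
        assert prop["total"] == 0.0

    def test_two_clone_fixture_rates(self, two_cell_state, two_cell_params):
        prop = enumerate_propensities(two_cell_state, two_cell_params)
        assert prop["total"] == pytest.approx(4.3)
        assert prop["rates"]["A"]["division"] == pytest.approx(1.0)
        assert prop["rates"]["B"]["death"] == pytest.approx(0.2)

    def test_interaction_raises_total_through_motility(self, two_cell_state,
                                                       two_cell_params):
        model = InteractionMatrix.received(by_a=4.0)
        prop = enumerate_propensities(two_cell_state, two_cell_params, model)
        # A's motility becomes 1 + 0.5 * 4 = 3; total rises by 2
        assert prop["total"] == pytest.approx(6.3)


class TestMove:
    def test_isolated_cell_moves_chebyshev_one(self, single_cell_state):
        state = single_cell_state
        assert execute_move(state, (4, 4, 4), seed=11)
        assert state.total_cells == 1
        new = state.positions("A")[0]
        assert np.abs(new - 4).max() == 1
        state.check_consistency()

    def test_fully_blocked_cell_is_null_event(self):
        sites = {(4 + dx, 4 + dy, 4 + dz): "A"
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)}
        state = state_from_sites(9, sites)
        before = state.grid.copy()
        assert not execute_move(state, (4, 4, 4), seed=5)
        assert np.array_equal(state.grid, before)

    def test_target_choice_is_uniform_over_neighbours(self):
        counts = {}
        n = 26_000
        for seed in range(n):
            state = state_from_sites(9, {(4, 4, 4): "A"})
            execute_move(state, (4, 4, 4), seed=seed)
            counts[tuple(state.positions("A")[0])] = counts.get(
                tuple(state.positions("A")[0]), 0) + 1
        assert len(counts) == 26
        expected = n / 26
        sigma = np.sqrt(n * (1 / 26) * (25 / 26))
        for c in counts.values():
            assert abs(c - expected) < 3 * sigma


class TestDivision:
    def test_open_neighbourhood_produces_two_cells(self, single_cell_state):
        state = single_cell_state
        assert execute_division(state, (4, 4, 4), seed=2)
        assert state.count("A") == 2
        d = np.abs(state.positions("A") - 4).max(axis=1)
        assert sorted(d.tolist()) == [0, 1]

    def test_full_shell_without_aggression_blocks(self):
        sites = {(4 + dx, 4 + dy, 4 + dz): "A"
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)}
        state = state_from_sites(9, sites)
        assert not execute_division(state, (4, 4, 4), aggression=1, seed=1)
        assert state.count("A") == 27

    def test_aggression_pushes_chain_outward_preserving_labels(self):
        # fully packed lattice except one empty site three steps along +x
        # from the dividing cell; the only legal push is down that ray
        L = 9
        sites = {(x, y, z): "A"
                 for x in range(L) for y in range(L) for z in range(L)}
        del sites[(5, 4, 4)]          # the single empty site
        sites[(2, 4, 4)] = "B"        # the dividing cell (k=0 on the ray)
        sites[(3, 4, 4)] = "B"        # k=1, pushed
        sites[(4, 4, 4)] = "A"        # k=2, pushed into the empty site
        state = state_from_sites(L, sites)
        n_a, n_b = state.count("A"), state.count("B")
        assert execute_division(state, (2, 4, 4), aggression=3, seed=8)
        assert state.grid[2, 4, 4] == 2   # mother stays
        assert state.grid[3, 4, 4] == 2   # daughter (clone B)
        assert state.grid[4, 4, 4] == 2   # pushed B
        assert state.grid[5, 4, 4] == 1   # pushed A fills the empty site
        assert state.count("B") == n_b + 1
        assert state.count("A") == n_a
        state.check_consistency()

    def test_aggression_cannot_reach_past_its_distance(self):
        # fully enclosed 5x5x5 block: nearest empty is 2 away, aggression 1
        sites = {(4 + dx, 4 + dy, 4 + dz): "A"
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)}
        state = state_from_sites(9, sites)
        assert not execute_division(state, (4, 4, 4), aggression=1, seed=3)
        assert execute_division(state, (4, 4, 4), aggression=2, seed=3)
        assert state.count("A") == 28
        state.check_consistency()


class TestDeath:
    def test_single_cell_death_empties_lattice(self, single_cell_state):
        state = single_cell_state
        execute_death(state, (4, 4, 4))
        assert state.total_cells == 0
        prop = enumerate_propensities(state, PhenotypeParams(1.0, 5.0))
        assert prop["total"] == 0.0

    def test_death_in_full_shell_opens_one_site(self):
        sites = {(4 + dx, 4 + dy, 4 + dz): "A"
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)}
        state = state_from_sites(9, sites)
        execute_death(state, (4, 4, 4))
        assert state.count("A") == 26
        assert state.grid[4, 4, 4] == 0
        state.check_consistency()


class TestCollapse:
    def test_single_cell_single_pixel(self, single_cell_state):
        masks = collapse_to_2d(single_cell_state)
        assert masks["A"].sum() == 1
        assert masks["A"][4, 4]
        assert masks["B"].sum() == 0

    def test_stacked_cells_collapse_to_one_pixel(self):
        state = state_from_sites(9, {(4, 4, 2): "A", (4, 4, 6): "A"})
        masks = collapse_to_2d(state)
        assert masks["A"].sum() == 1

    def test_random_occupancy_matches_projection_oracle(self):
        rng = np.random.default_rng(12)
        L = 12
        sites = {tuple(s): ("A" if rng.random() < 0.5 else "B")
                 for s in rng.integers(0, L, size=(80, 3))}
        state = state_from_sites(L, sites)
        masks = collapse_to_2d(state)
        for clone in ("A", "B"):
            expect = np.zeros((L, L), dtype=bool)
            for (x, y, z), c in sites.items():
                if c == clone:
                    expect[x, y] = True
            assert np.array_equal(masks[clone], expect)


def test_global_proportions_sum_to_one(two_cell_state):
    props = global_proportions(two_cell_state)
    assert props["A"] + props["B"] == pytest.approx(1.0)
    assert props["A"] == pytest.approx(0.5)
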