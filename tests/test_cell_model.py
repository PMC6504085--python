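"""Unit tests for the off-lattice cell-center Monte Carlo model."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from cellsim.cell_model import (
    Cell,
    CellType,
    ModelParams,
    Population,
    Trajectory,
    accept_probability,
    cycle_length_floor,
    divide_cell,
    local_density,
    monte_carlo_step,
    pair_potential,
    realized_division_intervals,
    run_cell_model,
    sample_cycle_length,
    seed_population,
    seeding_radius,
    total_energy,
)


def make_cell(cid=0, x=0.0, y=0.0, radius=1.0, phase="G1", axis=0.0,
              separation=-1.0, ctype=None):
    ctype = ctype or CellType(name="t", cycle_mean=12.0)
    c = Cell(id=cid, type=ctype, center=np.array([x, y], dtype=float),
             radius=radius, cycle_length=12.0, birth_time=0.0)
    c.phase = phase
    c.axis = axis
    c.separation = separation
    return c


# ---------------------------------------------------------------------------
# sample_cycle_length
# ---------------------------------------------------------------------------

class TestSampleCycleLength:
    def test_degenerate_sd_zero(self, rng):
        ct = CellType(name="t", cycle_mean=12.0, cycle_sd=0.0)
        assert sample_cycle_length(ct, rng) == 12.0

    def test_mean_recovered(self, rng):
        ct = CellType(name="A", cycle_mean=12.0, cycle_sd=4.0)
        draws = np.array([sample_cycle_length(ct, rng) for _ in range(10_000)])
        a = (cycle_length_floor(1.0) - 12.0) / 4.0
        m, v = stats.truncnorm.stats(a, np.inf, loc=12.0, scale=4.0, moments="mv")
        se = math.sqrt(float(v) / len(draws))
        assert abs(draws.mean() - float(m)) < 3 * se

    def test_truncation_bound(self, rng):
        ct = CellType(name="t", cycle_mean=1.0, cycle_sd=10.0)
        floor = cycle_length_floor(1.0)
        draws = [sample_cycle_length(ct, rng, mitosis_duration=1.0)
                 for _ in range(10_000)]
        assert min(draws) >= floor

    def test_deterministic_given_state(self):
        ct = CellType(name="t", cycle_mean=12.0, cycle_sd=4.0)
        a = sample_cycle_length(ct, np.random.default_rng(9))
        b = sample_cycle_length(ct, np.random.default_rng(9))
        assert a == b


# ---------------------------------------------------------------------------
# seed_population
# ---------------------------------------------------------------------------

class TestSeedPopulation:
    def test_realized_density_exact(self, rng):
        params = ModelParams(initial_num=100, hours=72.0, density=0.01)
        types = [CellType(name="t", cycle_mean=24.0)]
        cells = seed_population(params, types, rng)
        circle_r = seeding_radius(cells, params.density)
        occupied = sum(math.pi * r * r for c in cells for _, r in c.disks())
        assert occupied / (math.pi * circle_r ** 2) == pytest.approx(0.01, abs=1e-12)

    def test_single_cell(self, rng):
        params = ModelParams(initial_num=1, hours=1.0, density=0.05)
        cells = seed_population(params, [CellType(name="t", cycle_mean=24.0)], rng)
        assert len(cells) == 1

    def test_largest_remainder_counts(self, rng):
        params = ModelParams(initial_num=100, hours=1.0, density=0.01)
        types = [CellType(name="a", cycle_mean=12.0, proportion=0.5),
                 CellType(name="b", cycle_mean=24.0, proportion=0.5)]
        cells = seed_population(params, types, rng)
        names = [c.type.name for c in cells]
        assert names.count("a") == 50 and names.count("b") == 50

    def test_no_overlaps(self, rng):
        params = ModelParams(initial_num=60, hours=1.0, density=0.3)
        cells = seed_population(params, [CellType(name="t", cycle_mean=24.0)], rng)
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = np.hypot(*(cells[i].center - cells[j].center))
                assert d >= cells[i].radius + cells[j].radius - 1e-12

    def test_packing_failure_message(self, rng):
        params = ModelParams(initial_num=40, hours=1.0, density=0.85)
        with pytest.raises(RuntimeError, match="density"):
            seed_population(params, [CellType(name="t", cycle_mean=24.0)], rng)

    def test_desynchronized_radii(self, rng):
        params = ModelParams(initial_num=200, hours=1.0, density=0.01)
        cells = seed_population(params, [CellType(name="t", cycle_mean=24.0,
                                                  cycle_sd=2.0)], rng)
        radii = np.array([c.radius for c in cells])
        assert radii.min() >= 1.0 - 1e-12
        assert radii.max() <= math.sqrt(2.0) + 1e-12
        assert radii.std() > 0.05  # not all at the same cycle position


# ---------------------------------------------------------------------------
# pair_potential / accept_probability
# ---------------------------------------------------------------------------

class TestPairPotential:
    def test_out_of_range_is_zero(self):
        params = ModelParams()
        a = make_cell(0, 0.0, 0.0)
        b = make_cell(1, 2.0 + params.adhesion_range + 1.0, 0.0)
        assert pair_potential(a, b, params) == 0.0

    def test_contact_is_adhesion_well(self):
        params = ModelParams()
        a = make_cell(0, 0.0, 0.0)
        b = make_cell(1, 2.0, 0.0)  # d = s exactly
        assert pair_potential(a, b, params) == -params.epsilon_adh

    def test_half_overlap_hand_value(self):
        params = ModelParams(epsilon_rep=4.0)
        a = make_cell(0, 0.0, 0.0)
        b = make_cell(1, 1.0, 0.0)  # d = s/2
        assert pair_potential(a, b, params) == pytest.approx(1.0, abs=1e-12)

    def test_m_phase_sums_disk_pairs(self):
        params = ModelParams()
        m = make_cell(0, 0.0, 0.0, phase="M", axis=0.0, separation=1.0)
        b = make_cell(1, 3.0, 0.0)
        expected = sum(
            params.epsilon_rep * ((s - d) / s) ** 2 if d < s
            else (-params.epsilon_adh if d < s + params.adhesion_range else 0.0)
            for d, s in [(abs(3.0 - (-0.5)), 2.0), (abs(3.0 - 0.5), 2.0)]
        )
        assert pair_potential(m, b, params) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        params = ModelParams()
        a = make_cell(0, 0.0, 0.2, phase="M", axis=0.7, separation=0.8)
        b = make_cell(1, 1.5, -0.3, radius=1.2)
        assert pair_potential(a, b, params) == pair_potential(b, a, params)


class TestAcceptProbability:
    @pytest.mark.parametrize("de,expected", [
        (0.0, 1.0),
        (-5.0, 1.0),
        (math.log(2.0), 0.5),
    ])
    def test_closed_form(self, de, expected):
        assert accept_probability(de) == pytest.approx(expected, abs=1e-15)


# ---------------------------------------------------------------------------
# division geometry and cycle progression
# ---------------------------------------------------------------------------

class TestDivision:
    def test_daughter_geometry(self, rng):
        params = ModelParams()
        parent = make_cell(7, 1.0, 2.0, phase="M", axis=0.3, separation=1.5)
        da, db = divide_cell(parent, now=10.0, params=params, rng=rng,
                             id_a=100, id_b=101)
        assert da.radius == db.radius == parent.type.size
        assert np.hypot(*(da.center - db.center)) == pytest.approx(2.0, abs=1e-12)
        assert da.birth_time == db.birth_time == 10.0
        assert da.phase == db.phase == "G1"
        assert da.cycle_length > 0 and db.cycle_length > 0

    def test_isolated_cell_divides_at_cycle_length(self):
        params = ModelParams(initial_num=1, hours=30.0, density=0.001,
                             epsilon_adh=0.0, seed=2)
        types = [CellType(name="t", cycle_mean=12.0, cycle_sd=0.0)]
        traj = run_cell_model(params, types)
        intervals = realized_division_intervals(traj)
        assert len(intervals) > 0
        # one MC-step granularity plus rare sibling-contact rejections
        assert np.all(np.abs(intervals - 12.0) <= 0.3)

    def test_enter_s_emitted_once_per_cycle(self, small_trajectory):
        per_cell: dict[int, int] = {}
        for e in small_trajectory.events:
            if e.kind == "enter_S":
                per_cell[e.cell_id] = per_cell.get(e.cell_id, 0) + 1
        assert per_cell, "no enter_S events recorded"
        assert all(n == 1 for n in per_cell.values())


# ---------------------------------------------------------------------------
# local_density
# ---------------------------------------------------------------------------

class TestLocalDensity:
    def test_isolated_cell(self):
        c = make_cell(0)
        assert local_density(c, [c]) == 0.0

    def test_full_coverage(self):
        c = make_cell(0)
        giant = make_cell(1, 0.5, 0.0, radius=100.0)
        assert local_density(c, [c, giant]) == 1.0

    def test_radius_factor_validation(self):
        c = make_cell(0)
        with pytest.raises(ValueError):
            local_density(c, [c], radius_factor=1.0)

    def test_monte_carlo_area_oracle(self):
        # one unit neighbor tangent at (2, 0); annulus 1 < r <= 3
        c = make_cell(0)
        nb = make_cell(1, 2.0, 0.0)
        estimate = local_density(c, [c, nb], radius_factor=3.0)
        mc_rng = np.random.default_rng(2024)
        n_pts = 1_000_000
        rr = np.sqrt(mc_rng.uniform(1.0, 9.0, n_pts))  # equal-area radial sampling
        th = mc_rng.uniform(0.0, 2.0 * math.pi, n_pts)
        px, py = rr * np.cos(th), rr * np.sin(th)
        oracle = float((((px - 2.0) ** 2 + py ** 2) <= 1.0).mean())
        assert estimate == pytest.approx(oracle, abs=1e-2)


# ---------------------------------------------------------------------------
# monte_carlo_step / run_cell_model
# ---------------------------------------------------------------------------

class TestMonteCarloStep:
    def test_energy_bookkeeping_oracle(self, rng):
        params = ModelParams(initial_num=40, hours=0.0, density=0.25, seed=3)
        cells = seed_population(params, [CellType(name="t", cycle_mean=6.0,
                                                  cycle_sd=1.0)], rng)
        pop = Population(cells, params)
        for _ in range(120):
            if len(pop.cells) > 50:
                break
            e_tracked_before = pop.energy
            e_brute_before = total_energy(pop.cells, params)
            monte_carlo_step(pop, params, rng)
            de_tracked = pop.energy - e_tracked_before
            de_brute = total_energy(pop.cells, params) - e_brute_before
            assert abs(de_tracked - de_brute) < 1e-8
        assert abs(pop.energy - pop.total_energy()) < 1e-8

    def test_cell_count_never_decreases(self, rng):
        params = ModelParams(initial_num=10, hours=0.0, density=0.2, seed=4)
        cells = seed_population(params, [CellType(name="t", cycle_mean=4.0)], rng)
        pop = Population(cells, params)
        count = len(pop.cells)
        for _ in range(100):
            monte_carlo_step(pop, params, rng)
            assert len(pop.cells) >= count
            count = len(pop.cells)

    def test_isolated_growth_always_accepted(self, rng):
        params = ModelParams(initial_num=1, hours=0.0, density=0.01, seed=5)
        cells = seed_population(params, [CellType(name="t", cycle_mean=12.0)], rng)
        cells[0].growth_accepted = 0  # restart schedule
        cells[0].radius = 1.0
        cells[0].phase = "G1"
        pop = Population(cells, params)
        before = cells[0].growth_accepted
        for _ in range(20):
            monte_carlo_step(pop, params, rng)
        assert pop.cells[0].growth_accepted == before + 20


class TestRunCellModel:
    def test_workflow_example_parameters_complete(self):
        # initial count 100, 72 hours, density 0.01 -> growing population
        params = ModelParams(initial_num=100, hours=18.0, density=0.01, seed=6)
        traj = run_cell_model(params, [CellType(name="t", cycle_mean=18.0,
                                                cycle_sd=2.0)])
        assert len(traj.snapshots[-1]) > 100

    def test_hours_zero(self):
        params = ModelParams(initial_num=5, hours=0.0, density=0.05, seed=7)
        traj = run_cell_model(params)
        assert traj.times == [0.0]
        assert len(traj.snapshots) == 1

    def test_determinism(self, tmp_path):
        params = ModelParams(initial_num=8, hours=8.0, density=0.05, seed=8)
        types = [CellType(name="t", cycle_mean=8.0, cycle_sd=1.0)]
        t1 = run_cell_model(params, types)
        t2 = run_cell_model(params, types)
        p1, e1 = tmp_path / "a.jsonl", tmp_path / "ae.jsonl"
        p2, e2 = tmp_path / "b.jsonl", tmp_path / "be.jsonl"
        t1.save(p1, e1)
        t2.save(p2, e2)
        assert p1.read_bytes() == p2.read_bytes()
        assert e1.read_bytes() == e2.read_bytes()

    def test_times_strictly_increasing(self, small_trajectory):
        times = np.array(small_trajectory.times)
        assert np.all(np.diff(times) > 0)

    def test_population_growth_law_sparse(self, isolated_type_a_run):
        # sparse 12h-cycle cells should at least double every 15 h early on
        traj = isolated_type_a_run
        sizes = traj.population_sizes()
        for start in (0, 15, 21):
            assert sizes[start + 15] >= 2 * sizes[start]

    def test_trajectory_roundtrip(self, small_trajectory, tmp_path):
        tp, ep = tmp_path / "t.jsonl", tmp_path / "e.jsonl"
        small_trajectory.save(tp, ep)
        loaded = Trajectory.load(tp, ep)
        assert loaded.times == small_trajectory.times
        assert loaded.snapshots == small_trajectory.snapshots
        assert loaded.events == small_trajectory.events
        assert loaded.params == small_trajectory.params

    def test_division_events_produce_two_daughters(self, small_trajectory):
        traj = small_trajectory
        births: dict[float, int] = {}
        seen: set[int] = set()
        for snap in traj.snapshots:
            for c in snap:
                if c.id not in seen:
                    seen.add(c.id)
                    if c.birth_time > 0:
                        births[round(c.birth_time, 6)] = births.get(round(c.birth_time, 6), 0) + 1
        div_counts: dict[float, int] = {}
        for e in traj.events:
            if e.kind == "division":
                div_counts[round(e.time, 6)] = div_counts.get(round(e.time, 6), 0) + 1
        for t, n_div in div_counts.items():
            assert births.get(t, 0) == 2 * n_div
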