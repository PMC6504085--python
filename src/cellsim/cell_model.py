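"""Off-lattice, cell-center Monte Carlo model of a growing 2-D cell population.

Each cell is a disk (a two-disk dumbbell during mitosis) whose center moves in
continuous space.  Cells interact through a short-range pair potential
(quadratic overlap penalty plus a square adhesion well) and every change —
migration, growth, dumbbell deformation — is a Metropolis trial accepted with
probability ``min(1, exp(-dE))``.

Units: length in nominal cell radii (a size-1 newborn cell has radius 1),
time in hours, energy in units of kT.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

PHASES = ("G1", "S", "G2", "M")

#: area-ratio thresholds a = (r/r0)^2 at which a cell enters S, G2 and M.
PHASE_THRESHOLDS = (1.3, 1.7, 2.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellType:
    """A named cell type with its cycle-length distribution.

    ``size`` is the nominal newborn radius; ``proportion`` is the fraction of
    the initial population assigned to this type.
    """

    name: str
    size: float = 1.0
    cycle_mean: float = 24.0
    cycle_sd: float = 0.0
    proportion: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_mean <= 0:
            raise ValueError(f"cycle_mean must be > 0, got {self.cycle_mean}")
        if self.cycle_sd < 0:
            raise ValueError(f"cycle_sd must be >= 0, got {self.cycle_sd}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion must be in [0, 1], got {self.proportion}")
        if self.size <= 0:
            raise ValueError(f"size must be > 0, got {self.size}")


@dataclass
class Cell:
    """Mutable state of a single simulated cell."""

    id: int
    type: CellType
    center: np.ndarray
    radius: float
    cycle_length: float
    birth_time: float
    phase: str = "G1"
    axis: float = 0.0           # division axis (radians); meaningful in M
    separation: float = -1.0    # dumbbell center distance; >= 0 only in M
    growth_accepted: int = 0    # accepted area increments this cycle
    growth_target: int = 1      # increments needed to double the area
    growth_recent: int = 0      # accepted increments since the last snapshot
    m_entry: float | None = None
    phase_entry_times: dict = field(default_factory=dict)

    @property
    def area_ratio(self) -> float:
        return 1.0 + self.growth_accepted / self.growth_target

    def disks(self) -> list[tuple[np.ndarray, float]]:
        """Constituent disks: one in interphase, two (dumbbell) in M."""
        if self.phase == "M":
            half = 0.5 * max(self.separation, 0.0)
            off = half * np.array([math.cos(self.axis), math.sin(self.axis)])
            r0 = self.type.size
            return [(self.center - off, r0), (self.center + off, r0)]
        return [(self.center, self.radius)]


@dataclass
class ModelParams:
    """Parameters of the population-level Monte Carlo model."""

    initial_num: int = 10
    hours: float = 24.0
    density: float = 0.05
    boundary: str = "unbounded"          # "unbounded" | "circular"
    boundary_radius: float | None = None  # defaults to the seeding radius
    epsilon_rep: float = 2000.0
    epsilon_adh: float = 0.1
    adhesion_range: float = 0.3
    mc_steps_per_hour: int = 10
    max_migration: float = 0.25
    mitosis_duration: float = 1.0
    record_interval: float = 1.0
    phase_thresholds: tuple[float, float, float] = PHASE_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_num < 1:
            raise ValueError(f"initial_num must be >= 1, got {self.initial_num}")
        if self.hours < 0:
            raise ValueError(f"hours must be >= 0, got {self.hours}")
        if not 0.0 < self.density < 1.0:
            raise ValueError(f"density must be in (0, 1), got {self.density}")
        if self.boundary not in ("unbounded", "circular"):
            raise ValueError(f"boundary must be 'unbounded' or 'circular', got {self.boundary!r}")
        if self.mc_steps_per_hour < 1:
            raise ValueError("mc_steps_per_hour must be >= 1")
        if self.mitosis_duration <= 0:
            raise ValueError("mitosis_duration must be > 0")
        t1, t2, t3 = self.phase_thresholds
        if not 1.0 < t1 < t2 < t3 <= 2.0:
            raise ValueError(f"phase_thresholds must satisfy 1 < t1 < t2 < t3 <= 2, got {self.phase_thresholds}")


@dataclass(frozen=True)
class CellState:
    """Immutable per-cell record stored in trajectory snapshots."""

    id: int
    type_name: str
    x: float
    y: float
    radius: float
    phase: str
    axis: float
    separation: float
    cycle_length: float
    birth_time: float
    growth_recent: int | None
    growth_target: int
    type_size: float = 1.0

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def type(self):  # duck-types CellType enough for geometry helpers
        return _SizeOnly(self.type_size)

    def disks(self) -> list[tuple[np.ndarray, float]]:
        if self.phase == "M":
            half = 0.5 * max(self.separation, 0.0)
            off = half * np.array([math.cos(self.axis), math.sin(self.axis)])
            return [(self.center - off, self.type_size), (self.center + off, self.type_size)]
        return [(self.center, self.radius)]


@dataclass(frozen=True)
class _SizeOnly:
    size: float


@dataclass(frozen=True)
class Event:
    cell_id: int
    kind: str  # "division" | "enter_S" | "enter_M"
    time: float


@dataclass
class Trajectory:
    """Time-indexed snapshots of the population plus the per-cell event log."""

    times: list[float]
    snapshots: list[list[CellState]]
    events: list[Event]
    types: list[CellType]
    params: ModelParams

    def __post_init__(self) -> None:
        self._by_id_cache: dict[int, dict[int, CellState]] = {}

    @property
    def final_time(self) -> float:
        return self.times[-1]

    def nearest_index(self, t: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.times) - t)))

    def snapshot_at(self, t: float, tol: float = 1e-6) -> list[CellState]:
        idx = self.nearest_index(t)
        if abs(self.times[idx] - t) > tol:
            raise KeyError(f"no snapshot recorded at t={t} (nearest is {self.times[idx]})")
        return self.snapshots[idx]

    def cells_by_id(self, idx: int) -> dict[int, CellState]:
        if idx not in self._by_id_cache:
            self._by_id_cache[idx] = {c.id: c for c in self.snapshots[idx]}
        return self._by_id_cache[idx]

    def events_for(self, cell_id: int, kind: str | None = None) -> list[Event]:
        return [e for e in self.events if e.cell_id == cell_id and (kind is None or e.kind == kind)]

    def population_sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.snapshots])

    # -- serialization (JSON Lines, versioned schema) -----------------------

    def save(self, trajectory_path, events_path) -> None:
        with open(trajectory_path, "w", encoding="utf-8") as fh:
            header = {
                "format": "cellsim-trajectory",
                "version": 1,
                "params": _params_to_dict(self.params),
                "types": [vars(t).copy() for t in self.types],
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for t, snap in zip(self.times, self.snapshots):
                rec = {
                    "time": t,
                    "cells": [
                        [c.id, c.type_name, c.x, c.y, c.radius, c.phase, c.axis,
                         c.separation, c.cycle_length, c.birth_time,
                         c.growth_recent, c.growth_target, c.type_size]
                        for c in snap
                    ],
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        with open(events_path, "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(json.dumps({"cell_id": e.cell_id, "kind": e.kind, "time": e.time},
                                    sort_keys=True) + "\n")

    @classmethod
    def load(cls, trajectory_path, events_path) -> "Trajectory":
        times: list[float] = []
        snapshots: list[list[CellState]] = []
        with open(trajectory_path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "cellsim-trajectory":
                raise ValueError(f"{trajectory_path}: not a cellsim trajectory file")
            params = ModelParams(**{**header["params"],
                                    "phase_thresholds": tuple(header["params"]["phase_thresholds"])})
            types = [CellType(**t) for t in header["types"]]
            for line in fh:
                rec = json.loads(line)
                times.append(rec["time"])
                snapshots.append([CellState(*row) for row in rec["cells"]])
        events = []
        with open(events_path, encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                events.append(Event(rec["cell_id"], rec["kind"], rec["time"]))
        return cls(times, snapshots, events, types, params)


def _params_to_dict(params: ModelParams) -> dict:
    d = vars(params).copy()
    d["phase_thresholds"] = list(d["phase_thresholds"])
    return d


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def accept_probability(delta_e: float) -> float:
    """Metropolis acceptance probability min(1, exp(-delta_e))."""
    if delta_e <= 0:
        return 1.0
    return math.exp(-delta_e)


def cycle_length_floor(mitosis_duration: float) -> float:
    """Lower truncation bound for cycle-length draws."""
    return max(2.0 * mitosis_duration, 1.0)


def sample_cycle_length(cell_type: CellType, rng: np.random.Generator,
                        mitosis_duration: float = 1.0) -> float:
    """Draw a cycle length from Normal(cycle_mean, cycle_sd) truncated below.

    The truncation floor ``max(2 * mitosis_duration, 1 h)`` guarantees a
    positive interphase growth schedule.
    """
    floor = cycle_length_floor(mitosis_duration)
    if cell_type.cycle_sd == 0:
        return max(cell_type.cycle_mean, floor)
    a = (floor - cell_type.cycle_mean) / cell_type.cycle_sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=cell_type.cycle_mean,
                                     scale=cell_type.cycle_sd, random_state=rng))


def _disk_pair_energy(d: float, s: float, params: ModelParams) -> float:
    if d < s:
        return params.epsilon_rep * ((s - d) / s) ** 2
    if d < s + params.adhesion_range:
        return -params.epsilon_adh
    return 0.0


def pair_potential(cell_a, cell_b, params: ModelParams) -> float:
    """Interaction energy between two cells, summed over their disk pairs.

    Overlap (d < s, s = sum of radii) is penalized quadratically; a square
    adhesion well of depth ``epsilon_adh`` extends ``adhesion_range`` past
    contact; beyond that the cells do not interact.
    """
    e = 0.0
    for pa, ra in cell_a.disks():
        for pb, rb in cell_b.disks():
            dx = float(pa[0]) - float(pb[0])
            dy = float(pa[1]) - float(pb[1])
            # same kernel as the vectorized path so knife-edge contacts
            # (d == s exactly, e.g. newborn daughters) agree bitwise
            d = math.sqrt(dx * dx + dy * dy)
            e += _disk_pair_energy(d, ra + rb, params)
    return e


def total_energy(cells: Sequence, params: ModelParams) -> float:
    """Brute-force total energy: sum of pair_potential over unordered pairs."""
    e = 0.0
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            e += pair_potential(cells[i], cells[j], params)
    return e


def _largest_remainder_counts(total: int, proportions: Sequence[float]) -> list[int]:
    raw = [total * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _growth_target(cycle_length: float, params: ModelParams) -> int:
    return max(1, round((cycle_length - params.mitosis_duration) * params.mc_steps_per_hour))


def _phase_from_area_ratio(a: float, thresholds: tuple[float, float, float]) -> str:
    t1, t2, t3 = thresholds
    if a < t1:
        return "G1"
    if a < t2:
        return "S"
    if a < t3:
        return "G2"
    return "M"


def seeding_radius(cells: Sequence, density: float) -> float:
    """Radius of the seeding circle such that occupied area / circle area == density."""
    total_area = sum(math.pi * r * r for c in cells for _, r in c.disks())
    return math.sqrt(total_area / (math.pi * density))


def seed_population(params: ModelParams, types: Sequence[CellType],
                    rng: np.random.Generator) -> list[Cell]:
    """Place the initial population uniformly in a circle at the target density.

    Cells are assigned to types by largest-remainder rounding of the type
    proportions and desynchronized by a uniformly random initial progress
    through interphase (which also sets the initial radius).  Positions are
    drawn by dart-throwing with overlap rejection; the seeding-circle area is
    chosen from the realized cell areas, so occupied area / circle area equals
    ``params.density`` exactly by construction.
    """
    prop_sum = sum(t.proportion for t in types)
    if abs(prop_sum - 1.0) > 1e-9:
        raise ValueError(f"type proportions must sum to 1, got {prop_sum}")
    counts = _largest_remainder_counts(params.initial_num, [t.proportion for t in types])

    cells: list[Cell] = []
    next_id = 0
    for ctype, n in zip(types, counts):
        for _ in range(n):
            cycle = sample_cycle_length(ctype, rng, params.mitosis_duration)
            target = _growth_target(cycle, params)
            progress = min(int(rng.uniform() * target), target - 1)
            radius = ctype.size * math.sqrt(1.0 + progress / target)
            cell = Cell(id=next_id, type=ctype, center=np.zeros(2), radius=radius,
                        cycle_length=cycle, birth_time=0.0,
                        growth_accepted=progress, growth_target=target)
            cell.phase = _phase_from_area_ratio(cell.area_ratio, params.phase_thresholds)
            cell.phase_entry_times[cell.phase] = 0.0
            cells.append(cell)
            next_id += 1

    circle_r = seeding_radius(cells, params.density)
    placed_xy: list[np.ndarray] = []
    placed_r: list[float] = []
    budget = 1000 * params.initial_num
    tries = 0
    for cell in cells:
        while True:
            tries += 1
            if tries > budget:
                raise RuntimeError(
                    f"could not place {params.initial_num} non-overlapping cells at "
                    f"density {params.density}: dart-throwing retry budget exhausted "
                    f"(density too high to pack)")
            rmax = circle_r - cell.radius
            # uniform in the disk of radius rmax
            rr = rmax * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            pos = np.array([rr * math.cos(th), rr * math.sin(th)])
            ok = True
            for q, qr in zip(placed_xy, placed_r):
                if np.hypot(*(pos - q)) < cell.radius + qr:
                    ok = False
                    break
            if ok:
                break
        cell.center = pos
        placed_xy.append(pos)
        placed_r.append(cell.radius)
    return cells


def local_density(cell, population: Iterable, radius_factor: float = 3.0,
                  n_radial: int = 24, n_angular: int = 60) -> float:
    """Fraction of the annulus around a cell that is covered by other cells.

    The annulus is ``r_cell < |x - center| <= radius_factor * r_cell``; the
    covered fraction is estimated on a deterministic equal-area polar
    quadrature grid (``n_radial`` x ``n_angular`` nodes) and clamped to [0, 1].
    Accepts live ``Cell`` objects or ``CellState`` snapshot records.
    """
    if radius_factor <= 1.0:
        raise ValueError(f"radius_factor must be > 1, got {radius_factor}")
    center = np.asarray(cell.center, dtype=float)
    r_in = cell.disks()[0][1] if cell.phase != "M" else cell.type.size
    r_in = float(r_in)
    r_out = radius_factor * r_in

    disks_xy: list[np.ndarray] = []
    disks_r: list[float] = []
    for other in population:
        if other.id == cell.id:
            continue
        for p, r in other.disks():
            # prefilter: the disk must be able to reach the annulus
            if np.hypot(*(np.asarray(p) - center)) <= r_out + r:
                disks_xy.append(np.asarray(p, dtype=float))
                disks_r.append(float(r))
    if not disks_xy:
        return 0.0

    # equal-area radial nodes: r_j = sqrt(r_in^2 + (j+.5)/n * (r_out^2-r_in^2))
    j = (np.arange(n_radial) + 0.5) / n_radial
    radii = np.sqrt(r_in ** 2 + j * (r_out ** 2 - r_in ** 2))
    theta = (np.arange(n_angular) + 0.5) / n_angular * 2.0 * math.pi
    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    px = (center[0] + rr * np.cos(tt)).ravel()
    py = (center[1] + rr * np.sin(tt)).ravel()

    dx = px[:, None] - np.array([p[0] for p in disks_xy])[None, :]
    dy = py[:, None] - np.array([p[1] for p in disks_xy])[None, :]
    covered = (dx * dx + dy * dy) <= np.array(disks_r)[None, :] ** 2
    frac = float(covered.any(axis=1).mean())
    return min(1.0, max(0.0, frac))


# ---------------------------------------------------------------------------
# cell-cycle progression
# ---------------------------------------------------------------------------

def progress_cell_cycle(cell: Cell, dt: float, crowding_ok: bool,
                        params: ModelParams, now: float,
                        rng: np.random.Generator) -> list[str]:
    """Advance one cell's cycle bookkeeping over a time step ``dt``.

    In interphase one scheduled area increment is applied iff ``crowding_ok``
    (the increment's Metropolis trial was accepted); the radius follows the
    area-linear doubling schedule and phase is a deterministic function of the
    area ratio.  Returns the emitted event kinds among ``enter_S``,
    ``enter_M`` and ``divide_due`` (division itself — replacing the cell with
    two daughters — is carried out by the population container).
    """
    events: list[str] = []
    if cell.phase != "M":
        if crowding_ok and cell.growth_accepted < cell.growth_target:
            prev = cell.area_ratio
            cell.growth_accepted += 1
            cell.growth_recent += 1
            a = cell.area_ratio
            cell.radius = cell.type.size * math.sqrt(a)
            t1, t2, t3 = params.phase_thresholds
            if prev < t1 <= a:
                cell.phase = "S"
                cell.phase_entry_times["S"] = now
                events.append("enter_S")
            if prev < t2 <= a:
                cell.phase = "G2"
                cell.phase_entry_times["G2"] = now
            if a >= t3:
                cell.phase = "M"
                cell.phase_entry_times["M"] = now
                cell.m_entry = now
                cell.axis = float(rng.uniform(0.0, 2.0 * math.pi))
                cell.separation = 0.0
                events.append("enter_M")
    else:
        if now - cell.m_entry >= params.mitosis_duration - 1e-9:
            events.append("divide_due")
    return events


def divide_cell(cell: Cell, now: float, params: ModelParams,
                rng: np.random.Generator, id_a: int, id_b: int) -> tuple[Cell, Cell]:
    """Split a mitotic cell into two newborn daughters tangent along its axis."""
    r0 = cell.type.size
    axis_vec = np.array([math.cos(cell.axis), math.sin(cell.axis)])
    daughters = []
    for new_id, sign in ((id_a, -1.0), (id_b, 1.0)):
        cycle = sample_cycle_length(cell.type, rng, params.mitosis_duration)
        d = Cell(id=new_id, type=cell.type, center=cell.center + sign * r0 * axis_vec,
                 radius=r0, cycle_length=cycle, birth_time=now,
                 growth_target=_growth_target(cycle, params))
        d.phase_entry_times["G1"] = now
        daughters.append(d)
    return daughters[0], daughters[1]


# ---------------------------------------------------------------------------
# population container with incremental energy tracking
# ---------------------------------------------------------------------------

class Population:
    """Live population plus flattened disk arrays for fast energy evaluation.

    ``self.energy`` is tracked incrementally (updated by the exact dE of each
    accepted change) and must agree with the brute-force total to within
    floating-point accumulation error — this is verified in the test suite.
    """

    def __init__(self, cells: Sequence[Cell], params: ModelParams,
                 boundary_radius: float | None = None):
        self.cells: list[Cell] = list(cells)
        self.params = params
        self.boundary_radius = boundary_radius
        self.time = 0.0
        self.events: list[Event] = []
        self._next_id = max((c.id for c in self.cells), default=-1) + 1
        self._rebuild()
        self.energy = self._total_energy_arrays()

    # -- disk array maintenance --------------------------------------------

    def _rebuild(self) -> None:
        pos, rad, owner = [], [], []
        self._cell_disks: list[list[int]] = []
        for idx, c in enumerate(self.cells):
            rows = []
            for p, r in c.disks():
                rows.append(len(pos))
                pos.append(p)
                rad.append(r)
                owner.append(idx)
            self._cell_disks.append(rows)
        self._dpos = np.array(pos, dtype=float).reshape(-1, 2)
        self._drad = np.array(rad, dtype=float)
        self._downer = np.array(owner, dtype=int)

    def _sync_cell_disks(self, idx: int) -> None:
        rows = self._cell_disks[idx]
        for row, (p, r) in zip(rows, self.cells[idx].disks()):
            self._dpos[row] = p
            self._drad[row] = r

    # -- energy -------------------------------------------------------------

    def _pair_energy_sum(self, d: np.ndarray, s: np.ndarray) -> float:
        p = self.params
        e = 0.0
        overlap = d < s
        if overlap.any():
            x = (s[overlap] - d[overlap]) / s[overlap]
            e += p.epsilon_rep * float((x * x).sum())
        well = (~overlap) & (d < s + p.adhesion_range)
        e -= p.epsilon_adh * float(well.sum())
        return e

    def _energy_of(self, idx: int, pos: np.ndarray | None = None,
                   rad: np.ndarray | None = None) -> float:
        """Energy of cell ``idx``'s disks (current or proposed) vs all others."""
        if pos is None:
            rows = self._cell_disks[idx]
            pos = self._dpos[rows]
            rad = self._drad[rows]
        mask = self._downer != idx
        opos = self._dpos[mask]
        orad = self._drad[mask]
        if opos.shape[0] == 0:
            return 0.0
        e = 0.0
        for k in range(pos.shape[0]):
            diff = opos - pos[k]
            d = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2)
            e += self._pair_energy_sum(d, orad + rad[k])
        return e

    def _total_energy_arrays(self) -> float:
        n = self._dpos.shape[0]
        if n < 2:
            return 0.0
        diff = self._dpos[:, None, :] - self._dpos[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        s = self._drad[:, None] + self._drad[None, :]
        cross = self._downer[:, None] != self._downer[None, :]
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        sel = cross & upper
        return self._pair_energy_sum(d[sel], s[sel])

    def total_energy(self) -> float:
        """Recompute total energy from scratch (oracle for the tracked value)."""
        return self._total_energy_arrays()

    # -- geometry helpers ---------------------------------------------------

    def _outside(self, pos: np.ndarray, rad: np.ndarray) -> bool:
        if self.params.boundary != "circular":
            return False
        R = self.boundary_radius
        return bool(np.any(np.sqrt((pos ** 2).sum(axis=1)) + rad > R + 1e-9))

    def _clamp_inside(self, center: np.ndarray, r: float) -> np.ndarray:
        if self.params.boundary != "circular":
            return center
        R = self.boundary_radius
        norm = float(np.hypot(*center))
        if norm + r > R and norm > 0:
            return center * ((R - r) / norm)
        return center

    # -- structural changes (keep tracked energy consistent) ----------------

    def _enter_m_rebuild(self, idx: int, pos_before: np.ndarray,
                         rad_before: np.ndarray) -> None:
        """Swap cell idx's disk rows for its new dumbbell representation.

        ``pos_before``/``rad_before`` describe the interphase disk whose energy
        is currently folded into the tracked total.
        """
        e_before = self._energy_of(idx, pos_before, rad_before)
        self._rebuild()
        self.energy += self._energy_of(idx) - e_before

    def _divide(self, idx: int, now: float, rng: np.random.Generator) -> tuple[Cell, Cell]:
        parent = self.cells[idx]
        e_parent = self._energy_of(idx)
        da, db = divide_cell(parent, now, self.params, rng,
                             self._next_id, self._next_id + 1)
        self._next_id += 2
        for d in (da, db):
            d.center = self._clamp_inside(d.center, d.radius)
        self.cells[idx] = da
        self.cells.append(db)
        self._rebuild()
        ia, ib = idx, len(self.cells) - 1
        # the da<->db pair is counted by both _energy_of calls; remove one copy
        # using the same vectorized kernel to stay bit-consistent
        rows_a = self._cell_disks[ia]
        rows_b = self._cell_disks[ib]
        e_ab = 0.0
        for k in rows_a:
            diff = self._dpos[rows_b] - self._dpos[k]
            d = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2)
            e_ab += self._pair_energy_sum(d, self._drad[rows_b] + self._drad[k])
        e_new = self._energy_of(ia) + self._energy_of(ib) - e_ab
        self.energy += e_new - e_parent
        return da, db


def monte_carlo_step(population: Population, params: ModelParams,
                     rng: np.random.Generator) -> Population:
    """One sweep of dt = 1/mc_steps_per_hour.

    N random Metropolis trials (N = population size) of migration or, for
    mitotic cells, dumbbell deformation; then a bookkeeping pass that advances
    ages, attempts each cell's scheduled growth increment as its own Metropolis
    trial, and executes due divisions.  Trials that would push a disk through a
    circular boundary wall are rejected outright.
    """
    pop = population
    n = len(pop.cells)
    dt = 1.0 / params.mc_steps_per_hour

    for _ in range(n):
        idx = int(rng.integers(n))
        cell = pop.cells[idx]
        kinds = ["migration"]
        if cell.phase == "M" and cell.separation < 2.0 * cell.type.size:
            kinds.append("deformation")
        kind = kinds[int(rng.integers(len(kinds)))]

        if kind == "migration":
            th = rng.uniform(0.0, 2.0 * math.pi)
            step = rng.uniform(0.0, params.max_migration)
            shift = np.array([step * math.cos(th), step * math.sin(th)])
            rows = pop._cell_disks[idx]
            new_pos = pop._dpos[rows] + shift
            new_rad = pop._drad[rows]
            if pop._outside(new_pos, new_rad):
                continue
            de = pop._energy_of(idx, new_pos, new_rad) - pop._energy_of(idx)
            if rng.random() < accept_probability(de):
                cell.center = cell.center + shift
                pop._sync_cell_disks(idx)
                pop.energy += de
        else:  # deformation: widen the dumbbell
            new_sep = min(2.0 * cell.type.size,
                          cell.separation + rng.uniform(0.0, params.max_migration))
            half = 0.5 * new_sep
            off = half * np.array([math.cos(cell.axis), math.sin(cell.axis)])
            new_pos = np.stack([cell.center - off, cell.center + off])
            new_rad = np.full(2, cell.type.size)
            if pop._outside(new_pos, new_rad):
                continue
            de = pop._energy_of(idx, new_pos, new_rad) - pop._energy_of(idx)
            if rng.random() < accept_probability(de):
                cell.separation = new_sep
                pop._sync_cell_disks(idx)
                pop.energy += de

    # bookkeeping pass: ages, growth schedule, phase transitions, divisions
    now = pop.time + dt
    for idx in range(len(pop.cells)):
        cell = pop.cells[idx]
        crowding_ok = False
        new_pos = new_rad = None
        if cell.phase != "M" and cell.growth_accepted < cell.growth_target:
            a_new = 1.0 + (cell.growth_accepted + 1) / cell.growth_target
            new_rad = np.array([cell.type.size * math.sqrt(a_new)])
            new_pos = cell.center.reshape(1, 2)
            if not pop._outside(new_pos, new_rad):
                de = pop._energy_of(idx, new_pos, new_rad) - pop._energy_of(idx)
                if rng.random() < accept_probability(de):
                    crowding_ok = True
                    pop.energy += de
        emitted = progress_cell_cycle(cell, dt, crowding_ok, params, now, rng)
        if crowding_ok and cell.phase != "M":
            pop._sync_cell_disks(idx)
        for kind in emitted:
            if kind == "enter_S":
                pop.events.append(Event(cell.id, "enter_S", now))
            elif kind == "enter_M":
                pop.events.append(Event(cell.id, "enter_M", now))
                pop._enter_m_rebuild(idx, new_pos, new_rad)
            elif kind == "divide_due":
                parent_id = cell.id
                da, db = pop._divide(idx, now, rng)
                pop.events.append(Event(parent_id, "division", now))
    pop.time = now
    return pop


def realized_division_intervals(trajectory: Trajectory,
                                type_name: str | None = None,
                                cohort_cutoff: float | None = None,
                                include_founders: bool = False) -> np.ndarray:
    """Birth-to-division intervals of cells born during the simulation.

    Founders are excluded by default (their first interval is shortened by
    the t=0 desynchronization; ``include_founders`` keeps them when only
    relative comparisons are needed).  ``cohort_cutoff`` restricts to cells
    born at or before that hour so that censoring (cells that have not
    divided by the end of the run) does not bias the interval distribution.
    """
    birth: dict[int, float] = {}
    tname: dict[int, str] = {}
    for snap in trajectory.snapshots:
        for c in snap:
            if c.id not in birth:
                birth[c.id] = c.birth_time
                tname[c.id] = c.type_name
    division = {e.cell_id: e.time for e in trajectory.events if e.kind == "division"}
    out = []
    for cid, b in birth.items():
        if cid not in division or (b <= 0.0 and not include_founders):
            continue
        if type_name is not None and tname[cid] != type_name:
            continue
        if cohort_cutoff is not None and b > cohort_cutoff:
            continue
        out.append(division[cid] - b)
    return np.array(out)


def run_cell_model(params: ModelParams, types: Sequence[CellType] | None = None,
                   rng: np.random.Generator | None = None) -> Trajectory:
    """Seed a population and run the full Monte Carlo simulation.

    Snapshots are recorded at t = 0 and every ``record_interval`` hours
    (including the final hour); the run is fully reproducible from
    ``params.seed`` when ``rng`` is not supplied.
    """
    if types is None:
        types = [CellType(name="default", cycle_mean=24.0, cycle_sd=2.0, proportion=1.0)]
    if rng is None:
        rng = np.random.default_rng(params.seed)

    cells = seed_population(params, types, rng)
    boundary_radius = params.boundary_radius
    if params.boundary == "circular" and boundary_radius is None:
        boundary_radius = seeding_radius(cells, params.density)
    pop = Population(cells, params, boundary_radius=boundary_radius)

    def take_snapshot(first: bool = False) -> list[CellState]:
        snap = []
        for c in pop.cells:
            snap.append(CellState(
                id=c.id, type_name=c.type.name, x=float(c.center[0]), y=float(c.center[1]),
                radius=c.radius, phase=c.phase, axis=c.axis, separation=c.separation,
                cycle_length=c.cycle_length, birth_time=c.birth_time,
                growth_recent=None if first else c.growth_recent,
                growth_target=c.growth_target, type_size=c.type.size))
            c.growth_recent = 0
        return snap

    times = [0.0]
    snapshots = [take_snapshot(first=True)]
    n_sweeps = round(params.hours * params.mc_steps_per_hour)
    record_every = max(1, round(params.record_interval * params.mc_steps_per_hour))
    for sweep in range(1, n_sweeps + 1):
        monte_carlo_step(pop, params, rng)
        if sweep % record_every == 0 or sweep == n_sweeps:
            times.append(round(sweep / params.mc_steps_per_hour, 9))
            snapshots.append(take_snapshot())
    return Trajectory(times=times, snapshots=snapshots, events=pop.events,
                      types=list(types), params=params)
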