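"""Pathways: gene sets with activity rules and calibrated expression ranges.

A pathway maps the state of a simulated cell (or population) at a time point
to an activity value P in [0, 1], and carries per-gene expression bounds
(gmin, gmax) that the expression layer interpolates between.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import cell_model
from .cell_model import Trajectory

ActivityRule = Callable[[Trajectory, int, float], float]


@dataclass(frozen=True)
class Pathway:
    """Named gene set plus an activity rule and optional calibrated ranges."""

    name: str
    genes: tuple[str, ...]
    activity: ActivityRule
    gmin: np.ndarray | None = None
    gmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"pathway {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name!r} has duplicate gene names")
        object.__setattr__(self, "genes", tuple(self.genes))
        if (self.gmin is None) != (self.gmax is None):
            raise ValueError("gmin and gmax must be set together")
        if self.gmin is not None:
            gmin = np.asarray(self.gmin, dtype=float)
            gmax = np.asarray(self.gmax, dtype=float)
            if gmin.shape != (len(self.genes),) or gmax.shape != (len(self.genes),):
                raise ValueError("gmin/gmax must have one entry per gene")
            if np.any(gmin > gmax):
                raise ValueError(f"pathway {self.name!r}: gmin > gmax for some gene")
            object.__setattr__(self, "gmin", gmin)
            object.__setattr__(self, "gmax", gmax)

    @property
    def calibrated(self) -> bool:
        return self.gmin is not None


@dataclass(frozen=True)
class CalibrationParams:
    """Distributional calibration: per-gene mean ~ Exponential(mean=lam),
    per-gene range width = |Normal(0, stddev)|."""

    lam: float = 20.0
    stddev: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.stddev < 0:
            raise ValueError(f"stddev must be >= 0, got {self.stddev}")


# ---------------------------------------------------------------------------
# activity rules
# ---------------------------------------------------------------------------

def _state_of(trajectory: Trajectory, cell_id: int, t: float):
    idx = trajectory.nearest_index(t)
    by_id = trajectory.cells_by_id(idx)
    if cell_id not in by_id:
        raise KeyError(f"cell {cell_id} not present at t={trajectory.times[idx]}")
    return idx, by_id[cell_id]


def activity_phase_transition(trajectory: Trajectory, cell_id: int, t: float,
                              phase: str, window: float = 1.0) -> float:
    """1 if the cell entered the given phase (S or M) within (t-window, t], else 0."""
    if phase not in ("S", "M"):
        raise ValueError(f"phase must be 'S' or 'M', got {phase!r}")
    _state_of(trajectory, cell_id, t)  # validates the cell id
    kind = "enter_S" if phase == "S" else "enter_M"
    for ev in trajectory.events_for(cell_id, kind):
        if t - window < ev.time <= t:
            return 1.0
    return 0.0


def activity_contact_inhibition(trajectory: Trajectory, cell_id: int, t: float,
                                radius_factor: float = 3.0) -> float:
    """Local density of the cell in the snapshot nearest t."""
    idx, state = _state_of(trajectory, cell_id, t)
    return cell_model.local_density(state, trajectory.snapshots[idx], radius_factor)


def activity_growth_rate(trajectory: Trajectory, cell_id: int, t: float) -> float:
    """Accepted growth over the last recording interval relative to the
    unimpeded schedule (one increment per MC step); M-phase cells score 0."""
    _, state = _state_of(trajectory, cell_id, t)
    if state.phase == "M":
        return 0.0
    if state.growth_recent is None:  # initial snapshot: no history yet
        return 1.0
    params = trajectory.params
    scheduled = params.mc_steps_per_hour * params.record_interval
    return min(1.0, max(0.0, state.growth_recent / scheduled))


def activity_cell_type(trajectory: Trajectory, cell_id: int, t: float,
                       type_name: str) -> float:
    """Binary cell-type identity pathway."""
    if type_name not in {ct.name for ct in trajectory.types}:
        raise KeyError(f"unknown cell type {type_name!r}")
    _, state = _state_of(trajectory, cell_id, t)
    return 1.0 if state.type_name == type_name else 0.0


def phase_transition_rule(phase: str, window: float = 1.0) -> ActivityRule:
    def rule(traj, cell_id, t):
        return activity_phase_transition(traj, cell_id, t, phase=phase, window=window)
    return rule


def contact_inhibition_rule(radius_factor: float = 3.0) -> ActivityRule:
    def rule(traj, cell_id, t):
        return activity_contact_inhibition(traj, cell_id, t, radius_factor=radius_factor)
    return rule


def growth_rate_rule() -> ActivityRule:
    return activity_growth_rate


def cell_type_rule(type_name: str) -> ActivityRule:
    def rule(traj, cell_id, t):
        return activity_cell_type(traj, cell_id, t, type_name=type_name)
    return rule


#: registry used by the config loader: rule name -> factory(**kwargs)
RULES: dict[str, Callable[..., ActivityRule]] = {
    "phase_transition": phase_transition_rule,
    "contact_inhibition": contact_inhibition_rule,
    "growth_rate": growth_rate_rule,
    "cell_type": cell_type_rule,
}


def make_rule(name: str, **kwargs) -> ActivityRule:
    if name not in RULES:
        raise ValueError(f"unknown activity rule {name!r}; known: {sorted(RULES)}")
    return RULES[name](**kwargs)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_from_distribution(pathway: Pathway, params: CalibrationParams,
                                rng: np.random.Generator | None = None) -> Pathway:
    """Draw (gmin, gmax) per gene: mean m ~ Exp(mean=lam), width w = |N(0, sd)|,
    gmin = max(0, m - w/2), gmax = m + w/2."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(pathway.genes)
    m = rng.exponential(scale=params.lam, size=n)
    w = np.abs(rng.normal(0.0, params.stddev, size=n)) if params.stddev > 0 else np.zeros(n)
    gmin = np.maximum(0.0, m - w / 2.0)
    gmax = m + w / 2.0
    return replace(pathway, gmin=gmin, gmax=gmax)


def calibrate_from_reference(pathway: Pathway, reference: pd.DataFrame) -> Pathway:
    """Set gmin/gmax to the 5th/95th percentile of each gene's reference row."""
    missing = [g for g in pathway.genes if g not in reference.index]
    if missing:
        raise KeyError(f"genes missing from reference matrix: {missing}")
    rows = reference.loc[list(pathway.genes)].to_numpy(dtype=float)
    gmin = np.percentile(rows, 5, axis=1)
    gmax = np.percentile(rows, 95, axis=1)
    return replace(pathway, gmin=gmin, gmax=gmax)
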