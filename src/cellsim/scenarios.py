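"""Named worked-example scenarios: parameterized dataset generators.

Three ready-made setups exercise the full pipeline and serve as regression
fixtures and benchmark inputs:

* ``bulk_timecourse`` — bounded-domain growth with phase-transition and
  contact-inhibition pathways, microarray output (150 genes x 43 samples at
  the defaults).
* ``two_type_singlecell`` — fast- and slow-cycling cell types with binary
  identity pathways, single-cell RNA-seq counts with dropout.
* ``confounded_growth`` — two identical cell types plus a growth-rate
  pathway, emitted twice from the same trajectory: once with disjoint gene
  sets and once with the growth pathway annotated to every type gene, so the
  two datasets differ only in annotation overlap.

Default sizes are chosen for desk-scale runtimes and are freely overridable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from . import cell_model, pathways as pw
from .cell_model import CellType, ModelParams, Trajectory, run_cell_model
from .expression import ExpressionResult, GeneExpressionParams, simulate_gene_expression
from .pathways import CalibrationParams, Pathway


@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    results: dict[str, ExpressionResult]
    pathways: dict[str, list[Pathway]]
    seed: int

    @property
    def result(self) -> ExpressionResult:
        (only,) = self.results.values() if len(self.results) == 1 else (None,)
        if only is None:
            raise ValueError("scenario produced multiple datasets; use .results")
        return only


def gene_block(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1:04d}" for i in range(n))


def _merged(defaults: dict, overrides: dict | None) -> dict:
    cfg = dict(defaults)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown override {key!r}; known: {sorted(cfg)}")
        cfg[key] = value
    return cfg


def _calibrate(pathway: Pathway, seed: int, lam: float, stddev: float) -> Pathway:
    cal = CalibrationParams(lam=lam, stddev=stddev)
    return pw.calibrate_from_distribution(
        pathway, cal, substream(seed, f"calibration/{pathway.name}"))


def scenario_bulk_timecourse(overrides: dict | None = None, seed: int = 0) -> ScenarioResult:
    """Bounded 168-hour run; G1->S, G2->M and contact-inhibition pathways
    (50 genes each, 150 total); microarray sampled every 4 h -> 43 columns."""
    cfg = _merged(dict(
        hours=168.0, initial_num=20, density=0.05, cycle_mean=24.0, cycle_sd=4.0,
        genes_per_pathway=50, sample_freq=4.0, n_cells=50, microarray_sd=0.25,
        lam=20.0, stddev=2.0, window=1.0, mc_steps_per_hour=10,
    ), overrides)

    params = ModelParams(initial_num=int(cfg["initial_num"]), hours=cfg["hours"],
                         density=cfg["density"], boundary="circular",
                         mc_steps_per_hour=int(cfg["mc_steps_per_hour"]), seed=seed)
    types = [CellType(name="tumor", cycle_mean=cfg["cycle_mean"],
                      cycle_sd=cfg["cycle_sd"], proportion=1.0)]
    trajectory = run_cell_model(params, types, rng=substream(seed, "model"))

    n = int(cfg["genes_per_pathway"])
    pwys = [
        Pathway("g_to_s", gene_block("GS", n),
                pw.phase_transition_rule("S", window=cfg["window"])),
        Pathway("g_to_m", gene_block("GM", n),
                pw.phase_transition_rule("M", window=cfg["window"])),
        Pathway("contact_inhibition", gene_block("CI", n),
                pw.contact_inhibition_rule()),
    ]
    pwys = [_calibrate(p, seed, cfg["lam"], cfg["stddev"]) for p in pwys]

    eparams = GeneExpressionParams(sample_freq=cfg["sample_freq"],
                                   n_cells=int(cfg["n_cells"]),
                                   microarray_sd=cfg["microarray_sd"], seed=seed)
    result = simulate_gene_expression(trajectory, pwys, eparams)
    return ScenarioResult("bulk_timecourse", trajectory, {"default": result},
                          {"default": pwys}, seed)


def scenario_two_type_singlecell(overrides: dict | None = None,
                                 seed: int = 0) -> ScenarioResult:
    """Two cell types (cycle 12 +/- 4 h vs 36 +/- 4 h, equal proportions) with
    binary identity pathways plus phase-transition pathways; single-cell
    RNA-seq output with negative binomial noise and dropout."""
    cfg = _merged(dict(
        hours=48.0, initial_num=40, density=0.01,
        cycle_mean_a=12.0, cycle_sd_a=4.0, cycle_mean_b=36.0, cycle_sd_b=4.0,
        genes_per_type=50, genes_per_transition=25, sample_freq=8.0, n_cells=30,
        nb_dispersion=0.1, dropout_shape=1.0, lam=1.5, stddev=1.0, window=1.0,
        mc_steps_per_hour=10,
    ), overrides)

    params = ModelParams(initial_num=int(cfg["initial_num"]), hours=cfg["hours"],
                         density=cfg["density"], boundary="unbounded",
                         mc_steps_per_hour=int(cfg["mc_steps_per_hour"]), seed=seed)
    types = [
        CellType(name="A", cycle_mean=cfg["cycle_mean_a"], cycle_sd=cfg["cycle_sd_a"],
                 proportion=0.5),
        CellType(name="B", cycle_mean=cfg["cycle_mean_b"], cycle_sd=cfg["cycle_sd_b"],
                 proportion=0.5),
    ]
    trajectory = run_cell_model(params, types, rng=substream(seed, "model"))

    nt = int(cfg["genes_per_type"])
    nx = int(cfg["genes_per_transition"])
    pwys = [
        Pathway("type_A", gene_block("TA", nt), pw.cell_type_rule("A")),
        Pathway("type_B", gene_block("TB", nt), pw.cell_type_rule("B")),
        Pathway("g_to_s", gene_block("GS", nx),
                pw.phase_transition_rule("S", window=cfg["window"])),
        Pathway("g_to_m", gene_block("GM", nx),
                pw.phase_transition_rule("M", window=cfg["window"])),
    ]
    pwys = [_calibrate(p, seed, cfg["lam"], cfg["stddev"]) for p in pwys]

    eparams = GeneExpressionParams(sample_freq=cfg["sample_freq"],
                                   n_cells=int(cfg["n_cells"]), rnaseq=True,
                                   single_cell=True,
                                   nb_dispersion=cfg["nb_dispersion"],
                                   dropout_shape=cfg["dropout_shape"], seed=seed)
    result = simulate_gene_expression(trajectory, pwys, eparams)
    return ScenarioResult("two_type_singlecell", trajectory, {"default": result},
                          {"default": pwys}, seed)


def scenario_confounded_growth(overrides: dict | None = None, seed: int = 0,
                               confounded: bool | None = None) -> ScenarioResult:
    """Two identical cell types plus a growth-rate pathway, from one trajectory.

    The ``distinct`` dataset gives every pathway its own genes; in the
    ``confounded`` dataset the growth pathway is annotated to the union of
    both type gene sets, so growth confounds cellular identity.  With
    ``confounded`` set, only that one dataset is produced.
    """
    cfg = _merged(dict(
        hours=48.0, initial_num=30, density=0.01, cycle_mean=24.0, cycle_sd=2.0,
        genes_per_type=50, genes_growth=50, sample_freq=8.0, n_cells=30,
        nb_dispersion=0.1, dropout_shape=1.0, lam=1.5, stddev=1.0,
        mc_steps_per_hour=10,
    ), overrides)

    params = ModelParams(initial_num=int(cfg["initial_num"]), hours=cfg["hours"],
                         density=cfg["density"], boundary="unbounded",
                         mc_steps_per_hour=int(cfg["mc_steps_per_hour"]), seed=seed)
    types = [
        CellType(name="X", cycle_mean=cfg["cycle_mean"], cycle_sd=cfg["cycle_sd"],
                 proportion=0.5),
        CellType(name="Y", cycle_mean=cfg["cycle_mean"], cycle_sd=cfg["cycle_sd"],
                 proportion=0.5),
    ]
    trajectory = run_cell_model(params, types, rng=substream(seed, "model"))

    nt = int(cfg["genes_per_type"])
    type_x = gene_block("TX", nt)
    type_y = gene_block("TY", nt)
    growth_distinct = gene_block("GR", int(cfg["genes_growth"]))
    growth_union = type_x + type_y

    eparams = GeneExpressionParams(sample_freq=cfg["sample_freq"],
                                   n_cells=int(cfg["n_cells"]), rnaseq=True,
                                   single_cell=True,
                                   nb_dispersion=cfg["nb_dispersion"],
                                   dropout_shape=cfg["dropout_shape"], seed=seed)

    results: dict[str, ExpressionResult] = {}
    pathway_sets: dict[str, list[Pathway]] = {}
    variants = {"distinct": growth_distinct, "confounded": growth_union}
    if confounded is not None:
        variants = {("confounded" if confounded else "distinct"):
                    variants["confounded" if confounded else "distinct"]}
    for label, growth_genes in variants.items():
        pwys = [
            Pathway("type_X", type_x, pw.cell_type_rule("X")),
            Pathway("type_Y", type_y, pw.cell_type_rule("Y")),
            Pathway("growth", growth_genes, pw.growth_rate_rule()),
        ]
        pwys = [_calibrate(p, seed, cfg["lam"], cfg["stddev"]) for p in pwys]
        results[label] = simulate_gene_expression(trajectory, pwys, eparams)
        pathway_sets[label] = pwys
    return ScenarioResult("confounded_growth", trajectory, results,
                          pathway_sets, seed)


SCENARIOS = {
    "bulk_timecourse": scenario_bulk_timecourse,
    "two_type_singlecell": scenario_two_type_singlecell,
    "confounded_growth": scenario_confounded_growth,
}


def run_scenario(name: str, overrides: dict | None = None, seed: int = 0,
                 **kwargs) -> ScenarioResult:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return SCENARIOS[name](overrides=overrides, seed=seed, **kwargs)
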