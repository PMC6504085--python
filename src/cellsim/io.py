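"""Configuration loading/validation, the end-to-end orchestrator, and
bit-exact writers/readers for all artifact formats.

Formats: YAML/JSON config, TSV dense matrices (genes in the first column,
sample ids in the header), Matrix Market coordinate-integer sparse counts with
10x-style features.tsv/barcodes.tsv, JSON Lines trajectories, optional GMT
gene-set input.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy import io as scipy_io
from scipy import sparse

from ._rng import substream
from . import cell_model, pathways as pw
from .cell_model import CellType, ModelParams, Trajectory
from .expression import ExpressionResult, GeneExpressionParams, simulate_gene_expression
from .pathways import CalibrationParams, Pathway, make_rule


# ---------------------------------------------------------------------------
# config schema (unknown keys rejected, defaults filled)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class CellTypeConfig(_Strict):
    name: str
    size: float = Field(1.0, gt=0)
    cycle_mean: float = Field(24.0, gt=0)
    cycle_sd: float = Field(0.0, ge=0)
    proportion: float = Field(1.0, ge=0, le=1)


class ModelConfig(_Strict):
    initial_num: int = Field(10, ge=1)
    hours: float = Field(24.0, ge=0)
    density: float = Field(0.05, gt=0, lt=1)
    boundary: str = "unbounded"
    boundary_radius: Optional[float] = None
    epsilon_rep: float = 2000.0
    epsilon_adh: float = 0.1
    adhesion_range: float = 0.3
    mc_steps_per_hour: int = Field(10, ge=1)
    max_migration: float = 0.25
    mitosis_duration: float = Field(1.0, gt=0)
    record_interval: float = Field(1.0, gt=0)
    cell_types: list[CellTypeConfig] = Field(
        default_factory=lambda: [CellTypeConfig(name="default", cycle_mean=24.0,
                                                cycle_sd=2.0, proportion=1.0)])


class ActivityConfig(_Strict):
    rule: str
    phase: Optional[str] = None
    window: Optional[float] = None
    radius_factor: Optional[float] = None
    type_name: Optional[str] = None

    def build(self):
        kwargs = {k: v for k, v in self.model_dump().items()
                  if k != "rule" and v is not None}
        return make_rule(self.rule, **kwargs)


class CalibrationConfig(_Strict):
    lam: float = Field(20.0, gt=0, alias="lambda")
    stddev: float = Field(2.0, ge=0)
    reference: Optional[str] = None  # TSV path: calibrate from data instead


class PathwayConfig(_Strict):
    name: str
    genes: Optional[list[str]] = None
    gmt: Optional[str] = None       # GMT file holding the gene set
    gmt_set: Optional[str] = None   # set name within the GMT file (default: name)
    activity: ActivityConfig
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)


class ExpressionConfig(_Strict):
    sample_freq: float = Field(4.0, gt=0)
    n_cells: int = Field(50, ge=1)
    rnaseq: bool = False
    single_cell: bool = False
    microarray_sd: float = Field(0.25, ge=0)
    library_size: float = Field(1e5, gt=0)
    nb_dispersion: float = Field(0.1, ge=0)
    dropout_midpoint: Optional[float] = None
    dropout_shape: float = Field(1.0, gt=0)
    cell_library_mean: float = Field(1e4, gt=0)
    cell_library_log10_sd: float = Field(0.2, ge=0)


class OutputConfig(_Strict):
    directory: str = "cellsim_out"


class RunConfig(_Strict):
    seed: int = 0
    model: ModelConfig = Field(default_factory=ModelConfig)
    pathways: list[PathwayConfig] = Field(default_factory=list)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; defaults are filled."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.model_dump(by_alias=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# config -> domain objects
# ---------------------------------------------------------------------------

def build_model_params(config: RunConfig) -> ModelParams:
    m = config.model
    return ModelParams(
        initial_num=m.initial_num, hours=m.hours, density=m.density,
        boundary=m.boundary, boundary_radius=m.boundary_radius,
        epsilon_rep=m.epsilon_rep, epsilon_adh=m.epsilon_adh,
        adhesion_range=m.adhesion_range, mc_steps_per_hour=m.mc_steps_per_hour,
        max_migration=m.max_migration, mitosis_duration=m.mitosis_duration,
        record_interval=m.record_interval, seed=config.seed)


def build_cell_types(config: RunConfig) -> list[CellType]:
    return [CellType(name=t.name, size=t.size, cycle_mean=t.cycle_mean,
                     cycle_sd=t.cycle_sd, proportion=t.proportion)
            for t in config.model.cell_types]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one gene set per line -> name, description, genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line!r}")
        sets[fields[0]] = fields[2:]
    return sets


def build_pathways(config: RunConfig, base_dir=".") -> list[Pathway]:
    """Instantiate and calibrate every configured pathway."""
    out = []
    for pc in config.pathways:
        if pc.genes is not None:
            genes = pc.genes
        elif pc.gmt is not None:
            sets = read_gmt(Path(base_dir) / pc.gmt)
            set_name = pc.gmt_set or pc.name
            if set_name not in sets:
                raise KeyError(f"gene set {set_name!r} not found in {pc.gmt}")
            genes = sets[set_name]
        else:
            raise ValueError(f"pathway {pc.name!r}: provide 'genes' or 'gmt'")
        pathway = Pathway(name=pc.name, genes=tuple(genes), activity=pc.activity.build())
        if pc.calibration.reference is not None:
            ref = read_matrix_tsv(Path(base_dir) / pc.calibration.reference)
            pathway = pw.calibrate_from_reference(pathway, ref)
        else:
            cal = CalibrationParams(lam=pc.calibration.lam,
                                    stddev=pc.calibration.stddev)
            rng = substream(config.seed, f"calibration/{pc.name}")
            pathway = pw.calibrate_from_distribution(pathway, cal, rng)
        out.append(pathway)
    return out


def build_expression_params(config: RunConfig) -> GeneExpressionParams:
    e = config.expression
    return GeneExpressionParams(
        sample_freq=e.sample_freq, n_cells=e.n_cells, rnaseq=e.rnaseq,
        single_cell=e.single_cell, microarray_sd=e.microarray_sd,
        library_size=e.library_size, nb_dispersion=e.nb_dispersion,
        dropout_midpoint=e.dropout_midpoint, dropout_shape=e.dropout_shape,
        cell_library_mean=e.cell_library_mean,
        cell_library_log10_sd=e.cell_library_log10_sd, seed=config.seed)


def run_simulation(config: RunConfig, base_dir=".") -> tuple[Trajectory, ExpressionResult]:
    """End-to-end: cell model, calibrated pathways, expression simulation.

    One top-level seed governs the run through named sub-streams
    (model / calibration / sampling / noise).
    """
    params = build_model_params(config)
    types = build_cell_types(config)
    trajectory = cell_model.run_cell_model(params, types,
                                           rng=substream(config.seed, "model"))
    pwys = build_pathways(config, base_dir=base_dir)
    eparams = build_expression_params(config)
    result = simulate_gene_expression(trajectory, pwys, eparams)
    return trajectory, result


# ---------------------------------------------------------------------------
# artifact writers / readers
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, outdir) -> None:
    """10x-style triplet: matrix.mtx (coordinate integer) + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    mat = sparse.csc_matrix(counts.to_numpy(dtype=np.int64))
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in counts.index), encoding="utf-8")
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in counts.columns), encoding="utf-8")


def read_counts_mtx(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = scipy_io.mmread(str(outdir / "matrix.mtx")).toarray()
    features = (outdir / "features.tsv").read_text(encoding="utf-8").split()
    barcodes = (outdir / "barcodes.tsv").read_text(encoding="utf-8").split()
    return pd.DataFrame(mat, index=features, columns=barcodes)


def write_outputs(result: ExpressionResult, trajectory: Trajectory,
                  config: RunConfig, outdir) -> list[str]:
    """Write all artifacts for a completed run; returns the file names written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    write_config(config, outdir / "config_effective.yaml")
    written.append("config_effective.yaml")

    trajectory.save(outdir / "trajectory.jsonl", outdir / "events.jsonl")
    written += ["trajectory.jsonl", "events.jsonl"]

    write_matrix_tsv(result.mean_matrix, outdir / "mean_expression.tsv")
    write_matrix_tsv(result.activity_matrix, outdir / "activity.tsv",
                     index_label="pathway")
    result.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    written += ["mean_expression.tsv", "activity.tsv", "sample_meta.tsv"]

    if result.platform == "singlecell":
        write_counts_mtx(result.noisy_matrix, outdir)
        written += ["matrix.mtx", "features.tsv", "barcodes.tsv"]
    else:
        write_matrix_tsv(result.noisy_matrix, outdir / "expression.tsv")
        written.append("expression.tsv")
    return written
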